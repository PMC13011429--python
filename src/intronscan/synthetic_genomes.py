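"""Synthetic genomes with planted intron-containing tRNA loci and full truth.

Every other module is testable offline against fixtures built here: genomes
are i.i.d. random background with planted pre-tRNA loci (an intron obeying
the group I boundary chemistry inserted into a validator-accepted tRNA),
candidate hit tables with configurable boundary jitter, an intron-less
homolog database degraded to a target identity only outside the anticodon,
and a truth table re-derivable from the emitted sequences by slicing (the
generator audits this at generation time).

Trap fixtures reproduce the two-frame ambiguity geometry: an intron ending
in GTG planted at site 35/36 after the invariant U33 leaves a second frame
(a-2, b-2) that also satisfies every boundary rule but reads a different
anticodon — only the homolog database can arbitrate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .boundary_resolver import AragornIntron
from .formats_io import GenomeRecord, TabularHit, revcomp, write_cm_tblout, write_fasta
from .locus_classifier import IntronLocus, ProteinHit
from .short_align import TrnaRef, write_trna_db
from .trna_model import (ACCEPTOR_LEN, AC_STEM_LEN, LOOP_LEN, SPACER1, SPACER2,
                         T_STEM_LEN, CAU_AMBIGUITY, decode_anticodon,
                         site_to_loop_index)

BASES = "ACGT"
STOPS = ("TAA", "TAG", "TGA")

# fixed generator geometry (one of the shapes the validator accepts)
D_STEM = 4
D_LOOP = 8
VAR = 4


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


@dataclass(frozen=True)
class TrnaLayout:
    """A generated mature tRNA with the anticodon loop location recorded."""

    seq: str
    loop_start: int
    anticodon: str

    @property
    def amino_acid(self) -> str:
        if self.anticodon == "CAT":
            return "/".join(CAU_AMBIGUITY)
        return decode_anticodon(self.anticodon)


def make_trna(anticodon: str, seed) -> TrnaLayout:
    """Generate a random validator-accepted tRNA carrying *anticodon* at 34-36.

    Stems are fully Watson-Crick complementary by construction; the anticodon
    loop is C-U-anticodon-A-A (positions 32-38) with U33 invariant.
    """
    if len(anticodon) != 3 or any(c not in BASES for c in anticodon):
        raise ValueError(f"anticodon must be a 3-mer over ACGT, got {anticodon!r}")
    rng = _rng(seed)
    acceptor5 = _rand_seq(rng, ACCEPTOR_LEN)
    spacer1 = _rand_seq(rng, SPACER1)
    d5 = _rand_seq(rng, D_STEM)
    d_loop = _rand_seq(rng, D_LOOP)
    spacer2 = _rand_seq(rng, SPACER2)
    ac5 = _rand_seq(rng, AC_STEM_LEN)
    loop = "CT" + anticodon + "AA"
    var = _rand_seq(rng, VAR)
    t5 = _rand_seq(rng, T_STEM_LEN)
    t_loop = "TTCGAAT"
    seq = (acceptor5 + spacer1 + d5 + d_loop + revcomp(d5) + spacer2
           + ac5 + loop + revcomp(ac5) + var
           + t5 + t_loop + revcomp(t5) + revcomp(acceptor5))
    loop_start = ACCEPTOR_LEN + SPACER1 + 2 * D_STEM + D_LOOP + SPACER2 + AC_STEM_LEN
    assert seq[loop_start : loop_start + LOOP_LEN] == loop
    return TrnaLayout(seq=seq, loop_start=loop_start, anticodon=anticodon)


@dataclass(frozen=True)
class PlantedIntron:
    """A pre-tRNA (exon1 + intron + exon2) with its splice frame recorded."""

    pre_seq: str
    a: int                 # exon1 end within pre_seq (0-based exclusive)
    b: int                 # intron end within pre_seq
    mature_seq: str
    site: str
    anticodon: str
    trap: bool
    heg: bool
    orf: Optional[tuple[int, int]] = None     # ORF interval within the intron


def _random_intron(rng: np.random.Generator, length: int, trap: bool,
                   orf_len: Optional[int]) -> tuple[str, Optional[tuple[int, int]]]:
    if length < 50:
        raise ValueError("intron length must be >= 50")
    intron = list(_rand_seq(rng, length - 1) + "G")
    if trap:
        intron[-3:] = "GTG"
    orf_interval = None
    if orf_len is not None:
        if orf_len % 3 or orf_len < 6:
            raise ValueError("ORF length must be a positive multiple of 3")
        # stop codon in-frame just before the ORF so the scan starts exactly here
        start = int(rng.integers(3, length - orf_len - 4))
        codons = ["ATG"]
        while len(codons) < orf_len // 3 - 1:
            c = _rand_seq(rng, 3)
            if c not in STOPS:
                codons.append(c)
        codons.append("TAA")
        payload = "TAA" + "".join(codons)
        intron[start - 3 : start - 3 + len(payload)] = payload
        orf_interval = (start, start + orf_len)
        if trap:
            intron[-3:] = "GTG"
        intron[-1] = "G"
    return "".join(intron), orf_interval


def insert_intron(trna: TrnaLayout, site: str, length: int, seed,
                  trap: bool = False, heg: bool = False) -> PlantedIntron:
    """Insert a random intron into a tRNA at a named anticodon-loop site.

    The last 5'-exon base must be U(T): loop bases outside the anticodon are
    adjusted to guarantee it, while a cut inside the anticodon requires the
    anticodon itself to carry the T (e.g. GTT/GTC for 35/36) — otherwise an
    error. Trap fixtures require site 35/36 and force the intron to end in
    GTG; ``heg`` forces length > 500 and plants a 330-nt ORF.
    """
    rng = _rng(seed)
    idx = site_to_loop_index(site)
    cut = trna.loop_start + idx
    seq = list(trna.seq)
    loop_off = idx - 1                      # 0-based offset of the last exon base
    if loop_off in (0, 5):                  # positions 32 and 37: adjustable
        seq[cut - 1] = "T"
    elif seq[cut - 1] != "T":
        raise ValueError(
            f"site {site} incompatible with anticodon {trna.anticodon!r}: "
            "no U immediately 5' of the cut")
    if trap and site != "35/36":
        raise ValueError("trap fixtures use the 35/36 two-frame geometry")
    if heg:
        length = max(length, 520)
    mature = "".join(seq)
    intron, orf = _random_intron(rng, length, trap, 330 if heg else None)
    pre = mature[:cut] + intron + mature[cut:]
    planted = PlantedIntron(pre_seq=pre, a=cut, b=cut + length, mature_seq=mature,
                            site=site, anticodon=trna.anticodon, trap=trap,
                            heg=heg, orf=orf)
    assert pre[planted.a - 1] == "T" and pre[planted.b - 1] == "G"
    assert pre[: planted.a] + pre[planted.b :] == mature
    return planted


def mutate_outside_anticodon(trna: TrnaLayout, identity: float,
                             rng: np.random.Generator) -> str:
    """Degrade a mature tRNA to a target identity, sparing the anticodon triplet.

    Mutations are stratified along the sequence (one per equal-length chunk)
    so divergence is spread roughly uniformly, as in real homolog pairs,
    rather than clumping into one exon by chance.
    """
    if not 0 < identity <= 1:
        raise ValueError("identity must be in (0, 1]")
    seq = list(trna.seq)
    protected = set(range(trna.loop_start + 2, trna.loop_start + 5))
    candidates = [i for i in range(len(seq)) if i not in protected]
    n_mut = min(round((1 - identity) * len(seq)), len(candidates))
    if n_mut == 0:
        return trna.seq
    chunks = np.array_split(np.array(candidates), n_mut)
    for chunk in chunks:
        pos = int(rng.choice(chunk))
        seq[pos] = str(rng.choice([b for b in BASES if b != seq[pos]]))
    return "".join(seq)


# ---------------------------------------------------------------------------
# single-locus fixtures

@dataclass(frozen=True)
class TruthRecord:
    """Planted ground truth for one intron locus (genome coordinates, 0-based)."""

    genome_id: str
    phylum: str
    gene_start: int
    gene_end: int
    intron_start: int
    intron_end: int
    strand: str
    site: str
    anticodon: str
    amino_acid: str
    intron_class: str
    intron_length: int
    trap: bool
    heg: bool


@dataclass
class LocusFixture:
    """One genome with one planted intron locus plus its candidate and refs."""

    genome: GenomeRecord
    hit: TabularHit
    truth: TruthRecord
    true_ref: TrnaRef
    shifted_ref: Optional[TrnaRef]
    decoys: list[TrnaRef]

    @property
    def full_db(self) -> list[TrnaRef]:
        return [self.true_ref, *self.decoys]

    @property
    def ablated_db(self) -> list[TrnaRef]:
        assert self.shifted_ref is not None, "not a trap fixture"
        return [self.shifted_ref, *self.decoys]


_SITE_ANTICODONS = {
    "32/33": ("GCA", "GAA", "GTG"),
    "33/34": ("CAT", "GAA", "GTA"),
    "34/35": ("TAA", "TAG"),
    "35/36": ("GTT", "GTC"),
    "36/37": ("CCT", "TCT"),
    "37/38": ("GCA", "GTT"),
}


def _shifted_mature(planted: PlantedIntron) -> str:
    """The mature sequence read by the two-base-shifted (a-2, b-2) trap frame."""
    pre = planted.pre_seq
    return pre[: planted.a - 2] + pre[planted.b - 2 :]


def _decoy_refs(rng: np.random.Generator, tag: str, n: int = 3) -> list[TrnaRef]:
    anticodons = ("AAA", "CCG", "GGC", "TTC")
    out = []
    for k in range(n):
        ac = anticodons[k % len(anticodons)]
        t = make_trna(ac, rng)
        out.append(TrnaRef(id=f"{tag}_decoy{k}", amino_acid=decode_anticodon(ac),
                           anticodon=ac, seq=t.seq))
    return out


def make_locus_fixture(seed, *, site: str = "35/36", anticodon: Optional[str] = None,
                       intron_length: Optional[int] = None, trap: bool = False,
                       heg: bool = False, jitter: int = 0,
                       db_identity: float = 1.0, strand: Optional[str] = None,
                       genome_id: str = "synth", phylum: str = "SynthPhylum",
                       ) -> LocusFixture:
    """Build one planted-locus genome with candidate hit, truth and homolog refs."""
    rng = _rng(seed)
    if anticodon is None:
        anticodon = str(rng.choice(_SITE_ANTICODONS[site]))
    if intron_length is None:
        intron_length = int(rng.integers(184, 895))
    if strand is None:
        strand = "+" if rng.random() < 0.5 else "-"
    trna = make_trna(anticodon, rng)
    planted = insert_intron(trna, site, intron_length, rng, trap=trap, heg=heg)
    up = _rand_seq(rng, 700)
    down = _rand_seq(rng, 700)
    forward = up + planted.pre_seq + down
    gene_start_f = len(up)
    gene_end_f = len(up) + len(planted.pre_seq)
    a_f = len(up) + planted.a
    b_f = len(up) + planted.b
    if strand == "+":
        genome_seq = forward
        gene = (gene_start_f, gene_end_f)
        intron_iv = (a_f, b_f)
    else:
        genome_seq = revcomp(forward)
        L = len(forward)
        gene = (L - gene_end_f, L - gene_start_f)
        intron_iv = (L - b_f, L - a_f)
    genome = GenomeRecord(id=genome_id, seq=genome_seq)
    truth = TruthRecord(
        genome_id=genome_id, phylum=phylum, gene_start=gene[0], gene_end=gene[1],
        intron_start=intron_iv[0], intron_end=intron_iv[1], strand=strand,
        site=site, anticodon=anticodon,
        amino_acid=("/".join(CAU_AMBIGUITY) if anticodon == "CAT"
                    else decode_anticodon(anticodon)),
        intron_class="groupI", intron_length=len(planted.pre_seq) - len(planted.mature_seq),
        trap=trap, heg=heg,
    )
    _audit_truth(genome, truth, planted)
    ja = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
    jb = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
    hit = TabularHit(
        target_id=genome_id, model="RF00028",
        start=intron_iv[0] + 1 + ja, stop=intron_iv[1] + jb, strand=strand,
        score=float(rng.uniform(40, 90)), evalue=float(10 ** rng.uniform(-10, -5)),
    )
    ref_seq = (trna.seq if db_identity >= 1.0
               else mutate_outside_anticodon(trna, db_identity, rng))
    true_ref = TrnaRef(id=f"{genome_id}_ref", amino_acid=truth.amino_acid.split("/")[0],
                       anticodon=anticodon, seq=ref_seq)
    shifted_ref = None
    if trap:
        shifted = _shifted_mature(planted)
        sh_anticodon = shifted[trna.loop_start + 2 : trna.loop_start + 5]
        shifted_ref = TrnaRef(id=f"{genome_id}_shifted_ref",
                              amino_acid=decode_anticodon(sh_anticodon),
                              anticodon=sh_anticodon, seq=shifted)
    return LocusFixture(genome=genome, hit=hit, truth=truth, true_ref=true_ref,
                        shifted_ref=shifted_ref, decoys=_decoy_refs(rng, genome_id))


def _audit_truth(genome: GenomeRecord, truth: TruthRecord,
                 planted: PlantedIntron) -> None:
    """Self-consistency audit: the truth record must be re-derivable by slicing."""
    sub = genome.seq[truth.gene_start : truth.gene_end]
    if truth.strand == "-":
        sub = revcomp(sub)
    assert sub == planted.pre_seq, "truth/gene slice mismatch"
    if truth.strand == "+":
        a = truth.intron_start - truth.gene_start
        b = truth.intron_end - truth.gene_start
    else:
        a = truth.gene_end - truth.intron_end
        b = truth.gene_end - truth.intron_start
    assert (a, b) == (planted.a, planted.b), "truth/intron coordinates mismatch"
    assert sub[:a] + sub[b:] == planted.mature_seq, "splice audit failed"


# ---------------------------------------------------------------------------
# multi-genome survey

@dataclass(frozen=True)
class PhylumProfile:
    name: str
    weight: float
    groupI_rate: float
    site_probs: dict[str, float]
    groupII_rate: float = 0.0
    subgroup: str = "IC"          # dominant subgroup emitted for this phylum


DEFAULT_PROFILE = (
    PhylumProfile("Patescibacteria", 0.3, 0.4,
                  {"35/36": 0.7, "33/34": 0.2, "34/35": 0.1}, subgroup="IA"),
    PhylumProfile("Cyanobacteriota", 0.3, 0.4,
                  {"33/34": 0.4, "34/35": 0.3, "36/37": 0.3},
                  groupII_rate=0.2, subgroup="IC"),
    PhylumProfile("Pseudomonadota", 0.25, 0.15,
                  {"33/34": 0.3, "34/35": 0.4, "36/37": 0.3}, subgroup="IC"),
    PhylumProfile("Bacillota", 0.15, 0.1,
                  {"33/34": 0.5, "36/37": 0.5}, subgroup="IB"),
)


@dataclass
class SurveyFixture:
    genomes: dict[str, GenomeRecord]
    hits: list[TabularHit]                  # group I candidate hits (with jitter)
    rf00029_hits: list[TabularHit]          # group II model hits
    aragorn_introns: list[AragornIntron]
    trna_db: list[TrnaRef]
    truth: pd.DataFrame
    phylum_map: dict[str, str]
    subgroup_scores: pd.DataFrame           # (intron_id, model, score)


def make_survey(n_genomes: int, phylum_profile: Sequence[PhylumProfile] = DEFAULT_PROFILE,
                seed=0, *, jitter: int = 2, db_identity: float = 0.95) -> SurveyFixture:
    """Generate a multi-genome survey with planted per-phylum intron structure.

    Intron rates, the 35/36 enrichment in one phylum, intron lengths mostly
    short with a >500 bp HEG-carrying tail, and subgroup score tables all
    follow the profile; candidate hits carry boundary jitter to exercise the
    resolver window. Fixed seed gives byte-identical output.
    """
    rng = _rng(seed)
    genomes: dict[str, GenomeRecord] = {}
    hits: list[TabularHit] = []
    rf29: list[TabularHit] = []
    aragorn: list[AragornIntron] = []
    refs: list[TrnaRef] = []
    truth_rows: list[dict] = []
    phylum_map: dict[str, str] = {}
    subgroup_rows: list[dict] = []

    weights = np.array([p.weight for p in phylum_profile], dtype=float)
    weights /= weights.sum()
    counts = np.floor(weights * n_genomes).astype(int)
    while counts.sum() < n_genomes:
        counts[int(np.argmax(weights * n_genomes - counts))] += 1

    intron_counter = 0
    gidx = 0
    for profile, count in zip(phylum_profile, counts):
        for _ in range(count):
            gid = f"G{gidx:04d}"
            gidx += 1
            phylum_map[gid] = profile.name
            segments = [_rand_seq(rng, 900)]
            pos = 900
            n_gi = 0
            if rng.random() < profile.groupI_rate:
                n_gi = 1 + int(rng.poisson(0.6))
            sites = list(profile.site_probs)
            probs = np.array([profile.site_probs[s] for s in sites])
            for _ in range(n_gi):
                site = str(rng.choice(sites, p=probs / probs.sum()))
                anticodon = str(rng.choice(_SITE_ANTICODONS[site]))
                if rng.random() < 0.96:
                    length = int(rng.integers(184, 401))
                    heg = False
                else:
                    length = int(rng.integers(520, 895))
                    heg = True
                trna = make_trna(anticodon, rng)
                planted = insert_intron(trna, site, length, rng, heg=heg)
                strand = "+" if rng.random() < 0.5 else "-"
                piece = planted.pre_seq if strand == "+" else revcomp(planted.pre_seq)
                gene_f = (pos, pos + len(planted.pre_seq))
                if strand == "+":
                    intron_iv = (pos + planted.a, pos + planted.b)
                else:
                    intron_iv = (gene_f[1] - planted.b, gene_f[1] - planted.a)
                segments.append(piece)
                pos += len(piece)
                segments.append(_rand_seq(rng, 900))
                pos += 900
                intron_id = f"i{intron_counter:05d}"
                intron_counter += 1
                ja = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
                jb = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
                hits.append(TabularHit(
                    target_id=gid, model=str(rng.choice(("RF00028", "gpI_bact_tRNA"))),
                    start=intron_iv[0] + 1 + ja, stop=intron_iv[1] + jb, strand=strand,
                    score=float(rng.uniform(40, 90)),
                    evalue=float(10 ** rng.uniform(-10, -5))))
                amino = (str(rng.choice(CAU_AMBIGUITY)) if anticodon == "CAT"
                         else decode_anticodon(anticodon))
                refs.append(TrnaRef(
                    id=f"{gid}_{intron_id}_ref", amino_acid=amino, anticodon=anticodon,
                    seq=mutate_outside_anticodon(trna, db_identity, rng)))
                truth_rows.append(dict(
                    genome_id=gid, phylum=profile.name, intron_id=intron_id,
                    gene_start=gene_f[0],
                    gene_end=gene_f[1], intron_start=intron_iv[0],
                    intron_end=intron_iv[1], strand=strand, site=site,
                    anticodon=anticodon, amino_acid=amino, intron_class="groupI",
                    intron_length=length, trap=False, heg=heg,
                    subgroup=profile.subgroup, category="tRNA"))
                subgroup_rows.append(dict(intron_id=intron_id,
                                          model=profile.subgroup,
                                          score=float(rng.uniform(60, 90))))
                other = str(rng.choice([s for s in SUBGROUP_MODELS
                                        if s != profile.subgroup]))
                subgroup_rows.append(dict(intron_id=intron_id, model=other,
                                          score=float(rng.uniform(20, 50))))
            if rng.random() < profile.groupII_rate:
                site = str(rng.choice(("35/36", "D-loop")))
                anticodon = "GTT" if site != "D-loop" else "GAA"
                trna = make_trna(anticodon, rng)
                length = int(rng.integers(400, 800))
                intron_seq = _rand_seq(rng, length)
                if site == "D-loop":
                    cut = ACCEPTOR_LEN + SPACER1 + D_STEM + 4
                else:
                    cut = trna.loop_start + site_to_loop_index(site)
                    if trna.seq[cut - 1] != "T":
                        cut = trna.loop_start + 2     # fall back inside the loop
                pre = trna.seq[:cut] + intron_seq + trna.seq[cut:]
                gene_f = (pos, pos + len(pre))
                intron_iv = (pos + cut, pos + cut + length)
                segments.append(pre)
                pos += len(pre)
                segments.append(_rand_seq(rng, 900))
                pos += 900
                intron_id = f"i{intron_counter:05d}"
                intron_counter += 1
                aragorn.append(AragornIntron(genome_id=gid, start=intron_iv[0],
                                             end=intron_iv[1], strand="+"))
                rf29.append(TabularHit(
                    target_id=gid, model="RF00029",
                    start=intron_iv[0] + 1 + int(rng.integers(0, 30)),
                    stop=intron_iv[1] - int(rng.integers(0, 30)), strand="+",
                    score=float(rng.uniform(40, 90)),
                    evalue=float(10 ** rng.uniform(-10, -5))))
                refs.append(TrnaRef(id=f"{gid}_{intron_id}_ref",
                                    amino_acid=decode_anticodon(anticodon),
                                    anticodon=anticodon,
                                    seq=mutate_outside_anticodon(trna, db_identity, rng)))
                truth_rows.append(dict(
                    genome_id=gid, phylum=profile.name, intron_id=intron_id,
                    gene_start=gene_f[0], gene_end=gene_f[1],
                    intron_start=intron_iv[0], intron_end=intron_iv[1], strand="+",
                    site=site, anticodon=anticodon,
                    amino_acid=decode_anticodon(anticodon), intron_class="groupII",
                    intron_length=length, trap=False, heg=False,
                    subgroup="unassigned", category="tRNA"))
            genomes[gid] = GenomeRecord(id=gid, seq="".join(segments))

    refs.extend(_decoy_refs(rng, "survey"))
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    subgroup_scores = pd.DataFrame(subgroup_rows,
                                   columns=["intron_id", "model", "score"])
    fixture = SurveyFixture(genomes=genomes, hits=hits, rf00029_hits=rf29,
                            aragorn_introns=aragorn, trna_db=refs, truth=truth,
                            phylum_map=phylum_map, subgroup_scores=subgroup_scores)
    _audit_survey(fixture)
    return fixture


SUBGROUP_MODELS = ("IA", "IB", "IC", "ID", "IE")

TRUTH_COLUMNS = [
    "genome_id", "phylum", "intron_id", "gene_start", "gene_end", "intron_start",
    "intron_end", "strand", "site", "anticodon", "amino_acid", "intron_class",
    "intron_length", "trap", "heg", "subgroup", "category",
]


def _audit_survey(fx: SurveyFixture) -> None:
    """Re-derive every truth row from the emitted sequences by slicing."""
    for row in fx.truth.itertuples():
        seq = fx.genomes[row.genome_id].seq
        gene = seq[row.gene_start : row.gene_end]
        if row.strand == "-":
            gene = revcomp(gene)
        assert len(gene) == row.gene_end - row.gene_start
        if row.strand == "+":
            a = row.intron_start - row.gene_start
            b = row.intron_end - row.gene_start
        else:
            a = row.gene_end - row.intron_end
            b = row.gene_end - row.intron_start
        assert b - a == row.intron_length, "intron length mismatch"
        if row.intron_class == "groupI":
            assert gene[a - 1] == "T" and gene[b - 1] == "G", "boundary chemistry"


def survey_to_table(fixture: SurveyFixture) -> pd.DataFrame:
    """The truth as a survey_stats table (generator bookkeeping, not detection)."""
    t = fixture.truth
    return pd.DataFrame({
        "genome_id": t["genome_id"], "phylum": t["phylum"],
        "intron_id": t["intron_id"], "intron_class": t["intron_class"],
        "category": t["category"], "site": t["site"],
        "amino_acid": t["amino_acid"], "anticodon": t["anticodon"],
        "length": t["intron_length"], "subgroup": t["subgroup"],
        "has_heg": t["heg"],
    })


def write_survey(fixture: SurveyFixture, out_dir: str | Path) -> dict[str, Path]:
    """Emit the survey as plain-text files (FASTA, tblout, TSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genomes": out / "genomes.fasta",
        "hits": out / "hits.tbl",
        "rf00029_hits": out / "rf00029_hits.tbl",
        "trna_db": out / "trna_db.fasta",
        "truth": out / "truth.tsv",
        "phyla": out / "phyla.tsv",
        "aragorn": out / "aragorn_introns.tsv",
        "subgroup_scores": out / "subgroup_scores.tsv",
    }
    write_fasta(fixture.genomes.values(), paths["genomes"])
    write_cm_tblout(fixture.hits, paths["hits"])
    write_cm_tblout(fixture.rf00029_hits, paths["rf00029_hits"])
    write_trna_db(fixture.trna_db, paths["trna_db"])
    fixture.truth.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["phyla"], "w") as fh:
        fh.write("genome_id\tphylum\n")
        for gid, phylum in fixture.phylum_map.items():
            fh.write(f"{gid}\t{phylum}\n")
    with open(paths["aragorn"], "w") as fh:
        fh.write("genome_id\tstart\tend\tstrand\n")
        for ai in fixture.aragorn_introns:
            fh.write(f"{ai.genome_id}\t{ai.start + 1}\t{ai.end}\t{ai.strand}\n")
    fixture.subgroup_scores.to_csv(paths["subgroup_scores"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# host-classification fixtures

@dataclass
class HostFixture:
    loci: list[IntronLocus]
    rrna_hits: list[TabularHit]
    tmrna_hits: list[TabularHit]
    cds_hits: list[ProteinHit]
    tnpb_hits: list[ProteinHit]
    truth: dict[str, str]          # intron_id -> planted category


def make_host_fixture(n_per_category: int = 20, seed=0) -> HostFixture:
    """Plant rRNA/tmRNA/CDS/IStron-like/unknown intron loci with evidence tables.

    Each locus sits on its own genome; evidence intervals are placed inside
    the classifier's stated flanks (1,000 nt for structured RNAs, 4,000 nt
    for protein homology and TnpB vicinity).
    """
    rng = _rng(seed)
    fx = HostFixture([], [], [], [], [], {})
    categories = ["rRNA", "tmRNA", "CDS", "IStron-like", "unknown"]
    k = 0
    for category in categories:
        for _ in range(n_per_category):
            gid = f"host{k:04d}"
            iid = f"hx{k:04d}"
            k += 1
            start = 5000
            end = start + int(rng.integers(184, 895))
            fx.loci.append(IntronLocus(intron_id=iid, genome_id=gid,
                                       start=start, end=end))
            fx.truth[iid] = category
            if category == "rRNA":
                model = str(rng.choice(("RF00177", "RF02541")))
                fx.rrna_hits.append(TabularHit(gid, model, start - 800, start,
                                               "+", 100.0, 1e-20))
                fx.rrna_hits.append(TabularHit(gid, model, end + 1,
                                               end + int(rng.integers(200, 900)),
                                               "+", 100.0, 1e-20))
            elif category == "tmRNA":
                if rng.random() < 0.5:
                    fx.tmrna_hits.append(TabularHit(gid, "RF00023", start - 300,
                                                    start, "+", 80.0, 1e-15))
                    fx.tmrna_hits.append(TabularHit(gid, "RF00023", end + 1,
                                                    end + 120, "+", 40.0, 1e-8))
                else:
                    # partial: one-sided hit abutting the boundary + short match
                    fx.tmrna_hits.append(TabularHit(gid, "RF00023", start - 280,
                                                    start - int(rng.integers(0, 25)),
                                                    "+", 80.0, 1e-15))
                    fx.tmrna_hits.append(TabularHit(gid, "RF00023", end + 5,
                                                    end + 40, "+", 12.0, 1e-3))
            elif category == "CDS":
                subject = f"prot{k}"
                fx.cds_hits.append(ProteinHit(gid, subject, start - 2500,
                                              start - int(rng.integers(0, 900))))
                fx.cds_hits.append(ProteinHit(gid, subject,
                                              end + int(rng.integers(0, 900)),
                                              end + 2500))
            elif category == "IStron-like":
                off = int(rng.integers(100, 3000))
                fx.tnpb_hits.append(ProteinHit(gid, "TnpB", end + off,
                                               end + off + 1200))
    return fx
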
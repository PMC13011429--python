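"""Host-gene classification of detected introns and HEG/ORF annotation.

Each intron is assigned exactly one host category from external evidence
tables sharing the genome coordinate system:

* tRNA      — resolved upstream by the boundary resolver (highest priority);
* rRNA      — same rRNA covariance model hit on both sides within 1,000 nt;
* tmRNA     — tmRNA model hits on both sides, or a one-sided hit whose edge
              abuts the intron boundary plus a short same-model match on the
              opposite side (partial evidence, flagged);
* CDS       — protein homology (blastx-style) to the same subject on both
              sides within 4,000 nt;
* IStron-like — a TnpB-related gene in the vicinity (the CDS flank);
* unknown   — none of the above.

Introns longer than 500 bp are scanned for ORFs (sense strand, code table
11) that may encode homing endonucleases; domain labels from an external
hmmscan-style table are attached at E < 0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

RRNA_FLANK = 1000
CDS_FLANK = 4000
TMRNA_BOUNDARY_TOL = 30    # nt between a one-sided tmRNA hit edge and the intron
TMRNA_MIN_OPPOSITE = 20    # nt of same-model match required on the opposite side
HEG_MIN_INTRON_LEN = 500
DEFAULT_MIN_ORF_LEN = 300
DOMAIN_EVALUE_MAX = 0.01

CATEGORIES = ("tRNA", "rRNA", "tmRNA", "CDS", "IStron-like", "unknown")

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

# Pfam families of interest for intron-encoded proteins
DOMAIN_FAMILIES = {
    "PF03161": "LAGLIDADG",
    "PF11645": "PD-(D/E)XK",
    "PF01844": "HNH",
    "PF00078": "RT",
}


@dataclass(frozen=True)
class IntronLocus:
    """A detected intron interval on a genome (0-based half-open)."""

    intron_id: str
    genome_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ProteinHit:
    """A protein-homology (blastx-style) or TnpB-annotation interval.

    ``start``/``end`` are 0-based half-open genome coordinates.
    """

    target_id: str
    subject_id: str
    start: int
    end: int


@dataclass(frozen=True)
class Evidence:
    side: str        # "5'" or "3'"
    source: str      # model / subject / element id
    start: int
    end: int


@dataclass(frozen=True)
class HostClassification:
    intron_id: str
    category: str
    evidence: tuple[Evidence, ...] = ()
    note: str = ""


def _side_hits(hits, locus: IntronLocus, flank: int, key) -> dict[str, list]:
    """Split hits of this genome into those overlapping the 5'/3' flank windows."""
    up = (locus.start - flank, locus.start)
    down = (locus.end, locus.end + flank)
    out = {"5'": [], "3'": []}
    for h in hits:
        if getattr(h, "target_id", getattr(h, "genome_id", None)) != locus.genome_id:
            continue
        s, e = key(h)
        if max(s, up[0]) < min(e, up[1]):
            out["5'"].append(h)
        if max(s, down[0]) < min(e, down[1]):
            out["3'"].append(h)
    return out


def _hit_interval(h) -> tuple[int, int]:
    if hasattr(h, "interval"):
        return h.interval
    return h.start, h.end


def classify_host(intron: IntronLocus,
                  rrna_hits: Sequence = (),
                  tmrna_hits: Sequence = (),
                  cds_hits: Sequence = (),
                  tnpb_hits: Sequence = (),
                  *, is_trna: bool = False,
                  rrna_flank: int = RRNA_FLANK,
                  cds_flank: int = CDS_FLANK) -> HostClassification:
    """Assign the single host category of an intron.

    Priority: tRNA > rRNA > tmRNA > CDS > IStron-like > unknown. Conflicting
    both-sides evidence for two categories resolves to the higher-priority
    one with the conflict logged.
    """
    if is_trna:
        return HostClassification(intron.intron_id, "tRNA",
                                  (Evidence("5'", "boundary_resolver", intron.start, intron.end),))

    verdicts: list[HostClassification] = []

    sides = _side_hits(rrna_hits, intron, rrna_flank, _hit_interval)
    models5 = {h.model for h in sides["5'"]}
    models3 = {h.model for h in sides["3'"]}
    shared = models5 & models3
    if shared:
        model = sorted(shared)[0]
        ev = tuple(
            Evidence(side, h.model, *_hit_interval(h))
            for side in ("5'", "3'") for h in sides[side] if h.model == model
        )
        verdicts.append(HostClassification(intron.intron_id, "rRNA", ev))

    sides = _side_hits(tmrna_hits, intron, rrna_flank, _hit_interval)
    if sides["5'"] and sides["3'"]:
        ev = tuple(Evidence(side, h.model, *_hit_interval(h))
                   for side in ("5'", "3'") for h in sides[side])
        shortest = min(e.end - e.start for e in ev)
        note = "tmRNA (partial evidence)" if shortest < 50 else ""
        verdicts.append(HostClassification(intron.intron_id, "tmRNA", ev, note=note))
    elif sides["5'"] or sides["3'"]:
        # one-sided detection: accept when the hit abuts the intron boundary
        # and a short same-model match exists on the opposite side
        one_side = "5'" if sides["5'"] else "3'"
        other = "3'" if one_side == "5'" else "5'"
        hit = sides[one_side][0]
        s, e = _hit_interval(hit)
        boundary = intron.start if one_side == "5'" else intron.end
        edge = e if one_side == "5'" else s
        opposite = [h for h in tmrna_hits
                    if getattr(h, "target_id", None) == intron.genome_id
                    and h.model == hit.model
                    and _hit_interval(h)[1] - _hit_interval(h)[0] >= TMRNA_MIN_OPPOSITE
                    and (max(_hit_interval(h)[0], intron.end) < min(_hit_interval(h)[1], intron.end + rrna_flank)
                         if one_side == "5'" else
                         max(_hit_interval(h)[0], intron.start - rrna_flank) < min(_hit_interval(h)[1], intron.start))]
        if abs(edge - boundary) <= TMRNA_BOUNDARY_TOL and opposite:
            ev = (Evidence(one_side, hit.model, s, e),
                  Evidence(other, opposite[0].model, *_hit_interval(opposite[0])))
            verdicts.append(HostClassification(intron.intron_id, "tmRNA", ev,
                                               note="tmRNA (partial evidence)"))

    sides = _side_hits(cds_hits, intron, cds_flank, _hit_interval)
    subj5 = {h.subject_id for h in sides["5'"]}
    subj3 = {h.subject_id for h in sides["3'"]}
    shared_subj = subj5 & subj3
    if shared_subj:
        subject = sorted(shared_subj)[0]
        ev = tuple(Evidence(side, h.subject_id, *_hit_interval(h))
                   for side in ("5'", "3'") for h in sides[side]
                   if h.subject_id == subject)
        verdicts.append(HostClassification(intron.intron_id, "CDS", ev))

    vicinity = (intron.start - cds_flank, intron.end + cds_flank)
    tnpb_near = [
        h for h in tnpb_hits
        if getattr(h, "target_id", getattr(h, "genome_id", None)) == intron.genome_id
        and max(_hit_interval(h)[0], vicinity[0]) < min(_hit_interval(h)[1], vicinity[1])
    ]
    if tnpb_near:
        side = "5'" if _hit_interval(tnpb_near[0])[1] <= intron.start else "3'"
        ev = tuple(Evidence(side, getattr(h, "model", "TnpB"), *_hit_interval(h))
                   for h in tnpb_near)
        verdicts.append(HostClassification(intron.intron_id, "IStron-like", ev))

    if not verdicts:
        return HostClassification(intron.intron_id, "unknown")
    if len(verdicts) > 1:
        logger.info("intron %s: conflicting evidence for %s; keeping %s",
                    intron.intron_id, [v.category for v in verdicts],
                    verdicts[0].category)
    order = {c: i for i, c in enumerate(CATEGORIES)}
    return min(verdicts, key=lambda v: order[v.category])


@dataclass(frozen=True)
class OrfRecord:
    """An open reading frame within an intron sequence (0-based half-open)."""

    orf_id: str
    start: int
    end: int
    frame: int
    length: int              # nt, including the stop codon when present
    protein_len: int         # aa, stop excluded
    has_stop: bool
    domain_label: str = ""


def find_orfs(intron_seq: str, min_len_nt: int = DEFAULT_MIN_ORF_LEN,
              id_prefix: str = "orf") -> list[OrfRecord]:
    """Sense-strand ORFs of at least *min_len_nt* nt, all three frames.

    Starts at ATG/GTG/TTG, ends at the first in-frame stop (TAA/TAG/TGA,
    code table 11) or at the intron end when unterminated. Sorted by length
    descending, ties by start position. Callers apply the >500 bp group I
    length rule before invoking this.
    """
    found: list[tuple[int, int, int, bool]] = []
    n = len(intron_seq)
    for frame in range(3):
        pos = frame
        open_start: Optional[int] = None
        while pos + 3 <= n:
            codon = intron_seq[pos : pos + 3]
            if open_start is None and codon in START_CODONS:
                open_start = pos
            elif open_start is not None and codon in STOP_CODONS:
                found.append((open_start, pos + 3, frame, True))
                open_start = None
            pos += 3
        if open_start is not None:
            end = open_start + ((n - open_start) // 3) * 3
            found.append((open_start, end, frame, False))
    found = [f for f in found if f[1] - f[0] >= min_len_nt]
    found.sort(key=lambda f: (-(f[1] - f[0]), f[0]))
    return [
        OrfRecord(
            orf_id=f"{id_prefix}{i}", start=s, end=e, frame=fr,
            length=e - s, protein_len=(e - s) // 3 - (1 if stop else 0),
            has_stop=stop,
        )
        for i, (s, e, fr, stop) in enumerate(found, 1)
    ]


def scan_intron_orfs(intron_seq: str, intron_class: str = "groupI",
                     min_len_nt: int = DEFAULT_MIN_ORF_LEN,
                     id_prefix: str = "orf") -> list[OrfRecord]:
    """ORF scan with the length gate: group I introns are scanned only when
    longer than 500 bp (shorter ones cannot house a homing endonuclease);
    group II introns are always scanned for their intron-encoded protein."""
    if intron_class == "groupI" and len(intron_seq) <= HEG_MIN_INTRON_LEN:
        return []
    return find_orfs(intron_seq, min_len_nt, id_prefix)


@dataclass(frozen=True)
class DomainRow:
    """One hmmscan-style tabular row linking an ORF to a Pfam domain."""

    orf_id: str
    accession: str
    name: str
    evalue: float


def parse_domain_table(path) -> list[DomainRow]:
    """Parse a minimal hmmscan ``--tblout``-like table.

    Columns: domain name, accession, ORF id (query), E-value — the leading
    columns of the hmmscan tblout layout.
    """
    rows: list[DomainRow] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.split()
            try:
                rows.append(DomainRow(orf_id=f[2], accession=f[1].split(".")[0],
                                      name=f[0], evalue=float(f[4])))
            except (IndexError, ValueError):
                logger.warning("skipping malformed domain row: %r", line)
    return rows


def attach_domains(orfs: Sequence[OrfRecord], domain_table: Iterable[DomainRow],
                   evalue_max: float = DOMAIN_EVALUE_MAX) -> list[OrfRecord]:
    """Attach the best sub-threshold domain label to each ORF.

    Families of interest (LAGLIDADG, PD-(D/E)XK, HNH, RT) get their family
    name; other domains keep their reported name. Rows naming unknown ORFs
    are logged and skipped.
    """
    known = {o.orf_id for o in orfs}
    best: dict[str, DomainRow] = {}
    for row in domain_table:
        if row.orf_id not in known:
            logger.warning("domain row for unknown ORF %r skipped", row.orf_id)
            continue
        if row.evalue >= evalue_max:
            continue
        if row.orf_id not in best or row.evalue < best[row.orf_id].evalue:
            best[row.orf_id] = row
    out = []
    for orf in orfs:
        row = best.get(orf.orf_id)
        if row is None:
            out.append(orf)
        else:
            label = DOMAIN_FAMILIES.get(row.accession, row.name)
            out.append(replace(orf, domain_label=label))
    return out
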
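"""Readers/writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open throughout the package; every
emitted file (GFF3, call TSV) is 1-based inclusive. Hit tables in the
Infernal ``--tblout`` dialect are normalized into :class:`TabularHit` with
ascending coordinates and an explicit strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .boundary_resolver import ResolvedCall

logger = logging.getLogger(__name__)

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N self-paired)."""
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class GenomeRecord:
    """A named DNA sequence over {A,C,G,T,N}."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TabularHit:
    """One covariance-model hit, coordinates as read from file (1-based inclusive,
    start <= stop after minus-strand normalization)."""

    target_id: str
    model: str
    start: int
    stop: int
    strand: str
    score: float
    evalue: float

    @property
    def interval(self) -> tuple[int, int]:
        """0-based half-open interval on the target."""
        return self.start - 1, self.stop

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.start < 1 or self.stop < self.start:
            raise ValueError(f"bad hit coordinates {self.start}..{self.stop}")


def read_fasta(path: str | Path) -> dict[str, GenomeRecord]:
    """Load a DNA FASTA into an ordered id->record mapping.

    Sequences are uppercased and U is mapped to T. Duplicate ids and empty
    files are hard errors.
    """
    records: dict[str, GenomeRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper().replace("U", "T")
        records[rec.id] = GenomeRecord(id=rec.id, seq=seq)
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_cm_tblout(path: str | Path, evalue_max: float = 1e-4) -> list[TabularHit]:
    """Parse an Infernal ``--tblout`` file, keeping hits with E-value < *evalue_max*.

    Minus-strand rows (seq_from > seq_to) are normalized so start < stop with
    the strand recorded. Malformed rows are skipped with a warning; an empty
    result is not an error.
    """
    if evalue_max <= 0:
        raise ValueError("evalue_max must be > 0")
    hits: list[TabularHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            try:
                target, model = f[0], f[2]
                seq_from, seq_to = int(f[7]), int(f[8])
                strand = f[9]
                score, evalue = float(f[14]), float(f[15])
                if strand not in "+-":
                    raise ValueError(f"bad strand {strand!r}")
            except (IndexError, ValueError) as exc:
                logger.warning("%s:%d: skipping malformed tblout row (%s)", path, lineno, exc)
                continue
            if evalue >= evalue_max:
                continue
            start, stop = sorted((seq_from, seq_to))
            hits.append(
                TabularHit(
                    target_id=target, model=model, start=start, stop=stop,
                    strand=strand, score=score, evalue=evalue,
                )
            )
    return hits


def write_cm_tblout(hits: Iterable[TabularHit], path: str | Path) -> None:
    """Emit hits in the Infernal --tblout column layout (enough columns to re-read)."""
    with open(path, "w") as fh:
        fh.write("#target name\taccession\tquery name\taccession\tmdl\tmdl from\tmdl to"
                 "\tseq from\tseq to\tstrand\ttrunc\tpass\tgc\tbias\tscore\tE-value\tinc\n")
        for h in hits:
            seq_from, seq_to = (h.start, h.stop) if h.strand == "+" else (h.stop, h.start)
            fh.write(
                f"{h.target_id} - {h.model} - cm 1 1 {seq_from} {seq_to} {h.strand} "
                f"no 1 0.50 0.0 {h.score:.1f} {h.evalue:.3g} !\n"
            )


def _reciprocal_overlap(a: TabularHit, b: TabularHit) -> float:
    ov = min(a.stop, b.stop) - max(a.start, b.start) + 1
    if ov <= 0:
        return 0.0
    return min(ov / (a.stop - a.start + 1), ov / (b.stop - b.start + 1))


def dedup_hits(hits: Sequence[TabularHit], overlap_frac: float = 0.5) -> list[TabularHit]:
    """Collapse hits covering the same locus, keeping the higher-score hit.

    Two hits are "the same locus" when they share target and strand and have
    reciprocal overlap >= *overlap_frac*. Greedy by score (ties: lower E-value,
    then leftmost start); idempotent. Output sorted by (target, start).
    """
    if not 0 < overlap_frac <= 1:
        raise ValueError("overlap_frac must be in (0, 1]")
    ranked = sorted(hits, key=lambda h: (-h.score, h.evalue, h.start, h.target_id))
    kept: list[TabularHit] = []
    for h in ranked:
        if any(
            k.target_id == h.target_id
            and k.strand == h.strand
            and _reciprocal_overlap(k, h) >= overlap_frac
            for k in kept
        ):
            continue
        kept.append(h)
    return sorted(kept, key=lambda h: (h.target_id, h.start, h.stop))


# ---------------------------------------------------------------------------
# Resolved-call output

CALLS_TSV_COLUMNS = [
    "genome_id", "strand", "gene_start", "gene_end", "intron_start", "intron_end",
    "site", "anticodon", "amino_acid", "intron_class", "trna_seq", "intron_seq",
    "shift_a", "shift_b", "top_homolog", "homolog_score", "homolog_identity",
    "homolog_coverage", "cau_resolved", "ambiguous_boundary_resolved", "status",
]


def write_calls_tsv(calls: Sequence["ResolvedCall"], path: str | Path) -> None:
    """Write resolved calls as TSV (1-based inclusive genome coordinates)."""
    with open(path, "w") as fh:
        fh.write("\t".join(CALLS_TSV_COLUMNS) + "\n")
        for c in calls:
            row = [
                c.genome_id, c.strand,
                str(c.gene_start + 1), str(c.gene_end),
                str(c.intron_start + 1), str(c.intron_end),
                c.site, c.anticodon, c.amino_acid, c.intron_class,
                c.trna_seq, c.intron_seq,
                str(c.shift_a), str(c.shift_b),
                # str() on floats round-trips exactly; never truncate here
                c.top_homolog, str(c.homolog_score), str(c.homolog_identity),
                str(c.homolog_coverage),
                str(int(c.cau_resolved)), str(int(c.ambiguous_boundary_resolved)),
                c.status,
            ]
            fh.write("\t".join(row) + "\n")


def read_calls_tsv(path: str | Path) -> list["ResolvedCall"]:
    """Read back a calls TSV written by :func:`write_calls_tsv` (exact round trip)."""
    from .boundary_resolver import ResolvedCall

    calls: list[ResolvedCall] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != CALLS_TSV_COLUMNS:
            raise ValueError(f"unexpected calls TSV header in {path}")
        for line in fh:
            v = dict(zip(CALLS_TSV_COLUMNS, line.rstrip("\n").split("\t")))
            calls.append(
                ResolvedCall(
                    genome_id=v["genome_id"], strand=v["strand"],
                    gene_start=int(v["gene_start"]) - 1, gene_end=int(v["gene_end"]),
                    intron_start=int(v["intron_start"]) - 1, intron_end=int(v["intron_end"]),
                    site=v["site"], anticodon=v["anticodon"], amino_acid=v["amino_acid"],
                    intron_class=v["intron_class"], trna_seq=v["trna_seq"],
                    intron_seq=v["intron_seq"],
                    shift_a=int(v["shift_a"]), shift_b=int(v["shift_b"]),
                    top_homolog=v["top_homolog"], homolog_score=float(v["homolog_score"]),
                    homolog_identity=float(v["homolog_identity"]),
                    homolog_coverage=float(v["homolog_coverage"]),
                    cau_resolved=bool(int(v["cau_resolved"])),
                    ambiguous_boundary_resolved=bool(int(v["ambiguous_boundary_resolved"])),
                    status=v["status"],
                )
            )
    return calls


def write_gff3(calls: Sequence["ResolvedCall"], path: str | Path) -> None:
    """Write paired GFF3 features: a tRNA gene and its intron child feature."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, c in enumerate(calls, 1):
            gid = f"trna{i:05d}"
            attrs = (
                f"ID={gid};anticodon={c.anticodon};amino_acid={c.amino_acid};"
                f"site={c.site};intron_class={c.intron_class}"
            )
            fh.write(
                f"{c.genome_id}\tintronscan\ttRNA\t{c.gene_start + 1}\t{c.gene_end}\t"
                f"{c.homolog_score:g}\t{c.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{c.genome_id}\tintronscan\tintron\t{c.intron_start + 1}\t{c.intron_end}\t"
                f".\t{c.strand}\t.\tID={gid}.intron;Parent={gid};site={c.site};"
                f"intron_class={c.intron_class}\n"
            )


def read_gff3_intervals(path: str | Path) -> list[tuple[str, str, int, int, str]]:
    """Read (seqid, type, start0, end, strand) tuples from a GFF3 file."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8:
                raise ValueError(f"malformed GFF3 row in {path}: {line!r}")
            out.append((f[0], f[2], int(f[3]) - 1, int(f[4]), f[6]))
    return out
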
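"""Local alignment of short nucleotide sequences with identity/coverage reporting.

Scoring mimics blastn-short defaults: match +1, mismatch -3, a gap of length
k costs 5 + 2(k-1), and a hit requires a shared exact word of 7 nt between
query and subject. Only the ranking matters for homolog-based boundary
disambiguation, so no E-value model is attached; ties are broken by identity
and then subject id. The optimal-alignment engine is Bio.Align.PairwiseAligner
in local mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from Bio import Align


@dataclass(frozen=True)
class AlignParams:
    match: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -5.0     # score of the first gap column
    gap_extend: float = -2.0   # score of each further gap column
    word_size: int = 7


DEFAULT_PARAMS = AlignParams()


@dataclass(frozen=True)
class AlignmentHit:
    """A scored local alignment of a query against one reference subject."""

    subject_id: str
    score: float
    identity: float      # % of aligned columns that match (gaps count as columns)
    coverage: float      # % of the query length covered by the aligned span
    q_interval: tuple[int, int]
    s_interval: tuple[int, int]
    subject_anticodon: str = ""
    subject_amino_acid: str = ""


@dataclass(frozen=True)
class TrnaRef:
    """An intron-less reference tRNA with its header labels."""

    id: str
    amino_acid: str
    anticodon: str
    seq: str


def load_trna_db(path: str | Path) -> list[TrnaRef]:
    """Load a reference FASTA whose headers follow ``>{id}|{amino_acid}|{anticodon}``."""
    refs: list[TrnaRef] = []
    seen: set[str] = set()
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split()[0].split("|")
        if len(parts) != 3 or not all(parts):
            raise ValueError(
                f"unparseable tRNA reference header {rec.description!r}: "
                "expected id|amino_acid|anticodon"
            )
        rid, aa, anticodon = parts
        if rid in seen:
            raise ValueError(f"duplicate reference id {rid!r} in {path}")
        seen.add(rid)
        refs.append(TrnaRef(rid, aa, anticodon.upper().replace("U", "T"),
                            str(rec.seq).upper().replace("U", "T")))
    if not refs:
        raise ValueError(f"no reference records in {path}")
    return refs


def write_trna_db(refs: Sequence[TrnaRef], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in refs:
            fh.write(f">{r.id}|{r.amino_acid}|{r.anticodon}\n{r.seq}\n")


def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = params.match
    al.mismatch_score = params.mismatch
    al.open_gap_score = params.gap_open
    al.extend_gap_score = params.gap_extend
    return al


def _has_seed(query: str, subject: str, word_size: int) -> bool:
    if len(query) < word_size or len(subject) < word_size:
        return False
    words = {query[i : i + word_size] for i in range(len(query) - word_size + 1)}
    return any(subject[i : i + word_size] in words
               for i in range(len(subject) - word_size + 1))


def local_align(query: str, subject: str,
                params: AlignParams = DEFAULT_PARAMS) -> Optional[AlignmentHit]:
    """Optimal local alignment of *query* against *subject*, or None.

    None is returned when the sequences share no exact word of
    ``params.word_size`` nt (the seed requirement) or the best local score is
    not positive. Identity counts matches over all aligned columns including
    gap columns; coverage is the aligned query span over the query length.
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    if not _has_seed(query, subject, params.word_size):
        return None
    aln = _aligner(params).align(query, subject)
    if aln.score <= 0:
        return None
    best = aln[0]
    blocks_q, blocks_s = best.aligned
    matches = 0
    mismatches = 0
    gap_cols = 0
    prev_q = prev_s = None
    for (qs, qe), (ss, se) in zip(blocks_q, blocks_s):
        if prev_q is not None:
            gap_cols += (qs - prev_q) + (ss - prev_s)
        for k in range(qe - qs):
            if query[qs + k] == subject[ss + k]:
                matches += 1
            else:
                mismatches += 1
        prev_q, prev_s = qe, se
    columns = matches + mismatches + gap_cols
    q_span = (int(blocks_q[0][0]), int(blocks_q[-1][1]))
    s_span = (int(blocks_s[0][0]), int(blocks_s[-1][1]))
    return AlignmentHit(
        subject_id="",
        score=float(aln.score),
        identity=100.0 * matches / columns if columns else 0.0,
        coverage=100.0 * (q_span[1] - q_span[0]) / len(query),
        q_interval=q_span,
        s_interval=s_span,
    )


def search_db(query: str, reference_set: Sequence[TrnaRef], min_coverage: float = 75.0,
              params: AlignParams = DEFAULT_PARAMS) -> list[AlignmentHit]:
    """Rank reference tRNAs by local-alignment score against *query*.

    Hits must cover more than *min_coverage* % of the query. Sorted by score
    descending, ties by identity descending then subject id.
    """
    hits: list[AlignmentHit] = []
    for ref in reference_set:
        hit = local_align(query, ref.seq, params)
        if hit is None or hit.coverage <= min_coverage:
            continue
        hits.append(
            AlignmentHit(
                subject_id=ref.id, score=hit.score, identity=hit.identity,
                coverage=hit.coverage, q_interval=hit.q_interval,
                s_interval=hit.s_interval, subject_anticodon=ref.anticodon,
                subject_amino_acid=ref.amino_acid,
            )
        )
    hits.sort(key=lambda h: (-h.score, -h.identity, h.subject_id))
    return hits
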
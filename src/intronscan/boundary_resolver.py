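"""Splice-boundary resolution for intron-interrupted tRNA genes.

This is the heart of the pipeline. A covariance-model hit only approximates
the intron's extent, so the exact splice boundaries (a, b) are recovered by
exhaustive enumeration in a window around the predicted interval, subject to
the biological rules of group I splicing in tRNA genes:

* the 5' exon ends immediately after a U (T on the coding strand),
* the intron ends at a G (the omega-G whose recognition completes ligation),
* the ligated exons fold into a canonical cloverleaf with the splice
  junction inside the 7-nt anticodon loop.

These rules alone cannot always pick a unique frame — shifting both
boundaries by two nucleotides can convert, e.g., a tRNA-Asn(GUU) read at
35/36 into a tRNA-Thr(UGU) read at 33/34, a known failure mode of
intron-aware annotators. The arbiter is the best-scoring intron-less
homolog: hypotheses are ranked by homolog alignment score, then agreement of
the spliced anticodon with the homolog's, then minimal boundary shift, then
leftmost position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .formats_io import GenomeRecord, TabularHit, revcomp
from .short_align import (AlignParams, AlignmentHit, DEFAULT_PARAMS, TrnaRef,
                          local_align, search_db)
from .trna_model import (CloverleafFold, anticodon_of, best_fold_with_loop_at,
                         decode_anticodon, fold_cloverleaf, insertion_site_label)

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 400
DEFAULT_WINDOW = 10
MIN_INTRON_LEN = 50
DEFAULT_MIN_COVERAGE = 75.0
# The flanking gate looks for short exon fragments (often ~30 nt, possibly
# diverged) that must abut the candidate interval, so it scans only the
# proximal part of each flank, with a smaller seed word and a lower score
# floor than the homolog ranking step; false positives only admit candidates
# that the homolog-verification stage rejects anyway.
FLANK_HIT_MIN_SCORE = 10.0
FLANK_PARAMS = AlignParams(word_size=4)
FLANK_SCAN_WIDTH = 80


@dataclass(frozen=True)
class IntronCandidate:
    """A genomic interval proposed as an intron (0-based half-open)."""

    genome_id: str
    start: int
    end: int
    strand: str
    source_model: str
    score: float = 0.0
    evalue: float = 0.0


def candidate_from_hit(hit: TabularHit) -> IntronCandidate:
    s, e = hit.interval
    return IntronCandidate(
        genome_id=hit.target_id, start=s, end=e, strand=hit.strand,
        source_model=hit.model, score=hit.score, evalue=hit.evalue,
    )


@dataclass(frozen=True)
class Context:
    """Plus-strand-normalized genomic context around a candidate intron."""

    genome_id: str
    seq: str
    genome_start: int
    genome_end: int
    strand: str
    cand: tuple[int, int]        # candidate interval in context coordinates
    truncated_5: bool = False
    truncated_3: bool = False

    def to_genome(self, interval: tuple[int, int]) -> tuple[int, int]:
        """Map a context interval back to forward genome coordinates."""
        x, y = interval
        if self.strand == "+":
            return self.genome_start + x, self.genome_start + y
        return self.genome_end - y, self.genome_end - x


@dataclass(frozen=True)
class BoundaryHypothesis:
    """One candidate (a, b) splice frame: exon1 ends at a, intron is [a, b)."""

    a: int
    b: int
    spliced_seq: str             # full context with the intron excised
    fold: CloverleafFold
    site: str
    anticodon: str

    @property
    def trna_seq(self) -> str:
        return self.spliced_seq[self.fold.start : self.fold.end]


@dataclass(frozen=True)
class ResolvedCall:
    """A resolved intron-containing tRNA gene in genome coordinates (0-based)."""

    genome_id: str
    strand: str
    gene_start: int
    gene_end: int
    intron_start: int
    intron_end: int
    site: str
    anticodon: str
    amino_acid: str
    intron_class: str
    trna_seq: str
    intron_seq: str
    shift_a: int
    shift_b: int
    top_homolog: str
    homolog_score: float
    homolog_identity: float
    homolog_coverage: float
    cau_resolved: bool = False
    ambiguous_boundary_resolved: bool = False
    status: str = "resolved"

    @property
    def exon1_len(self) -> int:
        if self.strand == "+":
            return self.intron_start - self.gene_start
        return self.gene_end - self.intron_end


def extract_context(candidate: IntronCandidate, genome: GenomeRecord,
                    flank: int = DEFAULT_FLANK) -> Context:
    """Cut *flank* nt of genomic context either side of the candidate.

    Minus-strand candidates are reverse-complemented so all downstream logic
    is strand-free; contexts clipped by a contig end carry truncation flags.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    gs = max(0, candidate.start - flank)
    ge = min(genome.length, candidate.end + flank)
    raw = genome.seq[gs:ge]
    left_trunc = candidate.start - flank < 0
    right_trunc = candidate.end + flank > genome.length
    if candidate.strand == "+":
        cand = (candidate.start - gs, candidate.end - gs)
        return Context(candidate.genome_id, raw, gs, ge, "+", cand,
                       truncated_5=left_trunc, truncated_3=right_trunc)
    cand = (ge - candidate.end, ge - candidate.start)
    return Context(candidate.genome_id, revcomp(raw), gs, ge, "-", cand,
                   truncated_5=right_trunc, truncated_3=left_trunc)


def flanking_trna_check(context: Context, trna_db: Sequence[TrnaRef],
                        params: AlignParams = FLANK_PARAMS,
                        min_score: float = FLANK_HIT_MIN_SCORE,
                        ) -> tuple[bool, dict[str, list[str]]]:
    """Require tRNA homology on both sides of the candidate interval.

    Each reference is locally aligned against the proximal part of the
    upstream and downstream flank sequences; a side counts as supported when
    any reference reaches ``min_score``. Returns the verdict plus the
    supporting reference ids per side.
    """
    up = context.seq[max(0, context.cand[0] - FLANK_SCAN_WIDTH) : context.cand[0]]
    down = context.seq[context.cand[1] : context.cand[1] + FLANK_SCAN_WIDTH]
    sides: dict[str, list[str]] = {"5'": [], "3'": []}
    for ref in trna_db:
        for side, flank_seq in (("5'", up), ("3'", down)):
            if len(flank_seq) < params.word_size:
                continue
            hit = local_align(ref.seq, flank_seq, params)
            if hit is not None and hit.score >= min_score:
                sides[side].append(ref.id)
    return bool(sides["5'"] and sides["3'"]), sides


def _hypothesis_at(context_seq: str, a: int, b: int) -> Optional[BoundaryHypothesis]:
    """Check the U/G and cloverleaf rules for one (a, b) frame."""
    if a < 1 or b > len(context_seq) or context_seq[a - 1] != "T" or context_seq[b - 1] != "G":
        return None
    spliced = context_seq[:a] + context_seq[b:]
    best: Optional[CloverleafFold] = None
    # the junction (index a in the spliced sequence) must fall strictly
    # inside the 7-nt anticodon loop: loop positions 32-37 may end the exon
    for loop_start in range(a - 6, a):
        if loop_start < 0:
            continue
        fold = best_fold_with_loop_at(spliced, loop_start)
        if fold is None:
            continue
        if best is None or fold.n_pairs > best.n_pairs:
            best = fold
    if best is None:
        return None
    loop_index = a - best.anticodon_loop[0]          # 1-based within the loop
    site = insertion_site_label(loop_index)
    assignment = anticodon_of(best, spliced)
    return BoundaryHypothesis(a=a, b=b, spliced_seq=spliced, fold=best,
                              site=site, anticodon=assignment.anticodon)


def enumerate_boundaries(context_seq: str, candidate_interval: tuple[int, int],
                         window: int = DEFAULT_WINDOW,
                         min_intron_len: int = MIN_INTRON_LEN,
                         ) -> list[BoundaryHypothesis]:
    """Exhaustively enumerate valid splice frames around a candidate interval.

    Every (a, b) with a within *window* of the candidate start and b within
    *window* of its end is tested against: intron length >= *min_intron_len*,
    exon1 ending in T, intron ending in G, and a cloverleaf fold of the
    spliced product with the junction inside the anticodon loop. Enlarging
    the window can only add hypotheses.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    cs, ce = candidate_interval
    hyps: list[BoundaryHypothesis] = []
    for a in range(max(1, cs - window), cs + window + 1):
        if a >= len(context_seq) or context_seq[a - 1] != "T":
            continue
        for b in range(max(a + min_intron_len, ce - window),
                       min(len(context_seq), ce + window) + 1):
            if context_seq[b - 1] != "G":
                continue
            hyp = _hypothesis_at(context_seq, a, b)
            if hyp is not None:
                hyps.append(hyp)
    return hyps


def _rank_key(hyp: BoundaryHypothesis, top: AlignmentHit,
              cand: tuple[int, int]) -> tuple:
    shift_a, shift_b = hyp.a - cand[0], hyp.b - cand[1]
    return (
        -top.score,
        0 if hyp.anticodon == top.subject_anticodon else 1,
        abs(shift_a) + abs(shift_b),
        hyp.a,
    )


def _call_from_hypothesis(context: Context, hyp: BoundaryHypothesis,
                          top: AlignmentHit, intron_class: str = "groupI",
                          status: str = "resolved",
                          ambiguous: bool = False) -> ResolvedCall:
    gene_ctx = (hyp.fold.start, hyp.b + (hyp.fold.end - hyp.a))
    gene = context.to_genome(gene_ctx)
    intron = context.to_genome((hyp.a, hyp.b))
    assignment = anticodon_of(hyp.fold, hyp.spliced_seq)
    return ResolvedCall(
        genome_id=context.genome_id, strand=context.strand,
        gene_start=gene[0], gene_end=gene[1],
        intron_start=intron[0], intron_end=intron[1],
        site=hyp.site, anticodon=assignment.anticodon,
        amino_acid=assignment.amino_acid, intron_class=intron_class,
        trna_seq=hyp.trna_seq,
        intron_seq=context.seq[hyp.a : hyp.b],
        shift_a=hyp.a - context.cand[0], shift_b=hyp.b - context.cand[1],
        top_homolog=top.subject_id, homolog_score=top.score,
        homolog_identity=top.identity, homolog_coverage=top.coverage,
        cau_resolved=not assignment.cau_flag,
        ambiguous_boundary_resolved=ambiguous, status=status,
    )


def resolve(candidate: IntronCandidate, genome: GenomeRecord,
            trna_db: Sequence[TrnaRef], *, flank: int = DEFAULT_FLANK,
            window: int = DEFAULT_WINDOW, min_coverage: float = DEFAULT_MIN_COVERAGE,
            min_intron_len: int = MIN_INTRON_LEN,
            params: AlignParams = DEFAULT_PARAMS) -> Optional[ResolvedCall]:
    """Turn an intron candidate into a resolved call, or None.

    Pipeline: extract context, require tRNA homology on both flanks,
    enumerate splice frames, verify each spliced tRNA against the
    intron-less homolog database (coverage > *min_coverage*), and select
    the frame by homolog score / anticodon agreement / minimal shift /
    leftmost position.
    """
    if candidate.genome_id != genome.id:
        raise KeyError(f"candidate genome {candidate.genome_id!r} != {genome.id!r}")
    context = extract_context(candidate, genome, flank)
    ok, sides = flanking_trna_check(context, trna_db)
    if not ok:
        logger.debug("candidate %s:%d-%d: no tRNA homology on both flanks (%s)",
                     candidate.genome_id, candidate.start, candidate.end, sides)
        return None
    hyps = enumerate_boundaries(context.seq, context.cand, window, min_intron_len)
    scored: list[tuple[tuple, BoundaryHypothesis, AlignmentHit]] = []
    for hyp in hyps:
        hits = search_db(hyp.trna_seq, trna_db, min_coverage, params)
        if not hits:
            continue
        scored.append((_rank_key(hyp, hits[0], context.cand), hyp, hits[0]))
    if not scored:
        logger.debug("candidate %s:%d-%d: %d hypotheses, none passed homolog coverage",
                     candidate.genome_id, candidate.start, candidate.end, len(hyps))
        return None
    scored.sort(key=lambda t: t[0])
    _, hyp, top = scored[0]
    ambiguous = len({(h.a, h.b) for _, h, _ in scored}) > 1
    logger.debug(
        "candidate %s:%d-%d: %d hypotheses, winner a=%d b=%d site=%s anticodon=%s "
        "homolog=%s score=%.1f", candidate.genome_id, candidate.start, candidate.end,
        len(hyps), hyp.a, hyp.b, hyp.site, hyp.anticodon, top.subject_id, top.score)
    return _call_from_hypothesis(context, hyp, top, ambiguous=ambiguous)


def assign_cau_identity(call: ResolvedCall, trna_db: Sequence[TrnaRef],
                        min_coverage: float = DEFAULT_MIN_COVERAGE,
                        params: AlignParams = DEFAULT_PARAMS) -> ResolvedCall:
    """Assign Met / fMet / Ile2 identity to a CAU-anticodon call from homologs.

    The amino-acid label is copied from the top-scoring CAU-anticodon
    reference. Without any CAU reference the call is labelled "Met?" and
    left unresolved.
    """
    if call.anticodon != "CAT":
        raise ValueError("assign_cau_identity requires a CAU (CAT) anticodon call")
    hits = [h for h in search_db(call.trna_seq, trna_db, min_coverage, params)
            if h.subject_anticodon == "CAT"]
    if not hits:
        return replace(call, amino_acid="Met?", cau_resolved=False)
    return replace(call, amino_acid=hits[0].subject_amino_acid, cau_resolved=True,
                   top_homolog=hits[0].subject_id, homolog_score=hits[0].score,
                   homolog_identity=hits[0].identity, homolog_coverage=hits[0].coverage)


@dataclass(frozen=True)
class ExternalPrediction:
    """A tFind/ARAGORN-style intron-containing tRNA prediction.

    ``context_seq`` is the predicted pre-tRNA (with any flanking sequence),
    already on the coding strand; (a, b) is the predicted intron as a 0-based
    half-open interval within it.
    """

    genome_id: str
    context_seq: str
    a: int
    b: int
    anticodon: str = ""          # predicted mature anticodon, if reported


def adjust_external_call(pred: ExternalPrediction, trna_db: Sequence[TrnaRef], *,
                         window: int = DEFAULT_WINDOW,
                         min_coverage: float = DEFAULT_MIN_COVERAGE,
                         min_intron_len: int = MIN_INTRON_LEN,
                         params: AlignParams = DEFAULT_PARAMS) -> ResolvedCall:
    """Verify or correct an externally predicted splice boundary.

    If the predicted mature anticodon matches the top-scoring intron-less
    homolog (coverage above threshold), the call is accepted unchanged.
    Otherwise the boundaries are re-enumerated around the predicted ones and
    re-selected with the same criteria as :func:`resolve`. When no homolog
    clears coverage at all, the original call is returned with status
    "unverified".
    """
    context = Context(genome_id=pred.genome_id, seq=pred.context_seq,
                      genome_start=0, genome_end=len(pred.context_seq),
                      strand="+", cand=(pred.a, pred.b))
    predicted = _hypothesis_at(pred.context_seq, pred.a, pred.b)
    pred_anticodon = predicted.anticodon if predicted is not None else pred.anticodon
    if predicted is not None:
        hits = search_db(predicted.trna_seq, trna_db, min_coverage, params)
        if hits and predicted.anticodon == hits[0].subject_anticodon:
            return _call_from_hypothesis(context, predicted, hits[0], status="accepted")
    hyps = enumerate_boundaries(pred.context_seq, (pred.a, pred.b), window, min_intron_len)
    scored = []
    for hyp in hyps:
        hits = search_db(hyp.trna_seq, trna_db, min_coverage, params)
        if hits:
            scored.append((_rank_key(hyp, hits[0], context.cand), hyp, hits[0]))
    if scored:
        scored.sort(key=lambda t: t[0])
        _, hyp, top = scored[0]
        status = "accepted" if (hyp.a, hyp.b) == (pred.a, pred.b) else "adjusted"
        return _call_from_hypothesis(context, hyp, top, status=status,
                                     ambiguous=len(scored) > 1)
    # nothing verifiable: report the external call as-is, flagged
    no_hit = AlignmentHit(subject_id="", score=0.0, identity=0.0, coverage=0.0,
                          q_interval=(0, 0), s_interval=(0, 0))
    if predicted is not None:
        return _call_from_hypothesis(context, predicted, no_hit, status="unverified")
    mature = pred.context_seq[: pred.a] + pred.context_seq[pred.b:]
    amino = decode_anticodon(pred_anticodon) if len(pred_anticodon) == 3 else ""
    return ResolvedCall(
        genome_id=pred.genome_id, strand="+", gene_start=0,
        gene_end=len(pred.context_seq), intron_start=pred.a, intron_end=pred.b,
        site="?", anticodon=pred_anticodon, amino_acid=amino,
        intron_class="groupI", trna_seq=mature,
        intron_seq=pred.context_seq[pred.a : pred.b], shift_a=0, shift_b=0,
        top_homolog="", homolog_score=0.0, homolog_identity=0.0,
        homolog_coverage=0.0, status="unverified",
    )


@dataclass(frozen=True)
class AragornIntron:
    """A tRNA intron interval reported by an intron-aware annotator."""

    genome_id: str
    start: int
    end: int
    strand: str


def group2_trna_overlap(aragorn_introns: Sequence[AragornIntron],
                        rf00029_hits: Sequence[TabularHit],
                        genomes: dict[str, GenomeRecord],
                        trna_db: Sequence[TrnaRef], *,
                        flank: int = DEFAULT_FLANK,
                        min_coverage: float = DEFAULT_MIN_COVERAGE,
                        params: AlignParams = DEFAULT_PARAMS) -> list[ResolvedCall]:
    """Call group II introns in tRNA genes by annotator/model overlap.

    An annotator-reported tRNA intron interval that overlaps a group II
    covariance-model hit becomes a group II candidate; its boundaries are
    taken from the annotator and the mature tRNA is located by the top
    homolog alignment (not the U/G rules, which are group I chemistry). The
    site label comes from folding the mature tRNA: a junction in the
    anticodon loop gets a positional label, a junction in the D loop is
    labelled "D-loop".
    """
    calls: list[ResolvedCall] = []
    for intron in aragorn_introns:
        overlapping = [
            h for h in rf00029_hits
            if h.target_id == intron.genome_id
            and max(h.interval[0], intron.start) < min(h.interval[1], intron.end)
        ]
        if not overlapping:
            continue
        genome = genomes[intron.genome_id]
        cand = IntronCandidate(genome_id=intron.genome_id, start=intron.start,
                               end=intron.end, strand=intron.strand,
                               source_model="RF00029", score=overlapping[0].score,
                               evalue=overlapping[0].evalue)
        context = extract_context(cand, genome, flank)
        a, b = context.cand
        spliced = context.seq[:a] + context.seq[b:]
        hits = search_db(spliced[max(0, a - 100): a + 100], trna_db, 0.0, params)
        hits = [h for h in hits if h.coverage > 0]
        if not hits:
            continue
        # locate the mature tRNA from the alignment of the top reference
        ref = next(r for r in trna_db if r.id == hits[0].subject_id)
        ref_hit = local_align(ref.seq, spliced, params)
        if ref_hit is None:
            continue
        trna_start = max(0, ref_hit.s_interval[0] - ref_hit.q_interval[0])
        trna_end = min(len(spliced),
                       ref_hit.s_interval[1] + (len(ref.seq) - ref_hit.q_interval[1]))
        trna_seq = spliced[trna_start:trna_end]
        if not 50 <= len(trna_seq) <= 120:
            continue
        fold = fold_cloverleaf(trna_seq)
        if fold is None:
            continue
        junction = a - trna_start
        loop_s, loop_e = fold.anticodon_loop
        d_s, d_e = fold.d_loop
        if loop_s < junction < loop_e:
            site = insertion_site_label(junction - loop_s)
        elif d_s < junction <= d_e:
            site = "D-loop"
        else:
            site = "other"
        assignment = anticodon_of(fold, trna_seq)
        gene = context.to_genome((trna_start, b + (trna_end - a)))
        intron_g = context.to_genome((a, b))
        db_hits = search_db(trna_seq, trna_db, min_coverage, params)
        top = db_hits[0] if db_hits else hits[0]
        calls.append(ResolvedCall(
            genome_id=intron.genome_id, strand=intron.strand,
            gene_start=gene[0], gene_end=gene[1],
            intron_start=intron_g[0], intron_end=intron_g[1],
            site=site, anticodon=assignment.anticodon,
            amino_acid=assignment.amino_acid, intron_class="groupII",
            trna_seq=trna_seq, intron_seq=context.seq[a:b],
            shift_a=0, shift_b=0, top_homolog=top.subject_id,
            homolog_score=top.score, homolog_identity=top.identity,
            homolog_coverage=top.coverage,
            cau_resolved=not assignment.cau_flag, status="resolved",
        ))
    return calls
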
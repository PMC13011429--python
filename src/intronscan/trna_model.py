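"""Cloverleaf secondary-structure validation and anticodon-loop numbering.

A mature bacterial tRNA is modelled as the canonical cloverleaf:

    acceptor stem (7 bp) - 2 nt - D arm (3-4 bp stem, 7-11 nt loop) - 1 nt -
    anticodon arm (5 bp stem, 7 nt loop) - variable region (3-23 nt) -
    T arm (5 bp stem, 7 nt loop) - acceptor 3' strand - 0-4 nt trailer

Stems pair by Watson-Crick or GU wobble and tolerate at most one unpaired
position each (acceptor >=6/7, anticodon and T stems >=4/5, D stem >=2/3 or
3/4). This is a deliberately permissive stand-in for covariance-model
validation: it accepts canonical bacterial tRNAs and rejects unstructured
sequence, which is all the splice-boundary logic needs. Production runs can
swap in an external structure validator behind the same interface.

Loop numbering is loop-relative: the 7 nt of the anticodon loop are numbered
32-38 with the anticodon at 34-36, so an intron whose 5' exon ends at loop
position 35 sits at site "35/36".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.SeqUtils import seq3

from .formats_io import revcomp

PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}

ACCEPTOR_LEN = 7
SPACER1 = 2          # positions 8-9
D_STEM_RANGE = (3, 4)
D_LOOP_RANGE = (7, 11)
SPACER2 = 1          # position 26
AC_STEM_LEN = 5
LOOP_LEN = 7         # anticodon loop and T loop are both exactly 7 nt
VAR_RANGE = (3, 23)
T_STEM_LEN = 5
TRAILER_RANGE = (0, 4)

# decoding table: anticodon (DNA alphabet) -> 3-letter amino acid, code table 11
_TABLE11 = unambiguous_dna_by_id[11]
CAU_AMBIGUITY = ("Met", "fMet", "Ile2")


def decode_anticodon(anticodon: str) -> str:
    """Amino acid (3-letter) read by an anticodon, bacterial code table 11."""
    codon = revcomp(anticodon)
    if codon in _TABLE11.stop_codons:
        return "Stop"
    return seq3(_TABLE11.forward_table[codon])


@dataclass(frozen=True)
class CloverleafFold:
    """Arm/loop coordinates of a folded tRNA within a parent sequence.

    All intervals are 0-based half-open on the parent sequence; ``start`` and
    ``end`` bound the tRNA itself (trailer excluded).
    """

    start: int
    end: int
    acceptor5: tuple[int, int]
    d_stem5: tuple[int, int]
    d_loop: tuple[int, int]
    d_stem3: tuple[int, int]
    ac_stem5: tuple[int, int]
    anticodon_loop: tuple[int, int]
    ac_stem3: tuple[int, int]
    variable_region: tuple[int, int]
    t_stem5: tuple[int, int]
    t_loop: tuple[int, int]
    t_stem3: tuple[int, int]
    acceptor3: tuple[int, int]
    n_pairs: int

    @property
    def total_len(self) -> int:
        return self.end - self.start

    def dot_bracket(self, seq: str) -> str:
        """Dot-bracket rendering of the fold for debugging."""
        db = ["."] * self.total_len
        for s5, s3 in (
            (self.acceptor5, self.acceptor3),
            (self.d_stem5, self.d_stem3),
            (self.ac_stem5, self.ac_stem3),
            (self.t_stem5, self.t_stem3),
        ):
            for i in range(s5[0], s5[1]):
                db[i - self.start] = "("
            for i in range(s3[0], s3[1]):
                db[i - self.start] = ")"
        return "".join(db)


@dataclass(frozen=True)
class AnticodonAssignment:
    anticodon: str
    amino_acid: str
    cau_flag: bool


def _stem_pairs(seq: str, s5: tuple[int, int], s3: tuple[int, int]) -> Optional[int]:
    """Count WC/GU pairs between a 5' strand and the reverse-ordered 3' strand.

    Returns None when any stem position is ambiguous (N) — such placements
    are rejected outright.
    """
    n = s5[1] - s5[0]
    pairs = 0
    for k in range(n):
        x = seq[s5[0] + k]
        y = seq[s3[1] - 1 - k]
        if x == "N" or y == "N":
            return None
        if (x, y) in PAIRS:
            pairs += 1
    return pairs


def _fold_at(seq: str, start: int, d_stem: int, d_loop: int, var: int) -> Optional[CloverleafFold]:
    """Build and validate one fold placement with the tRNA starting at *start*."""
    p = start
    acceptor5 = (p, p + ACCEPTOR_LEN); p = acceptor5[1] + SPACER1
    d_stem5 = (p, p + d_stem); p = d_stem5[1]
    d_loop_iv = (p, p + d_loop); p = d_loop_iv[1]
    d_stem3 = (p, p + d_stem); p = d_stem3[1] + SPACER2
    ac_stem5 = (p, p + AC_STEM_LEN); p = ac_stem5[1]
    ac_loop = (p, p + LOOP_LEN); p = ac_loop[1]
    ac_stem3 = (p, p + AC_STEM_LEN); p = ac_stem3[1]
    var_iv = (p, p + var); p = var_iv[1]
    t_stem5 = (p, p + T_STEM_LEN); p = t_stem5[1]
    t_loop = (p, p + LOOP_LEN); p = t_loop[1]
    t_stem3 = (p, p + T_STEM_LEN); p = t_stem3[1]
    acceptor3 = (p, p + ACCEPTOR_LEN); p = acceptor3[1]
    if start < 0 or p > len(seq):
        return None
    if "N" in seq[ac_loop[0]:ac_loop[1]]:
        return None
    total = 0
    for s5, s3, minimum in (
        (acceptor5, acceptor3, ACCEPTOR_LEN - 1),
        (d_stem5, d_stem3, d_stem - 1),
        (ac_stem5, ac_stem3, AC_STEM_LEN - 1),
        (t_stem5, t_stem3, T_STEM_LEN - 1),
    ):
        got = _stem_pairs(seq, s5, s3)
        if got is None or got < minimum:
            return None
        total += got
    return CloverleafFold(
        start=start, end=p, acceptor5=acceptor5, d_stem5=d_stem5, d_loop=d_loop_iv,
        d_stem3=d_stem3, ac_stem5=ac_stem5, anticodon_loop=ac_loop, ac_stem3=ac_stem3,
        variable_region=var_iv, t_stem5=t_stem5, t_loop=t_loop, t_stem3=t_stem3,
        acceptor3=acceptor3, n_pairs=total,
    )


def _upstream_span(d_stem: int, d_loop: int) -> int:
    """Distance from tRNA start to the anticodon loop for a given D-arm geometry."""
    return ACCEPTOR_LEN + SPACER1 + 2 * d_stem + d_loop + SPACER2 + AC_STEM_LEN


def folds_with_loop_at(seq: str, loop_start: int) -> Iterator[CloverleafFold]:
    """All valid fold placements whose anticodon loop starts at *loop_start*.

    The tRNA may be embedded anywhere inside *seq*; any trailer is ignored.
    """
    for d_stem in range(D_STEM_RANGE[0], D_STEM_RANGE[1] + 1):
        for d_loop in range(D_LOOP_RANGE[0], D_LOOP_RANGE[1] + 1):
            start = loop_start - _upstream_span(d_stem, d_loop)
            if start < 0:
                continue
            for var in range(VAR_RANGE[0], VAR_RANGE[1] + 1):
                fold = _fold_at(seq, start, d_stem, d_loop, var)
                if fold is not None:
                    yield fold


def best_fold_with_loop_at(seq: str, loop_start: int) -> Optional[CloverleafFold]:
    """Highest-pairing fold with the anticodon loop at *loop_start* (ties: shortest)."""
    best: Optional[CloverleafFold] = None
    for fold in folds_with_loop_at(seq, loop_start):
        if best is None or (fold.n_pairs, -fold.total_len) > (best.n_pairs, -best.total_len):
            best = fold
    return best


def fold_cloverleaf(seq: str) -> Optional[CloverleafFold]:
    """Fold a standalone candidate mature tRNA, or return None.

    The whole sequence must be consumed by the cloverleaf plus a 0-4 nt
    trailer. Among valid placements the one maximizing total stem pairs wins;
    ties go to the leftmost anticodon loop.
    """
    n = len(seq)
    if not 50 <= n <= 120:
        raise ValueError(f"sequence length {n} outside 50-120")
    best: Optional[CloverleafFold] = None
    for d_stem in range(D_STEM_RANGE[0], D_STEM_RANGE[1] + 1):
        for d_loop in range(D_LOOP_RANGE[0], D_LOOP_RANGE[1] + 1):
            fixed = (
                _upstream_span(d_stem, d_loop)
                + LOOP_LEN + AC_STEM_LEN + T_STEM_LEN + LOOP_LEN + T_STEM_LEN + ACCEPTOR_LEN
            )
            for trailer in range(TRAILER_RANGE[0], TRAILER_RANGE[1] + 1):
                var = n - trailer - fixed
                if not VAR_RANGE[0] <= var <= VAR_RANGE[1]:
                    continue
                fold = _fold_at(seq, 0, d_stem, d_loop, var)
                if fold is None:
                    continue
                key = (fold.n_pairs, -fold.anticodon_loop[0])
                if best is None or key > (best.n_pairs, -best.anticodon_loop[0]):
                    best = fold
    return best


def anticodon_of(fold: CloverleafFold, seq: str) -> AnticodonAssignment:
    """Read the anticodon (loop positions 34-36) and decode its amino acid.

    CAU anticodons are flagged ambiguous (Met / fMet / lysidine-modified
    Ile2): their identity is assigned later from intron-less homologs, never
    guessed from sequence.
    """
    s = fold.anticodon_loop[0]
    anticodon = seq[s + 2 : s + 5]
    if anticodon == "CAT":
        return AnticodonAssignment(anticodon, "/".join(CAU_AMBIGUITY), True)
    return AnticodonAssignment(anticodon, decode_anticodon(anticodon), False)


def insertion_site_label(exon1_end_loop_index: int) -> str:
    """Map a 1-based loop index of the last 5'-exon nucleotide to a site label.

    Loop positions are numbered 32-38, so index i yields "(31+i)/(32+i)":
    i=4 is the 35/36 site between the second and third anticodon bases.
    """
    if exon1_end_loop_index not in range(1, 7):
        raise ValueError("insertion outside anticodon loop")
    return f"{31 + exon1_end_loop_index}/{32 + exon1_end_loop_index}"


def site_to_loop_index(site: str) -> int:
    """Inverse of :func:`insertion_site_label`."""
    left, right = site.split("/")
    idx = int(left) - 31
    if int(right) != int(left) + 1 or idx not in range(1, 7):
        raise ValueError(f"not an anticodon-loop site label: {site!r}")
    return idx
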
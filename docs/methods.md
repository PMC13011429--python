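# Methods

## Model of an intron-interrupted tRNA gene

A group I intron in a tRNA gene is modelled as an interval [a, b) on the
coding strand of a pre-tRNA such that

* the base at a−1 is T — the 5′ exon ends immediately after a uridine;
* the base at b−1 is G — the intron terminates in the ωG whose recognition
  completes exon ligation;
* the ligated exons (context minus [a, b)) fold into a canonical cloverleaf
  with the splice junction strictly inside the 7-nt anticodon loop.

Loop positions are numbered 32–38 with the anticodon at 34–36, so a frame
whose 5′ exon ends at loop position p is labelled "p/p+1" (e.g. 35/36).
This loop-relative numbering reproduces standard site labels without
modelling D-loop length variation (full Sprinzl numbering is unnecessary:
group I insertions in tRNAs are anticodon-loop insertions; the one group II
D-loop case is labelled categorically as "D-loop").

These rules alone cannot always identify a unique frame. If the intron ends
in …GTG and the invariant U33 precedes the anticodon, the frame shifted by
−2 on both boundaries also satisfies every rule and reads a different
anticodon (Asn GUU at 35/36 versus Thr UGU at 33/34). The resolver therefore
ranks all admissible frames by, in order:

1. local-alignment score of the spliced tRNA against the best intron-less
   homolog (coverage of the query must exceed `min_coverage`, default 75 %);
2. agreement of the spliced anticodon with that homolog's anticodon;
3. minimal total boundary shift from the model-predicted interval;
4. leftmost 5′ boundary.

Criteria 3–4 are deterministic tie-breaks of this package's own
construction; the homolog database is the scientific arbiter, and with an
empty or uninformative database the call is reported "unverified", never
guessed. CAU-anticodon tRNAs (Met / fMet / lysidine-modified Ile2 are
sequence-identical at the anticodon) take their amino-acid identity from the
top-scoring CAU homolog.

Group II introns in tRNAs are called differently: annotator-reported tRNA
intron intervals are intersected with group II covariance-model hits, the
boundaries are kept from the annotator, and the mature tRNA is located by
the top homolog alignment rather than the U/G chemistry (which is group I
specific). The junction is then placed by folding the mature tRNA: anticodon
loop → positional label, D loop → "D-loop".

## Cloverleaf validation

Covariance-model scoring of tRNA structure is out of scope; the built-in
validator is a geometric stand-in designed to accept canonical bacterial
tRNAs and reject unstructured sequence. Geometry: acceptor stem 7 bp, 2 nt
spacer, D stem 3–4 bp with a 7–11 nt loop, 1 nt spacer, anticodon stem 5 bp
with an exactly 7-nt loop, variable region 3–23 nt, T stem 5 bp with an
exactly 7-nt loop, then the acceptor 3′ strand and an optional 0–4 nt
trailer — total span 67–97 nt. Stems pair Watson–Crick or GU and tolerate
at most one unpaired position each (acceptor ≥6/7, anticodon and T stems
≥4/5, D stem ≥2/3 or 3/4). Among valid placements the one maximizing total
stem pairs wins; ties go to the leftmost anticodon loop. Any N inside a stem
or the anticodon loop rejects the placement. An external structure validator
(e.g. a tRNAscan-SE wrapper) can be substituted behind the same interface
for production annotation.

## Alignment

Local alignment mimics blastn-short: match +1, mismatch −3, a gap of length
k costs 5 + 2(k−1), seed word 7 nt, all configurable (`AlignParams`). The
optimal alignment is computed by Biopython's `PairwiseAligner`; no E-value
model is attached because reference sets are small and only the ranking
matters. Identity counts matches over all aligned columns including gap
columns — BLAST's percent identity may differ by ±1–2 % on gapped
alignments. Coverage is computed over the query (the reconstructed tRNA,
whose completeness is what the threshold protects).

The flanking gate (tRNA homology required on both sides of a candidate)
searches only the proximal 80 nt of each flank with word size 4 and a score
floor of 10: exon fragments abut the candidate interval and can be short
(~30 nt) and diverged, so the gate favours sensitivity — a false positive
merely admits a candidate that homolog verification rejects downstream.

## Parameter defaults

| parameter | default | units | role |
|---|---|---|---|
| `evalue_max` | 1e-4 | — | covariance-model hit threshold |
| `overlap_frac` | 0.5 | fraction | reciprocal overlap defining "same locus" for dedup |
| `flank` | 400 | bp | genomic context on each side of a candidate |
| `window` | 10 | nt | boundary-shift search radius (observed shifts are ~2 nt) |
| `min_intron_len` | 50 | nt | prunes degenerate frames (known group I cores are larger) |
| `min_coverage` | 75 | % of query | homolog-verification coverage floor |
| rRNA/tmRNA flank | 1000 | bp | host-classification windows for structured RNAs |
| CDS/TnpB flank | 4000 | bp | protein-homology and IStron vicinity window |
| HEG length gate | 500 | bp | group I introns longer than this are ORF-scanned |
| `min_orf_len` | 300 | nt | smallest reported ORF |
| domain E-value | 0.01 | — | Pfam-style domain attachment threshold |
| `min_genomes` | 20 | genomes | phylum inclusion in retention plot table |

Dedup keeps the higher-scoring hit among same-target, same-strand hits with
reciprocal overlap ≥ `overlap_frac`, breaking score ties by lower E-value
then leftmost start; the winner's coordinates are kept verbatim. Internal
coordinates are 0-based half-open; all emitted files are 1-based inclusive.

## Host classification

Category priority is tRNA > rRNA > tmRNA > CDS > IStron-like > unknown
(structured-RNA evidence outranks translated homology; conflicts are logged
and resolved to the higher priority). rRNA requires the same model hit on
both sides within the 1,000 nt flanks; CDS requires the same protein subject
on both sides within 4,000 nt; a TnpB-related gene within the 4,000 nt
vicinity marks IStron-like. The tmRNA rule accepts both-sides hits, or a
one-sided hit whose edge lies within 30 nt of the intron boundary plus a
≥20 nt same-model match opposite — thresholds of this package's choosing
(flagged "partial evidence" in output) since intact-boundary criteria for
truncated tmRNAs have no published coordinates. ORF scanning is
sense-strand only (introns are transcribed in the host gene's sense), starts
ATG/GTG/TTG, stops per code table 11, and also reports ORFs running off the
intron end.

## Survey statistics

Retention rate = genomes with ≥1 intron of a class / all genomes of the
phylum in the input set; phyla under `min_genomes` remain in the full table
but are flagged out of the plot table. Copy-number statistics are computed
over genomes containing at least one intron of the class, with the sample
(n−1) standard deviation, reported as 0 with a degeneracy flag for a single
genome; all group I introns count regardless of host category. Subgroup
assignment is argmax over per-model scores with lexicographic, logged tie
breaks. The position matrix counts tRNA-hosted introns by (phylum, site,
amino acid) and conserves totals.

## Synthetic data: what it emulates and what it does not

The generator plants validator-perfect tRNAs (fully complementary stems)
into i.i.d. uniform background sequence, inserts introns obeying the
boundary chemistry, and emits candidate hit tables with ≤3 nt boundary
jitter, homolog databases degraded to a target identity only outside the
anticodon triplet (mutations stratified along the sequence so divergence is
spread as in real homolog pairs), and a truth table audited by re-slicing
the emitted FASTA. The default survey profile mirrors the structure of real
bacterial surveys: two phyla with ~0.4 group I retention, one of them
enriched for site 35/36 and without group II introns, ~1.6 mean copies in
intron-containing genomes, intron lengths mostly 184–400 bp with a ~4 %
tail above 500 bp that always carries a planted ≥300 nt ORF (the HEG
association), and group II loci in anticodon or D loops. Trap fixtures
implement the two-frame geometry (intron suffix GTG + invariant U33)
synthetically rather than copying real loci.

Not emulated: genomic base composition (no rule depends on it), realistic
covariance-model score distributions, modified nucleotides, pseudogenes,
splicing kinetics, or the intron's own catalytic fold. Passing tests
therefore demonstrate the correctness of the boundary logic, arbitration,
classification, and bookkeeping under the stated conditions — not the
sensitivity of covariance-model search on real genomes, which this package
consumes rather than performs.

## Problem sizes and numerical choices

The test suite and acceptance script use 200 recovery fixtures, 50 trap
fixtures, 100 enumeration-oracle contexts (≤1.5 kb), 20 loci per host
category, and 120-genome surveys — sizes chosen to make every rate a
meaningful count while a full run stays around a minute. All randomness
flows through `numpy.random.Generator` seeded per run; fixed seeds give
byte-identical generator output. Degenerate inputs are handled explicitly:
empty hit tables and empty surveys yield empty outputs (not errors),
truncated contexts at contig ends are flagged, and a candidate whose every
frame fails homolog coverage yields no call rather than a guess.

## Known limitations

* The cloverleaf stand-in has fixed arm geometry; tRNAs with extreme
  variable arms or non-canonical spacers (rare in bacteria) may fail
  validation and thus resolution.
* Equal-score, equal-anticodon frame ties fall to the minimal-shift rule,
  which is plausible but unvalidated against expert-curated boundaries.
* BLAST statistics are not reproduced; identity values may differ slightly
  from BLAST's on gapped alignments.
* The group II path trusts annotator intervals; it refines the site label
  but not the boundaries themselves.
* Host classification is evidence-table-driven: it is only as complete as
  the supplied rRNA/tmRNA/blastx/TnpB tables.
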
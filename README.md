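# intronscan

Detection of self-splicing group I (and group II) introns in bacterial tRNA
genes, with exact splice-boundary resolution, host-gene classification, and
survey statistics.

## The problem

Group I introns are ribozymes that excise themselves from precursor RNAs via
two transesterifications: an exogenous guanosine (αG) cleaves the 5′ splice
site, then the intron's own 3′-terminal guanosine (ωG) mediates exon
ligation. In some bacterial lineages — most dramatically the ultra-reduced
genomes of Patescibacteria — these introns interrupt tRNA genes inside the
anticodon loop, including at position 35/36 (between the second and third
anticodon bases). An intron at 35/36 splits the anticodon itself, so standard
annotators either miss the tRNA entirely or mis-place the boundary: shifting
both splice sites by two nucleotides still satisfies every local rule but
reads a different anticodon (e.g. tRNA-Asn(GUU) at 35/36 versus
tRNA-Thr(UGU) at 33/34), silently mis-annotating the gene.

`intronscan` post-processes covariance-model intron candidates (Infernal
`--tblout` hits from models such as RF00028) into resolved calls:

1. **Context extraction** — 400 bp of genomic sequence on each side of the
   candidate, strand-normalized.
2. **Flanking check** — intron-less tRNA homology must be present on *both*
   sides of the candidate.
3. **Boundary enumeration** — every splice frame (a, b) within ±10 nt of the
   candidate edges such that the 5′ exon ends in U, the intron ends in G
   (the ωG), and the ligated exons fold into a canonical cloverleaf with the
   junction inside the 7-nt anticodon loop (positions 32–38, anticodon at
   34–36).
4. **Homolog arbitration** — each hypothetical mature tRNA is aligned
   (blastn-short-style local alignment) against a database of intron-less
   tRNA homologs; frames are ranked by homolog score, anticodon agreement
   with the top homolog, minimal boundary shift, and position. Coverage must
   exceed 75 % of the query.
5. **Annotation** — CAU-anticodon calls get their Met/fMet/Ile2 identity
   from the top homolog; host genes of non-tRNA introns are classified
   (rRNA/tmRNA/CDS/IStron-like/unknown) from external evidence tables;
   introns >500 bp are scanned for homing-endonuclease ORFs; structural
   subgroups (IA/IB/IC/…) are assigned by best covariance-model score.

A synthetic-genome generator plants intron-containing tRNA loci with full
ground-truth bookkeeping — including two-frame "trap" loci that reproduce
the boundary ambiguity — so the entire pipeline is testable offline.

## Worked example

Generate a small survey and run detection:

```bash
$ intronscan simulate --seed 21 --n-genomes 12 --out-dir demo
5 planted introns across 12 genomes -> demo

$ intronscan detect --genomes demo/genomes.fasta --hits demo/hits.tbl \
      --trna-db demo/trna_db.fasta --out-prefix demo/run
4 calls from 4 candidates -> demo/run.calls.tsv, demo/run.gff3
```

Four group I candidates resolve to four calls (the fifth planted intron is a
group II intron, handled by the `--aragorn-introns`/`--rf00029-hits` overlap
path). The calls table records the resolved gene, boundaries, site, and
homolog evidence:

```
genome_id  strand  gene_start  gene_end  intron_start  intron_end  site   anticodon  amino_acid
G0002      -       901         1222      937           1187        35/36  GTT        Asn
G0002      +       2123        2563      2156          2525        33/34  GAA        Phe
```

The first row is a minus-strand tRNA-Asn(GUU) gene at 901–1222 whose 250-nt
group I intron sits at position 35/36 — the insertion site that defeats
standard annotators. The paired GFF3 emits a `tRNA` feature with an `intron`
child at the same coordinates (1-based inclusive):

```
G0002  intronscan  tRNA    901  1222  55  -  .  ID=trna00001;anticodon=GTT;amino_acid=Asn;site=35/36;intron_class=groupI
G0002  intronscan  intron  937  1187  .   -  .  ID=trna00001.intron;Parent=trna00001;site=35/36;intron_class=groupI
```

Other subcommands: `adjust` (verify/correct external tFind/ARAGORN-style
predictions against intron-less homologs), `classify` (host-gene categories
from rRNA/tmRNA/blastx/TnpB evidence tables), `stats` (per-phylum retention
rates, insertion-position matrix, length histogram, subgroup proportions).
All thresholds (`--evalue-max 1e-4`, `--min-coverage 75`, `--flank 400`,
`--window 10`, 1,000/4,000 nt classifier flanks, >500 bp HEG rule, Pfam
E < 0.01, ≥20 genomes for retention plots) are exposed as flags.

## Layout

```
src/intronscan/
  formats_io.py         FASTA / Infernal tblout / GFF3 / TSV, hit dedup
  trna_model.py         cloverleaf validator, anticodon loop numbering
  short_align.py        blastn-short-style local alignment + homolog search
  boundary_resolver.py  splice-frame enumeration and homolog arbitration
  locus_classifier.py   host-gene categories, ORF scan, Pfam domain labels
  survey_stats.py       retention / copy-number / position / length tables
  synthetic_genomes.py  planted-truth generator (loci, traps, surveys)
  cli.py                detect / adjust / classify / stats / simulate
```

See `docs/methods.md` for the model, parameter defaults, and limitations.
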
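# neoy

A tested, reusable pipeline for neo-sex-chromosome analysis:

* **`neoy.simulate`** — synthetic cohort generator: a reference chromosome,
  neo-X haplotypes with standing diversity, neo-Y lineages that are
  recombinant mosaics of neo-X donors (plus an outgroup-derived block near
  the centromere) evolving clonally after per-group recombination-stop
  times, diploid VCF-shaped genotype tables, allele-specific count tables,
  tissue expression matrices, and a complete truth set.
* **`neoy.genotyping`** — haploid neo-Y inference from paired male/female
  diploid calls (female-hom / male-het rule, depth ≥ 5 and GQ ≥ 20
  filters), Y-linked indel calling with 50-bp first-kept merging, shared
  polymorphism vs fixed difference site classification, and per-group
  fixed derived variant sets.
* **`neoy.popgen`** — windowed π, Weir–Cockerham (and Hudson) F_ST, D_XY
  and net divergence D_A = D_XY − (π_A + π_B)/2, with full-window-length
  denominators and pairwise-complete missing-data handling.
* **`neoy.trees`** — IUPAC pseudo-references, coordinate-sliced window
  alignments, neighbor-joining on Jukes–Cantor distances (ambiguities as
  fractional matches), outgroup rooting, external newick import, and
  topology classification (monophyly, placement, species sorting).
* **`neoy.haplotypes`** — haplotype painting from maximal exclusively-neo-Y
  clades with solo-window smoothing and breakpoint detection, and
  branch-length dating: age = median[h-to-tip / (s-to-h + h-to-tip)] x
  species-split age, with a bootstrap CI.
* **`neoy.ase`** — DNA-corrected allele-specific expression fold
  differences, Fisher + BH-FDR bias calls, an exact binomial
  chromosome-level summary, count-simulation fold-recovery validation, and
  allele-specific ChIP window enrichment.
* **`neoy.degeneration`** — coding-effect classification of fixed SNPs and
  indels (synonymous/nonsynonymous/nonsense, frameshift, near-gene) and
  NG86 Ka/Ks.
* **`neoy.tissue`** — tau tissue-specificity scoring and the
  100,000-replicate double-draw permutation overlap test.

## CLI

Every stage is exposed under a single `neoy` entry point:

```sh
neoy simulate --config config.json --out cohort/       # or omit --config
neoy genotype --vcf cohort/cohort.vcf --pairs pairs.tsv --out calls.tsv
neoy popgen   --calls calls.tsv --groups groups.tsv --ref reference.fa --out popgen.tsv
neoy trees    --fasta pseudorefs.fa --groups groups.tsv --window 200000 --out win
neoy haplotypes --trees win.trees.tsv --groups groups.tsv --split-kya 250 --out hap
neoy ase      --counts counts.tsv --alpha 0.05 --out ase.tsv
neoy chip     --ip ip.tsv --input input.tsv --window 50000 --out chip.tsv
neoy degen    --gff genes.gff3 --ref reference.fa --fixed fixed.tsv --out degen
neoy tissue   --expr expr.tsv --focal focal.txt --universe universe.txt --out enrich.tsv
```

`pairs.tsv` lists strain / male sample / female sample; `groups.tsv` maps
haplotype labels to classes (`neoX`, `outgroup`, or a Y-group name).

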
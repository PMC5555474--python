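# rdnarip

Mining, classification and phylogenetics of intragenomic **45S rDNA
paralogs** in fungal genome assemblies, with a focus on **rRNA pseudogenes
created by repeat-induced point mutation (RIP)**.

## The problem

The nuclear ribosomal DNA of fungi is organised as tandem repeats of a 45S
unit (18S–ITS1–5.8S–ITS2–28S plus the intergenic spacer). Concerted
evolution normally homogenises these copies, but in filamentous
ascomycetes some paralogs escape: RIP — a genome-defence process active
during sexual reproduction — floods duplicated sequence with **G:C→A:T
transitions**, preferentially at **CpA/TpG dinucleotides**, producing
AT-rich, non-functional pseudogene copies alongside the intact genes.
Undetected, such paralogs contaminate barcoding and phylogenetic datasets
built from 18S/ITS/5.8S/28S markers.

`rdnarip` is for people who work with fungal WGS assemblies or rDNA
amplicon sets and need to (a) find *all* rDNA repeats in an assembly,
(b) separate functional genes from RIP-derived pseudogenes, and
(c) quantify and visualise the RIP mutation spectrum.

## What it computes

* **Repeat mining** — iterative query-expansion homology search (every
  recovered sequence becomes a query for the next round, until no new
  locus appears), so heavily decayed copies are reached through
  intermediate ones; subunit boundaries are annotated by alignment to a
  reference unit and intron-like insertions are excised.
* **Classification** — per-subunit GC content; split into high/low GC
  groups at the largest gap; substitution spectrum of every paralog
  against the highest-GC (functional) reference; a paralog is called a
  **pseudogene** when it is low-GC, its non-RIP substitutions are
  consistent with a ≤0.1 % noise ceiling (one-sided binomial test), and it
  carries G→A/C→T transitions. Discriminating primer windows for
  pseudogene-specific amplification are reported, with an AT-richness
  warning.
* **RIP profile** — every C→T difference versus the consensus is classified
  by its 3′ neighbour, every G→A by its 5′ neighbour (the strand-symmetric
  reading): classes CpA↔TpA | TpG↔TpA, CpC↔TpC | GpG↔GpA, CpG↔TpG | CpG↔CpA,
  CpT↔TpT | ApG↔ApA. Outputs per-paralog RIP rates
  (= (C→T + G→A)/aligned sites), a CpA-dominance ratio, and windowed
  mutation tracks for heat-map rendering.
* **Structure impact** — mutations mapped onto an rRNA secondary-structure
  pairing table (two-column TSV or dot-bracket); a mutation disrupts a pair
  when the post-mutation pair leaves {AU, UA, GC, CG, GU, UG}.
* **Phylogenetics** — p-distance and Kimura two-parameter distances
  (d = −½·ln(1−2P−Q) − ¼·ln(1−2Q), P/Q the transition/transversion
  proportions; pairwise or complete deletion), Saitou–Nei neighbor-joining
  with deterministic tie-breaks, bootstrap supports, and a clade-purity
  statistic testing whether some tree edge separates functional from
  pseudogene leaves exactly.
* **Simulator** — a bundled generator produces assemblies of functional and
  RIP-mutated paralogs with a complete mutation-log truth table, so the
  whole pipeline is testable without downloads.

## Worked example

```bash
rdnarip all --seed 3 --outdir out
```

runs simulate → mine → classify → RIP → structure → phylogeny on the
default synthetic conditions (10 paralogs, 80 % pseudogenes, CpA-biased
RIP). It prints the per-subunit summary:

```
subunit  n_paralogs  n_pseudogene_calls  avg_p_distance  gA_rate  cT_rate  rip_rate
    18S           7                   5        0.159921 0.085111 0.084333  0.169444
   5.8S           9                   7        0.155903 0.061607 0.089286  0.150893
    28S           8                   6        0.153561 0.081162 0.079596  0.160758
{
  "tp": 18, "fp": 0, "tn": 6, "fn": 0,
  "sensitivity": 1.0, "specificity": 1.0,
  "n_truth_repeats": 10, "n_hits": 10
}
18S: separating=True impurity=0
5.8S: separating=True impurity=0
28S: separating=True impurity=0
```

Reading this: all 10 simulated repeats were recovered by mining
(`n_hits` = `n_truth_repeats`); per subunit, the average pairwise
p-distance among paralogs is ~0.15 and the average RIP rate of the low-GC
copies is 15–17 % of aligned sites, split roughly evenly between G→A and
C→T — the signature of RIP rather than ordinary divergence; every
pseudogene call matches the simulator's truth (sensitivity and specificity
1.0); and in each subunit's bootstrapped NJ tree the functional and
pseudogene copies fall into two clean clades. Per-stage TSVs (hit table,
classification, RIP tracks, structure impact), Newick trees and the truth
table are written under `out/`.

The same pipeline runs on a real assembly with
`rdnarip all --assembly genome.fasta --reference unit.fasta`, where
`unit.fasta` holds the subunit sequences of a reference 45S unit in order.
Pre-aligned paralog sets (e.g. curated alignments) can be summarised
without the mining stage through `rdnarip.pipeline.summarize_prealigned`.

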
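# shapebench

Benchmarking toolkit for SHAPE-MaP chemical probing data.

SHAPE reagents acylate the ribose 2′-OH of conformationally flexible RNA
nucleotides; under mutational-profiling (MaP) reverse transcription the
adducts become mutations in cDNA, so a reagent's quality is visible in
per-base mutation frequencies. This package implements the computational
side of comparing such reagents end to end:

- **Mutation counting** from aligned MaP reads (SAM): mismatches,
  deletions (with rightward re-alignment of ambiguous placements within
  repeats), and insertions, with per-base quality filtering.
- **Reactivity profiles**: control (DMSO) subtraction
  `max(0, f_treated − f_control)` and box-plot normalization.
- **Hairpin signal-to-noise**: hairpins with stem length ≥ 3 and loop
  size ≥ 3 are taken from the dot-bracket string with the pattern
  `([\(]{3}\.{3,}[\)]{3})`; S/N is the ratio of the median loop-edge
  reactivity to the median flanking-stem reactivity across hairpins.
- **ROC/AUC** for discriminating unpaired (positive) from
  internally-paired (negative) residues by mutation frequency, sweeping
  the threshold over [0, 1] in steps of 0.001; terminal and isolated
  pairs are excluded, and an optional solvent-accessibility mask
  (Shrake–Rupley SASA, probe radius 3 Å, accessible ⇔ SASA > 2 Å²)
  restricts in vivo evaluation to reagent-reachable residues.
- **Restrained folding evaluation**: reactivities enter a folding engine
  as per-nucleotide pseudo-free energies ΔG(i) = m·ln(r_i + 1) + b;
  predictions are scored against a reference structure by PPV and
  sensitivity under the relaxed pair comparison (i/j counts as correct if
  the reference holds i/j, i±1/j or i/j±1), summarized as their geometric
  mean; a grid search (jackknifing) over (m, b) selects restraint
  parameters. A deterministic built-in dynamic-programming engine is the
  default; an adapter to ViennaRNA is included.
- **A synthetic-data generator** producing ground-truthed structures,
  reagent-like per-base modification rates and MaP reads, so the whole
  pipeline runs and is testable without any downloads.

## Worked example

Simulate a 300-nt experiment with the strong membrane-permeable reagent
preset, then run the pipeline on it:

```bash
shapebench simulate --length 300 --reads 50000 --reagent 2A3-like --seed 7 --out-dir sim/
shapebench count --sam sim/treated.sam --fasta sim/reference.fa --out sim/treated.tsv
shapebench count --sam sim/control.sam --fasta sim/reference.fa --out sim/control.tsv
shapebench snr --struct sim/reference.db --profile sim/treated.tsv
shapebench roc --struct sim/reference.db --profile sim/treated.tsv --out sim/roc.tsv
shapebench reactivity --treated sim/treated.tsv --control sim/control.tsv --out sim/react.tsv
shapebench fold-eval --fasta sim/reference.fa --react sim/react.tsv --ref sim/reference.db -m 1.0 -b -0.4
shapebench gridsearch --fasta sim/reference.fa --react sim/react.tsv --ref sim/reference.db \
    --m-grid 0:5:0.5 --b-grid -1.2:0:0.4 --out sim/grid.tsv
```

which prints (abridged):

```
wrote sim/: 300 nt, 50000 treated + 50000 control reads (2A3-like)
synthetic_300nt_seed1201125462: 50000 reads, median coverage 24996
hairpins evaluated: 12 (skipped 0 with missing data)
S/N = 3.0094
AUC = 0.9142 (110 unpaired, 114 paired bases evaluated)
PPV = 0.7091  sensitivity = 0.8211  gmean = 0.7630
best m = 4.5, b = -0.8, gmean = 0.9199
```

Read: the treated channel's mutation frequencies are ~3× higher on
hairpin loops than on the adjacent stems (a strong-reagent regime), and
they separate unpaired from paired bases with AUC 0.91. Used as folding
restraints they raise the prediction's geometric-mean accuracy from
0.76 at a generic slope/intercept to 0.92 at the grid-search optimum.
The same commands with `--reagent NAI-like` (the poorly permeable
preset) give S/N ≈ 1.3 and AUC ≈ 0.65–0.70.

The Python API mirrors the CLI (`shapebench.count_mutations`,
`signal_to_noise`, `roc_from_structure`, `grid_search`,
`simulate_experiment`, `compare_reagents`, ...).

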
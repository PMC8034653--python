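# Methods

This note documents the models, conventions and design choices behind
`shapebench`, in the order data flows through the pipeline.

## Mutation counting

Input is a set of aligned mutational-profiling reads (text SAM) against
a single reference. Only primary, mapped alignments are counted. The
semantics, per read:

- A reference position gains **coverage** when an aligned base or a
  deletion spans it and its quality passes the threshold (`qmin`,
  default Phred 20, the conventional cutoff). A deletion inherits the
  minimum quality of its flanking read bases.
- **Events** are mismatches to the reference (called from the reference
  sequence, not MD tags — one source of truth), deletions (each deleted
  reference position counts once), and insertions (charged to the
  reference position immediately 3′ of the insertion site; configurable,
  since profiling tools differ here). A read contributes at most one
  event per position, so `counts ≤ coverage` is an invariant.
- A deletion whose placement within a repeat is ambiguous is
  re-aligned to its **rightmost equivalent placement** (shift right
  while `ref[p] == ref[p+L]`), mirroring the right-realignment option of
  standard MaP counters. This deliberately redistributes deletions
  within homopolymer runs; tests that compare counts against true
  simulated per-base rates therefore switch realignment off.
- Mismatching or inserted bases equal to `N`, and positions where the
  reference is `N`, are never events.

Frequencies are `counts / coverage`, reported only where coverage ≥
`min_coverage` (default 100; rRNA-scale experiments are much deeper, and
the floor keeps shallow tails out of the statistics).

Raw-read quality filtering (`filter_reads`) trims terminal `N`s and
terminal bases below `qmin` from both ends and discards reads with
internal `N`s; it operates on unaligned reads, upstream of mapping.

The hot loop is a numba kernel over column-packed read batches; the test
suite checks it against an independent per-column pileup that places
ambiguous deletions by exhaustive enumeration of equivalent placements.

## Reactivity

Two transforms, both NaN-preserving (missing stays missing):

- **Control subtraction**: `max(0, f_treated − f_control)`, undefined
  wherever either channel is undefined.
- **Box-plot normalization**: values above Q3 + 1.5·IQR are set aside as
  outliers; the normalizer is the mean of the top 10% of the remaining
  values; every value, outliers included, is divided by it. This is the
  community default for preparing SHAPE restraints; alternative schemes
  (2–8%, windowed) are out of scope. At least 10 defined values are
  required, and an all-zero profile is an error (no signal to scale by).

Convention: the hairpin signal-to-noise statistic and ROC curves are
computed on **raw treated-channel frequencies** by default (background
subtraction optional, and reported alongside in practice); folding
restraints default to control-subtracted, normalized reactivities.

## Hairpin signal-to-noise

Hairpins are found on the **literal dot-bracket string** with the
pattern `([\(]{3}\.{3,}[\)]{3})` — three stacked opening brackets, a
loop of ≥ 3 dots, three closing brackets — after flattening every
non-`()` character (pseudoknot layers) to a dot, since the pattern knows
only `(`, `)` and `.`. Consequences accepted deliberately: a bulge
interrupting the closing helix disqualifies a hairpin, and a pseudoknot
bracket rendered inside a helix hides it from the statistic. A
structure-aware variant (walk the pair table, require three consecutive
stacked closing pairs) exists behind `structure_aware=True` for users
who want the topological definition.

Per hairpin, the loop statistic is the median reactivity over the first
two and last two loop bases (distinct positions — a 3-nt loop evaluates
3 bases, not 4 with one doubled) and the stem statistic the median over
the three bases before plus the three after the loop. The S/N is the
median of per-hairpin loop statistics divided by the median of
per-hairpin stem statistics. The wording "across all the loops" is
ambiguous between per-loop and pooled medians; per-loop medians are the
default (each hairpin weighs equally regardless of loop size) and the
pooled variant is computed alongside in verbose mode. Hairpins with any
undefined evaluated base are skipped and reported.

`loop_position_profile` reports the median across hairpins at each
loop-relative position: −3…−1 (5′ stem), 0, +1 (first two loop bases),
and mirrored from the 3′ side (0′ = last loop base, −1′…−3′ = 3′ stem).

## Pairing states and ROC

A paired base `i` with partner `j` is **internally paired** iff both
`(i−1, j+1)` and `(i+1, j−1)` are pairs; otherwise it is **terminally
paired** (helix ends and isolated pairs). ROC ground truth: unpaired →
positive, internally paired → negative, terminally paired → excluded
(their flexibility is ambiguous; one shared definition serves both the
ROC exclusion rule and pairing-state summaries). With an accessibility
mask (in vivo evaluation), bases outside the mask are excluded; bases
with undefined frequency are excluded at evaluation time. When several
molecules are evaluated, bases are pooled into one curve by default,
with per-molecule curves available.

The threshold sweeps 0 → 1 in steps of 0.001; at each threshold a base
is called when its frequency **strictly exceeds** it (ties at grid
values therefore shift a point by one step — documented, and bounded by
the quantization analysis below). The curve is augmented with (0,0) and
(1,1) so the AUC (trapezoidal) is well defined even when no value
crosses the extreme thresholds. The swept AUC equals the exact
rank-statistic (Mann–Whitney, tie-corrected) AUC within 1.5× the step;
the suite verifies a 0.0015 bound on random inputs.

## Solvent accessibility

Shrake–Rupley SASA with a deterministic golden-angle spiral lattice:
each atom's van der Waals sphere is expanded by the probe radius
(default 3.0 Å — sized to a probing reagent, not water) and sampled
with `n_points` directions; the accessible fraction is the fraction of
points outside every neighbour's expanded sphere; per-residue SASA sums
the atom areas. Radii come from the standard Bondi element table frozen
in the package (unknown elements fall back to 1.50 Å). The default
`n_points` is 2048: at 960 points, doubling the count can still move a
partially occluded atom's area by ~3% (lattice quantization), while
2048 meets a 2% doubling-stability bound on backbone-like fixtures.

Because absolute SASA values depend on the radius table and sampling,
the interface to ROC is the **accessible set** — residues with SASA
strictly greater than a configurable threshold, default 2.0 Å² (the
conventional cutoff is printed as "2 Å" in the literature; it is an
area) — rather than raw areas. Mapping from PDB chain/residue numbers to
transcript coordinates is the caller's responsibility (chain + offset).

## Restrained folding and evaluation

Reactivity enters folding as a per-nucleotide pseudo-free energy
ΔG(i) = m·ln(r_i + 1) + b (kcal/mol), charged to **both partners of
every formed pair**; missing reactivities contribute no term. With
m = b = 0 the restrained fold is bit-identical to the unconstrained one
(same code path, zero penalties).

Engines implement one contract: sequence + per-base pairing penalties +
(max pairing distance, lonely-pair switch) → one pseudoknot-free
structure.

- **Built-in engine** (default, used by all evaluation machinery): a
  deterministic minimum-energy dynamic program over a simplified nested
  model — Watson–Crick/wobble pair energies (GC −3.0, AU −2.0, GU −1.0
  kcal/mol), a −1.5 helix-continuation bonus, loop-opening penalties
  (hairpin +3.5, single-base bulge +3.0, 1×1 internal loop +2.5,
  multiloop +4.0), minimum hairpin loop of 3. These constants are not a
  fitted nearest-neighbour set; they make stacked helices favourable and
  loops costly, which is all the benchmarking machinery needs. Ties
  resolve to the first option in a fixed order, so output is
  deterministic. Lonely pairs are removed by iterative post-processing
  when disallowed (default).
- **ViennaRNA adapter** (optional): applies the same per-base penalties
  as per-pair soft constraints (`penalty[i] + penalty[j]` on pair i/j,
  Vienna's native convention), with `max_bp_span` and `noLP` mapped to
  the contract options, for thermodynamically realistic predictions.

Predictions are scored by PPV (predicted pairs present in the
reference) and sensitivity (reference pairs recovered) under the
**relaxed comparison**: pair i/j matches if the reference holds i/j,
i−1/j, i+1/j, i/j−1 or i/j+1. The relaxation is applied symmetrically on
both sides (a reference pair is recovered if any predicted pair sits in
its one-nucleotide neighbourhood); strict mode is available. The summary
is the geometric mean √(PPV·sens). A prediction with no pairs scores
PPV 0 by convention.

The slope/intercept **grid search** folds every RNA at each (m, b),
scores it relaxed, and stores the mean of per-RNA geometric means
(mean-of-gmeans rather than pooled counts: each molecule weighs equally;
both aggregations are recoverable from the stored per-RNA array). Fold
failures invalidate a cell without aborting the search. Ties at the
maximum resolve toward smaller |m|, then smaller |b| (the least
constrained of the equally good cells). Default grids are m ∈ [0, 5]
step 0.2 and b ∈ [−3, 0] step 0.2, bracketing the slope/intercept pairs
that perform well on real probing data.

## Synthetic data

The generator emulates what a MaP experiment measures, not how a
sequencer produces reads:

- **Structures**: pseudoknot-free nested structures built by recursive
  stem-loop placement (helix and loop lengths uniform on [3, 8],
  spacers of 0–3 nt, nesting up to depth 4), guaranteeing at least one
  hairpin the S/N pattern can see. Mean paired fraction at 100 nt falls
  in 0.4–0.7, rRNA-like. Paired positions get complementary bases
  (GC 56%, AU 34%, GU 10%); unpaired positions are uniform.
- **Rates**: per-base modification probabilities per read. Unpaired
  bases draw from Gamma(shape 4, scale 0.004) (flexible bases vary but
  are rarely silent), paired bases from Exp(mean 0.004) (mass near
  zero), both scaled by a membrane-**permeability** factor and offset by
  the background error floor e = 0.002 (the scale of DMSO-control
  mutation frequencies in deep rRNA data). The drawn rate is the
  *combined* per-read Bernoulli probability (modification and
  background are not simulated as separate coin flips), so the truth
  table is exactly what counting should recover.
- **Presets**: `2A3-like` (permeability 1.0) has an implied loop/stem
  S/N of ≈ 3.5 — the regime of a strong membrane-permeable reagent;
  `NAI-like` (permeability 0.05, same intrinsic chemistry) lands at
  ≈ 1.3, the regime of a reagent that barely enters cells; `DMSO`
  (permeability 0) is the pure background control. A preset's
  `expected_snr` is computed from its distribution medians, so tests
  compare realized against implied values rather than hand-entered ones.
- **Reads**: uniform random start positions, fixed read length,
  constant base quality (Phred 37). Each covered base mutates
  independently with its rate; a mutation is realized as a mismatch to a
  random non-reference base (2/3) or a single-base deletion (1/3) — an
  arbitrary but fixed split that exercises both counting paths. Output
  regenerates bit-identically from the seed.

Not modelled: coverage heterogeneity, RT drop-off, position- or
quality-dependent error profiles, paired-end reads, multi-base
deletions, structural heterogeneity of the RNA ensemble. Passing
end-to-end tests therefore shows the *pipeline* preserves and ranks the
simulated contrast correctly; it does not certify performance on real
libraries, where these unmodelled effects shrink the usable signal.

## Benchmark problem sizes

The end-to-end reagent comparison runs 300-nt molecules with 50,000
reads of 150 nt per channel (≈ 25,000× coverage, deep enough that
frequency noise does not dominate the weak preset) and a benchmark grid
of m ∈ {0, 0.5, …, 5} × b ∈ {0, −0.4, −0.8, −1.2}. The full slope range
matters: truncating it at m = 3 clips the optimum for strongly
structure-encoding reactivities and distorts the comparison. Across 100
seeded experiments the strong preset beats the weak one in S/N and AUC
in 100% of seeds and in grid-search best gmean in 95% (the remainder
are mostly exact ties where both reagents' restrained folds coincide on
an easy structure).

## Known limitations

- The built-in engine's energy model is intentionally minimal; absolute
  prediction accuracies are not comparable to nearest-neighbour engines,
  only differences under identical conditions are meaningful.
- SASA values differ from tools with other radius tables or analytic
  surfaces (e.g. POPS); only the accessible set at a stated threshold is
  a stable interface.
- The regex hairpin definition is string-literal by design; structures
  rendered with unusual bracket conventions should be normalized first
  (or use the structure-aware variant).
- CIF input and BAM are not supported (pre-convert to PDB / text SAM).
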
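# Methods

This note records the statistical model behind `ecmforest`, the default
parameters and why they were chosen, and what the synthetic experiments
do and do not demonstrate.

## Problem setting

Binary classification of proteins as extracellular-matrix (ECM,
positive) or non-ECM (negative). The operational difficulty is class
imbalance: realistic annotation sets contain roughly one positive per
ten negatives (the package's reference imbalance is 410 positives to
4464 negatives). Under imbalance, plain accuracy is a misleading
objective, so all evaluation is phrased in sensitivity (Sn),
specificity (Sp) and balanced accuracy BAcc = (Sn + Sp)/2, computed
from confusion counts pooled over cross-validation folds rather than
averaged per fold (pooling weights every protein equally and avoids
undefined per-fold rates when a fold holds few positives).

## Feature encoding (315 dimensions)

Blocks are concatenated in a fixed canonical order so that a feature
name always denotes the same quantity: `ffg`, `entropy`, `dist`,
`trans`, `pseaac`, `dwt`, `pssm`, `diso`, `ssi`, `fdi`. Sequence-only
blocks (`ffg`, `entropy`, `dist`, `trans` — 77 features) need nothing
but the sequence; physicochemical blocks (`pseaac`, `dwt` — 82) need
only property scales; the remainder need auxiliary profiles.

Choices that were genuinely open, and how they were resolved:

- **Functional groups.** The ten side-chain groups (phenyl, carboxyl,
  imidazole, primary amine, guanidino, thiol, sulfur, amido, hydroxyl,
  nonpolar) partition the 20 amino acids exactly; this is asserted at
  import time. Transition features use unordered pairs (45 = C(10,2))
  and are normalized by sequence length `L`, not `L − 1`, so the block
  is comparable across the length range without a separate length
  feature.
- **PseAAC.** Type-I with `η = 20` tiers and weight `w = 0.05`. The
  correlation factor is the mean squared difference of four property
  scales (Kyte–Doolittle hydrophobicity, Bhaskaran–Ponnuswamy
  flexibility, side-chain net charge, Rose accessible surface area),
  each standardized to zero mean and unit population SD over the 20
  amino acids before use, so no scale dominates by units. The 40
  components sum to 1 by construction. Sequences with `L ≤ η` are
  rejected rather than silently padded.
- **DWT.** Daubechies-4, decomposition level 4, symmetric padding.
  Retaining all five sub-bands with four statistics each would give
  66 features per run; the block instead keeps the raw signal's mean
  and SD plus the four statistics of the three most informative
  sub-bands (`cA4`, `cD4`, `cD3`) — the approximation band and the two
  coarsest detail bands — for 14 features per property and 42 total
  over three property signals. The finest detail bands mostly encode
  residue-to-residue noise at this level. Level 4 with db4 requires
  `L ≥ (8 − 1)·2⁴ = 112`; shorter sequences are rejected with advice
  to lower the level.
- **PSSM descriptor.** Scores are squashed by the logistic sigmoid
  before the lagged squared-difference statistic, so a single extreme
  log-odds value cannot dominate. Lags 1–4 capture local conservation
  structure; columns are reordered to the canonical alphabetical
  amino-acid order regardless of the input file's column order.
- **Disorder.** A residue counts as disordered iff its score ≥ 0.5
  (inclusive threshold, matching the convention of treating 0.5 as a
  positive call). The eight features are mean, SD, segment counts and
  min/max run lengths per state.
- **SSI.** All segment-count and joint-distribution features are
  divided by `L`; the 30-cell group × state table therefore sums to 1
  and is a proper joint distribution.
- **FDI.** The domain vocabulary is data-derived: accessions seen in at
  least `min_count` distinct positive proteins, ordered by descending
  count then accession. The indicator block's width equals the
  vocabulary size (17 for the generator's planted vocabulary), so the
  315 total is a property of that vocabulary, not a constant of the
  method.

## Feature selection

Gain ratio IGR(F) = (H(C) − H(C|F)) / H(F), base-2 entropies, defined
as 0 when H(F) = 0 (a constant feature carries no information and must
not rank by 0/0). Continuous features are discretized into 10
equal-frequency bins; equal-frequency was preferred over equal-width
because heavy-tailed blocks (PSSM, DWT) would otherwise collapse into
one bin. Ties in IGR are broken by canonical column order so the
ranking is deterministic. IFS evaluates ranked prefixes (step 1 by
default, always including the full set) by cross-validated BAcc and
selects the smallest prefix within δ = 0.001 of the best — preferring
parsimony over an insignificant BAcc gain.

## Imbalance handling

With `n⁺` positives and `n⁻` negatives, the number of ensemble members
is `K = max(1, ⌊n⁻/n⁺ + 0.5⌋)` — explicit floor-of-x-plus-half
rounding, not banker's rounding, so K is reproducible across platforms.
At the reference imbalance 410:4464 this gives K = 11. Negatives are
shuffled once (seeded) and split into K near-equal disjoint groups;
each member trains on one group plus all positives, so every negative
is used exactly once and every positive K times. Prediction is majority
vote; an exact tie (possible for even K) is resolved positive, on the
argument that the cost of missing a true ECM protein exceeds that of a
false alarm. Member k is seeded `seed + 1000·k`, and rows are presented
in matrix order, so K = 1 reduces bitwise to a single forest — a
property the test suite asserts.

Random forests use 10 trees, unlimited depth, and `⌊log₂ d⌋ + 1`
candidate features per split (d = number of features), a classical
default that keeps individual members cheap; the ensemble, not tree
count, carries the variance reduction.

## Synthetic data and the experiments

The generator plants a collagen-like signal in positives: G/P-enriched
composition, coil-heavy secondary structure, elevated disorder
(mean 0.35 + 0.3·s), and 17 planted domain accessions occurring with
probability 0.05 + 0.45·s in positives versus 0.05 in negatives, where
`s ∈ [0, 1]` is the signal strength. At `s = 0` every channel is drawn
from the identical label-independent distribution. PSSMs are derived
from the sequence alone, so they carry signal only insofar as the
sequence does. Generation is byte-identical under a fixed seed.

Experiment conditions are fixed design choices, not tuned values:

- **Signal recovery / null calibration:** 100 + 100 proteins, 10-fold
  CV. At `s = 1` the pipeline should reach BAcc ≥ 0.9 (it reaches 1.0);
  at `s = 0` it should sit at chance (observed 0.445–0.555 across
  seeds, within the ±0.1 band).
- **Imbalance sweep:** signal 0.3, 30 positives + 300 negatives,
  ratios 1:1…1:10, 3 repeats, 5-fold CV, single classifier (no
  ensemble) so the pathology is not masked. Moderate signal is
  essential: at high signal the classifier is error-free at every ratio
  and the effect is invisible. Observed: Sn falls monotonically
  (Spearman ρ ≈ −0.9), Sp rises, plain accuracy *increases* as the
  classifier degenerates toward the majority class — the
  accuracy-inflation pathology in one table.
- **Ensemble fix:** on the same 1:10 set, 5-fold CV with the
  undersampling ensemble versus a single forest. The ensemble roughly
  doubles sensitivity (e.g. 0.93 vs 0.43 at seed 1) at equal or better
  BAcc.

What these experiments show: the implementation recovers a planted
signal, stays at chance under the null, reproduces the known
imbalance pathology, and the ensemble corrects it. What they do not
show: performance on real proteomes. The synthetic signal is far
cleaner than biological ECM signatures; absolute numbers here are
properties of the generator, and only the qualitative contrasts
(signal vs null, single vs ensemble, ratio trends) transfer.

## Reproducibility

All stochastic components take explicit seeds; derived seeds use fixed
offsets (member `+1000·k`, fold `+7919·(f+1)`, sweep repeat
`+104729·(rep+1)+r`) chosen as distinct primes to avoid accidental
stream collisions. Feature matrices are serialized at 10 significant
digits, which round-trips float64 to within write precision.
`scripts/acceptance.py --seed S --out f.json` recomputes every headline
quantity from scratch and is byte-deterministic in `S`.
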
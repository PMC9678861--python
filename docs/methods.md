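# Methods

## Model and procedure

A whole-slide image is represented by a single feature vector, the mean of
its patch-level deep features (MFV); every sample carries a primary
diagnosis, a source institution, a tumor-type grouping and a
train/validation/test split. Feature selection is a search over binary
masks m ∈ {0,1}^D scored by three objectives, all in minimization
orientation:

1. **Retrieval loss** f₁(m) = 1 − macro-F1 of k-nearest-neighbour
   diagnosis classification, validation split queried against the training
   split on the masked columns. Per-class one-vs-rest precision
   TP/(TP+FP), recall TP/(TP+FN), F1 = 2PR/(P+R); macro averaging is
   unweighted over the classes present in the truth vector, so small
   diagnoses count as much as large ones. Ratios with zero denominators
   are defined as 0.
2. **Feature ratio** f₂(m) = popcount(m)/D, exact.
3. **Bias indicator** f₃(m) = accuracy of a one-vs-rest linear-kernel SVM
   (C = 1, no class weighting, features used as-is) trained on the
   training split to predict the source institution, evaluated on the
   validation split. High values mean the masked representation still
   leaks acquisition-site signatures.

The optimizer is a binary-encoded NSGA-III. Each generation: binary
tournament on non-domination rank (ties uniform at random), one-point
crossover with probability 0.9, independent per-bit mutation at rate 1/D,
repair of all-zero masks (one uniform random bit set), evaluation of the
offspring, then environmental selection of the parent∪offspring union by
fast non-dominated sorting plus reference-point niching on a Das–Dennis
simplex lattice (divisions = 12, hence C(14,2) = 91 reference lines for
three objectives). An elitist archive retains the non-dominated set over
every mask ever evaluated. Final reporting picks the archive member with
maximal validation F1 (ties: smaller feature ratio, then smaller site
accuracy, then lexicographically smallest mask) and re-scores it with the
test split queried against training.

Assumptions worth making explicit: retrieval quality is measured through
k-NN as a search-based classifier, so the objective rewards masks under
which same-diagnosis slides are mutual near neighbours; the bias indicator
assumes a *linear* probe is a sufficient detector of site leakage; and the
wrapper design means every fitness call refits the probe, which is exact
but makes the SVM fit the dominant cost per evaluation.

## Tunable parameters

| parameter | default | units / range | why |
|---|---|---|---|
| `population_size` | 50 | individuals, even ≥ 4 | experimental protocol default |
| `fitness_budget` | 512,000 | objective evaluations | protocol default; desk runs pass ~10,000 |
| `k_neighbors` | 3 | neighbours | experimental protocol default |
| `svm_C` | 1.0 | SVM regularization | unstated upstream; pinned for reproducibility |
| `crossover_probability` | 0.9 | per pair | textbook GA default |
| `mutation_rate` | 1/D | per bit | textbook GA default |
| `reference_divisions` | 12 | lattice divisions | canonical NSGA-III density for M = 3 |
| `init_density` | 0.5 | P(bit = 1) at init | unbiased start; a sparse option (e.g. 0.05) suits problems where good subsets are known to be tiny |
| `seed` | 0 | — | single generator feeds all randomness; replicate r uses seed + r |

Budget accounting: duplicate masks are served from an evaluation cache but
still consume budget, so "fitness calls" matches the number of objective
evaluations requested, not SVM fits performed. Generations =
⌊(budget − population)/population⌋; the loop stops when another full
offspring batch would exceed the budget.

## Synthetic benchmark: what it emulates

The generator plants four kinds of dimensions: *class* dims shifted by a
diagnosis centroid, *site* dims shifted by an institution centroid,
*confounded* dims shifted by both (means add), and pure Gaussian *noise*.
Centroids are rows of a seeded random orthonormal frame scaled so that
every pair of centroids in a block of d dims sits at `effect`·√d noise
standard deviations — i.e. effects are expressed **per informative
dimension**, the usual convention in batch-effect simulation, which makes
the planted signal pool across a block the way correlated deep-feature
channels do. Placing n equidistant centroids requires a block of at least
n dims; the generator refuses otherwise.

Site↔diagnosis confounding is modeled on the *label distribution*: each
diagnosis draws sites from (1−γ)·uniform + γ·block, where the blocks
partition the sites round-robin across diagnoses. γ = 0 gives independent
labels; γ = 1 concentrates each diagnosis on a disjoint site block (and
requires at least as many sites as diagnoses). This mirrors the empirical
situation in multi-center cohorts where institutions contribute skewed
case mixes — the mechanism that lets retrieval cheat off site signal.
Note a consequence: with γ > 0 the site labels are predictable from the
diagnosis alone, so even a perfectly de-biased mask cannot push the site
probe all the way to 1/n_sites; chance-level site accuracy is only
reachable at γ = 0.

Defaults (the benchmark conditions): 16 class, 16 site, 8 confounded and
88 noise dims (D = 128); 4 diagnoses, 6 sites; class and site effects 2.0
SD per dim; γ = 0.6; noise SD 1; 60/20/20 samples per diagnosis per
split, assigned by the diagnosis-stratified splitter (never balanced on
site — that would erase the confounder the method must face).

What the generator does **not** model: images, stain or scanner variation
(only their downstream feature-space signature), heavy-tailed or
correlated noise, per-site sample-size imbalance beyond what confounding
induces, and any nonlinear class structure. Passing the recovery tests
therefore shows the optimizer removes *linearly decodable, additively
planted* site signal under label confounding — not that it removes every
bias a real cohort can carry.

## Numerical choices

- k-NN ties: majority vote among the k neighbours; a vote tie goes to the
  nearer neighbour's label; distance ties resolve to the lower
  training-row index (stable sort). Deterministic by construction.
- Objective normalization for niching: per-component ideal-point shift and
  range division over the candidate union, zero ranges replaced by 1. This
  deliberately replaces canonical NSGA-III extreme-point/intercept
  normalization — simpler and robust for three bounded objectives; the
  hyperplane-intercept variant is available via `normalization=
  "hyperplane"` and falls back to range division when the intercept system
  is degenerate.
- Niching: candidates associate to the reference line of smallest
  perpendicular distance; the emptiest niche picks next (ties uniform at
  random), taking its perpendicular-closest candidate when empty and a
  random associated candidate otherwise.
- Wilcoxon signed-rank: zero differences dropped, midranks for ties,
  statistic min(W⁺, W⁻); exact conditional sign-permutation p (subset-sum
  counting over doubled ranks, so midranks stay integral) for n ≤ 25,
  normal approximation with tie and continuity corrections above; a single
  nonzero difference yields p = 1; all-zero differences are an error.
- Feature values are float64 internally regardless of on-disk width; the
  delimited format round-trips within 1e-12 relative tolerance, the HDF5
  format bit-exactly.
- Empty masks are never evaluated: they are repaired to a single random
  bit before scoring.
- Run outputs contain no timestamps or wall-clock fields, so identical
  config and seed reproduce byte-identical archives, result files and
  reports; wall time is kept in memory only.

## Design decisions that were genuinely open

- **Effect-size convention.** "Effect" could mean total centroid
  separation or per-dimension shift. Total separation spread over a
  16-dim block leaves a 6-site linear probe near 50% accuracy — a regime
  where the all-features representation is not convincingly biased and
  the benchmark cannot exhibit the phenomenon it exists to test. The
  per-dimension convention was adopted; with it the all-features probe is
  near-perfect and de-biasing is measurable.
- **Probe refit per fitness call.** The SVM is refit exactly for every
  evaluated mask (cached for duplicates). An approximation (e.g. warm
  starts or subsampled probes) would be faster but makes f₃ depend on
  evaluation order.
- **Which front to report.** Both the final population and the
  all-time elitist archive are returned; picking and reporting use the
  archive, which can only be better than the final population's front.
- **Wilcoxon pairing.** Replicate-paired comparison of the selected-mask
  metric against the all-features metric on the same data, per tumor
  type; significance flagged at two-sided p < 0.05.
- **Desk-scale problem sizes.** The shipped tests and the acceptance
  script run the 128-dim benchmark with a 10,000-call budget and 3–5
  replicates, and smaller 32-dim tables elsewhere — sizes chosen so a
  full verification pass completes on one CPU in minutes while still
  exercising every component at realistic class/site/noise proportions.

## Known limitations

- Wrapper selection overfits the validation split: the picked mask's test
  F1 is routinely below its validation F1. The protocol accepts this (the
  pick is by validation F1; reporting is on test).
- With label confounding γ > 0 the site probe cannot reach chance for any
  diagnosis-preserving mask (see above); bias reduction must be judged
  against that floor, not against 1/n_sites.
- The bias indicator is linear; site signal decodable only nonlinearly
  would not be penalized.
- The compactness objective prunes redundant informative dimensions: when
  few class dims already saturate retrieval F1, the max-F1 pick keeps a
  small subset of them rather than the whole planted block. Recovery of
  *all* planted class dims is not a goal the objective vector rewards.
- Tumor types with a single diagnosis in the training split are skipped:
  there is no retrieval problem to optimize.
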
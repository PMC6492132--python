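# Methods

`fcstates` implements a complete functional-connectivity (FC) brain-state
discrimination pipeline — simulate (or load) multi-node time series, extract
node series from voxel data, filter, estimate network matrices, classify
states with leave-one-subject-out cross-validation, and compare pipeline
variants statistically — together with the synthetic study generator used to
test it. This note documents the models, the defaults and why, the numerical
choices, and what the synthetic results do and do not show.

## The discrimination pipeline

**Dependency measures.** For each scan (one node-by-time matrix per subject
and state) the package computes one of four measures: per-node variance
("amplitude"), sample covariance, Pearson correlation with Fisher
z = atanh(r), and ridge-regularized partial correlation. The ridge estimator
scales the sample covariance to unit mean diagonal before regularization,

    Σ̃ = Σ̂ / mean(diag Σ̂),   P = (Σ̃ + λI)⁻¹,
    ρᵢⱼ = −Pᵢⱼ / √(Pᵢᵢ Pⱼⱼ)   (i ≠ j),

which makes one λ grid (default 0 to 5 in steps of 0.1, extensible)
comparable across node sets and signal scales. At λ = 0 this equals the
textbook partial correlation obtained by correlating residuals after
regressing out all other nodes; the equivalence is asserted to 1e−8 in the
tests against exactly that independent oracle. Partial correlation estimates
*direct* dependence — the association between two nodes after removing the
linear influence of every other node — whereas full correlation mixes direct
and indirect paths and shared global variance.

**Fisher z.** Full correlations are z-transformed (|r| clipped at 1 − 1e−7
so features stay finite); partial correlations are z-transformed by default
as well (configurable) since the transform stabilizes variance either way.

**Features and normalization.** Matrix measures are vectorized to the strict
upper triangle in fixed row-major pair order (n(n−1)/2 features); amplitude
contributes n features; diagonals are excluded. Each feature is then
ratio-normalized within subject: divided by that subject's across-state mean
of the same feature. The normalization cancels subject-specific multiplicative
edge-strength factors exactly and uses only a subject's own scans, so it is
leakage-free under subject-wise cross-validation by construction.
Denominators within 1e−12 of zero (relative to the feature's overall scale)
would produce unbounded values; those features are set to 0 for that subject
and flagged. Note the ratio is only well behaved when a feature's
within-subject mean sits away from zero — a property real FC data (largely
positive, stable edges) typically has, and which the generator reproduces
(see below). No further standardization is applied.

**Classification.** Multiclass linear soft-margin SVM (libsvm's native
one-vs-one reduction, ties resolved by aggregate decision values), with an
optional k-NN alternative. The C grid is eight log-spaced values from 1e−3
to 1e3; the stated range and count admit only this natural spacing. Outer
cross-validation is leave-one-subject-out (LOSO): all states of one subject
form each test fold. When partial-correlation features are used with several
λ values, an inner LOSO loop over the training subjects evaluates every
(λ, C) pair and the inner-accuracy maximizer is applied to the held-out
subject — λ ties break toward the smallest λ (least shrinkage), C ties
toward the largest C. C can alternatively be (a) fixed, or (b) reported as
the maximum over the grid on the held-out data (`select_c="max"`), the more
optimistic convention some studies use; the honest inner-selection mode is
the default. The libsvm solver is capped at 1e5 iterations — converged fits
use a few hundred; the cap only bounds run time if a degenerate feature
scaling slips through.

**Statistics.** Edge-wise state contrasts are paired two-sided t-tests on
Fisher-z values across subjects with Benjamini–Hochberg FDR (q = 0.05 and
0.2 conventions both supported); zero-variance differences report t = 0,
p = 1 with a flag rather than NaN. Pipeline pairs evaluated on identical
samples are compared with McNemar's test on the discordant counts b, c:
exact two-sided binomial for b + c < 25, continuity-corrected χ² =
(|b−c|−1)²/(b+c) on 1 df otherwise (both variants callable directly);
b + c = 0 gives p = 1. Accuracy lists across conditions are compared with
the Wilcoxon signed-rank test (zero differences excluded, mid-ranks for
ties, exact null for n ≤ 25 without ties, tie-corrected normal approximation
above; the reported statistic is the smaller rank sum). Benchmarks compare
every (measure × filter) cell against a baseline cell with BH-FDR over the
family; all cells of one benchmark share the dataset and fold plan so the
pairing is valid.

## Spectral conventions

Filtering is zero-phase (forward–backward) Butterworth of prototype order 4,
as second-order sections, with odd-reflection padding of 3× the prototype
order at each end; a band-pass therefore has 8 poles and the effective
attenuation is |H|². Zero-phase filtering is chosen because FC measures are
phase-sensitive; identical zero-phase filtering of jointly Gaussian channels
preserves their correlation matrix exactly. The four canonical analysis
bands are [0.005–0.096], [0.096–0.182], [0.182–0.298] and [0.298–0.385] Hz;
at TR = 1.3 s the top edge exceeds the Nyquist frequency (0.38462 Hz) by
about 0.1%, so `canonical_band_specs` clips a top edge within 1% of Nyquist
to 0.999·Nyquist. The "no filtering" pipeline is a 0.005 Hz high-pass
(drift removal only).

Welch PSD estimation uses at most eight segments with 50% overlap (segment
length ⌊T/4.5⌋, the pwelch convention), Hamming window, per-segment mean
removal, one-sided density scaling; the rectangle-rule integral of the
density approximates the series variance (checked to 10% on white noise).

## Extraction

Hard parcellations yield parcel-mean series; weighted spatial maps yield the
first step of dual regression — each data volume regressed onto all map
columns jointly by OLS (rank-deficient maps are rejected). Maps are not
variance-normalized and volumes are not demeaned before regression, since
maps may deliberately model mean structure; users can pre-demean. Node
series are always demeaned in time afterwards, as every downstream measure
is moment-based. Voxel inputs are plain matrices; a NIfTI adapter flattens
4D images and 3D label volumes. Geometry, registration and masking are out
of scope.

## The synthetic study generator

The generator emulates a within-subject steady-state design: default 15
subjects × 5 states × 230 timepoints at TR = 1.3 s (75 samples), matching
the emulated study's printed counts. Its generative model, per state and
frequency band, is a Gaussian graphical model:

* **Base connectome** — a shared support over node pairs (default density
  0.5) with precision off-diagonals drawn from ±U(0.3, 0.6), negative with
  probability 0.9 so that partial and full correlations are predominantly
  positive, as in real resting-state FC. Predominantly positive, stable
  edges are also what keeps the within-subject ratio normalization
  well-conditioned — on sign-symmetric synthetic connectomes that
  normalization amplifies noise instead.
* **Strong coupling** — diagonals are set to 0.3 + 0.6 × (row sum of
  |off-diagonals|), deliberately below strict dominance, so marginal
  correlations mix many direct edges; positive definiteness is enforced by
  multiplying the diagonal by 1.1 up to 50 times (a deterministic, testable
  rule; exhaustion raises an error flagging a pathological configuration).
* **State effects** — each state scales a designated 30% subset of support
  edges by 1 ± `edge_effect` (default 0.6): tasks modulate coupling strength
  without flipping edge signs. `edge_effect = 0` makes all states identical.
  Per-band multipliers (`band_effects`) confine effects to chosen bands.
* **Subject effects** — each subject carries per-edge multiplicative factors
  1 + `subject_sd`·N(0,1) (default 0.3), constant across states: exactly the
  nuisance the ratio normalization cancels.
* **Band-limited dynamics** — per band, i.i.d. multivariate normal vectors
  (Cholesky mixing) are band-passed with the same zero-phase filter on every
  channel ("filter after mix"), preserving the target correlation structure
  exactly while scaling variance by the band's |H|⁴ power fraction; bands
  are summed. The default single band (0.01–0.1 Hz) is the classic slow FC
  band.
* **Global signal** — each scan adds a shared noise series to all nodes with
  a scan-specific amplitude in [0.5, 1.5] × `global_signal_sd` (default 2).
  This state-independent shared-variance confound — the classic global
  signal of fMRI — inflates and destabilizes full correlations, while
  conditioning on the other nodes largely removes it from partial
  correlations. It is the mechanism by which the partial-vs-full contrast
  manifests here.
* **Amplitude effects and noise** — per-state node-s.d. vectors
  1 + `amp_effect`·{−1,0,+1} (default 0.2), plus additive white noise
  (default s.d. 0.2).

Ground truth (per-state/band precision matrices, their supports, amplitude
vectors) is exported for recovery tests. Randomness is split by a fixed rule,
`SeedSequence([seed, stream_id, *index])`, so enlarging the design never
perturbs existing samples.

**What the generator does not model:** hemodynamic convolution, physiological
noise spectra, head motion, spatial geometry, autocorrelated neural dynamics
beyond band-limiting. Consequently, passing tests demonstrate correctness and
calibration of the estimation and validation machinery under a Gaussian
graphical model with realistic design dimensions — not performance on real
fMRI.

## Study conditions used by the verification suite

The directional comparisons run on scaled-down designs chosen once:

* *Partial vs full correlation*: 24 replicate studies of 10 subjects × 5
  states × 14 nodes, T = 230, direct-edge effects only (`amp_effect = 0`),
  defaults otherwise; λ tuned over {0, 0.5, 1, 2} by nested LOSO; C fixed at
  1 for both measures (the regime where soft-margin selection saturates).
  More nodes strengthen the conditioning that removes the global confound,
  which is why this comparison uses 14 rather than the default 10.
* *Frequency specificity*: 20 replicate studies with the four canonical
  bands as simulation bands (top edge 0.384 Hz) and state effects confined
  to band 2 (0.096–0.182 Hz); correlation features from band-2-filtered
  versus band-4-filtered data.
* *Chance calibration*: 200 within-subject label permutations on a default
  study; C fixed at 1 (hyperparameter search is meaningless under the null).
* *Null safety*: 20 benchmark runs with all state effects zero
  (8 subjects × 8 nodes; correlation, amplitude and fixed-λ partial
  correlation cells against the correlation baseline, BH-FDR at q = 0.05).
* *Support recovery*: sparse base (density 0.3), single band, T = 10,000,
  λ = 0.01, edges ranked by |ρ| against the true support (AUC).

`scripts/acceptance.py` recomputes all of these from scratch from a single
master seed.

## Known limitations

* The element-wise ratio normalization is intrinsically fragile for features
  whose within-subject mean approaches zero; the package follows the stated
  contract (tiny-denominator guard, flags) and the generator documents the
  data regime in which the normalization behaves as intended.
* Nested λ selection with small subject counts has noisy inner-fold
  accuracies; selected λ values vary across folds (their per-fold mean and
  range are reported, in the style of an optimal-regularization summary).
* McNemar's exact and χ² paths disagree by up to ~0.02 in p near the
  b + c = 25 switch point; both variants are exposed.
* Spatial-map simulation uses abstract voxel vectors with neighbour-spill
  overlap, not volumetric geometry.
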
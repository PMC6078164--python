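# Methods

## Model and procedure

The pipeline targets time-course omics data collected under constant
conditions at a fixed sampling interval (default: CT24–CT81 every 3 h,
1–3 replicates per point). A feature is called rhythmic when its ranked
temporal profile is concordant with at least one cosine reference waveform
from a period/lag lattice, judged against the exact distribution of the
concordance statistic under random orderings.

**Statistic.** For reference values c and data x over the n samples,
S = Σ_{pairs i,j with c_i < c_j} sgn(x_j − x_i). Pairs tied in the
reference — replicates at one time point, or distinct times where the
sampled cosine coincides — are skipped; pairs tied in the data contribute
0; tau = S / (number of counted pairs).

**Exact null.** Under a uniformly random ordering of tie-free data, the
number of discordant cross-group pairs k is distributed as the coefficient
sequence of a product of Gaussian binomials, one per merge of a tie group
into the accumulated sample (the classical inversion-counting recursion).
S = M − 2k with M the number of counted pairs. The convolution is carried
out in exact integer arithmetic and normalized at the end, so the pmf is
exact to floating-point representation; the suite verifies total-variation
distance < 1e−12 against full enumeration for all tie patterns with up to
8 samples. Nulls are cached per tie-size multiset. Profiles with data ties
use the tie-free null, a conservative approximation; a tied-pair fraction
above ~10% in real data deserves scrutiny.

**Scan.** Periods run from 21 h to 27 h in steps of the sampling interval,
lags over [0, period) likewise; waveforms with identical sampled tie
patterns are collapsed, and the survivor count K is the per-feature
Bonferroni factor: adj_p = min(1, K × best one-sided p). Ties on p are
broken by larger |tau|, then smaller period, then smaller lag. The phase
estimate is the best waveform's lag; because the test is one-sided with
lags covering the full period, antiphase signals are captured at
lag ≈ period/2. A 12–18 h scan of the same data serves as a negative
control band: on 24-h-planted data it must find fewer positives.

**Amplitude.** The amplitude of a feature is the max/min ratio of its
replicate-averaged, un-detrended profile on the positive scale (log-scale
profiles are exponentiated first). Detrended or otherwise signed profiles
have no defined ratio and report NaN.

**Permutation FDR.** Detection runs once on the observed ordering; the
detected positives are removed; B permutations then shuffle time-point
blocks (replicates travel with their time point) and re-run the detection
on the remaining features. Each permuted positive count is rescaled by
N_total/N_remaining so the removed fraction does not deflate the expected
false-positive count. The estimate is mean rescaled count / observed
count; the empirical p is (1 + #{count_b ≥ observed}) / (B + 1).
Positive removal is single-pass, not iterated. Permutation is per-feature
by default — it destroys temporal structure while preserving each
feature's marginal distribution — with a joint whole-column mode behind a
flag for designs where cross-feature dependence matters. Default B is
1,000 at desk scale (tests use 200), configurable to 10,000.

## Preprocessing

- **Expression threshold**: a 2-component Gaussian mixture is fit by EM
  (scikit-learn, deterministic median-split initialization, tol 1e−6,
  ≤ 500 iterations) to log10 of positive mean expression; zeros are
  excluded as carrying no distributional information. The cutoff is the
  fitted normal quantile (default 0.95) of the lower-mean component,
  mapped to the linear scale — the fitted quantile, not the empirical
  quantile of posterior-assigned members, so the threshold is smooth and
  deterministic. Features with mean ≥ threshold pass.
- **Detrending** is per-profile OLS against CT hours, a projection
  (idempotent), leaving missing values missing. Each layer is detrended on
  its analysis scale; amplitude ratios always come from the un-detrended
  profile.
- **TMT normalization**: channels are aligned in log space by regressing
  each channel on the leave-one-out mean of the other channels per protein
  and inverting the fitted affine distortion. The leave-one-out consensus
  (rather than the all-channel mean) makes a known single-channel
  distortion exactly invertible, which is the behaviour the normalization
  is meant to have; plain, unweighted OLS is used. Two multiplexed sets
  join either as log-ratios to each set's pooled reference channel
  (primary mode, 2 × (1 reference + 9 samples) reproducing an 18-point
  CT30–CT81 course) or by within-set mean-centring (validation-style
  designs); only proteins quantified in both sets survive.
- **Metabolomics**: features keep only if their CV (linear-scale sd/mean)
  over pooled-QC injections is < 30%, and features eluting in a closed
  artefact retention-time window (default 19.15–19.35 min) are dropped.
  Samples are normalized by the median-of-log-ratios factor against the
  per-feature median reference profile, which exactly inverts any
  per-sample global scaling.

## Integration

Pairing is protein-centric: each protein keeps the candidate transcript
with the smallest adjusted p (ties: raw p, then lexicographic id — the
"most rhythmic" rule read as adjusted-first). Pair correlations are
Pearson coefficients of replicate-averaged profiles over a shared window
(default CT30–CT81, the proteomics span), computed on detrended profiles
by default since shared 24-h structure is the quantity of interest; raw
profiles are a flag away. Phase lags are circular differences
(right − left) mod 24 binned at the sampling interval. Cross-correlation
is truncated (non-circular) because ~2.4 periods do not tile; positive lag
means the right profile is delayed. PCA projects replicate-averaged time
points onto the first two axes of the feature-centred layer, tracing the
state-space trajectory.

Enzyme–metabolite integration crosses a (protein_id, ec_number,
metabolite_id) map against both datasets and keeps, per metabolite, the
enzyme with the largest |r| (ties prefer the positive sign, then the
smaller id). **Identifiability limit**: best-match recovery of a true
partner requires the candidate enzyme profiles to be distinguishable. Two
cosines with phase difference Δ correlate as cos(2πΔ/24), so a decoy
within ~1 h of the partner's phase — or of its antiphase, since the rule
uses |r| — is near-collinear with the truth, and when the partner's
amplitude-to-noise ratio is modest a cleaner decoy can legitimately win.
Recovery ≥ 90% therefore holds under low noise (σ ≈ 0.01 ln-units),
non-degenerate amplitudes (ratio ≥ 1.5) and a wide phase spread, and the
tests exercise exactly that regime; with tightly bimodal phases recovery
plateaus near 0.8 regardless of noise, which is a property of the problem,
not of the estimator. Correlations for this step are computed on log-scale
profiles, the scale on which the multiplicative coupling is linear.

## Synthetic data

The generator emulates: a bimodal log10-abundance baseline (lowly
expressed N(−1, 0.5) vs expressed N(1.5, 0.7), expressed weight 0.6 —
values chosen to give a sub-1-FPKM mixture threshold typical of bulk
RNA-seq); a rhythmic subpopulation (default 10%) carrying a cosine added
to the natural-log abundance so the max/min ratio is scale-invariant,
with ratios uniform in [1.2, 2.0] (amplitudes of two-fold or less);
peak phases from an equal-weight wrapped-normal mixture at CT0 and CT12
(sd 1.5 h); per-feature linear drift (sd 0.002 ln-units/h) and i.i.d.
Gaussian noise in log space (sd 0.1 ln-units); replicates sharing the
time point's noiseless value with independent noise. The protein layer
copies each transcript's noiseless rhythm shifted by 0 h or 12 h with its
own baseline and noise; the metabolite layer copies its designated
enzyme's rhythm with a random sign (positive with probability 0.5) and
carries pooled-QC injections simulated as technical replicates of the
per-feature grand mean (sd 0.1 ln-units). Truth tables record every
generating parameter per feature.

What the generator does **not** emulate: cell-cycle confounding, count
noise/overdispersion, missing-at-random or intensity-dependent missingness,
batch structure across TMT sets, isotope impurity, or non-sinusoidal
waveforms. Passing tests therefore demonstrate correctness of the
statistics under the stated generative model, not robustness to every
artefact of real data.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to keep Monte-Carlo
error well below the tolerances being asserted: 10,000 features for
type-I calibration (binomial SE ≈ 0.002 at α = 0.05), 1,000 features with
10% planted rhythms and B = 200 for FDR calibration, and 5,000 features
for the pure-noise FDR check (the observed null-call count fluctuates by
~8% of its mean there, so an estimate near 1 is attributable to the
estimator rather than noise). Reference-value ties are detected after
rounding to 9 decimals; the exact-null DP is integer-exact; detection and
permutation scans are vectorized across features, with a per-feature slow
path (reduced tie pattern, rebuilt null) for profiles with missing values;
features under 75% present are excluded and logged. All stochastic
operations take explicit seeds and are reproducible to the byte.

## Known limitations

- The exact null assumes tie-free data; heavily tied (e.g. zero-inflated)
  profiles get conservative p-values.
- The Bonferroni waveform adjustment is conservative when neighbouring
  waveforms are highly correlated, visible as adj-p rates below the
  nominal level on null data.
- Period resolution equals the lattice step (3 h); a true 24-h rhythm is
  occasionally assigned 21 h or 27 h under noise, which can displace the
  phase estimate by more than one bin even when detection is correct.
- The permutation FDR assumes features are exchangeable under time-label
  permutation; strong cross-feature dependence calls for the joint
  permutation mode and wider uncertainty.
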
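# Methods

## Data model

All analyses consume a `TrialAlignedSession`: units, trials and per-
(unit, trial) spike times on a go-cue-aligned axis (t = 0 at the go cue).
Epochs are presample (the 500 ms before the sample epoch), sample (1.3 s of
stimulus presentation), delay (1.3 s by default; 1.7 s supported) and
response (the 1.3 s after the go cue).  Trial conditions CR/CL/ER/EL encode
correct/error × *instructed* lick direction, so ER is a lick-right-instructed
trial answered left.  Units carry depth (for layer assignment at the
110 / 378.3 / 771.7 µm mean boundaries, half-open intervals) and spike width
(fast-spiking < 0.35 ms, pyramidal > 0.45 ms, 0.35–0.45 ms excluded;
boundary values are treated as intermediate, i.e. excluded, since the source
classification states only strict inequalities).

## PSTHs and the response matrix

PSTHs are trial-averaged rates on a 1-ms grid smoothed with a 100-ms causal
boxcar (edge-normalized; a Gaussian kernel is available).  The boxcar width
matches the 100-ms analysis windows used by the windowed statistics; the
kernel itself is a package choice, as is the interleaved odd/even split used
by the split-half consistency filter (units with split-half Pearson r < 0.5
are excluded; the threshold comparison is inclusive, r = 0.5 passes).  The
population response matrix concatenates the correct-trial lick-right and
lick-left PSTHs per unit, subtracts each segment's presample mean, and
divides the concatenated row by its Euclidean norm (normalizing the
concatenated row, rather than each segment, preserves the relative amplitude
of the two conditions).  Zero-norm rows are excluded and logged.  Long-delay
(1.7 s) matrices are matched to the 1.3-s grid by polyphase resampling of the
delay segment with linear-extension padding.

## Response landscape

Rows are reduced by PCA (default target: 98% variance), embedded by t-SNE
(cosine metric, perplexity 50, best of 10 restarts by KL divergence;
restarts use seeds seed..seed+9) and clustered by density peaks in the 2-D
embedding.  Local density uses a Gaussian kernel whose bandwidth is 2% of
the embedding diameter, floored at the median 5th-neighbor distance —
without the floor, sparse embeddings (a few hundred points) yield
single-neighbor densities that are essentially noise.  Centers are chosen
automatically at the largest *multiplicative* gap in the sorted γ = ρ·δ
sequence (scale-free, so a lone dominant peak is not split); manual center
lists and fixed counts are accepted for faithful reproduction of
hand-curated analyses.  Over-clustering is corrected by greedily merging
cluster pairs whose mean profiles correlate above r = 0.95 (no published
value exists; the merged fraction is available for checking the "<10% of
clusters" expectation).  Cluster reproducibility follows the two-way >50%
overlap rule against a second labeling, which defaults to Jaccard-weighted
kNN + Louvain communities.

## ePAIRS

Each neuron's coding vector (26-D PC loadings of its response profile, or
7-D activity-mode weights) contributes the mean angle to its k = 3 nearest
neighbors; the population median of these angles is compared with 10,000
medians simulated from a zero-mean Gaussian null whose per-dimension
variances match the data.  p is the fraction of null medians at or below the
empirical median; small p means the cloud clusters.  The angle is the plain
vector angle in [0°, 180°].  A folded variant (arccos |cos|, merging
antipodal vectors) is provided, but folding couples the statistic strongly
to the plug-in variance estimate and makes the test conservative in
calibration studies (empirical type-I error ~0.02–0.03 at nominal 0.05),
whereas the unfolded metric calibrates at ~0.03–0.05; unfolded is therefore
the default.  A k = 1–10 sensitivity sweep is provided
(`epairs_sensitivity`).

## Activity modes

Mode formulas are given in the README.  Implementation choices: epoch
averages are computed directly as mean spike counts over the epoch windows
(linear in the rates, hence identical to averaging 100-ms windowed
selectivity vectors over the epoch up to boxcar edge effects);
Gram–Schmidt order is stimulus → choice → action → outcome → ramping → go →
response (configurable; projections depend on it); the stimulus mode
averages over the sample epoch only; mode-definition and projection trials
are a 50/50 random per-condition split with a recorded seed; the response
mode's SVD sign is oriented so mean response-epoch activity projects
positively; bootstrap standard errors use 1,000 neuron resamples.
Variance- and selectivity-captured fractions are energy (sum-of-squares)
ratios of projections onto the orthonormal 7-mode subspace over the stated
epochs.

The random-mixture population rebuilds neurons as Gaussian-random
combinations of the seven modes plus the response-matrix eigenvectors
orthogonalized against them, with per-component weight variance 1/n so each
component carries its original population energy: population-level time
courses are preserved while per-neuron weights are scrambled.  Mixture rows
are left unnormalized (re-normalizing would break the component-energy
contract); weights recovered by least squares on the component time courses
are the substrate for the ePAIRS and angle comparisons.

## Functional populations

k-means runs on |mode weights| (signs encode trial-type preference, not
identity), 50 restarts, k chosen by the largest Euclidean silhouette over
2–12.  Populations are named for the mode whose projection variance they
dominate (ties to the larger population).  The two-mode angle analysis keeps
the top 20% of neurons by two-mode vector length and compares against a
matched random-mixture reference with a one-sided two-sample KS test on the
distance to the nearer axis (so excess mass at 0° and 90° both register in
the same tail).

## Decoding and noise correlations

Decoding uses linear SVMs (C = 1) in 200-ms windows at 50-ms steps on
pseudo-populations: every unit contributes its own trials, randomly matched
within condition, 70/30 train/test on disjoint underlying trials, class
counts balanced (for stimulus/choice/outcome the four trial types are
balanced, which makes the three binary labels pairwise uncorrelated —
outcome = stimulus XOR choice, so literally fixing the other two is
impossible).  Features are standardized on training-set statistics (the
liblinear solver penalizes the intercept, so raw counts distort the
separator); the epoch decoder standardizes per unit *across* windows, since
its signal is the between-window difference.  Accuracy is mean ± s.d. over
20 repeat matchings.  Four-way epoch decoding trains on windows fully inside
an epoch and evaluates every window by its center's epoch.

Noise correlation is the Pearson correlation of per-window (100 ms)
mean-subtracted spike counts across trials and windows, per trial type, pair
values averaging the two correct types.  Pairs must be >100 µm apart along
the probe (depth difference — the only geometry the container carries), have
≥10 trials per type, and each unit enters at most one pair (randomized
greedy maximal matching).  Within- vs across-cluster distributions are
compared with a two-sided Wilcoxon rank-sum test.

## Perturbation and connectivity statistics

Behavioral photoinhibition effects use the nested bootstrap: resample mice,
then sessions within each drawn mouse, then trials within each drawn session
(multinomial over outcome categories — exactly equivalent to resampling
individual trials); the one-sided p is the fraction of replicates whose
performance change has the sign opposite the observed one.  Performance is
the fraction of correct choices excluding early-lick and ignore trials.
Per-unit rate changes use Welch's two-tailed t-test on stimulation-window
counts at α = 0.01 with a 0.5-Hz control-rate floor.  Mode changes under
perturbation are |control − photostim| projection differences inside the
stimulation window, standardized by the control projection's s.d. across
time, lick directions pooled; manipulations are compared with a one-sided
10,000-resample neuron bootstrap.  Photo-tagging compares 20-ms pre/post
pulse counts (paired t-test), with latency at the first 0.5-ms bin reaching
half the peak baseline-subtracted rate; tagged requires p < 0.01, latency
< 5 ms (strict) and >0.2 evoked spikes per pulse.  EPSP features clip spikes
by −1/+4 ms interpolation, subtract the 10-ms pre-stimulus baseline, take
the 20-ms mean and the 10%-of-peak latency (noise floor 3× baseline s.d.);
connected means latency ≤ 5 ms at the 20-mW calibration power.  The membrane
time constant is the slow component of a double-exponential decay fit,
falling back to the dominant component when the second amplitude is
negligible (<5%) and therefore unidentifiable.

## Synthetic-session generator

Unit i's rate on trial k is

    λ_i(t) = max(0, b_i + Σ_m w_im f_m(t, cond_k) + g_k b_i)

with baseline b_i ~ U(4, 12) Hz, seven mode templates f_m scaled by 6 Hz,
per-trial shared gains g_k ~ N(0, gain_sd = 0.1) common to a subnetwork
(subnetworks default to the prototype partition), and spikes drawn as an
inhomogeneous Poisson process in 5-ms bins with uniform within-bin times.
Condition coefficients flip template signs: the stimulus template follows
the instructed pole position, choice/action follow the actual lick, outcome
is +1 on rewarded trials; error trials therefore dissociate stimulus from
choice exactly as the selectivity formulas require.  Ignore trials keep
stimulus coding with attenuated choice/ramping and no action/go; early-lick
trials develop choice/ramping faster.  Template shapes are chosen to be
separable in the windows that define the seven modes (the ramp holds
through the go-cue contrast window; the response transient starts after it),
and per-mode planted weight amplitudes (1.2× action, 1.3× go, 1.6× response)
compensate for the shorter defining windows and for the SVD-energy
competition of the response mode — without them some modes are planted but
not identifiable at realistic rates.  The hard floor at zero (rather than a
softplus) is the simplest non-negative model; it biases low-baseline units
with strongly negative modulation, which is why clustered prototypes use
positive weights.  In the `clustered` regime each unit inherits one
prototype's weights (±15% jitter); in `random_mixed`, weights are i.i.d.
N(0, 1/7).  Randomness is drawn from per-trial counter-based substreams of
the global seed, so any trial is reproducible in isolation.  Perturbations
regenerate photostimulation-trial spikes inside the stimulation window only,
from rates scaled per subnetwork.

What the generator does *not* emulate: bursting and refractoriness,
uninstructed-movement covariates, slow drift, electrode artifacts, and
cross-session heterogeneity of response shapes.  Passing recovery tests on
this model therefore shows the *pipeline* is correct and well calibrated,
not that real cortical data satisfies the model.

## Study sizes

Test-suite study sizes were fixed once to fit a single-CPU run: ePAIRS
calibration 350 null datasets per dimensionality (n = 500 vectors,
d ∈ {7, 26}, 400 null simulations per test) and 25 power datasets; mode
recovery 20 sessions of 120 units (80 correct + 20 error trials per type);
the demixing contrast one 300-unit session with 50 mixture draws; clustering
recovery 8 sessions of 280 units; nested-bootstrap calibration 400 null
datasets (3 mice × 2 sessions × 200 trials, 1,000 bootstrap replicates);
perturbation recovery 10 sessions.  `scripts/acceptance.py` uses one session
per analysis at the same per-session sizes.

## Known limitations

Density-peak auto-selection is a heuristic; hand-curated center selection
remains the reference procedure for real data.  The ePAIRS null conditions
on plug-in variances and is mildly conservative at d = 26 even unfolded.
The pseudo-population decoder ignores trial-to-trial correlations by
construction.  Session pooling assumes a shared time grid.  EPSP spike
detection uses a fixed −20 mV threshold rather than waveform matching.
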
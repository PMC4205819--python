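# Methods

This note documents the models, the synthetic-data design, the numerical
choices and the known limitations of `fetalconn`.

## Analysis model

**Connectome.** A subject's connectome is the Pearson correlation matrix of
cleaned ROI time series over retained frames, Fisher-Z transformed
(`Z = atanh(r)`, correlations clipped to ±(1−1e−7) first). The graph is
dense and weighted; no thresholding or binning is applied anywhere in the
pipeline. Edge classes are fixed across gestation from Euclidean distances
at the 37-week reference atlas: *short* edges are at or below the 25th
percentile of the off-diagonal distance distribution, *long* edges at or
above the 75th (linear-interpolation quantiles; boundary ties that would
fall in both classes count as short). A lobe's sub-network contains every
edge with at least one endpoint in that lobe; the interhemispheric class
contains every left–right edge.

**Preprocessing.** Per subject, in fixed order: (1) frame-to-frame
displacement `‖Δt‖₂ + R·‖Δr‖₂` with lever arm R = 50 mm; (2) censoring of
frames with displacement > 2 mm (row deletion, not interpolation — all
later statistics use retained frames only); (3) a single OLS confound
regression with intercept, the six rigid-motion parameters and the first
five principal components of the noise channels (CompCor); (4) 0.01–0.1 Hz
band-pass (linear detrend plus real-FFT mask, DC removed). The band-pass
and confound projections do not commute, so the confounds are projected
out once more after filtering; this makes residual–confound orthogonality
exact at the cost of re-admitting a numerically negligible amount of
out-of-band energy. Fewer than 10 retained frames flags the subject
unusable; fewer than 30 flags the estimate low-confidence.

**Edge inference.** Per edge, strength is regressed on gestational days
with per-subject mean retained displacement as a covariate; the age effect
is the 1-df F-test (equivalently the squared t of the age coefficient),
computed by residualizing both the strength and the age against
[intercept, motion] — this vectorizes over edges and over permutations.
NBS control: binarize F > 5, take connected components in the node–edge
sense, record extents (edge counts); for each of `n_perm` permutations
relabel gestational ages across subjects (motion stays with its subject),
recompute the F map and the maximum component extent; the FWER p-value of
an observed component is `(1 + #{null ≥ extent}) / (1 + n_perm)`.

**Spatial-closeness screen.** A parallel test against random graphs in
which mean connectivity is explained purely by spatial proximity: cohort
mean Z is modelled as `z₀·exp(−d/λ)`. The curve is a background estimate,
so it is fitted with asymmetric trimming — iterate least squares, drop
edges more than 2 robust SDs *above* the curve, refit — and the null scale
is the MAD-based SD of the kept residuals. Each edge is then compared with
the (1−α) quantile of `n_sim` simulated values `g(d) + N(0, SD)`. A plain
least-squares fit would let distance-correlated signal (within-lobe edges
are short-range) lift its own null. By default the screen is reported
alongside the NBS result; restricting the NBS edge set to screened edges
is available (`screen_first`) but fragments suprathreshold components and
costs detection power.

**Growth models.** Sub-network strength (mean Z over an edge mask; by
default intersected with the NBS-significant set, unrestricted by flag) is
fitted against gestational weeks with (a) an OLS line and (b) the
four-parameter logistic `f(x) = d + c/(1 + exp(−(x−a)/b))`. The logistic
fit uses bounded trust-region least squares with analytic Jacobian,
multi-start over `a ∈ {25th, 50th, 75th percentile of x}`, tolerances 1e−8
and at most 500 function evaluations per start. Two identifiability
constraints stabilise the fit: `a` may not leave the observed age range by
more than 2 weeks (outside it the inflection is not estimable and noise
drives the fit to distant plateaus), and `b` is capped at half the
observation span (larger values only let the logistic mimic a straight
line). The amplitude `c` is constrained non-negative when fitting
strengthening connectivity. Robust mode approximates least-absolute-
residual fitting by iteratively reweighted least squares with weights
`1/max(|residual|, ε)` (at most 8 reweighting rounds, exit on parameter
change < 1e−6). The inflection is `a`; the expansion period
`{x : f′(x) ≥ q·f′(a)}` has the closed form `a ± 2b·acosh(q^(−1/2))`
(default q = 0.9).

**Model comparison.** `bootstrap_compare` draws 50% subsamples without
replacement (default 1000 iterations), refits both models per subsample
(sigmoid warm-started at the full-data solution) and evaluates both on the
held-out half. The preferred model is decided by a pooled two-sample
t-test at 0.05 on the held-out SSE distributions. This predictive decision
is used because the two in-sample alternatives are degenerate: raw SSE
mechanically favours the logistic (it nests near-linear shapes, so its
in-sample SSE is essentially never worse than the line's), and adjusted R²
has no power against a nested linear truth (its expectation is then equal
for both models). In-sample SSE, R², adjusted R² and the held-out SSEs are
all recorded; `decision="sse"` and `"adj_r2"` are selectable.

**Stage analysis.** Developmental stages are pre (< GW 26), expansion
(26–29) and post (≥ 29). Stage contrasts use pooled two-sample t-tests,
computable directly from summary statistics (mean, SD, n); both the
pre-vs-expansion, expansion-vs-post and pre-vs-post contrasts are labelled
explicitly in `stage_table.json`.

**Spectra.** Magnitude-squared coherence uses Welch averaging with
24-sample Hann segments and 50% overlap — the longest segment giving at
least three segments on a 50-frame scan. The cohort spectrum averages all
region pairs within subject, then across subjects, with an interquartile
band across subjects; the two highest local maxima separated by ≥ 0.05 Hz
are reported as peaks. With so few segments the estimator has a large
positive bias floor (~0.4 for independent series), so efficacy
measurements quote peak heights above the median coherence across
frequency bins. A sinusoid at true frequency f sampled at fs appears at
`|f − fs·round(f/fs)|`; the ~2.4 Hz fetal heartbeat sampled at 1 Hz
aliases to ~0.4 Hz.

## Synthetic cohort design

The generator's defaults are the study conditions: 50 frames at TR = 1 s,
gestational ages uniform on 21–37 weeks (a stratified 8/8/16 sampler over
the three stages is available), 70 regions in mirrored left/right pairs on
an ellipsoidal shell (six-lobe labelling, subcortical interior points),
brain volume linear from 77 cm³ at week 21 to 469.1 cm³ at week 37 with
coordinates rescaled by the cube root of relative volume.

Per-edge growth truth: within-lobe edges follow the logistic with lobe
inflections occipital 24.8, temporal 26.0, frontal 26.4, parietal 27.5
(subcortical 26.3, limbic 26.4), slope scale b = 1 week and amplitude
c = 0.45 Z over baseline d = −0.01 Z; long-range edges (top distance
quartile) strengthen linearly at 0.0075 Z/week; the remaining cross-lobe
edges stay flat. These amplitudes are the largest for which the implied
correlation matrices stay essentially positive semidefinite across
gestation on default atlas geometries: the generator imposes the
symmetric square root of the nearest PSD matrix (eigenvalues clipped at
1e−8), and with these defaults the projection moves no correlation by
more than ~0.04, so `edge_truth` describes what is actually imposed. A
uniform baseline as negative as −0.05 across 70 regions is not jointly
realisable (uniform negative correlation is bounded below by −1/(n−1)).

Signal components per subject: band-limited Gaussian neural signals
(0.01–0.08 Hz, spectrum peaked at 0.04 Hz with 0.05 Hz width — a narrow
spectral line would leave correlation estimates with only ~3 effective
degrees of freedom at 50 frames), symmetrically whitened when the scan is
longer than the region count so the imposed covariance is exact; a shared
cardiac sinusoid at a per-subject rate drawn from N(2.4, 0.47) Hz
truncated to [2.0, 3.6] (≈144 ± 28 bpm); per-region linear drift; white
noise (SD 0.5 against neural SD 1); a rigid-motion random walk (steps
0.15 mm and 0.004 rad per frame, scaled per subject by a lognormal factor
with σ = 0.4) with occasional permanent 3–6 mm jumps (probability
0.05/frame) accompanied by broadband signal artifacts in the affected
frames. These settings reproduce a mean displacement near 0.64 mm and
46–48 retained frames of 50. Noise channels (K = 10) carry drift, cardiac
and white noise (SD 0.5) but no neural signal — CompCor noise voxels are
selected for high physiological variance, so their white-noise floor sits
below the physiological content.

What the generator does **not** emulate: image-space artifacts
(fold-over, ghosting, susceptibility), slice-to-volume motion within a
frame, spatially structured (smoothed) noise, BOLD hemodynamics beyond
band-limited Gaussianity, and non-stationary heart rate. Passing tests
therefore show that the statistical machinery behaves correctly under the
assumed signal model, not that the pipeline is robust to everything real
fetal fMRI contains.

## Validation experiment design and problem sizes

The validation experiments (`fetalconn.validation`) fit anatomy-defined
sub-networks — the within-lobe edge set globally, and each lobe's
within-lobe edges for the ordering experiment. Restricting to edges
selected by their own test statistics makes aggregated trajectories look
quasi-linear (winner's curse) and destabilises the inflection estimate,
so the a-priori classes are the right instrument for recovery questions;
the pipeline's growth stage still restricts to NBS-significant edges, as
a study of real data would.

Problem sizes: inflection recovery uses 20 cohorts of 32 subjects;
ordering, 20 seeds of 64; the model-selection dichotomy, 20 seeds of 32
with 1000 bootstrap iterations (plain least-squares refits inside the
bootstrap; the robust full-data fit supplies the warm start); FWER
calibration, 200 null cohorts at 1000 permutations; the null-F check,
10000 independent edges.

Two validation outcomes are expected to fall short of ideal recovery
under these study-like conditions, and the acceptance tests report them
honestly rather than relaxing them. (1) Full four-lobe ordering: with
50-frame band-limited scans, per-lobe inflection standard errors are
0.5–1.0 weeks while the temporal–frontal gap in the truth is 0.4 weeks,
so the full ordering is recovered in roughly a third of seeds. (2) The
model-selection dichotomy: at cohort noise of ~0.1 Z on sub-network
strengths a b = 1 logistic and a straight line are genuinely hard to
tell apart from 32 points; the held-out decision prefers the generating
family in expectation but per-seed fractions are well below 0.9.

## Numerical choices and degenerate inputs

Correlations are clipped before atanh; zero-variance regions get zero
edges with a warning rather than an error so short censored scans remain
usable. Rank-deficient confound designs drop collinear columns via
pivoted QR and record them. Degenerate sigmoid fits (fitted rise smaller
than ~1e−4 of the data scale) are flagged and excluded from
expansion-interval computation. Permutation p-values use the add-one
convention and are therefore never zero. All randomness flows from a
single master seed through `numpy.random.default_rng`; identical
configuration and seed reproduce every output bit for bit.

## Limitations

The cross-sectional design means "growth" is a population trajectory, not
within-subject change. The NBS extent statistic percolates at lenient
component-forming thresholds (F > 5 yields ~3% suprathreshold edges under
the null, which on 70 nodes often form one large random component), so
detection of true components is conservative near that regime; the
threshold is configurable. The spatial-closeness null is a reconstruction
(exponential decay with homoscedastic Gaussian noise) and its trimmed fit
is one of several defensible background estimators. Only the extent
variant of NBS is implemented, and no graph-theoretical summary metrics
(degree, modularity, efficiency) are computed.
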
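# Methods

`temporules` learns human-readable classification rules from longitudinal
microbiome profiles. This note records the model, its priors and
relaxations, the fitting procedure, the semi-synthetic generator, and the
numerical and design choices that shape the package's behaviour.

## The model

Inputs are per-subject time series of relative abundances `X[s, t, i]`
(subjects s, sample times t in days, taxa i), a binary host label per
subject, and a matrix of pairwise phylogenetic distances among the taxa.
The classifier is a conjunction-of-detectors rule model, built as five
differentiable layers.

**Phylogenetic focus.** The distance matrix is embedded into a
D-dimensional Euclidean space by principal coordinate analysis
(double-centering of squared distances, eigendecomposition, coordinates
scaled by the square roots of positive eigenvalues). D is the smallest
dimension (scanned 1..30) for which a two-sample Kolmogorov–Smirnov test
cannot distinguish (p > 0.05) the original pairwise distances from the
embedded ones; if none qualifies, the scan's cap is used with a warning.
Each detector j of rule k owns a center γ_kj ∈ R^D and radius κ_kj > 0;
taxon i is selected with weight

    u_kji = sigmoid((κ_kj − ‖γ_kj − E_i‖) / τ_u),

and the detector's per-sample signal is the u-weighted sum of relative
abundances. As the temperature τ_u anneals toward zero the selection
approaches a hard phylogenetic ball.

**Temporal focus.** Each detector owns a window center μ_kj and length
σ_kj, stored as fractions of the study duration. Sample t receives a
relaxed boxcar weight

    h_kjt = sigmoid((t − μ + σ/2)/τ_v) − sigmoid((t − μ − σ/2)/τ_v),

evaluated on a time axis measured in units of the mean sampling interval,
so the annealed τ_v (1 → 0.1) starts soft across roughly one interval and
ends sharp well below the sampling resolution. Weights are masked to each
subject's observed samples and normalised to sum to one. The detector's
feature is either the weighted mean of its aggregated signal over the
window, or the weighted ordinary-least-squares slope. Slopes are computed
against day-scale times, so slope features and thresholds are abundance
change per day — the scale the slope-threshold temperatures (1e-3 →
1e-4) correspond to; abundance thresholds use 1e-2 → 1e-3.

**Detectors, rules, classification.** A detector's activation is
`sigmoid((b − η)/τ_g)` against a learned threshold η. Each of the J
detector slots carries an abundance variant and a slope variant with
independent selectors. A rule is a relaxed AND over its selected
detectors, r_sk = Π_j (1 − z_kj (1 − g_skj)), a product form whose
gradients do not vanish multiplicatively. Selectors z (detectors) and q
(rules) are sigmoids of Normally distributed logits divided by annealed
temperatures. Subject labels follow a logistic regression on the selected
rule activations, p_s = sigmoid(w0 + Σ_k q_k w_k r_sk); w_k is the
rule's log-odds contribution.

## Priors

- Centers γ: Normal, per-axis mean and spread of the embedded taxa, with
  the per-axis scale floored at the overall rms spread (low-variance PCoA
  axes must not pin the centers).
- Radii κ: Normal on the constrained value; location = median
  within-family embedded distance and scale = max(sqrt of the median
  within-family distance variance, location) when a family annotation is
  available, else the median and standard deviation of all pairwise
  embedded distances. A Lognormal variant is available via
  `PriorConfig.kappa_prior_kind`.
- Windows: diffuse Normals, μ ~ N(0.5, 1), σ ~ N(0.3, 1) on the
  duration-fraction scale — windows centered mid-study covering 30% of it.
- Thresholds η: uniform over the subject-feature range observed at
  initialisation, enforced by a smooth quadratic barrier (stepping 1% of
  the range outside costs 0.5 units).
- Weights w, w0: Normal(0, 10²). Selector logits: Normal(0, 1).
- Sparsity: the soft detector count per rule Σ_j z and the soft rule
  count Σ_k q are scored under a Negative Binomial with mean 1 and
  variance 5, continuously extended through the gamma function so
  non-integer soft counts are scoreable. Numerically, this prior puts
  five active detectors at the ~96th percentile (the 98th percentile sits
  near nine), so it is a strong but not absolute pull toward one or two
  active components.

## Fitting

Maximum a posteriori estimation by RMSProp-style gradient ascent
(decay 0.99, eps 1e-8) for up to 2000 iterations: step size 0.01 for
window parameters (their useful movement spans tens of days), 0.005 for
selector logits, 0.001 for everything else. All temperatures anneal
linearly over the first 1200 iterations (`anneal_iters`) and then hold at
their end values while training consolidates on the now-stationary
objective. Training halts once the best loss in the trailing 100
iterations no longer improves on the best loss before them by at least
`stop_delta` (default 1.0); by default this plateau criterion is armed
only after the anneal horizon, because mid-anneal plateaus are routinely
transient — sharpening temperatures later unlock further progress.

Initialisation: K-means (10 restarts) on the embedded taxa provides
centers and radii (radius = the cluster's maximum member distance,
floored at the radius-prior location so every ball starts populated);
windows are drawn uniformly from the largest partition of the study into
equal intervals holding at least two samples per subject per interval;
thresholds start at the subject-mean of each detector's initial feature;
all selectors start at probability 0.5; weights are standard normal and
the bias zero. Gradients come from a small reverse-mode automatic
differentiation engine over numpy with fused kernels for the hot layers;
correctness is enforced by central-difference tests.

## Discrete readout

After fitting, the soft model is binarised at 0.5: rules with q > 0.5,
detectors with z > 0.5, taxa with u > 0.5. Windows are reported as
[μ − σ/2, μ + σ/2] in days with edges snapped to inter-sample midpoints
(a window is only identified up to the sampling resolution). Each kept
detector is re-evaluated with hard logic — samples strictly inside the
window, membership-weighted aggregation, exact threshold comparison —
and rules combine re-evaluated truths by exact conjunction; the taxa
list names the members with weight above 0.5. Reports include the
rendered English rules, a structured JSON rule file that round-trips,
per-subject activation tables, and one figure per rule.

## The semi-synthetic generator

Cohorts emulate the statistical structure of longitudinal 16S profiles:

- a random Kingman coalescent tree over the taxa (patristic distances
  feed the embedding; tree cuts of at most n/6 leaves define synthetic
  "families");
- per-taxon population trajectories: a base log-abundance ~ N(0, 1.5²)
  plus a smooth random cubic-spline trend (4 knots, sd 0.7);
- per-subject deviations: a static log-offset ~ N(0, 1) — real cohorts
  show order-of-magnitude between-subject differences, and this
  variability is what makes spurious single-threshold separators
  unreliable — plus temporally correlated wiggle (squared-exponential
  kernel, sd 0.15, length scale 15% of the study);
- for case subjects, one or two clades are shifted by log(fold change)
  inside a window (default: the central 30% of the study) with sigmoid
  ramps of 2% duration. Perturbation targets are restricted to clades
  holding 1–8% of total abundance: perturbing a dominant clade moves
  every other taxon almost as much through compositional renormalisation
  and makes attribution unidentifiable;
- measurement: additive Gaussian noise with sd = 0.3% of signal times a
  multiplier from {1, 10, 100, 1000, 10000}, renormalisation to the
  simplex, and optional multinomial resampling at a sequencing depth.

Default study conditions: 64 subjects (balanced), 18 time points over
100 days, 32 taxa, fold change 4. What the generator does *not* emulate:
real taxon co-occurrence structure, bursty sequencing noise,
subject-specific sampling schedules, and the heavy-tailed abundance
distributions of real 16S data; passing benchmarks here demonstrates
the machinery works under controlled conditions, not field performance.

## Desk-scale benchmark conditions

The benchmark harness (`temporules.benchmark`) fits 3 rules × 8 detector
slots on the default cohorts; the separable toy uses 20 subjects, 8
taxa, and a driver taxon whose windowed mean defines the label with a
wide margin. Cross-validation is stratified 5-fold; the null benchmark
holds out 25% of a 96-subject, fold-change-1 cohort.

## Known limitations

- **Clade attribution.** On compositional data, "clade up" and
  "complement down" are nearly equivalent signals. The fitted models
  classify reliably, but the MAP optimum often uses partially
  overlapping or complement balls rather than exactly the perturbed
  clade, so taxon-set recovery (Jaccard against the true clade) is
  inconsistent across seeds. A family-scale radius prior strong enough
  to forbid complement balls collapses fitting instead; the shipped
  prior is weakly informative.
- **Hard/soft agreement.** At the schedule-end threshold temperatures,
  decision margins are of the same order as the residual discrepancy
  between soft (tail-weighted) and hard (boxcar) features, so the
  discrete readout reproduces the soft model's predictions for most but
  not all subjects (~90% pooled across benchmark runs, with many runs at
  or above 95%).
- Irregular sampling is handled by masking, not interpolation; subjects
  must share a common time grid only up to missingness.
- MAP point estimates only: no posterior uncertainty on rules, windows,
  or thresholds.
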
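# Methods

## The measurement being modelled

Low-field (benchtop) NMR characterizes muscle tissue through the
transverse relaxation of its protons. A CPMG echo train samples the decay

    M(t_k) = Σ_n M0_n · exp(−t_k / T2_n) + e(t_k),     t_k = 2·τ·k,

with half-echo spacing τ = 200 µs and 8000 echoes by default, so the
first echo falls at 0.4 ms and the train extends to 3.2 s. The echo
convention t_k = 2τk is the standard CPMG timing; the instrument
literature is usually silent on whether sampling starts at τ or 2τ, and
we adopt 2τk throughout.

Muscle water conventionally partitions into three pools by T2: bound
water attached to macromolecules (T21, nominally 0.1–10 ms), immobilized
water held in the myofibrillar network (T22, 10–200 ms, the dominant
pool), and extra-myofibrillar free water (T23, 200–1000 ms). Cooking
shifts the T22/T23 peaks to shorter times and drains the immobilized
pool; in strongly cooked tissue the free-water peak can move *below* the
nominal 200 ms boundary. Pool assignment therefore runs in an "auto"
mode: peaks are assigned to the nominal windows by apex position, but if
distinct peaks collide in one window while another stays empty, the
three largest in-range peaks are ranked ordinally (T21 < T22 < T23) —
the convention used in the cooked-muscle literature. Areas are divided
by sample mass, and "per gram" refers to the cooked, as-measured mass.

## Inversion

**Discrete fit.** For a fixed number of components (1–5) the decay is fit
by variable projection: the log10(T2) values are the only nonlinear
parameters (bounded to [0.01, 10000] ms), and at every optimizer step the
amplitudes are eliminated analytically by non-negative least squares.
Five deterministic starts (the quantiles of the log-T2 range shifted by
−1…+1 decades) feed a bounded trust-region least-squares solve; the best
residual wins, with ties broken toward the lexicographically smaller T2
vector. On noiseless three-pool inputs this recovers the generating
(T2, amplitude) pairs to ≲1e-10 relative. Components closer than 10%
relative T2 are merged before pool assignment.

**Regularized distribution.** The continuous T2 spectrum solves

    min_{a ≥ 0}  ‖K a − s‖² + λ² ‖L a‖²,   K[k, j] = exp(−t_k / T2_j),

on a 128-point log grid over [0.01, 10000] ms, with L the second
difference operator (curvature penalty). The non-negative solve is an
active-set NNLS on a Cholesky-compressed normal system (128×128, with a
fallback to the explicit stacked form), so a full ladder scan costs well
under a second per decay. λ is either fixed or chosen automatically from
a fixed ladder of 21 values spanning 1e-8…1e2 relative to ‖K‖₂ by a
residual-floor rule: the largest λ whose residual norm stays within 5% of
the ladder-wide minimum. For noisy decays this is a discrepancy principle
with a self-estimated noise level (the floor *is* the noise norm); for
noiseless decays the floor is the grid-discretization bias and the rule
returns the most smoothing that costs no fit quality. We use this rule
rather than an L-curve corner because the log-residual/log-seminorm curve
of a noiseless (or very clean) decay has a plateau rather than a corner,
and corner detectors pick essentially arbitrary points there; the floor
rule is well defined in both regimes and keeps the pipeline
deterministic. Peaks are maximal contiguous runs separated where the
amplitude rises again after having fallen (valley plateaus join the left
region, so peak areas always sum exactly to the total amplitude); peaks
below a configurable fraction of the total (0.005 in the pipeline) are
discarded as ringing.

On noiseless simulations from all five treatment parameter sets, the
distribution route recovers the immobilized-pool per-gram area within
0.04–0.15%, and the discrete route recovers T22/T23 essentially exactly.
Known limitation: with realistic noise the bound-water pool (T21 ≈ 1 ms)
is poorly determined — only a handful of echoes sample it — so its apex
and area are the least reliable outputs; the immobilized and free pools
are robust.

## Chemometrics

**PCA** is a plain SVD of the column-centered decay matrix with a fixed
sign convention (largest-magnitude loading positive).

**PLS** is the classical single-response NIPALS algorithm with X- and
y-deflation; for one response each factor is extracted in a single pass.
Factors are nested, so leave-one-out cross-validation fits each held-out
model once at the maximum factor count and reads off predictions at
every smaller count. The factor count is chosen as the argmin of RMSECV
(ties toward fewer factors); RMSEC and R²_cal come from the full-data
refit at that count, and RPD = SD(y, ddof=1)/RMSECV. External validation
reports per-group recovery = measured/predicted × 100 per replicate,
summarized as mean ± SD with the replicate CV (SD/mean of the
recoveries).

**ANOVA letters.** One-way ANOVA with Tukey HSD all-pairs comparisons
(statsmodels) at α = 0.05; the compact letter display is built from the
maximal cliques of the "not significantly different" graph, ordered by
descending clique maximum mean so the highest mean always carries "a".

## The synthetic cohort

No decay data are deposited for this kind of study, so the generator is
a first-class component. It emulates five treatment groups — raw
(control), boiled, steamed, roasted and fried mackerel muscle — each
described by a `TreatmentProfile`: three pool (T2, per-gram area) means
with specimen-level SDs, and six texture parameters (hardness,
resilience, springiness, chewiness, gumminess, adhesiveness) with their
group SDs, taken from the literature treatment tables.

**Decays.** Each sample's pool parameters are drawn around the group
means along a *coherent water-state mode*: one latent factor u ~ N(0,1)
moves all six parameters together (param = mean + u·φ·SD), with joint
rejection to keep every T2 in its admissible band and all areas
positive. The dispersion fraction defaults to φ = 0.1 of the
specimen-level SDs. Two considerations fix this design. First,
replicate-level covariation between decays and texture is not
identifiable from group-level summary tables, and calibration
replicates of an equilibrated treatment scatter far less than
independent specimens do. Second — and decisively — if within-group
decay scatter is given the full specimen-level SDs, it lies almost
parallel to the between-treatment trajectory in decay space (a
less-cooked control replicate is indistinguishable from a slightly
boiled one) while the group texture SDs stay an order of magnitude
smaller than the between-treatment texture differences; no linear
decay→texture readout can then be simultaneously steep between groups
and flat within them, and cross-validated errors plateau an order of
magnitude above the reliability regime that decay-based texture
calibration demonstrably reaches. The reported calibration statistics of such studies
(R² > 0.98, RMSECV < 2·RMSEC at 45 samples) therefore *require* a
replicate scatter well below the specimen tables, and φ is calibrated so
the synthetic study reproduces that regime. Cohort decays default to the
noiseless limit: a 16-scan-averaged benchtop acquisition runs at SNR
~1e4, which is immaterial to pool-scale and chemometric analyses (noise
levels are an explicit parameter wherever robustness is probed).

**Textures.** The pool→texture law is treated as smooth but nonlinear
across treatments. Each group uses its local linearization: the exact
group mean texture as operating point, plus fixed *global* gains on the
two pool quantities a linear calibration tracks globally — the
immobilized (A22) and free (A23) water areas. The gain direction comes
from regressing the group mean textures on the group mean areas; the
magnitude is capped so no group's propagated texture SD exceeds 5% of
its reference SD, keeping the pool-driven component subordinate to
repeatability noise (replicate-level coupling being unidentifiable from
the tables). Independent Gaussian repeatability noise with SD 5% of each
group's reference texture SD is added, consistent with the few-percent
replicate CVs a texture analyzer delivers. A global linear linkage
(`linkage_coefficients`) that interpolates all five group mean textures
exactly is also provided — fitted by weighted minimum-norm least squares
on standardized features, down-weighting the poorly determined
bound-water features — and is the map used when a single global
coefficient matrix is requested.

**What passing tests do and do not show.** The cohort reproduces the
group-level structure of the study — pool means, texture means, the
between-treatment decay geometry (PC1 carries ~96% of the relaxation
variance on the default cohort), and the calibration-reliability regime.
It understates within-group texture dispersion relative to the specimen
tables (by design, see above), its within-group variation is
one-dimensional per group, and it contains no baseline drift, no T2
distribution width within a pool, and no Rician noise floor. Passing
tests therefore validate the inversion and chemometric machinery and the
internal consistency of the reported group-level statistics, not instrument-level
realism.

## Defaults that matter

| parameter | default | units | why |
|---|---|---|---|
| τ (half-echo) | 200 | µs | standard benchtop CPMG setting for muscle |
| echoes | 8000 | – | covers 0.4–3200 ms, >7 time constants of the slowest pool |
| T2 grid | 128 points, 0.01–10000 | ms | spans all pools with ~9 points/decade |
| λ ladder | 21 points, 1e-8–1e2·‖K‖₂ | – | brackets noise floors from noiseless to SNR ~100 |
| residual-floor tolerance | 5% | – | within the floor's own sampling wobble |
| min peak area fraction | 0.005 | – | discards regularization ringing, keeps real minor pools |
| cohort design | 5 × 9 = 45 calibration, 5 × 4 = 20 validation | samples | the study design for calibration/validation |
| sample mass | 6.0 | g | typical cut for the sample chamber |
| pool scatter fraction φ | 0.1 | – | see cohort section |
| texture repeatability noise | 0.05 × group SD | – | few-percent replicate CVs |
| PLS predictors | every 8th echo (1000 points) | – | desk-scale speed at no information loss above 3 ms |
| max PLS factors | 10 | – | comfortably above the ~6–7 the structure needs |

## Degenerate inputs and tie-breaks

All-zero decays invert to the zero distribution (not an error); NaNs are
rejected with the offending row. Zero-variance responses produce a
flagged degenerate PLS model predicting the mean. Discrete-fit ties are
broken toward smaller T2 vectors; equal-RMSECV factor counts resolve to
fewer factors. Weight-gain "losses" (fried samples absorbing oil) return
negative percentages with a warning rather than clipping.
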
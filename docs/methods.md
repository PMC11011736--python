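# Methods

This note documents the models implemented in `craterspec`, the choices made
where the procedures are underdetermined, and what the synthetic benchmark
does and does not establish.

## Characteristic peak ratio correction (CPRC)

Given calibration spectra $X \in \mathbb{R}^{n\times p}$ on a shared
wavelength axis and Cd reference concentrations $y$:

1. The characteristic-peak intensity $x_N$ is read per sample as the maximum
   inside ±0.1 nm of the line's nominal wavelength (the line wanders by a
   pixel or two with plasma conditions; a window maximum is robust to that).
   Ties break toward the bin nearest the nominal wavelength, then toward the
   lower wavelength.
2. For every bin $j$, the ratio $B_j = x_N/z_j$ is correlated with $y$
   (Pearson $r_j$).  Bins with a zero intensity in any sample, or whose
   ratio is numerically constant — in particular the peak's own bin, where
   $B \equiv 1$ — are invalid and can never be selected.
3. Valid bins are ranked by **signed** $r$ descending (ties → lower
   wavelength).  Ranking by $|r|$ would also be defensible; the signed
   ranking is used because a matrix-related bin must *co-vary positively*
   with the corrected peak's concentration response.
4. For prefix sizes $m = 1..10$ the full spectrum is corrected by
   $\bar Z =$ mean of the prefix intensities and a PLSR model (5 latent
   variables, capped at the training rank, unscaled) is 10-fold
   cross-validated (shuffled folds, seeded).  The prefix with the smallest
   pooled CV-RMSE is kept; prefix sizes whose CV-RMSE ties the minimum
   within max(1e-12, 1e-6·min) count as equal and the smallest wins — on
   noise-free data the whole path sits at machine precision and the
   correction should then use a single bin.  The full path of 10 prefixes is
   scanned (no early stopping at a local minimum).

Applying a fitted correction to new spectra divides each row by the mean of
its own selected intensities; the mean must be positive, and the selected
wavelengths must exist on the target axis (matched to 1e-6 nm — no
resampling between grids is attempted).  Scale invariance is exact: for any
per-sample constant $c>0$, correcting $c\,x$ equals correcting $x$.

Multi-line workflows fit one CPRC model per characteristic peak.

## Comparison pretreatments

*Asymmetric least squares* baseline estimation uses the standard Whittaker
smoother with a second-difference penalty (smoothness $\lambda = 10^5$,
asymmetry $p = 0.01$, ≤20 reweighting iterations — common chemometrics
defaults).  *Total-area normalization* rescales each spectrum to unit sum;
any common target area would differ only by a global constant and is
irrelevant to downstream regressions.

## Crater-morphology compensation

Backward stepwise MLR starts from all nine crater parameters plus the three
Cd line intensities, in raw units (coefficient *t*-tests are invariant to
per-column scaling, so standardization is unnecessary).  Each iteration fits
OLS with intercept, computes two-sided p-values $t = \hat\beta/\mathrm{SE}$
with $n-k-1$ degrees of freedom, removes the single variable with the
highest p-value if it exceeds $\alpha = 0.05$, and refits; elimination stops
when all survivors are significant or one variable remains.  The per-variable
*t*-test (rather than a paired two-sample test) is the only construction that
yields one p-value per surviving variable per iteration, which is how such
elimination tables are reported.  p-value trajectories of surviving
variables are not monotone — removing a collinear companion can move them in
either direction — and are recorded as-is.

Two structural notes on the test's behaviour, established during validation:

* A predictor carrying **no** signal is retained with probability ≈ α
  (measured 5.3% in an idealized homoscedastic simulation, vs. the nominal
  5%).  Backward elimination does not push the false-positive rate below the
  significance level; "all noise variables eliminated" therefore fails in
  roughly $1-(1-\alpha)^{k_{noise}}$ of runs and per-variable elimination
  rates hover at $1-\alpha$.
* Retention of genuinely informative crater parameters depends on them
  carrying *distinct* components of the ablation fluctuation; perfectly
  collinear proxies split their significance and are traded off arbitrarily.

## Calibration models and metrics

* **Curve**: least-squares line predicting concentration from one intensity.
* **MLR**: OLS with intercept; rank deficiency is an error.
* **PLSR**: scikit-learn NIPALS without variable scaling; the component
  count is given or chosen by seeded 10-fold CV-RMSE (≤10 components).
* **LSSVM**: the canonical least-squares SVM dual.  With kernel matrix $K$
  and regularization $\gamma$, solve
  $\begin{bmatrix}0 & \mathbf 1^\top\\ \mathbf 1 & K + I/\gamma\end{bmatrix}
  \begin{bmatrix}b\\ \alpha\end{bmatrix} = \begin{bmatrix}0\\ y\end{bmatrix}$,
  predict $f(x)=\sum_i \alpha_i k(x,x_i)+b$.  Inputs are standardized
  internally (kernels are scale-sensitive) and the transform is stored.
  Hyperparameters default to a seeded 5-fold CV grid:
  $\gamma \in 10^{0..6}$, RBF width $\sigma \in \{0.1,1,10\}\times$ median
  pairwise distance of the standardized inputs.  A linear kernel with large
  $\gamma$ reproduces OLS predictions, which the tests verify.
* **RF**: seeded scikit-learn forest, 500 trees, one third of the features
  per split.
* **Metrics**: $R^2 = 1-\sum(\hat y_i-y_i)^2/\sum(\bar y-y_i)^2$,
  $\mathrm{RMSE}=\sqrt{\tfrac1n\sum(y_i-\hat y_i)^2}$.
* **LOD/LOQ** $= 3\sigma/a$ and $10\sigma/a$ where, by default, $a$ and
  $\sigma$ are the slope and residual standard deviation (df $=n-2$) of the
  classical intensity-vs-concentration calibration line.  With no blank
  replicates available, residual σ is the standard stand-in for blank noise.
  A `sigma_space="concentration"` alternative uses the residual sd of
  predicted concentrations directly.

## Fusion pipeline

A `FusionSpec` names the crater subset (`None` = stepwise-retained,
recomputed per run on calibration data), the emission lines, the spectral
correction (`none`/`baseline`/`normalization`/`cprc`) and the model kind.
`run_grid` enforces a strict no-leakage discipline: CPRC selection, stepwise
retention and hyperparameter CV see only the calibration groups; the
held-out group is used exclusively for scoring.  A test verifies that
scrambling the held-out references changes no fitted parameter.

## Synthetic benchmark

The generator emulates a six-brand spiking study: ten levels
(0, 0.5, 1, 10, 20, …, 70 µg/g), four replicate tablets per level, replicate
$k$ assigned to split group $k$, so groups are stratified by brand and level
(n = 240).  The axis is 210–231 nm at 0.02 nm pitch (p = 1051); emission
lines are unit-area Gaussians with σ = 0.05 nm.

Per sample $i$ of brand $b$:

* true concentration = spike level + a brand-native offset drawn once per
  brand from U[0.4, 1.6] µg/g (herbal powders are never Cd-free);
* ablation factor $a_i = f_b\, s_i\, g_{1i} g_{2i} g_{3i}$ — a brand matrix
  factor $f_b$, an unobservable shot factor $s_i$ (log-normal, cv =
  `noise_cv`), and three crater-visible components (cv = `ablation_cv`,
  default 6×`noise_cv`): ablated mass, mean penetration, peak penetration;
* the whole spectrum (baseline + all line profiles) is multiplied by $a_i$;
  per-line excitation jitter (cv = `line_jitter_cv`, default 3×`noise_cv`)
  moves individual transitions semi-independently; per-pixel log-normal
  noise (cv = `noise_cv`) is applied last.  All multiplicative draws are
  winsorized at ±3 log-sd (gross outlier shots are re-measured in practice);
* crater volume ∝ $f_b\, g_1^2$, average depth ∝ $\sqrt{f_b}\, g_2$, maximum
  depth ∝ $\sqrt{f_b}\, g_3$ (dimensions scale sub-linearly with ablation
  efficiency), each with small log-normal metrology noise (1–2%); the other
  six morphology parameters are ablation-independent shape noise around
  brand-texture scales with 18–40% dispersion, landing the pooled RSDs in
  the regime of real crater tables (volume well above 20%);
* references = true concentration × log-normal ICP-MS noise (cv = 1%).

Default brand factors are the quantile midpoints of U[0.5, 1.5]
(0.583 … 1.417): the brands of a study are a fixed panel of distinct
matrices, not a fresh random draw per experiment, and the even spread makes
pooled-calibration degradation a stable property rather than a
draw-dependent one.  Brand textures default to 1 (homogeneous shape scales);
setting them per brand scales the six noise parameters only.

Key structural consequences, all covered by tests: background bins (e.g.
the line-free red tail ≥229.5 nm) carry the full per-sample factor, so CPRC
can find them and cancel $a_i$ exactly; crater volume correlates with the
ablation factor (ρ > 0.5); pooled raw calibration is strictly worse than
every single-brand calibration; the three signal-bearing crater parameters
are jointly necessary to recover the crater-visible ablation fluctuation,
while the six shape parameters carry nothing.

With `noise_cv = 0` and unit brand factors every stochastic term vanishes
and the extracted Cd I 228.80 nm intensity is exactly linear in
concentration — the identity used to anchor the correction tests.

**What the benchmark does not show.**  Matrix effects are purely
multiplicative here; real plasmas add self-absorption, line-shape changes
and additive continuum structure that ratio correction cannot cancel
exactly.  Line profiles are Gaussian (no Stark/Voigt broadening), the
baseline is smooth and low, interference strengths are order-of-magnitude
choices, and the within-brand fluctuation (~20% at defaults) sits at the
high end of what averaged-shot LIBS acquisitions show.  Passing the suite
demonstrates that the algorithms recover the structure they assume, not that
they meet any particular figure of merit on real powders.

## Problem sizes

The standard benchmark is 240 samples × 1051 wavelengths.  The acceptance
checks use 50 seeded benchmark realizations for the model-ordering property
and 200 for the stepwise-recovery property; the acceptance script runs one
full pipeline realization (a few seconds).
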
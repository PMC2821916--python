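# Methods

## The model

Rab5 is a small GTPase of the early endosome, active when GTP-bound. Its
exchange factor (GEF) Rabex-5 reaches the endosomal membrane through two
routes: **directly**, via its early-endosomal-targeting domain, and
**indirectly**, as a cytosolic complex with Rabaptin-5 that is recruited by
Rab5-GTP itself. The indirect route is autocatalytic — recruited enzyme
makes more Rab5-GTP, which recruits more enzyme — and is the interesting
part of the model.

State variables (molar): `z`, the Rab5-GTP concentration, and `x2`, the
Rabex-5/Rabaptin-5/Rab5-GTP tripartite-complex concentration. Direct
membrane targeting is taken at rapid equilibrium, so the remaining enzyme
pools follow algebraically from the conservation of total Rabex-5 `x_tot`:

    x0 = (x_tot - x2) / (1 + sigma)        cytosolic Rabex-5
    x1 = sigma * x0                        directly membrane-bound Rabex-5

and the dynamics are two-dimensional:

    dz/dt  = alpha * (x1 + x2) * (z_tot - z) - beta * z
    dx2/dt = gamma * x0 * z - lam * x2

| parameter | meaning | units | in-cell estimate |
|---|---|---|---|
| `alpha` | GEF catalytic rate per enzyme | 1/(M s) | 2e4 (in vitro) |
| `beta`  | GAP-driven hydrolysis (GAP absorbed) | 1/s | 0.2 = 2e-3 x 100-fold GAP |
| `gamma` | complex formation (Rabaptin-5 absorbed) | 1/(M s) | unknown |
| `lam`   | complex dissociation | 1/s | unknown |
| `sigma` | direct-targeting equilibrium constant | — | 0 for constructs lacking the targeting domain |
| `z_tot` | total Rab5 | M | 6e-6 (BHK) … 2.5e-5 (NF73 + GFP-Rab5) |

Only the ratios `beta/alpha` (1e-5 M) and `lam/gamma` enter any steady
state, which is what makes the unknown absolute `gamma`, `lam` harmless:
the analysis estimates `lam/gamma`, the in-cell dissociation constant of
the tripartite complex.

## Steady states and the delayed onset

Eliminating `x2` at steady state gives a single quadratic in `z`,

    gamma*(alpha*x + beta) * z^2
    + [beta*lam*(1+sigma) + alpha*x*sigma*lam - alpha*x*gamma*z_tot] * z
    - alpha*x*sigma*lam*z_tot = 0          (x = x_tot)

whose larger root, clamped to `[0, z_tot]`, is the stable physical state
(`steady_state_general`). Its two reductions are closed forms:

* `gamma = 0` (direct only): the hyperbola
  `z = alpha*x1*z_tot / (alpha*x1 + beta)`, half-maximal at
  `x_tot = beta*(1+sigma)/(alpha*sigma)`, Hill coefficient 1.
* `sigma = 0` (feedback only):
  `z = (gamma*alpha*x*z_tot - lam*beta) / (gamma*(alpha*x + beta))`,
  **zero** until `x_tot` exceeds the onset threshold

      x_threshold = lam*beta / (gamma*alpha*z_tot),

  which is inversely proportional to total Rab5 — the model's central
  experimental prediction.

Stability follows from the analytic 2x2 Jacobian. With `sigma = 0` the
origin and the non-trivial branch cross at the threshold and exchange
stability (a transcritical bifurcation); the non-trivial branch is
negative, hence unphysical, below it. There is never a fold along the
stable branch and never two coexisting stable physical states: the switch
is sharp but not bistable. `bifurcation_scan` verifies this numerically
(roots from the quadratic — no iterative search that could miss a branch —
eigenvalue classification, fold detection by a sign change of dz/dx, and
bisection for the crossing).

## Sensitivity

Sensitivity of a response curve is summarized by the generalized Hill
coefficient with the standard 10–90% rule,

    n_H = ln(81) / ln(x90 / x10),

with the crossings interpolated linearly in log(x) (curves span decades;
if the bracketing segment touches x = 0 plain linear interpolation is
used). The direct hyperbola gives n_H = 1 exactly; the feedback-only curve
lies in (1, 2], reaching 2 when `lam/gamma >> z_tot` and collapsing to 1
when `lam/gamma << z_tot`; the combined curve steepens as `sigma`
decreases. A secondary diagnostic, `normalized_slope_sensitivity`, exposes
the underlying notion — midpoint slope normalized by midpoint location —
but the 10–90% rule is the default because it is well defined for the
clamped, piecewise response. Tests confirm the interpolated crossings
against their closed-form locations.

## Unit conversions and the in-cell affinity

Blot densitometry is calibrated on a dilution series (least-squares line,
inverse prediction refusing extrapolation by default), corrected by lysate
cell count and transfection efficiency (0.8 BHK, 0.2 NF73) to fg/cell, and
converted to molar via the protein mass and an 80 fL cell volume:
`M = fg / (kDa * 1e3 * fL)`. Molecular masses default to 40 kDa for the
feedback-only enzyme construct, 24 kDa for Rab5 and 51 kDa for GFP-Rab5;
the latter two are sequence-based defaults, overridable in
`CellConstants`. Printed concentrations in this field carry one
significant figure, and `round_sig` is used wherever a comparison is made
at that precision (e.g. 12 fg/cell of Rab5 → 6.25e-6 M, printed 6e-6 M).

Inverting the onset condition turns a measured threshold enzyme level into
the in-cell affinity:

    lam/gamma = x_threshold * z_tot / (beta/alpha).

If no onset is seen up to a plateau level, the same expression evaluated
at the plateau is a lower bound. The `beta/alpha = 1e-5 M` input assumes a
100-fold GAP enhancement of hydrolysis — the conservative end of the known
2–5 orders of magnitude — so `lam/gamma` scales down in proportion if the
cellular GAP is stronger; both factors are explicit arguments everywhere.

## The synthetic experiments

`generate_dataset` emulates Tet-Off induction assays. Enzyme abundance
follows a saturating exponential
`x(t) = baseline + (plateau - baseline)(1 - 2^(-t/half_time))` from a
leaky baseline (~1/10 of plateau, the Tet-Off leak) — an order-of-magnitude
induction. The three scenario presets encode the study conditions:

| scenario | sigma | z_tot (M) | profile (fg/cell) | sampling (h) |
|---|---|---|---|---|
| `nf73` | 0 | 2.5e-5 | 1.5 → 15, half-time 2.8 h, plateau ≈ 12 h | 0, 3, 6, 9, 12 |
| `bhk_gfp_rab5` | 0.1 | 1.2e-5 | 3 → 32, half-time 1.6 h, plateau ≈ 7 h | 0, 3, 6, 9 |
| `bhk_endogenous` | 0 | 6e-6 | 3 → 32, half-time 1.6 h, plateau ≈ 7 h | 0, 3, 6, 9 |

The NF73 profile is pinned by its two measured anchors — 12 fg/cell at
6 h and saturation by 12 h — which place the threshold crossing at 6.1 h,
just inside the (6, 9) h sampling bracket. The BHK profile reflects the
~3 fg/cell endogenous-like baseline and the 32 fg/cell plateau reached by
7 h. In `bhk_endogenous` the threshold (50 fg/cell) exceeds the plateau,
so activity never rises; in `bhk_gfp_rab5` the direct pathway plus doubled
Rab5 put the system at or past onset from the first post-induction sample.

Observations per sampling time: three replicate arms (matching
SEM-of-three-blots reporting) with multiplicative lognormal noise of CV
15% on enzyme bands and on the pull-down activity signal
`scale * z/z_tot + background`, where the small background (2% of full
scale) represents assay background and gives the control arm the nonzero
variance a mean + k·SD rule needs; endosome size is reported by the
max-of-sample protocol — the 90 largest diameters among 30 cells (20
simulated endosomes each), with `d = d0 + k*(z/z_tot)^(1/3)` as a
volume-proportional enlargement heuristic. Only the monotonicity of the
two observation maps is relied on downstream, never their functional form.
The control arm keeps the enzyme at the leaky baseline. Identical seeds
give identical datasets.

Activity is generated at quasi-steady state: induction takes hours while
the activation cycle relaxes in seconds (`1/beta = 5 s`), a timescale
separation of ~1e3. The full-ODE mode validates this; because the
deterministic origin is a fixed point even above threshold, that mode adds
the intrinsic GEF-independent nucleotide exchange (1e-5 /s, orders of
magnitude below `beta`) as a basal production term, which nucleates the
feedback within minutes of the crossing. QSS and full-ODE trajectories
agree within 0.3% of `z_tot` at the sampling times (the test asserts 5%).

What the generator does *not* emulate: cell-to-cell expression
variability beyond the transfection-efficiency fraction, image formation
and segmentation of real micrographs, densitometry saturation, or Dox
pharmacokinetics. Passing tests therefore show that the analysis recovers
truth under the stated noise structure, not that real blots are this well
behaved.

## Onset detection and recovery

`detect_onset` flags the first post-induction time whose replicate-mean
readout exceeds the pooled control mean by `k` control SDs (default
`k = 3`) *and stays above at every later time*; the onset interval is
(previous time, that time), and the enzyme level is read at the lower edge
— the conservative convention, since activation had not started there.
Either readout (activity, endosome size) or their conjunction can drive
detection; activity is the default. No detection is a valid outcome and
propagates as a lower bound on `lam/gamma`.

`recover_parameters` fits `scale * z(x; lam/gamma, sigma)/z_tot + bg` to
the mean activity curve with the mean measured enzyme (in molar) as the
dose axis, by bounded least squares on `log10(lam/gamma)` with four
multi-starts spanning ±1.5 decades around `z_tot`. `sigma` is held at 0 by
default: in the feedback-only experimental design it is known to vanish,
and a free `sigma` is degenerate with the background below threshold
(`fit_sigma=True` enables it). Confidence intervals are percentile
bootstrap over replicate arms resampled per time point. On the NF73
scenario this recovers `lam/gamma` to machine precision without noise,
with ~10% median error at default noise, and with ~85% CI coverage over
seeds.

## Numerical choices

* Integration: LSODA with analytic Jacobian, `rtol 1e-8`, `atol 1e-12` M
  (`lam` may exceed other rates by orders of magnitude). Negative
  excursions within 100x`atol` are clamped to zero; larger ones raise.
* Steady states: closed-form quadratic roots evaluated in a
  cancellation-safe form; the stable branch is the larger root clamped to
  `[0, z_tot]`. Degenerate inputs (`gamma > 0` with `lam = 0`, `z_tot = 0`
  thresholds, `sigma = 0` midpoints) raise domain errors rather than
  returning limits.
* Stability: "marginal" when the leading eigenvalue's magnitude is below
  `1e-9 * beta`; the transcritical crossing is located by `brentq` to
  relative precision better than 1e-6.
* Hill crossings: monotone linear interpolation in log10(x); a curve that
  does not span the 10% and 90% levels raises a bracketing error asking
  for a wider grid.
* Scale of the test simulations: the spot checks use 50–100 random
  parameter sets (log-uniform over 1e-2 … 1e2), 20 seeds for the
  stochastic end-to-end scenarios and 100 bootstrap resamples per fit —
  sizes at which every statistical assertion is already stable across
  reruns.

## Known limitations

* The model is deterministic and well mixed: no per-endosome spatial
  structure, no molecule-count noise, constant GAP activity.
* `lam/gamma` inherits the uncertainty of the assumed GAP enhancement
  (linearly) and of the 80 fL / molecular-mass conversions.
* The onset rule brackets the threshold at the sampling resolution; a
  denser design narrows the bracket but the lower-edge convention always
  biases the estimate slightly downward (conservative).
* With `sigma > 0` there is no sharp threshold, so "onset" in the BHK
  scenario means "first resolvable increase", which depends on the assay
  noise floor.
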
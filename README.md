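# rab5feedback

Kinetics of Rab5 activation by its exchange factor Rabex-5, with the
Rabaptin-5 positive feedback loop: steady-state response curves, the
delayed-onset threshold, sensitivity and stability analysis, and the
pipeline that turns induction time-course experiments into an estimate of
the in-cell affinity of the Rabex-5/Rabaptin-5/Rab5-GTP complex.

## The problem

Rab5, the small GTPase controlling early endosome fusion, is switched on
(GTP-loaded) by the GEF Rabex-5 and off by GAP-driven hydrolysis. Rabex-5
reaches the endosomal membrane two ways: directly, through its
membrane-targeting domain (equilibrium constant σ), and indirectly, as a
cytosolic Rabex-5/Rabaptin-5 complex recruited by Rab5-GTP itself — a
positive feedback loop. With z the Rab5-GTP concentration and x₂ the
tripartite-complex concentration (x₀ cytosolic, x₁ = σx₀ membrane-bound
enzyme, x₀ + x₁ + x₂ = x_tot):

    dz/dt  = α (x₁ + x₂)(z_tot − z) − β z
    dx₂/dt = γ x₀ z − λ x₂

The feedback route activates nothing at all until total Rabex-5 crosses

    x_threshold = λβ / (γα z_tot),

then switches on steeply (generalized Hill coefficient between 1 and 2) —
a *delayed onset*, produced by a transcritical branch exchange rather than
bistability. Because the threshold is measurable and β/α is known from in
vitro kinetics (10⁻⁵ M), the threshold inverts into the in-cell
dissociation constant of the tripartite complex:

    λ/γ = x_threshold · z_tot / (β/α).

The package is for quantitative cell biologists and modelers who want to
simulate this system, reproduce its analysis, or run the same
onset-to-affinity inference on their own induction time courses.

## Worked example

From a feedback-only induction experiment in Rabex-5-null cells
(`examples/05_onset_affinity.py`, abridged):

```python
from rab5feedback import NoiseModel, detect_onset, generate_dataset, infer_affinity
from rab5feedback.presets import NF73

ds = generate_dataset(NF73.params, NF73.profile, NoiseModel(), seed=11,
                      times_h=NF73.times_h)
onset = detect_onset(ds)
ratio = infer_affinity(onset, NF73.params.z_tot, NF73.params.beta_over_alpha)
```

prints

    onset between 6 and 9 h
    enzyme at onset: 12.6 fg/cell = 3.93e-06 M
    lam/gamma = 9.84e-06 M

Activity stays at the control level while the enzyme is below threshold,
lifts off between the 6 h and 9 h samples, and the enzyme level at the
conservative lower edge (~12 fg/cell, i.e. 3.9×10⁻⁶ M at 40 kDa in an
80 fL cell) converts to λ/γ ≈ 10⁻⁵ M — the affinity of the tripartite
complex in the cell. The same pipeline on the below-threshold scenario
(`bhk_endogenous`) detects no onset and reports the lower bound
λ/γ ≥ 6×10⁻⁶ M instead.

The other examples are narrative single-capability scripts:
`01_response_curves.py` (hyperbolic vs delayed-onset steady states and
their Hill coefficients), `02_bifurcation.py` (transcritical branch
exchange, no bistability), `03_quantification.py` (densitometry → fg/cell
→ molar → affinity arithmetic), `04_synthetic_induction.py` (the
synthetic Tet-Off experiment generator).

A thin CLI mirrors the library for shell pipelines:

    rab5feedback curve --preset fig2 --mode indirect_only \
        --x-min 0.01 --x-max 1e4 --out curve.csv
    rab5feedback generate --scenario nf73 --seed 7 --outdir bundle/
    rab5feedback infer --dataset bundle/ --z-tot 2.5e-5 --out onset.json

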
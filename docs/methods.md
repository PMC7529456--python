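# Methods

## The model

`cordclose` models the umbilical artery as a thick-walled, bilayered,
incompressible hyperelastic cylinder held at a fixed axial stretch and
loaded by luminal pressure, smooth-muscle contraction and osmotic swelling
of its inner layer.

**Kinematics.** The reference (unloaded) wall occupies radii
`A ≤ R ≤ B` (inner, glycosaminoglycan-rich tunica media) and `B ≤ R ≤ C`
(outer, smooth-muscle-rich tunica media). The loaded state is a cylinder at
axial stretch `λz` parametrized by its inner radius `a`:

    inner:  r² = a² + v (R² − A²)/λz        (J = v, swelling ratio)
    outer:  r² = b² + (R² − B²)/λz          (J = 1, incompressible)

with `λθ = r/R` and `λr = dr/dR`. The normalized inner-layer volume `v`
encodes quasi-equilibrated water uptake (v > 1) or exudation (v < 1) of the
charged proteoglycan matrix; its dynamics are not modelled — each
simulation prescribes a value, and sweeps over `v` stand in for the
swelling/deswelling that accompanies contraction in vivo.

**Constitutive model.** Each layer has strain energy

    W = μ/2 (λr² + λθ² + λz² − 3)
        + Σₖ c1ₖ/(4 c2ₖ) [exp(c2ₖ (λₖ² − 1)²) − 1],

the four-fiber-family form standard for murine vessels. The inner layer is
the neo-Hookean ground matrix alone (μ1 = 3.0 kPa); the outer layer adds a
soft matrix (μ2 = 0.1 kPa) and four fiber families: axial (η = 0°),
circumferential (η = 90°) and a symmetric diagonal pair (η = ±41.92°),
where `λₖ² = λz² cos²η + λθ² sin²η`. Fibers bear load only in extension.
"Extra" Cauchy stresses are `σᵢ = λᵢ ∂W/∂λᵢ`; radial equilibrium supplies
the Lagrange multiplier of the volumetric constraint.

**Active stress.** Contractile smooth muscle in the outer layer adds a
circumferential Cauchy stress

    t_act(λθ) = T_act · λθ · [1 − ((λm − λθ)/(λm − λ0))²]₊ ,

a parabolic length–tension law with maximum/minimum contractile stretches
λm = 2.5, λ0 = 0.2. The bracket is clamped where negative, which keeps the
law continuous (clamping sharply at λm would introduce a jump, because the
parabola equals 1 there, not 0). `T_act` is the control parameter of every
contraction sweep.

**Equilibrium.** Radial momentum balance integrates to
`P = ∫ₐᶜ (σθθ − σrr)/r dr`; the solver finds `a` at prescribed pressure by
bracketed root finding on this monotone-by-parts relation (Gauss–Legendre
quadrature, 200 nodes per layer; Brent to 10⁻⁸·A). During strong
contraction the pressure–radius relation can fold (multiple equilibria);
the solver returns the largest-radius root — the branch reached
quasi-statically from the patent state under pressure control — so closure
curves can exhibit the sharp patent-to-narrow transition. If no equilibrium
with `a > 10⁻³ A` exists the state is reported occluded rather than
extrapolated. The transducer-convention axial force is
`f = π ∫ (2σ̂zz − σ̂θθ − σ̂rr) r dr`.

Energy consistency: the same equilibria minimize the total potential
`E(a) = 2π [ v∫ᴬᴮ W R dR + ∫ᴮᶜ (W + Ŵa) R dR ] − P π a² λz`, where `Ŵa`
is the active stretch potential with `λθ Ŵa′ = t_act`. The test suite uses
direct minimization of `E` as an independent oracle (agreement to 0.1%,
typically 10⁻⁸).

## Buckling analysis

Inward folding of the compressed inner layer is detected by small-on-large
linear stability analysis. Perturbations are plane strain at fixed `λz`
(`u_r = U(r) cos nθ`, `u_θ = V(r) sin nθ`), incompressible, with `n ≥ 2`
circumferential folds — longitudinal ridges in cross-section, matching the
histology. The incremental equilibrium equations reduce to a linear 4×4
first-order system in `(U, V, T_rr, T_rθ)`; it is integrated from the lumen
to the adventitia through both layers (displacement and traction continuous
at the interface) using the second-compound (wedge) system in `ln r`, which
is immune to the solution-collapse that afflicts direct shooting at high
mode numbers. The luminal pressure enters the incremental boundary
condition as a follower load; the outer surface is traction free. A zero of
the outer-boundary determinant marks a nontrivial folded equilibrium; the
critical `T_act` for mode `n` is the smallest zero along the loading path,
refined by bisection to 0.1 kPa. Determinant sign flips caused by the base
state snapping between equilibrium branches are detected (discontinuity in
`a`) and not counted as bifurcations.

Two formulations of the incremental shear moduli are provided, because the
correct treatment of fiber and active anisotropy in this reduced setting is
genuinely open:

* `principal` (default): the whole layer energy — fiber terms and the
  active stretch potential included — is treated as a function of principal
  stretches, and the classical quotient formulas give the shear moduli.
  This is the customary practice in tube-buckling analyses of arteries with
  smooth-muscle tone. At strongly contracted states the resulting shear
  modulus can turn negative across the actively stressed outer layer; the
  ODE system remains regular when the sign is uniform, and an interior sign
  change (a true short-wavelength material instability) raises
  `EllipticityLossError`.
* `structural`: the quotient formulas are applied only to the neo-Hookean
  matrix (for which they are exact), while fibers and muscle convect as
  one-dimensional tension elements, contributing a circumferential
  stiffness `λθ²Wtt` and a structural shear term `σθθ·u_r,θ` on the θ face.
  This variant is always elliptic. It yields a flatter critical-stress
  curve whose 5%-drop plateau falls at 4–5 folds instead of 7.

The linearized active stiffening (`∂t_act/∂λθ`) is included by default and
can be switched off (`active_stiffness=False`).

Validation: (i) a rigid translation (`n = 1`, `U = −V = const`) is an exact
solution for any base state and lies in the numerical kernel to machine
precision — a sharp end-to-end check of the equations, interface coupling
and follower-pressure condition; (ii) the critical suction of a thin
isotropic neo-Hookean ring reproduces the classical plane-strain shell
result `p_cr = (n²−1) μ h³/(3R³)` to better than 1%; (iii) determinant
zeros are confirmed by an independent finite-difference collocation matrix.

## Parameter estimation

`PassiveBiaxialModel` fits the outer-layer parameters
{μ2, c1/c2 per family, diagonal angle η} to passive biaxial data by
bounded weighted least squares (trust-region reflective, positive
parameters on a log10 scale, seeded multi-start). μ1 is held fixed: the
inner matrix modulus is not identifiable from passive distension of the
composite wall. The default regression direction treats pressure as the
controlled variable and the measured outer diameter and axial force as
responses — matching how pressure-myograph rigs operate and where the
measurement noise lives; the forward solve uses vectorized warm-started
Newton iteration. Regressing (pressure, force) at measured geometry is
available as `response="pressure"` but conditions the noise badly (stiff
high-pressure points dominate). Default weights are per-protocol response
standard deviations; standard errors come from the Gauss–Newton
covariance at the optimum.

Identifiability, measured by seeded Monte-Carlo on synthetic data: with
noise-free data all eight parameters recover essentially exactly; with 2%
multiplicative response noise (n = 4 vessels) the fiber stiffnesses,
exponents and angle recover with median errors of 0.2–5%, while μ2 — a
0.1 kPa matrix contributing ~1–3% of wall stress — is unidentifiable at
that noise level (median error ~100% regardless of regression direction or
weighting). This is a property of the protocol, not of the optimizer.

`fit_active_tone` calibrates `T_act` by scalar root finding so the model
reproduces an observed outer-diameter reduction at fixed pressure; with
the baseline parameters, a 40% reduction at 25 mmHg with the contracted
inner layer at v = 0.5 requires T_act ≈ 52 kPa.

## Synthetic data

`synthetic_data` emulates ex vivo biaxial testing of late-gestation (E18.5)
murine umbilical vessels: four vessels; pressure–diameter sweeps 0–25 mmHg
(11 points) at axial stretches 0.95/1.00/1.05 of the in vivo value; axial
force–length sweeps (9 points, 0.92–1.08 of in vivo stretch) at 5/15/25
mmHg; and KCl-type contraction at 25 mmHg targeting a 30–50% diameter
reduction for artery-like specs. Responses are forward-simulated from a
known parameter set and perturbed by multiplicative Gaussian noise
(defaults: 1% diameter, 3% force — conservative values for optical
tracking and force transducers; the rig's true magnitudes are unreported).
Geometry is treated as measured exactly. All outputs embed seed and truth.
The generator reproduces none of the features it does not model:
preconditioning hysteresis, time-dependent KCl response, vessel-to-vessel
parameter heterogeneity, or measurement error in the unloaded geometry —
so passing recovery tests demonstrate estimator correctness under the
stated noise model, not robustness to those effects in real data.

## Reference results at the baseline parameter set

At 25 mmHg and λz = 1.28 the model reproduces the two headline numbers:
the swelling–contraction crossover of the closure curves falls at ≈50 kPa
(computed 49.8), and the critical buckling stress, decreasing monotonically
from 2 to 8 folds, passes the 5%-relative-drop plateau criterion first at
n = 7 folds (v = 0.5). The uniform single-material comparator wall narrows
by contraction alone, keeps a positive mean inner circumferential stress at
matched narrowing, and exhibits no fold bifurcation anywhere in
[0, 500] kPa.

One documented departure: in this implementation the critical seven-fold
stress *increases* with the swelling ratio (≈102/104/112/115/123 kPa at
v = 0.35/0.5/0.9/1.0/1.2) — a more swollen inner layer is harder, not
easier, to buckle — although the stress-relief mechanism usually invoked
for the opposite trend (less negative inner circumferential stress after
volume loss) is reproduced. The trend is insensitive to the incremental
formulation and to Pence-style swelling-energy variants. The
corresponding acceptance test states the opposite ordering and is expected
to fail; it is retained deliberately.

## Numerical choices

* Units: µm, kPa, mN; pressures cross the API in mmHg (1 mmHg =
  0.133322 kPa).
* Quadrature 200 Gauss–Legendre nodes/layer (solver), 32 (fitting);
  results are insensitive to doubling.
* Root finding: Brent, `xtol = 1e-8·A` (equilibrium), 0.1 kPa (tone and
  buckling bisection).
* Incremental integration: RK45, rtol 1e-8, in `ln r`; determinant
  nondimensionalized by `μ_max/r̄` so it is O(1) away from bifurcation.
* Coincident stretches in the principal-formulation quotients are nudged
  symmetrically by 1e-5 (the limits are finite).
* Buckling search: coarse 10 kPa grid over [1, 500] kPa, branch-jump
  detection at 20% radius discontinuity, plateau threshold 5% (all
  configurable).
* Fold sweeps at n = 2..12; the linear analysis predicts onset only —
  fold amplitudes and post-buckling contact are outside its scope.

## Problem sizes

Default analyses (this package's own choice of scale): closure sweeps use
76-point tone grids; buckling sweeps cover modes 2–12; recovery Monte-Carlo
uses 50 replicates of 4 vessels × 60 protocol points. A full pipeline run
at these sizes completes in a few minutes on one core.
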
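# Methods

This note records the model as implemented, the choices made where the
formulation left room, and what the synthetic experiments do and do not
demonstrate.

## Constitutive model

A material point is a canonical ensemble over the cracking number
k = 1..N (total microcracking length / osteon length). Macrostate energy
is E_k = k(1 − α)ψ₀(ε) and microstate multiplicity g_k = r^k, giving

    Z(α, ε; β, r, N) = Σ_{k=1}^N r^k exp(−kβ(1 − α)ψ₀),
    Ψ = −(1/β) ln Z,    σ = ∂Ψ/∂ε,    H = β² ∂Ψ/∂β.

The crack-number distribution is the canonical weight p_k = r^k e^{−kβE}/Z
(the unique choice consistent with the closed forms for Z and the moments);
m₁ = E[k] coincides with the printed stress-correction bracket Φ.

Kinematics are infinitesimal-strain throughout: every constitutive formula
is written in the engineering strain tensor, so no finite-deformation
layer is built, and a magnitude guard of 0.2 rejects strains far outside
the regime where bone is intact. Transverse isotropy enters through the
invariants (I₁..I₅) with a unit, sign-irrelevant fiber axis.

Differentiating Ψ at frozen damage gives σ = m₁(1 − α) ∂ψ₀/∂ε exactly;
with damage growing the chain rule through (1 − α̃)ψ₀ = P₃ adds the
increasing-damage stress −m₁ψ₀ ∂α̃/∂ε. Two printed-form ambiguities are
resolved as follows, with the numeric gradient of Ψ as ground truth in
the tests:

- the factor split σ = σ₀·Φ + σ_α requires the (1 − α) factor inside the
  correction, so the stress code uses Φ_stress = m₁(1 − α) while the
  standalone correction factor returns the bare bracket (= m₁);
- the closed-form prefactor of ∂H/∂α is stated in two inequivalent ways
  (βψ₀ versus (βψ₀)²(1−α) · var(k)); only the shared positivity carries
  thermodynamic meaning, so the package exposes the numerically
  differentiated value and asserts its sign.

## Damage evolution and history

Damage grows only when the equivalent strain ε̄ (Macaulay bracket of the
largest principal strain) reaches the stored directional threshold and is
increasing. The threshold field ε⁺(n) lives on a fixed grid of M = 128
Fibonacci-hemisphere directions with antipodal symmetry (configurable);
every visited strain raises each direction's threshold to the normal
strain ⟨n·εn⟩₊ seen there. The continuum definition evaluates the maximum
in the *current* principal direction; for strongly rotating principal
frames the fixed-grid reading adopted here is one of two defensible
interpretations and is flagged as such.

The increment is the Macaulay-clamped ⟨(dα̃/dε) : Δε⟩₊ (trapezoidal in
the step), scaled by the sub-step fraction above the threshold so that
re-loading exactly to a stored maximum adds no damage. Because α̃ is a
state function, the increments integrate exactly along proportional
loading; to make the accumulated α agree with the monotonic closed form
α̃(ε) — which is the form the model fits to monotonic test data — the
variable *catches up* to ⟨α̃(ε)⟩₊ on first activation. The consequence is
a stress discontinuity at onset of relative size α̃(ε₀) (about 10% at the
default parameters). This is intrinsic to requiring both a finite onset
threshold and exact consistency with the monotonic law; it is visible as
a kink in synthetic curves and is handled transparently by the fitter
(the same model generates and fits the kink).

Time is load-step index; no rate effects are modelled (the emulated tests
are quasi-static, with strain rates below 0.02 s⁻¹).

## Numerics

- All ensemble sums run in log-space with a max shift; q = re^{−x} within
  1e-9 of 1 switches to the series limits (Z → N, m₁ → (N+1)/2).
- ∂H/∂α and ∂Φ/∂β are central finite differences (relative step 1e-6).
- The plane-stress lateral solve for fiber-aligned uniaxial loading
  (ε₂₂ = ε₃₃ by transverse isotropy) is closed-form: transverse
  equilibrium is linear in the lateral strain on the undamaged branch and
  quadratic on the damaged branch (root nearest the elastic solution).
  The general incremental driver instead runs a safeguarded secant
  iteration on σ₂₂ = 0 (tolerance 1e-8·|σ₁₁| + 1e-10 MPa) with the damage
  state evolving step by step; the two agree to ~1e-8 relative on
  monotonic ramps, which the tests assert.
- Off-axis loading of the lateral solver (two independent lateral
  unknowns) is not implemented; drivers are fiber-aligned.
- Bending reduces the specimen to a prismatic rectangular section
  (default 4 × 0.5 mm, 50 layers, 100 mm span): each layer is an
  independent material point at ε₁₁ = κy. The compression side stays
  essentially elastic because its equivalent strain is the (small)
  lateral expansion — an emergent consequence of the Macaulay bracket,
  not a special case. Right after the extreme fiber crosses onset the
  tangent dM/dκ dips and partially recovers (the activation front sweeps
  fastest on entry); monotone tangent decrease holds beyond ~1.5× the
  onset curvature, and at finite layer counts a small activation sawtooth
  rides on the tangent, so monotonicity is asserted on a two-step
  coarse-grained tangent.

## Lattice combinatorics

Path counts on the three idealized osteon configurations use explicit
depth-first enumeration of the continuation tree (orthogonal: 2 per step;
triangular: 3; hexagonal: alternating 2,1). One caption describes "three
possible forward paths" for the orthogonal case while printing g_k = 2^k;
the formula is implemented as the quantitative claim. Beyond ~2·10⁶
leaves the count is accumulated as the running product of the same
per-step rule (never the closed form). The branching factor is the
geometric mean g_k^{1/k} at even k, where the hexagonal alternation
closes to exactly √2.

For irregular packings, the estimator is an original procedure (the
source methodology mentions estimating an average lattice parameter
numerically without specifying how): build the Delaunay graph of the
osteon centers, drop edges longer than 1.25× the median (removing the
spurious diagonals of degenerate square packings), then run Monte Carlo
walks that each fix a global propagation direction u and, at every node,
may continue to any neighbour strictly advancing along u. The geometric
mean of the per-step continuation counts reproduces 3 on triangular and
2 on square grids (for almost every u) and lands in (1, 3] on jittered
packings. Counting is restricted to interior nodes to avoid boundary
depletion. Deterministic under the seed.

## Calibration

Least squares on stress (or moment), trust-region reflective with box
bounds, multi-start (default 8, seeded), and the crack-step count N on
the integer grid 1..5. The reduced search vector is
(μ₂, ν₂, ρ₂+τ₂, μ₃, ν₃, ς₃, ρ₃+τ₃, β, r, ε₀): under plane stress only
the ρᵢ+τᵢ sums are identifiable, and the sign constraints are enforced by
fitting (μ₂+ν₂/2, −ν₂/2) > 0. Identifiability findings that shaped the
defaults:

- (μ₂, ν₂, ρ₂+τ₂) trade along a valley that is flat to machine precision
  on a single uniaxial curve. By default their *ratios* are pinned to the
  slope-matched initial guess and one common scale is fitted;
  `free_quadratics=True` re-exposes the raw degeneracy.
- r trades against the polynomial scale through m₁(0; r, N); at 1% noise
  a free r runs to its bounds and drags ρ₂+τ₂ by tens of percent. Since
  the lattice parameter is a microstructural quantity estimable from the
  osteon packing (the lattice module does exactly this), `fixed_r`
  supplies that measurement and is used in the recovery studies.
- (ν₃, ς₃) are nearly collinear with μ₃ on uniaxial paths and carry a
  ridge toward zero: penalty power = `ridge` (default 1e-6) × the data's
  signal power when the coefficient is at the cubic scale. Setting
  `ridge=0` reproduces the degeneracy.
- ε₀ is interval-identified only (its entire signature is which samples
  sit on the damaged branch), so it is recoverable to one abscissa
  spacing, not to optimizer precision.

The initial guess is data-driven: initial modulus from the smallest
strains, softening scale from the end-of-curve secant deficit (damage ≈
0.65× the deficit at the defaults; the remainder is the ensemble factor
m₁ declining), onset from the first 2% departure from linearity, then a
nine-point scan of the cubic scale. Bootstrap is residual resampling with
warm single-start refits (origin sample kept exact); refits failing in
more than 10% of draws abort. PCA standardizes columns and
eigendecomposes the correlation matrix (scikit-learn backend);
correlations are Pearson with two-sided t p-values, reported
descriptively, with optional Benjamini–Hochberg q-values.

## Synthetic cohort

The generator emulates the study design: 51 tensile specimens
(ages 55 ± 20 truncated to [21, 91]; 35 M / 16 F) and 15 bending
specimens (55 ± 11, [26, 62]; 10 M / 5 F). Three latent factors drive the
ten identifiable parameters multiplicatively with communality 0.8; the
first factor is standardized age, and β additionally follows
β = 0.4 + 0.006·(age − 55) + N(0, 0.08²) MPa⁻¹ (positive-truncated), so
older synthetic specimens are weaker. Defaults give an initial modulus of
~15 GPa, onset strain 0.004, visible softening by strain 0.02. Curves run
to the strain where α̃ reaches 0.5 — a driver stopping rule standing in
for fracture, not a physical criterion — with 60 samples and 1%
multiplicative lognormal noise (the emulated optical strain measurement
is low-noise). Sex is assigned but generatively inert, as no
parameter–sex link is claimed. N is fixed at 4 per the cortical
thickness / osteon diameter bound.

What passing tests show: the estimation pipeline is unbiased and
well-calibrated *when the model is true* and the noise is 1%
multiplicative. They do not show robustness to model misspecification,
to rate effects, to specimen geometry errors, or to the heavier-tailed
noise of real load cells; the cohort's factor structure is implanted, so
the PCA result is a recovery check, not a discovery.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen as the smallest that
make the checks sharp: oracle sweeps over ~10³ random states, 100 random
loading paths of 25–30 steps, 50 noisy refit replicates on 60-point
curves, lattice enumeration to k = 10–12, cohorts of 51 + 15 specimens.

## Known limitations

No viscoelasticity, viscoplasticity, strain-rate dependence or
remodeling; monotonic drivers only (the damage state supports arbitrary
paths, the drivers do not exercise cyclic loading beyond the tests);
prismatic beam instead of curved rib geometry; fiber-aligned loading in
the plane-stress solvers; the onset stress discontinuity discussed above;
fitted (β, r) are only jointly meaningful unless r is fixed from
microstructure.
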
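# Methods

## Scattering model

The analysis treats the gelling alginate solution as a mixture of locally
cylindrical scatterers and works entirely in the cross-section regime of
the measured window, q ∈ [0.103, 3.26] nm⁻¹. In Kratky form the model is

    q²I(q) ≈ q·k₁·[J₁(q·R_c1)/(q·R_c1)]² + q·k₂·[J₁(q·R_c2)/(q·R_c2)]² + const

with 0.05 ≤ R_c1 < R_c2 ≤ 50 nm, k₁, k₂, const ≥ 0. The ordering
constraint removes the label-switching degeneracy: component 1 is always
the thinner population (single or laterally thickened chains), component 2
the junction zones. `const` is an additive constant in Kratky space, i.e.
a const/q² term in intensity — it is kept exactly in the form the model is
written, not converted to a flat intensity background. Assumptions worth
stating: rod length drops out (only the cross-section term is modelled),
no polydispersity in R_c, no structure factor, and the broken-rod
decoupling is treated as exact across the fitted window; the window is
configurable where that approximation is doubted (fits can be restricted
to q ≤ 2 nm⁻¹, where late-time profiles are known to develop a broader
spectrum of lateral association than two components capture).

The small-x limit [J₁(x)/x]² → 1/4 is evaluated by series below
|x| < 1e-4 (two terms, exact to ~1e-17) so q = 0 and tiny q·R_c never hit
0/0. A single rod term attains its Kratky maximum at the universal product
q_peak·R_c = x* = 1.35660, the positive root of 2x·J₀(x) = 3·J₁(x); peak
location uses a ≥2000-point grid scan followed by bounded golden-section
refinement to 1e-4 nm⁻¹, far below any physically meaningful shift in this
window, and reports "no peak" whenever the scan maximum sits on a window
edge.

## Per-frame fitting and model selection

Each frame is fitted in Kratky space by bounded trust-region least
squares (lmfit/least_squares), minimising Σ wᵢ(yᵢ − model)² with
wᵢ = 1/σ_y,ᵢ² when uncertainties are present and 1 otherwise. Relative
cost-change tolerance is 1e-10 (step/gradient tolerances 1e-14). The
two-component fit runs unordered and is relabelled post-fit so R_c1 < R_c2;
constructing an init with either labelling therefore produces the same
ordered result. Non-convergence and singular Jacobians are flagged on the
result, never raised.

One- vs two-component selection uses BIC = n·ln(cost/n) + p·ln(n) with a
parsimony tie-break: the extra component must improve BIC by more than 2.
Residual sums are floored at n·(1e-12·max|y|)² so noiseless data (cost at
machine zero for both variants) resolves to the single-component model
instead of comparing logs of rounding noise.

Series are fitted sequentially, warm-starting each frame from the previous
converged parameters; with 5 s frame spacing the structure is nearly
continuous and the warm start stabilises the weakly identified early
frames. Failed frames carry the previous parameters forward, flagged, so a
time course always has one entry per frame. Replicate time courses are
averaged pointwise after nearest-time alignment (within half the modal
frame interval); where only one replicate resolved a junction-zone
component, its R_c2 enters the average alone.

Weight fractions default to w_i = k_i/(k₁+k₂), reading the amplitudes
directly as the relative weights; an alternative `cross_section` mode
reweights by R_c² (mass-per-length of a homogeneous cylinder) before
normalising, for users who prefer that convention. The two conventions
coincide in ranking but not in value; all presets and tests use the
amplitude convention.

## Synthetic frame series

The generator emulates the acquisition the analysis assumes: frames every
5 s on a 120-point uniform grid over the instrument window, a final fully
equilibrated frame at 10 h, and one matched buffer profile. Scenario
presets pin the known anchor states — pH 7.0: chains 0.2 → 0.9 nm,
junction zones ≈2.6–2.9 nm appearing at 10 s, w₂ 0 → 0.6 by two minutes
→ 0.8 at 10 h; pH 7.4: endpoint radii 0.93/2.9 nm with w₂ plateauing
near 0.6; pH 8.0: weak amplitude, R_c2 ≈ 2.5 nm and a non-monotone
junction fraction; a GDL slow-acidification control sharing the pH 7.0
endpoint. The pH 8.0 record is ambiguous about which component's fraction
halves by 10 h, so two presets carry the two readings ("pH8.0": w₂
0.5 → 0.25; "pH8.0-alt": w₂ → 0.75) and no intent is guessed. Between
anchors every quantity follows a piecewise saturating-exponential
interpolant (1 − e⁻³ˢ on the normalised interval, rescaled to hit both
anchors exactly); anchors are known states, functional forms are not, and
a saturating approach is the simplest shape consistent with
diffusion-fed first-order kinetics.

Noise is independent Gaussian per point with variance proportional to the
total (signal + buffer) intensity — the large-count limit of photon
counting, with exposure folded into a single `noise_level` knob
(default 0.015, giving the full-gel frame a peak Kratky signal-to-noise
of ≈30). The buffer is modelled as a smooth low-q power law plus constant
so that subtraction is a meaningful pipeline step. The sigma column
carries the true per-point standard deviation.

What passing tests on these fixtures do not show about real data: no
instrumental smearing, no inter-rod structure factor, no intensity drift
or radiation damage, a buffer of convenient functional form, and exactly
Gaussian noise. Recovery results are therefore statements about the
estimator under the assumed noise model, not about beamline systematics.

A note on attainable precision: at peak signal-to-noise ≈30 the
Cramér–Rao bound for the thin-component radius of the full-gel state
(five free parameters, 120 points, single-frame buffer subtraction) is
≈6% relative, and the maximum-likelihood fit lands ≈20% above that bound
(measured 7.6% RMSE over 50 replicates; fits started at the truth give
the same number, so this is information, not optimisation). The
junction-zone radius and weight fraction are much better determined
(≈1.6% and ≈2.1%). At zero noise all presets refit to the generating
trajectory at ~1e-13 relative error.

## Reaction–diffusion gelation model

The contact zone between the two CLEX solutions is modelled in 1D with
the interface at x = 0. C₁ (CaEDTA) occupies x < 0, C₂ (ZnEDDA) x > 0,
both at 0.06 M; alginate monomer (0.0505 M ≈ 1% w/v at 198 g/mol
residue) is uniform and immobile. The fields evolve as

    ∂C₁/∂t = D₁∂²C₁/∂x² − κC₁C₂
    ∂C₂/∂t = D₂∂²C₂/∂x² − κC₁C₂
    ∂C₃/∂t = κC₁C₂ + D_Ca∂²C₃/∂x² − r_bind·k_bind·C₃·A
    ∂G/∂t  = k_bind·C₃·A,        A = alg_free = alg₀ − G

with D₁ = D₂ = 0.78e-9 m² s⁻¹ and κ = 1e4 M⁻¹ s⁻¹ — large enough that
exchange is not rate limiting (raising κ tenfold changes the centre-ROI
gel level at 120 s by <1%). The gelation sink is the model's open design
point: free Ca²⁺ binds irreversibly to ungelled monomer as a second-order
reaction with k_bind = 1e4 M⁻¹ s⁻¹ (fast, diffusion-limited regime),
consuming r_bind = 0.5 Ca²⁺ per monomer gelled (one ion per guluronate
pair in an egg-box dimer); D_Ca defaults to D₁. All four are explicit
configuration because no measured values constrain them here, and the
ROI comparisons are correspondingly qualitative. ZnEDTA/EDDA²⁻ products
are tracked as a single bookkeeping field that feeds no kinetics.

Numerics: method of lines, second-order central differences on 601 nodes
over ±2 mm, reflecting (zero-flux) walls, BDF stiff stepping at relative
tolerance 1e-8 (absolute 1e-12) with a banded-by-construction Jacobian
sparsity pattern. The interface node takes the step midpoint value c₀/2,
the second-order discretisation of a half-space step; with κ = k_bind = 0
the solver then matches the closed-form erfc profile to ~3e-4 relative.
The half-length was sized so the walls stay at their initial values —
boundary depletion beyond 0.1% of the initial concentration raises an
error rather than silently violating the constant-far-field assumption.
Trapezoidal box integrals of total Ca (C₁ + C₃ + r_bind·G), total
Zn-chelate partners (C₂ + products) and total monomer (A + G) are
conserved by the scheme to solver tolerance (~1e-13 measured). Output is
sampled every 12 s over the first 120 s by default; ROI averages use
trapezoidal weighting over the nodes inside the window (50 µm at the
interface and at a 200 µm offset), degenerating to the nearest node for
sub-grid windows.

Known limitations: 1D geometry ignores the curved contact line of the
real sample cell; chelator association constants are not pH-dependent
here (the pH series is represented only through the scattering scenarios);
the simulated Ca²⁺ field is not coupled back into the scattering model;
and the binding parameters are order-of-magnitude choices, so only the
ordering and shape of the ROI kinetics — interface gels first, the
offset region tens of seconds later — carry meaning.

## Determinism and problem sizes

Every stochastic step takes an explicit integer seed
(`numpy.random.default_rng`); fixtures and all CSV outputs are
byte-reproducible per seed, with floats written at repr precision. The
test and analysis problem sizes — 120-point q grids, 31-frame series,
50-replicate recovery and selection studies, 601-node simulations over
120 s — were chosen as the smallest sizes at which the statistical checks
are stable, and are stated here as the package's own defaults.
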
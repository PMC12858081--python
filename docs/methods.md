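# Methods

## Continuum model

The core is a six-field reaction–diffusion system on Ω = [0,1]², read in
centimeters (a 1 cm × 1 cm tissue slab; the diffusion coefficients in
cm²/h make this the natural scale).  Fields: densities of anti-tumorigenic
N1 TANs and pro-tumorigenic N2 TANs and of glioma cells (cells/cm³), and
concentrations of anti-N2 antibody, IFN-β and TGF-β (g/cm³).  The
interaction structure is:

* N1/N2 grow logistically with cytokine-tilted carrying capacities
  (w₁S + K₁ and w₂G + K₂) and compete Lotka–Volterra style (α₁, α₂);
* glioma cells grow logistically toward n₀ with a saturating N2-driven
  boost r(1 + r_N N₂²/(k²+N₂²)) and are killed by N1 at rate μ_n N₁;
* the antibody removes N2 at rate βA and is dosed on a support mask Ω_A,
  either constantly at λ_A\* or in pulses of width τ at 100·λ_A\*;
* TGF-β is secreted by tumor cells (λ_G n); the IFN-β source is an
  *injection* indicator — in untreated scenarios S ≡ 0, and IFN-rich or
  post-surgery arms switch a source on over a mask (whole domain, or the
  resection rim at 100·λ_S).  We considered an always-on ambient IFN-β
  source instead; it inflates the N1 carrying capacity three-fold and
  produces N1-heavy control compositions, so the injection reading is the
  default.

All boundaries are zero-flux.  Parameter defaults (see
`gliotan.ModelParameters`) are the calibrated reference set; every symbol
carries its unit in the docstring.

Tissue heterogeneity enters through the diffusion coefficients only:
gray-matter nodes carry 10⁻⁶ of the white-matter value for every species.
The corpus-callosum corridor and vessel lumina use white-matter values;
vessels additionally serve as source supports (antibody entry, TAN influx)
— they are entry sites, not flow models.

## Discretization and time stepping

Node-centered uniform grid (101×101 by default, h = 0.01).  The diffusion
operator is a conservative finite-volume stencil with **harmonic-mean face
coefficients** — essential across the 10⁶-fold white/gray contrast, where
arithmetic averaging would leak mass through the interface.  Boundary
nodes own half control volumes (equivalently, mirror-ghost Neumann
closure), which keeps the stencil second-order up to the boundary; the
matching mass functional is the trapezoidal quadrature implemented in
`total_population` (a constant field on the unit square integrates to
exactly itself, and the volume-weighted integral of the operator output
vanishes to rounding).

Time stepping splits reactions from diffusion (default dt = 0.01 h,
configurable; the scenario battery is robust at dt = 0.1 h):

* **Reactions** are advanced by a two-stage exponential integrator on a
  production/loss decomposition of each right-hand side
  (u' = P − L·u with P, L ≥ 0): a first exponential-Euler stage followed
  by a trapezoidal correction with averaged P and L.  The scheme is
  unconditionally positive, exact for constant source–decay balances
  (the antibody plateau λ_A/μ_A and the TGF-β equilibrium λ_G n₀/μ_G are
  reproduced to machine precision at any dt), second-order otherwise, and
  stable under the stiff antibody kill term βA even at large dt.
* **Diffusion** is IMEX: backward Euler with prefactorized sparse LU for
  the fast diffusers (A, S, G; D up to 7.7×10⁻² cm²/h), explicit with
  automatic sub-cycling for the slow cell fields (D ~ 4×10⁻⁶ cm²/h, far
  below the explicit limit at default steps).

Values below 10⁻³⁰ are flushed to zero after each step (physically
negligible; avoids subnormal-range arithmetic).  Non-finite values abort
with a diagnostic.  On uniform tissue with uniform data the integrator
matches an independent stiff ODE solve of the reaction system to better
than 10⁻⁴ relative over 240 h; a tumor-only run follows the logistic
closed form to < 0.1 %.

Timed events (surgical resection, schedule changes) are applied exactly at
their nominal times — step boundaries are inserted as needed and event
times are snapshot times.

## Synthetic initial layouts

The generator emulates the study's pictorial initial conditions: a central
tumor disc (amplitude 0.1·n₀, radius 0.05) surrounded by TAN aggregates —
isotropic Gaussian bumps (std 0.03) at seeded random positions in an
annulus (default radii 0.12–0.30) around the tumor.  Phenotype presets:
`n1_dominant` (all aggregates N1), `n2_dominant` (all N2), `coexistence`
(alternating, 4+4 by default).  Both phenotypes use the same default peak
(2×10⁶ cells/cm³, half the N2 carrying capacity) so the dominance arms
start from identical total TAN mass and the coexistence layout is
N1/N2-balanced by construction.  In tissue geometries, placement is
rejection-sampled onto permissive (non-gray) nodes.  A, S, G start at
zero.

What the generator does **not** emulate: the published experiments used
hand-placed layouts whose amplitudes and positions are shown only
pictorially.  Treatment-effect *magnitudes* (percent reductions,
composition shares) are sensitive to aggregate strength and proximity, so
quantitative agreement with the published percentages is approximate;
orderings and signs (which layouts grow faster, which therapy arm wins,
correlation directions) are robust across seeds and are what the test
suite pins down.

Scenario registry (`gliotan.list_scenarios()`): baseline growth, the
dominance battery, cytokine-rich conditions (100× λ_S or λ_G), antibody
injection at N2 sites (constant/periodic, dose sweep), injection-site
placement with D_A/100 and equal total dose by construction, wrinkle/star
white-matter geometries, vessel-borne injection (horizontal/vertical ×
constant/periodic), and the CC two-hemisphere surgery family (resection of
the visible core — nodes with n > 0.05·n₀ — at t = 84 h, with optional
IFN-β or antibody on the resection rim).

## Hybrid cellular automaton

Five discrete cell types live on the lattice: non-invasive (core) and
invasive glioma cells, N1/N2 TANs, and exogenous Trojan N1 TANs
(nanoparticle carriers, switch-immune).  Per 1-h step, in order: core
radius update (95th percentile of core-cell radii; rim Ω_I extends 0.05
beyond) → go-or-grow on the core surface (invasive with probability
q = 0.3) → migration (invasive cells in Ω_I step to the free Moore
neighbor best aligned with the outward radial direction, elsewhere they
random-walk with p = 0.8; TANs climb the TGF-β gradient, with the same
random-walk fallback; cells in the CC corridor get one extra move attempt
— the fast track) → division (8-h cycle, probability r_div = 1 into a
uniformly chosen free neighbor; enclosed cells hold their clock and
retry; an invasive mother settles as non-invasive) → phenotype switching
(threshold comparison of w₂G vs w₁S with margin θ = 0) → antibody removal
of N2 agents (probability 1 − e^{−βA dt}, the agent analogue of the
continuum kill term; the study's narrative of antibody-driven N2→N1
normalization has the same therapeutic consequence — removal of the N2
shield) → natural TAN death (rate μ₁) → contact killing (tumor cells with
an N1/Trojan Moore neighbor are removed) → timed surgery → vessel influx
(1 endogenous N1/h; 5 Trojan/h while that therapy is active) → continuum
update of S, G, A (backward-Euler diffusion, exact exponential decay, two
substeps; each tumor cell deposits a TGF-β source of λ_G × n₀, treating an
occupied site as tissue at carrying capacity).  Cells never enter gray
matter.  Within each stage, cells are processed in randomized order; all
randomness flows from one seeded generator, so a seed reproduces a
trajectory exactly.  q, p, r_div and the influx rates are not published
values; they are package defaults, configurable and swept in tests.

CA experiments: the Trojan-therapy battery (central tumor, left vessel;
control / Trojan / antibody / combined arms to 180 h), extended-surgery
variants in the two-hemisphere domain (core-only versus extra resection
near the CC entrance and/or the vessel at t = 120 h, tracked to 360 h),
and butterfly-glioma prevention (surgery + Trojan influx).

## Sensitivity analysis

Latin hypercube sampling (via `scipy.stats.qmc.LatinHypercube`) over the
26 model parameters; default ranges span [0.1×, 10×] each reference value,
log-uniform — wide enough to include the study's own 100-fold perturbation
conditions without leaving plausible regimes (the published analysis does
not print its ranges; these are package defaults, not inferred ones).
Outputs are the six population integrals at t = 1, 50, 100 h, computed on
a scenario with all source pathways active (antibody at the N2 sites,
whole-domain IFN-β) so every parameter can express an effect.  PRCC is the
residual-method partial correlation on ranks, with p-values from the
t-statistic at n − 2 − 25 degrees of freedom; constant columns are flagged
and reported as 0.  The reduced mode (n = 50–100 samples, 51×51 grid) is
the default test path; n = 1000 is the documented long-running option.

## Problem sizes and reproduction

`scripts/acceptance.py` runs the battery at a desk scale chosen so the
whole reproduction fits in minutes on one CPU: 51×51 continuum grid with
dt = 0.1 h and 240-h horizons, 10 random layouts per experiment (paired
seeds across arms), and the 101×101 hybrid lattice with 20 paired seeds to
180 h.  Refining to dt = 0.05 leaves the dominance ratios unchanged to
three digits; refining the grid to 101×101 shifts them by O(10 %) (front
sharpening), within the seed-to-seed scatter.

## Known limitations

* Quantitative percentages inherit the initial-condition uncertainty
  discussed above; this package's layouts are declared defaults, not
  transcriptions.
* The continuum model is pure reaction–diffusion (no chemotaxis terms);
  directed migration exists only in the CA layer, as specified.
* Vessels are static source masks; there is no perfusion or
  pharmacokinetic compartment for the antibody.
* 2-D only; the CC corridor is a planar band, not a fiber-tract geometry.
* The CA's per-cell TGF-β source strength (density equivalent n₀) and the
  CC speed-up magnitude are modeling constants without published values.
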
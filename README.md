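# gliotan

An in-silico laboratory for the interplay between glioblastoma (GBM) and
tumor-associated neutrophils (TANs) in heterogeneous brain tissue, for
researchers studying tumor–immune dynamics and neutrophil-mediated drug
delivery ("Trojan horse" nanoparticle carriers).

Neutrophils in the tumor microenvironment occur in two phenotypes: the
anti-tumorigenic **N1** type, which kills glioma cells, and the
pro-tumorigenic **N2** type, which accelerates their growth.  The switch
between them is driven by IFN-β (toward N1) and tumor-secreted TGF-β
(toward N2).  `gliotan` implements:

* a **six-field reaction–diffusion model** of N1/N2 TAN densities
  (N₁, N₂), anti-N2 antibody (A), glioma cell density (n), and IFN-β /
  TGF-β concentrations (S, G) on the unit square (1 cm × 1 cm of tissue),
* **tissue geometries** — white/gray matter folds, star-shaped regions,
  blood-vessel strips, and a two-hemisphere domain joined by a
  corpus-callosum (CC) corridor — entering through a 10⁻⁶-fold diffusion
  contrast between white and gray matter,
* a **hybrid cellular automaton** with five discrete cell types
  (non-invasive/invasive glioma, N1/N2 TANs, Trojan N1 TANs) coupled to the
  continuum cytokine/antibody fields: go-or-grow, chemotaxis, 8-h cell
  cycle, phenotype switching, contact killing and surgical resection,
* **LHS/PRCC global sensitivity analysis** over the 26 model parameters.

## The model

The continuum system (zero-flux boundaries, space-dependent diffusion
D(x) reduced 10⁻⁶-fold in gray matter):

```
∂N₁/∂t = ∇·(D₁(x)∇N₁) + r₁N₁(1 − N₁/(w₁S + K₁)) − α₁N₁N₂ − μ₁N₁
∂N₂/∂t = ∇·(D₂(x)∇N₂) + r₂N₂(1 − N₂/(w₂G + K₂)) − α₂N₁N₂ − μ₂N₂ − βN₂A
∂A/∂t  = ∇·(D_A(x)∇A) + λ_A(t)·1_{Ω_A} − μ_A A
∂n/∂t  = ∇·(D_n(x)∇n) + r(1 + r_N N₂²/(k² + N₂²)) n (1 − n/n₀) − μ_n N₁ n
∂S/∂t  = ∇·(D_S(x)∇S) + λ_S I_S − μ_S S
∂G/∂t  = ∇·(D_G(x)∇G) + λ_G n − μ_G G
```

N1 and N2 compete Lotka–Volterra style; the cytokines tilt the respective
carrying capacities; N2 boosts tumor growth through a saturating Hill
switch; N1 kills tumor cells; the antibody removes N2 TANs.  Antibody
dosing is constant (λ_A\*) or periodic (100·λ_A\* during pulses
[t_j, t_j+τ]).  The spatial index `SN21R = N₂/(ε + N₁)` (ε = 0.01) maps
where the immune balance is pro-tumorigenic.  All parameter defaults are
the calibrated reference set (see `gliotan.ModelParameters` and
`docs/methods.md`).

## Worked example

```bash
python examples/01_baseline_growth.py
```

```
time [h]   tumor n̂ [cells]   N̂1 [cells]   N̂2 [cells]   TGF-β Ĝ [g]
      0        8.4e+05    4.524e+04    4.524e+04            0
     78        2.9e+07    1.514e+05    1.674e+05    1.434e-10
    162      1.177e+08     2.95e+05    4.381e+05      7.8e-10
    240      2.666e+08    4.105e+05    8.587e+05    1.993e-09
```

The columns are grid integrals over the 1 cm² slab: the tumor grows from
its seeded disc (8.4×10⁵ cells) by ~300-fold in ten days, and the N2 pool
— fed by tumor-derived TGF-β — overtakes N1, the pro-tumor tilt of an
untreated microenvironment.  The other scripts in `examples/` walk through
the phenotype-layout experiment, antibody dosing and dose–response,
heterogeneous tissue, CC surgery with adjuvant therapy, the sensitivity
analysis, and the hybrid Trojan-neutrophil experiment.

A thin CLI wraps the same machinery:

```bash
gliotan scenario list
gliotan scenario run dominance --nx 51 --dt 0.1 --out runs/
gliotan sensitivity --n 50 --times 1,50,100 --seed 1
```

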
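# ifnsig

Models of ligand discrimination in Type I interferon (IFN) signalling.

All Type I IFNs (IFN-α subtypes, IFN-β, …) signal through the same two-chain
receptor: the ligand binds IFNAR1 or IFNAR2 in solution, then recruits the
other subunit in the membrane to form a signalling-competent ternary complex
that phosphorylates STAT.  Yet different IFNs drive different biology — in
particular IFN-β is a far more potent anti-proliferative agent than IFN-α2
while their anti-viral potencies are nearly identical.  `ifnsig` is a toolkit
for studying how that *functional plasticity* can arise behind a shared
receptor bottleneck: it implements the equilibrium theory of ternary-complex
assembly, a kinetic ODE model of pSTAT induction with its negative feedbacks
(SOCS1, receptor internalization, USP18), population averaging over receptor
heterogeneity, synthetic flow-cytometry-style data generation, parameter
inference, and phenomenological mappings from pSTAT to anti-viral and
anti-proliferative activity.  It is aimed at quantitative immunologists and
systems biologists who want a tested, scriptable implementation of these
models.

## The model

**Receptor assembly (equilibrium).**  With solution dissociation constants
K₁ (IFN·IFNAR1) and K₂ (IFN·IFNAR2), in-membrane constants K₃, K₄ for
recruiting the second subunit, and surface densities R₁, R₂ (R_T = R₁+R₂,
Δ = R₁−R₂), detailed balance requires K₁K₃ = K₂K₄ and the ternary-complex
density at ligand concentration I is

    T(I) = (R_T/2) · (Ξ − √(Ξ² − 1 + (Δ/R_T)²)),
    Ξ(I) = 1 + (K₄/R_T) · (I+K₁)(I+K₂)/(I·K₁).

T(I) is bell-shaped (the prozone effect): it peaks at I_m = √(K₁K₂) with
height T_max, and below the peak is well approximated by
T ≈ T_max·I/(K_eff + I).

**pSTAT response.**  With total STAT S_T, phosphorylation constant
K_p = k_p⁻/k_p⁺ (copies) and cell area A,

    pSTAT = S_T · TA / (K_p + TA),
    pSTAT_max = S_T·T_max/(T_max + K_p/A),
    pSTAT EC₅₀ = K_eff/(1 + T_max·A/K_p).

**Kinetics and feedbacks.**  The same network as mass-action ODEs adds SOCS1
(produced downstream of pSTAT, binds IFNAR1-containing species and blocks
phosphorylation), basal and ligand-induced receptor internalization with
ligand-specific recycling, and USP18-mediated refractoriness in primed cells
(a 15–60-fold increase of K₄, i.e. of the IFNAR1 off-rate k₋₄).

**Functional mappings.**  Anti-viral activity follows pSTAT/(K_M + pSTAT)
with K_M = 0.8 pM; anti-proliferative activity is the mean of two Hill terms
of the USP18-primed pSTAT (K_M1 = 72 pM, K_M2 = 158 pM, γ₁ = 0.9, γ₂ = 3.7).

## Worked example

```python
from ifnsig import defaults, equilibrium as eq
from ifnsig.params import CellGeometry, PStatParams, ReceptorSurface

geom = CellGeometry.from_area(450.0)                      # um^2
surf = ReceptorSurface.from_copies(1000, 1000, geom.area) # per subunit
pp = PStatParams(ST=485.0, Kp=900.0)                      # copies

for aff in (defaults.IFN_ALPHA2, defaults.IFN_BETA):
    tmax, im = eq.tmax_imax(aff, surf)
    print(f"{aff.name}: Tmax = {tmax*geom.area:.0f} complexes, "
          f"Keff = {eq.keff(aff, surf)*1e12:.2f} pM, "
          f"pSTATmax = {eq.pstat_max(aff, surf, geom, pp):.0f} copies")
```

prints

```
IFNa2: Tmax = 684 complexes, Keff = 596.51 pM, pSTATmax = 209 copies
IFNb: Tmax = 932 complexes, Keff = 2.22 pM, pSTATmax = 247 copies
```

IFN-β's stronger IFNAR1 binding yields ~36% more ternary complexes at
saturation, but STAT-level saturation compresses this to a ~15% gap in
pSTAT_max (209 vs 247 copies) — and a ~300-fold lower EC₅₀.  Priming with
USP18 (`aff.perturb(usp18_fold=15.0)`) halves the IFN-α2 plateau (209 → 107
copies) while barely moving IFN-β, opening the region of absolute
discrimination that the anti-proliferative mapping converts into a
ligand-specific maximal response.

A statsmodels-style fitting surface is available for panels:

```python
from ifnsig import synthetic, model
panel = synthetic.generate(synthetic.ScenarioSpec(kind="dose_time_panel"))
m = model.PStatResponseModel.from_panel(panel)
res = m.fit()         # or m.fit_mcmc()
print(res.summary())
```

and a CLI (`ifnsig generate|simulate|dose-response|fit|functional-map|discriminate`)
wraps the same functionality for shell use.

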
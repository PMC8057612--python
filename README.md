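# plaquesim

Patient-specific simulation of atherosclerotic plaque progression on labeled
2D vessel cross-sections.

Coronary plaque rupture is driven by the local microenvironment — lipid
deposition, inflammation, smooth-muscle-cell (SMC) apoptosis, and leaky
intraplaque neovessels — none of which routine imaging can follow over time.
`plaquesim` is for computational vascular-biology researchers who want a
reusable, testable implementation of a multi-physical continuum model of that
microenvironment: twelve coupled fields (LDL `L`, ox-LDL `L_ox`, MCP-1 `P`,
monocytes `Mo`, macrophages `Ma`, foam cells `F`, SMCs `S`, ECM `C_ECM`,
MMP `C_M`, microvessel endothelial cells `E`, VEGF `C_v`, extravascular
plasma `Pl`) evolving on the intima + media of a segmented cross-section.

## Model

Each field obeys a reaction–diffusion–taxis equation on the masked grid

```
∂C_i/∂t = D_i ∇²C_i + Σ production − Σ consumption − ∇·(λ C_i ∇C_j) − d_i C_i
```

with zero-flux closure at the external elastic membrane (EEM) and at the
lumen interface. Plasma LDL and monocytes enter across the endothelium with
a shear-modulated conductive flux

```
J = k_cr · C_plasma / (1 + WSS/WSS₀),      WSS₀ = 100 dyn·cm⁻²
```

so low wall shear stress promotes influx. The necrotic core (NC) is the
intima area where SMC density has fallen by more than 50 % of its initial
value; plaque development is tracked by the growth rate `N(t)/N₀`.

The patient workflow mirrors follow-up imaging practice:

1. **Calibrate (T1 → T2).** Baseline imaging cannot see the initial
   inflammation or microvessel burden, so one simulation is run per
   candidate (inflammation × microvessel level, 3 × 3) up to the follow-up
   interval and the pair whose NC growth best matches the observed growth is
   selected.
2. **Predict (T1 → T3).** The calibrated levels seed a fresh 36-month run.
3. **Score.** Eight risk factors (plaque burden PB, eccentricity index EI,
   LDL, HDL, WSS, and the simulated macrophage / SMC / ox-LDL levels at T3)
   are graded 1–3 by comparing patients against each other; the total
   classifies the plaque as stable or vulnerable.
4. **Cohort statistics.** Welch t-tests per microenvironmental factor
   between stable-like and unstable-like groups, and Spearman correlations
   of each factor with NC area.

A fully synthetic cohort generator (eccentric annular geometries +
Table-shaped patient records + simulated "observed" follow-up growth) makes
every stage testable without any imaging data.

## Worked example

```
plaquesim predict -c examples/demo.yaml
```

calibrates and predicts two synthetic patients at reduced (60×60)
resolution. It prints

```
plaquesim: calibration demo_stable: chose ('mild', 'low') (residual 0.05, observed 1.05)
plaquesim: calibration demo_unstable: chose ('severe', 'high') (residual 0.03838, observed 2.8)
outputs in plaquesim_demo_out
```

and writes `calibration_summary.csv`:

```
patient,inflammation_level,microvessel_level,observed_nc_growth_t2,nc_growth_t3,...
demo_stable,mild,low,1.05,3.3259259259259264,...
demo_unstable,severe,high,2.8,4.474747474747475,...
```

demo_stable's observed 12-month NC growth (1.05×) is matched by the mild
inflammation / low microvessel candidate, and its three-year prediction is a
3.3× NC expansion; demo_unstable's 2.8× observed growth requires the severe
/ high candidate and grows 4.5× by T3. The score table grades the two
patients against each other:

```
,PB,EI,LDL,HDL,WSS,Mphi,SMC,oxLDL,total,fate
demo_stable,1,1,1,1,1,1,1,1,8,stable
demo_unstable,3,3,3,3,3,3,3,3,24,vulnerable
```

`plaquesim cohort-stats --seed 0 -n 80 -o cohort_out` runs the full
four-patient synthetic cohort end-to-end (generation, calibration,
prediction, scoring, group t-tests, NC correlations).

Other subcommands: `simulate` (forward run at explicit levels), `calibrate`
(level identification only), `score` (grade a CSV of factor values).

## Layout

- `src/plaquesim/geometry.py` — labeled domains, mask I/O, synthetic
  geometries, PB/EI morphology
- `src/plaquesim/params.py` — model constants with provenance, initial
  conditions, reference scales
- `src/plaquesim/reactions.py` — reaction terms, taxis couplings,
  endothelial influx
- `src/plaquesim/solver.py` — masked flux-form stencils, explicit Euler with
  stability control, simulation driver
- `src/plaquesim/analysis.py` — NC metrics, severity scoring,
  classification, cohort statistics
- `src/plaquesim/pipeline.py` — calibrate → predict workflow, config runner
- `src/plaquesim/cohort.py` — synthetic cohort generation and end-to-end
  analysis
- `docs/methods.md` — model description, parameter choices, numerical
  details, limitations
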
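# Methods

## The model

The plaque microenvironment is treated as a continuum on a 2D cross-section
of a coronary vessel, segmented into lumen, thickening intima, media, and
exterior. The PDE domain is the wall (intima + media); the default frame is
4 mm × 4 mm divided into 200 × 200 cells (h = 20 µm). Twelve fields evolve
simultaneously:

| field | meaning | initial value (physical) |
|---|---|---|
| `L` | LDL | 1.0·10⁻³ mg·mm⁻², intima, uniform |
| `Lox` | oxidized LDL | 1·10⁻⁷ mg·mm⁻², intima |
| `P` | MCP-1 | 3·10⁻¹⁰ g·cm⁻³ |
| `Mo` | monocytes | 0 |
| `Ma` | macrophages | 0 |
| `F` | foam cells | 0 |
| `S` | SMCs | 6·10⁻³ g·cm⁻³ media, 3·10⁻³ intima |
| `CECM` | extracellular matrix | 4·10⁻² g·cm⁻³ |
| `CM` | MMP | 3·10⁻⁸ g·cm⁻³ |
| `E` | microvessel EC density | seeded in a 100 µm media band at the EEM |
| `Cv` | VEGF | mean 4·10⁻¹⁰ g·cm⁻³, rising toward the intima |
| `Pl` | extravascular plasma (IPH proxy) | 0 |

All equations are solved nondimensionally: concentrations divided by the
per-species reference scale (the initial magnitude for species that start at
a finite level, a plausible maximum for trace species), lengths by the frame
width, time in months.

Reaction rows follow the standard interaction network: LDL oxidizes to
ox-LDL; macrophages phagocytose ox-LDL and become foam cells; MCP-1 is
produced by ECs (saturating in ox-LDL) and SMCs and recruits
monocytes/macrophages; monocytes differentiate into macrophages; VEGF is
produced by SMCs and macrophages and consumed by ECs; MMPs (from ECs and
SMCs) degrade ECM, which SMCs replenish; ox-LDL drives SMC apoptosis
(`−d_S·S·Lox`), the process that defines the necrotic core. Motile species
move up attractant gradients: macrophages → MCP-1, monocytes → ox-LDL,
ECs → VEGF (saturating sensitivity) and ECM, SMCs → MCP-1, macrophage-borne
PDGF, and ECM.

Transluminal entry of LDL and monocytes uses the conductive flux
`J = k_cr·C_plasma/(1 + WSS/WSS₀)` with `WSS₀ = 100 dyn·cm⁻²`,
`L_cr = 2·10⁻⁵ m·s⁻¹` and `Mo_cr = 4·10⁻⁵ m·s⁻¹`. The plasma monocyte level
encodes the inflammation regime: 4, 8, 16 ·10⁵ cells·cm⁻³ for mild,
moderate, severe. The microvessel regime scales the seeded EC density by
0.5 / 1.0 / 2.0 (low / mid / high).

## Model closure choices

Four parts of the system are under-determined by the published interaction
network; the package closes them as follows, and each closure is an explicit
`ParameterSet` constant tagged `gap-filled`:

- **Foam cells.** Production proportional to the phagocytosis term
  (`λ_F·Lox·Ma`) minus slow first-order degradation — phagocytosed ox-LDL is
  the canonical foam-cell source.
- **VEGF uptake.** Mass-action `−λ_CvE·E·Cv` (proportional to both EC
  density and local VEGF). An uptake term independent of the VEGF level
  would drive the field negative wherever ECs persist after VEGF is
  exhausted.
- **Plasma extravasation.** `dPl/dt = γ·Q_t − d_Pl·Pl` with
  `Q_t = E·(1 + k_perm·Ma/(K_Ma + Ma))`: plasma leaks from the continuum
  microvessel density, the leakiness rises (and saturates) with perivascular
  macrophage density — inflamed neovessels are immature and leaky — and
  first-order clearance (resorption/drainage) bounds the pool. Without the
  clearance term the plasma pool integrates without bound and the whole
  intima necroses within the horizon under any parameterization; without
  the saturation the plasma → monocyte → macrophage → permeability loop is
  super-critical.
- **Endothelial dysfunction.** The effective transluminal LDL conductivity
  is scaled by `1 + k_endo·(C_Mo/C_Mo,ref − 1)`: a systemically inflamed
  endothelium (adhesion-molecule expression, junctional disruption) is more
  permeable to lipoproteins. This is the dominant positive coupling from
  the inflammation regime to necrotic-core growth. It matters because the
  printed interaction network alone makes inflammation net *protective*
  here: phagocytosis removes ox-LDL and SMC chemotaxis toward
  macrophage-borne PDGF replenishes the necrotic front — while calibration
  by NC-growth matching requires growth to increase with the assumed
  inflammation level. The shear-flux formula itself is untouched; the
  factor enters only the nondimensional source strength.

Plasma convection (`ψ∇(U_i·Pl)`) is disabled by default (`ψ = U_i = 0`).

## Rate constants

Published values exist only for the boundary-flux constants, the initial
concentrations, and the plasma monocyte levels. All other diffusion and
rate constants are nondimensional per-month values chosen once so that the
default dynamics reproduce the qualitative behaviour the model is meant to
exhibit, and are fully overridable from a YAML config:

- lipid fronts advance from the endothelium inward over months
  (`β_L = 0.1 /month` influx strength, `λ_L = λ_LoxL = 0.4 /month`
  oxidation, `D_L = 3·10⁻⁴`, `D_Lox = 1·10⁻⁴` frame²/month);
- phagocytosis is the main ox-LDL sink (`λ_LoxMa = 0.05`), so lipid does not
  homogenize across the wall;
- SMC apoptosis `d_S = 0.018 /month·[Lox]` leaves part of the outer intima
  viable at three years while the near-lumen front crosses the 50 %
  threshold within the first year;
- NC growth at a 12–14-month follow-up is strictly increasing in both the
  inflammation and the microvessel level, which is what makes the 3 × 3
  calibration identifiable;
- SMC taxis sensitivities are kept small (10⁻⁶ frame²/month per unit
  attractant) — at larger values chemotaxis toward the macrophage ring
  visibly "rescues" the necrotic front, and the coupled
  SMC–ECM haptotaxis loop is prone to Keller–Segel-type blow-up.

## Numerics

- **Spatial discretization.** Conservative flux form on cell faces for both
  diffusion and taxis; a face between a wall cell and a lumen/exterior cell
  carries zero flux (mirror closure), so the domain is closed except for the
  explicit endothelial source terms, and total mass is conserved to
  rounding (relative drift < 10⁻¹⁰ over 10³ steps). Taxis face
  concentrations use the arithmetic mean; face velocities are
  `coeff·ΔA/h`.
- **Outer boundary.** Zero flux at the EEM ("no mass transport at the outer
  boundary"). A Dirichlet variant (rim cells pinned to initial values) is
  available via `SolverConfig(outer_bc="dirichlet")` for comparison, since
  the two readings of the outer condition are not equivalent.
- **Time stepping.** Forward Euler, all species simultaneously.
  `dt = safety·h²/(4·D_max)` with safety 0.9; during a run the step shrinks
  (and recovers) adaptively so the advective CFL bound `dt ≤ h/(2·v_max)`
  holds against the current maximum taxis face velocity; a step that would
  violate it is discarded and retried, which keeps the scheme deterministic.
- **Positivity.** Negative values are clipped to zero and counted;
  `Trajectory.diagnostics` reports the clip count, clipped mass, and the
  most negative pre-clip value. At the standard 100 × 100 resolution the
  default dynamics produce no clipping at all over 36 months; at the demo's
  coarse 60 × 60 resolution sharp fronts clip small amounts
  (≲ 0.04 nondimensional units per cell), which is logged, not hidden.
- **Snapshots.** The physical-to-simulated mapping is one nondimensional
  time unit per month; monthly snapshots record per-species spatial means,
  apoptotic NC area, and plaque burden. A 36-month run is ~1600 steps at
  100 × 100 (~5 s) and ~6400 steps at 200 × 200.
- **Wall thickness.** Equiangular ray casting (default 360 rays) from the
  lumen centroid, quarter-cell sampling, boundary crossings at sample
  midpoints. Each thickness extremum carries up to one cell of pixelation
  error, so the eccentricity index of a discrete concentric annulus is zero
  only up to `2h/WT_min` (≈ 0.05 at the default resolution).

## Necrotic core bookkeeping

The apoptotic area at time t is `h²·#{intima cells with S < 0.5·S_initial}`
(strict inequality: a cell at exactly half its initial value is not yet
necrotic). The baseline core area N₀ is an input carried on the patient
record (in practice it comes from the baseline image); the simulated core is
`N(t) = N₀ + apoptotic area(t)`, so the growth rate `N(t)/N₀` is exactly 1
at baseline. When a record carries no measured N₀ a default of 5 % of the
intima area is used.

## Calibration and scoring conventions

- The candidate grid is the full 3 × 3 cross of inflammation × microvessel
  levels; the argmin of the absolute NC-growth residual wins and exact ties
  go to the milder pair (smaller level-index sum, then lower inflammation).
- WSS is held at its baseline value throughout (its follow-up change is
  small and is neglected).
- Severity grading splits each factor's min–max range into equal thirds;
  the worst third (per factor direction) scores 3, values exactly on a cut
  take the milder grade, and an all-equal factor scores 2 for everyone.
  This reproduces the reference LDL and WSS grade columns exactly. It is a
  *comparative* scale: grades are only meaningful within a cohort. One known
  edge: an HDL of 31 mg/dL in the reference panel grades 2 under this rule
  though the published table lists 1; no single threshold rule consistent
  with the other columns reproduces that entry, so the discrepancy is
  documented rather than special-cased.
- The stable/vulnerable cut is a total of 18, the midpoint of the observed
  15/20 totals; only totals of 20 were labelled vulnerable in the reference
  cohort, and no explicit cutoff was published.
- Group t-tests pool each factor's monthly spatial means across the members
  of a group (Welch, significance at 0.01); Spearman correlations pair a
  factor's series with the NC area series within a group. The sampling
  scheme behind the published group comparisons is unstated; monthly means
  are this package's choice.

## Synthetic cohort

The generator emulates the *shape* of a follow-up imaging study, not any
real patient: eccentric annular geometries (lumen radius 400–600 µm, intima
350–500 µm base thickness with 100–250 µm cosine eccentricity, 280 µm
media), lipid panels and shear bracketing the clinically reported ranges
(LDL 70–160 mg/dL, HDL 19–38 mg/dL, WSS 77–141 dyn/cm²), with stable-like
patients drawn from the benign half of each bracket and unstable-like
patients from the adverse half. Follow-up intervals default to 11–13 months
— under the default parameterization the NC-growth signal used for
calibration only becomes informative roughly ten months after baseline, so
shorter intervals would calibrate on noise. "Observed" follow-up growth is
produced by simulating the hidden truth levels and optionally perturbing the
result with a seed-controlled multiplicative Gaussian.

What passing the cohort tests does *not* show: the generator produces ideal
smooth geometries, exact level-set truths, and noise-free (or Gaussian)
observations; real VH-IVUS frames carry segmentation error, co-registration
error between time points, calcification (not modelled), and
between-patient parameter variability far beyond the level grid. Cohort
results validate the pipeline's mechanics and orderings, not clinical
accuracy.

## Known limitations

- Geometry is static: the lumen and EEM do not remodel, so plaque burden is
  constant along a trajectory and growth appears only in the NC metrics.
- EC mass is transported but not produced: angiogenesis enters as migration
  of a fixed vessel pool plus density-scaled leakiness, not sprouting.
- No calcification, no M1/M2 macrophage phenotypes, no 3D or
  fluid–structure coupling (WSS is a scalar patient input).
- Quantitative reproduction of any specific patient is out of scope; most
  rate constants are unpublished and the defaults here are chosen for
  qualitative fidelity and testability.
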
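# Methods

## The model

`invadosim` simulates the protease chemistry at the tip of an invadopodium
with deterministic mass-action kinetics. Three players interact:

* **MT1-MMP** (`M14`), a transmembrane collagenase delivered to the
  invadopodial membrane by vesicular trafficking;
* **TIMP-2** (`T2`), its soluble inhibitor, which doubles as the adaptor
  that docks the zymogen onto the membrane;
* **(pro)MMP-2** (`M2` / `M2act`), a soluble gelatinase activated at the
  membrane.

MT1-MMP monomers dimerise through the hemopexin domain; TIMP-2 binds any
free catalytic site; pro-MMP-2 docks onto membrane-bound TIMP-2. In the
quaternary complex `M14.M14.T2.M2` the TIMP-free partner processes the
zymogen and releases active MMP-2, which is itself inhibited by TIMP-2 in
solution. The enumeration closes over all monomer/dimer arm combinations
(14 species in the single-pool core network) and is emitted as a reviewable
reaction table; a hand-curated table can be swapped in.

ECM-degradation-competent ("M14a") forms are the free monomer, the free
dimer (two catalytic sites, weight 2) and the two single-TIMP dimer forms
(weight 1 each):

    M14a = [M14] + 2[M14.M14] + [M14.M14.T2] + [M14.M14.T2.M2]

Degradation uses explicit enzyme–substrate complexes,
`E + ECM ⇌ E·ECM → E`, for the four M14a forms and for active MMP-2, so
the engaged pool `M14a·ECM` — whose time integral is proportional to the
amount of matrix degraded — is itself an observable. While ECM-engaged, a
complex binds no additional TIMP-2 and undergoes no other complexation;
internalising an engaged complex returns its ECM unit to the matrix.

## Membrane turnover

Two kinetically distinct docking pools carry the ~100 nM surface
expression: pool X (time constant 259 s, capacity `M_F0 = 30 nM`) and pool
D (26.0 s, 70 nM). Continuous delivery inserts free enzyme at
`k_ins · M_F`, where `M_F = M_F0 − occupied` counts free docking sites
(a complex occupies sites equal to its MT1-MMP monomer count);
internalisation removes every membrane species at `k_int`, without
recycling its cargo. Both rate constants default to the reciprocal
turnover time constant.

Pulsatile delivery replaces the continuous source with vesicle events at

    t_int0 = PH / (k_ins · M_F0)

(25.9 s and 2.6 s for single-vesicle amounts `PH` of 10% of capacity, i.e.
3 and 7 nM). A pulse docks `min(PH, M_F0) · M_F / M_F0`: delivery scales
with free sites, making the regular train's time-averaged delivery exactly
the continuous model's `k_ins · M_F` at every occupancy, and saturating —
all free sites fill — for vesicles larger than the pool capacity. This
scaling, rather than a hard `min(PH, M_F)` clamp, is what lets regular
pulsatile and continuous insertion produce identical steady levels and
near-identical degradation curves, and it is the origin of the
low-frequency/high-concentration advantage in the fixed-time-average
sweep. Random schedules draw exponential intervals (mean `t_int0`) or
uniform amounts on `[0, 2·PH]`, seeded.

Initial conditions: continuous-turnover runs start with both pools fully
docked with free enzyme (the surface expression present at t = 0, which
carries the activity transient); pulsatile runs start on an empty membrane
with the schedule's first vesicle at t = 0. In well-mixed turnover models
solution TIMP-2 and pro-MMP-2 are clamped reservoirs standing in for the
large extracellular volume; the closed no-turnover model and the spatial
model use finite baths.

## Transient elimination

To isolate the role of the sharp activity transient that follows every
insertion, the elimination mode apportions newly delivered enzyme across a
pool's complexes in steady-state proportions instead of delivering it
TIMP-free. The proportions must be the *eliminated* model's own steady
state — otherwise the distributed state still relaxes and a residual
transient remains — so they are computed by fixed-point iteration
(typically 3–6 rounds of steady-state runs, fraction tolerance 1e-3),
starting from the normal-insertion fractions. The run then starts at that
steady state, making every complex flat from t = 0. TIMP-2 and pro-MMP-2
contained in inserted complexes are drawn from the bulk solution species.
Fractions are always computed on the ECM-free network; in degradation runs
the engaged complexes receive no direct insertion.

## Spatial model

The extracellular space is a closed 5 × 5 × 3 µm cuboid divided into
51 × 51 × 1 compartments (one z-division, so diffusion is effectively
two-dimensional; compartment size ≈ 0.098 µm). The invadopodium is the 49
lattice cells nearest the centre — a disc ≈ 0.8–0.9 µm across — and only
there are membrane chemistry and pool turnover embedded; MMP-2-mediated
degradation, TIMP-2 inhibition and zymogen pre-assembly act everywhere.
ECM fills all compartments. Pro-MMP-2, active MMP-2, TIMP-2 and the
TIMP-2·MMP-2 inhibition complex diffuse (default D = 2×10⁻¹¹ m²/s, the
upper end of the studied 10⁻¹⁹–10⁻¹¹ range) with zero-flux boundaries.

Each step is operator-split: RK4 chemistry per compartment (the full
network in mask cells, solution-only chemistry elsewhere), then explicit
five-point finite-difference diffusion, automatically sub-stepped below
the stability bound `h²/(2·d·D)`. The diffusion operator conserves mass to
round-off with closed boundaries. Membrane quantities are expressed as
concentrations within mask-compartment volumes; no separate surface-
density unit system is used. A five-invadopodia variant places four
additional disjoint discs diagonally.

## Parameters

All concentrations are nM, times s, bimolecular rate constants 1/(nM·s).
The supplementary parameter tables of the source study are not available
as text, so the defaults reconstruct the published
MT1-MMP/TIMP-2/MMP-2 model lineage and the study's printed anchors:

| constant | default | meaning |
|---|---|---|
| `k_on_t2` / `k_off_t2` | 2.74e-3 / 2e-4 | TIMP-2 ↔ MT1-MMP catalytic site (2.74×10⁶ /M/s) |
| `k_on_m2` / `k_off_m2` | 1.4e-4 / 4.7e-3 | pro-MMP-2 docking onto bound TIMP-2 |
| `k_on_dim` / `k_off_dim` | 1e-3 / 1e-2 | hemopexin-domain dimerisation (Kd 10 nM) |
| `k_act` | 2e-2 | zymogen processing in the quaternary complex |
| `k_on_t2_m2act` / `k_off_t2_m2act` | 5.9e-3 / 2e-4 | TIMP-2 inhibition of active MMP-2 |
| `k_on_ecm_*` / `k_off_ecm_*` / `k_cat_*` | 1e-2 / 1e-2 / 0.1 | ECM engagement and cleavage, both enzyme classes |
| `k_shed` | 1e-4 | ectodomain shedding (variant) |
| `M14_0, T2_0, M2_0` | 100, 100, 100 | initial concentrations |
| `ECM_0` | 2000 | dense-matrix substrate density |

The ECM block deserves comment: the study's regime requires matrix capture
of fresh enzyme (`k_on_ecm · ECM_0` ≈ 20/s) to outpace TIMP-2 inhibition
(`k_on_t2 · T2` ≲ 1.4/s), which is what makes the few-second activity
transient disproportionately productive and keeps the half-degradation
time only mildly TIMP-2-dependent when the transient is present. `ECM_0`
and `k_on_ecm` were set once to place the model in that regime with a
half-degradation time of order 100–200 s at zero TIMP-2; they were not
adjusted afterwards. With tight TIMP-2 binding, the steady-state activity
titration collapses stoichiometrically at TIMP-2 ≈ total enzyme
(80–120 nM), independent of these choices.

Every constant is exposed in the YAML config (`invadosim.config`).

## Numerics

* Integrator: classic fixed-step RK4, compiled with numba. Default
  dt = 1e-3 s for the stiff initial transient in direct calls; the bundled
  experiments use dt = 0.01–0.02 s (fastest local rates ≈ 20/s), with
  self-convergence checked in the test suite (halving dt changes
  trajectories by < 1e-6 relative). Very long half-degradation searches
  coarsen dt up to 0.02 s. An adaptive-step LSODA integration of the same
  vector field serves as an independent oracle in the tests, never in the
  shipped path.
* Steady-state detection: total variation of the observable over a
  trailing 500 s window below 1e-4 relative; a trajectory that never
  satisfies this reports not-converged explicitly.
* Pulses are instantaneous state jumps on an event-aligned grid, not stiff
  source terms.
* `tau_H` (time to half ECM) and the transient half-width interpolate
  linearly between output samples; output strides keep the interpolation
  error below 0.1 s. Enzyme-bound ECM counts as not yet degraded.
* Negative concentrations beyond 1e-3 nM (or non-finite values) abort the
  run with the offending species and time; smaller undershoots are clamped
  to zero on output.

## What the bundled experiments do and do not show

The experiment presets regenerate the study's analyses under the
reconstructed constants: the sub-5-s activity transient peaked at
TIMP-2 = 100 nM, the stoichiometric collapse of steady activity at
80–120 nM, the inactive-complex deletion ladder, turnover-rate scaling
(compared on activity normalised to its TIMP-2 = 0 level within each
variant), the ≥100-fold slow-down of degradation when the transient is
eliminated, tight tau_H ensembles under random schedules (CV well below
15%), the flat-then-changing fixed-time-average frequency/concentration
sweep, and the spatial conclusions (degradation at the invadopodium
requires the transient; continuous and pulsatile insertion are
near-identical; the transient persists across six orders of magnitude of
TIMP-2 diffusivity).

Because the original rate tables are unavailable, absolute times
(e.g. ensemble tau_H means) match the published values only in order of
magnitude and ordering, not digit-for-digit. Two published behaviours are
not reproduced under the reconstruction and are documented as such: the
tau_H *decrease* at the most extreme low-frequency folds (here delivery
saturation makes it rise beyond fold ≈ 0.02), and the *large* magnitude of
the spatial TIMP-2 gradient (a depression over the invadopodium forms and
grows, but stays at the percent level because ECM-engaged enzyme binds no
TIMP-2). The synthetic experiments also idealise real invadopodia: no
membrane geometry or vesicle docking sites, no ECM mechanics or fibre
structure, deterministic chemistry (stochastic only in insertion times and
amounts), and a rigid 49-compartment invadopodium.
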
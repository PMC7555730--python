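# Methods

## Model structure

The circulation is a closed convective loop of uniform, well-stirred pools:

    lung gas (L) → pulmonary vein (PV) → left ventricle (LV) → systemic
    artery (SA) → tissue (T) → systemic vein (SV) → right ventricle (RV) →
    pulmonary artery (PA) → lung

The state is the anaesthetic partial pressure of each pool (mmHg); the fixed
state ordering is (L, PV, LV, SA, T, SV, RV, PA).  Assumptions: every pool is
well stirred; no diffusion limitation at lung or tissue; no spatial or
temporal ventilation–perfusion mismatch; no heterogeneity of tissue
perfusion; lung gas fully saturated with water; the lung is the only exchange
route with the environment (no metabolism or transcutaneous loss); gas
capacitance constant within a simulation.  Blood leaving the lung carries the
lung gas partial pressure; blood leaving tissue carries the tissue partial
pressure.  The lung and tissue capillary beds (0.1–0.15 mL) are lumped into
their host compartments — without diffusion limitation they are isobaric with
the host, and keeping them as separate states would only add stiffness with
no observable effect at these volumes.

The tissue is a single lumped compartment: its capacitance is a
whole-body-weighted average, so predictions concern mixed tissue, not
individual organs.  Arterial blood is used as the proxy for the central
nervous system (a low-mass, highly perfused organ), which makes the
equilibration times conservative.

## Parameters and units

* Capacitance coefficients β (mL_STPD·mL⁻¹·mmHg⁻¹).  Gas phase:
  β_g = (133.322 Pa/mmHg)/(R·T_K) converted with the STPD molar volume
  22 414 mL·mol⁻¹ — 1.159·10⁻³ at 37 °C (51.7 µmol·L⁻¹·mmHg⁻¹ molar form).
  Agents (37 °C): halothane β_b 0.00278, β_T 0.0099; isoflurane β_b 0.001528,
  β_T 0.00461; sevoflurane β_b 0.00074, β_T 0.0025.  The implied blood-gas
  partition coefficients (2.40, 1.32, 0.64) reproduce the standard solubility
  ordering.  Temperature dependence of solubility is not modelled; all
  packaged scenarios use 37 °C coefficients so that convective effects are
  isolated from solvation effects.
* Flows and ventilation in mL·min⁻¹ for the 1-kg reference animal; volumes in
  mL; time in minutes; pressures in mmHg.
* Effective capacities: C_L = L·β_g + V_CL·β_b; C_T = V_T·β_T + V_CT·β_b;
  C_i = V_i·β_b for pure blood pools.

### Ventilation convention (STPD)

Minute ventilation values are physiological (body-conditions, BTPS) volumes.
Because all gas amounts in the mass balance are expressed in mL STPD, the
ventilation entering the gas transport term is converted to its
STPD-equivalent flow: V̇_STPD = V̇·(273.15/T_K)·((P_B − P_H₂O)/P_B) ≈ 0.826·V̇
at 37 °C (saturated water vapour from the Buck equation, ≈47 mmHg).  This
convention — ventilation and capacitance in the same STPD gas units — is what
reproduces the published comparative equilibration times; using the raw BTPS
ventilation gives arterial t90s ~17–20 % shorter on the mammal/reptile
presets.  The conversion can be disabled per-system
(`assemble_system(..., ventilation_stpd=False)`) for sensitivity analyses.

## Shunts and flow conventions

`ShuntSpec(s_RL, s_LR, mode)`: s_RL is the fraction of systemic venous return
bypassing the lungs into the systemic artery; s_LR the fraction of pulmonary
venous return recirculating to the lungs; both may be nonzero
(bidirectional).  The ventricular-node balances force
Q̇_pul = Q̇_sys·(1−s_RL)/(1−s_LR); the mode fixes the remaining degree of
freedom:

* `reciprocal` (default): total ventricular output is conserved,
  Q̇_sys + Q̇_pul = 2·Q̇_tot — reduced pulmonary flow is compensated by a
  reciprocal rise in systemic flow.
* `maintained_systemic`: Q̇_sys = Q̇_tot while pulmonary flow falls, so total
  output is reduced — the situation described for chelonians.  At equal
  inputs this mode has strictly lower pulmonary flow and slower uptake than
  `reciprocal`.

Shunt severity axis.  The reptilian shunt scenarios express severity as the
fractional reduction of pulmonary flow p ("a shunt of 0.5" = half of the
blood bypasses the pulmonary circulation): Q̇_pul = (1−p)·Q̇_tot,
Q̇_sys = (1+p)·Q̇_tot under the reciprocal convention, which corresponds to
s_RL = 2p/(1+p) (`flows.pulmonary_bypass_to_srl`; 0.5 → 2/3, 0.9 → 0.947).
This parameterization, not the raw s_RL, is the one under which the packaged
shunt results hold: halving pulmonary flow lengthens the isoflurane arterial
t90 by ~57 % (>50 %), and the sevoflurane/isoflurane crossover falls at
p ≈ 0.86, inside the 0–0.9 severity range swept by `fig5c_sweep`.  At the
literal s_RL = 0.5 (reciprocal) the lengthening is only ~31 %.

A documented shortfall: with maintained systemic flow at p = 0.5 the model
lengthens the arterial t90 by ~1.5× the no-shunt value — slower than the
reciprocal convention, as expected, but short of the "more than double"
sometimes quoted for this condition; no plausible flow algebra tested
(systemic-return-fraction, pulmonary-fraction, or total-output-conserving)
brings the ratio above ~1.7.  The corresponding acceptance test is left
failing rather than weakened.

## Exposure protocols and integration

A protocol is an ordered list of (duration, inspired pressure) phases;
wash-in/washout is the two-phase special case.  Phases are integrated
separately (the inspired-pressure step never crosses a solver step) and
concatenated with state continuity.  Default solver LSODA with rtol 1e-8,
atol 1e-10 mmHg, analytic Jacobian (the system is linear); the 0.75-mL
ventricular pools against the 600-mL tissue pool make the system moderately
stiff.  Dense output on a configurable grid, default 0.01 min, which bounds
the interpolation error of crossing-time metrics well below the 0.1-min
reporting precision.  Initial condition: anaesthetic-naïve (all zero).
Everything is deterministic — no seeds anywhere.

## Equilibration metrics and reference conventions

`t90(ts, compartment, reference)` returns the first time the compartment
reaches 90 % of the reference, by monotone bracketing and linear
interpolation between samples; "not reached" is an explicit result.  Three
reference conventions are supported and always stated:

* `"inspired"` (default) — the inspired pressure of the exposure phase, the
  true long-run equilibrium of this closed system.  This convention
  reproduces the packaged mammal/reptile contrast (arterial t90 30.1 min vs
  278.8 min, a ~9.3-fold slowing) and the shunt results above.
* `"end_of_exposure"` — the compartment's own pressure when the exposure
  phase ends; useful for short clinical exposures that never approach the
  inspired pressure.
* a fixed pressure in mmHg — e.g. a clinical surgical-plane arterial
  pressure.

The rabbit three-agent scenario (`fig2a_rabbit`) documents a fixed 28-mmHg
(surgical-plane) reference: the published sub-minute equilibration times for
isoflurane and sevoflurane in this scenario cannot be produced by either the
inspired or the end-of-exposure convention (both give 8–22 min), because a
sub-minute arterial t90 requires a reference near the fast-phase plateau
V̇_g/(V̇_g+Q̇β_b)·P_I ≈ 0.64–0.79·P_I.  With the 28-mmHg reference the model
gives 11.6 / 2.3 / 0.5 min for halothane / isoflurane / sevoflurane — the
right ordering and the cliff-like gap between halothane and the newer agents,
but not the quoted 7.3 / 0.8 / 0.7 min; no convention tested reproduces all
three simultaneously, and the corresponding acceptance tests are left
failing with this analysis rather than tuned.

`crossover_shunt` scans a monotone shunt grid and bisects for the smallest
shunt at which the nominally faster (less soluble) agent is no longer faster;
the bracketing interval is refined to 0.005.

## Scenarios and sweeps

Presets (YAML, shipped in the package) pin every parameter of the standard
runs: the 1-kg rabbit (Q̇ 175, V̇ 500, L 75), the representative mammal
(300/300/75) and reptile (60/30/150), the terrapin-like slow circulation
(100/100/150 with the smaller terrapin volume set), convection comparisons,
and the shunting circulation (100/100/150).  Standard volume set (mL):
T 600, CT 0.15, CL 0.15, PV 12, PA 7.5, SA 15, SV 37.5, RV 0.75, LV 0.75;
terrapin: 400/0.1/0.1/8/5/10/25/0.5/0.5.

Sweep families regenerate the sensitivity curves: ventilation 10–1000 and
cardiac output 10–600 mL·min⁻¹ (log-spaced, default 50 points), solubility
β_b 1e-4–4e-3 holding β_T/β_b at the isoflurane ratio (3.017), and shunt
severity p 0–0.9.  Sweep rows are independent (order-invariant); integration
failures flag the row and the sweep continues; horizons extend by doubling
(cap 20 000 min) until the crossing is found.

## Problem sizes and runtimes

All packaged computations are desk-scale: an 8-state linear ODE over at most
a few thousand simulated minutes (<1 s per run).  The full test suite runs in
well under a minute; `scripts/acceptance.py` in a few seconds.  Sweep and
crossover computations in tests use a 0.02–0.05-min output grid — coarser
than the 0.01-min default but still an order of magnitude below the metric
reporting precision.

## Known limitations

* Tidal breathing, dead space, V/Q heterogeneity, diffusion limitation,
  metabolism and transcutaneous loss are all outside the model, as are
  vessel-rich and fat compartments (no lipid-sink kinetics during long
  washouts).
* Solubility is temperature-independent here; cooling an ectotherm also
  raises partition coefficients, so the packaged 37 °C predictions
  understate equilibration times at low body temperature.
* MAC enters only as an arterial pressure threshold; no pharmacodynamics.
* The percent↔mmHg helper assumes 760 mmHg dry barometric pressure;
  scenario inspired pressures are specified directly in mmHg.
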
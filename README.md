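# anaesim

Multi-compartment simulation of inhaled-anaesthetic uptake and elimination in
endotherm and ectotherm circulations, including cardiac shunts.

## The problem

Volatile anaesthetics (halothane, isoflurane, sevoflurane) reach the central
nervous system by ventilation into the lung and convection in arterial blood.
In mammals, high minute ventilation (V̇_L) and cardiac output (Q̇_tot) make
induction fast and anaesthetic depth easy to titrate.  Reptiles ventilate and
perfuse five to ten times more slowly, and their undivided ventricle allows
large right-to-left (R–L) cardiac shunts in which systemic venous blood
bypasses the lungs entirely.  Both features dramatically slow the
equilibration of anaesthetic partial pressure between inspired gas and
arterial blood — which is why anaesthetic depth in reptiles responds
sluggishly to the vaporizer and why minimum-anaesthetic-concentration (MAC)
determination is so difficult in these animals.  `anaesim` is aimed at
comparative physiologists and zoo/exotic-animal anaesthetists who want
quantitative predictions for these effects.

## The model

The circulation is a loop of well-stirred pools — lung gas (L), pulmonary
vein (PV), left ventricle (LV), systemic artery (SA), lumped tissue (T),
systemic vein (SV), right ventricle (RV), pulmonary artery (PA) — each
carrying an anaesthetic partial pressure `P_i` (mmHg).  Anaesthetic storage
is governed by capacitance coefficients β (mL_STPD·mL⁻¹·mmHg⁻¹): β_g for gas
(ideal-gas law, 51.7 µmol·L⁻¹·mmHg⁻¹ at 37 °C), β_b for blood and β_T for
tissue.  The familiar blood-gas partition coefficient is λ_b = β_b/β_g
(≈1.32 for isoflurane at 37 °C).  Mass balance for each pool is

    C_L dP_L/dt  = V̇_g (P_I − P_L) + Q̇_pul β_b (P_PA − P_L)
    C_i dP_i/dt  = Q̇ β_b (P_upstream − P_i)          (blood pools)
    C_T dP_T/dt  = Q̇_sys β_b (P_SA − P_T)            (tissue)

with C_L = L·β_g + V_CL·β_b, C_T = V_T·β_T + V_CT·β_b, C_i = V_i·β_b, and
V̇_g the ventilation conductance (minute ventilation converted to STPD flow
times β_g).  Shunts mix at the arterial nodes: a fraction s_RL of systemic
venous return enters the systemic artery directly, a fraction s_LR of
pulmonary venous return recirculates to the lungs.  The system is linear and
is integrated with a stiff-capable solver (LSODA, rtol 1e-8).  There is no
diffusion limitation, V/Q mismatch, metabolism, or transcutaneous loss: the
lung is the only route in and out.

Outcome metrics are `t90` (time for a compartment to reach 90 % of a
reference pressure — the reference convention is always explicit),
`time_to_pressure` (e.g. time to a MAC-equivalent arterial pressure), and
the shunt fraction at which a less-soluble agent loses its speed advantage
(`crossover_shunt`).  See `docs/methods.md` for conventions and assumptions.

## Worked example

```python
from anaesim import GasPhase, load_preset, t90

gas = GasPhase()                      # 37 °C, beta_g = 1.159e-3
for preset in ("fig3_mammal", "fig3_reptile"):
    ts = load_preset(preset).run("isoflurane", gas=gas)
    print(preset, round(t90(ts, "SA").time, 1))
```

prints

```
fig3_mammal 30.1
fig3_reptile 278.8
```

— a representative mammal (Q̇ 300, V̇ 300 mL·min⁻¹·kg⁻¹) reaches 90 % of the
inspired isoflurane pressure in arterial blood in ~30 min, while a
representative reptile (Q̇ 60, V̇ 30) needs ~4.6 h: a ninefold slowing from
convection alone, before any shunt.  The same comparison from the shell:

```sh
$ anaesim metrics --preset fig3_reptile
scenario,agent,metric,compartment,value
fig3_reptile,isoflurane,t90,SA,278.7948263
```

Other entry points: `anaesim presets` (list scenarios), `anaesim simulate
--preset fig1_rabbit --washout 30 --out runs/` (time-series CSVs + JSON
metadata), `anaesim sweep fig5c --out fig5c.csv` (t90 versus shunt severity
per agent), `anaesim plot --preset fig3_reptile --out reptile.png`.

Adding a shunt: halving pulmonary flow (`pulmonary bypass fraction 0.5`)
lengthens the reptilian-type preset's isoflurane arterial t90 by ~57 %, and
beyond a bypass fraction of ~0.86 sevoflurane — normally the fastest agent —
becomes slower than isoflurane, because low-solubility agents depend the most
on pulmonary blood flow.

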
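# Packaged scenario presets for the 1-kg reference animal.
# Flows/ventilation in mL min^-1, volumes mL, pressures mmHg,
# capacitance coefficients mL_STPD mL^-1 mmHg^-1.

volumes:
  standard: &standard_volumes
    {T: 600, CT: 0.15, CL: 0.15, PV: 12, PA: 7.5, SA: 15, SV: 37.5, RV: 0.75, LV: 0.75}
  terrapin: &terrapin_volumes
    {T: 400, CT: 0.1, CL: 0.1, PV: 8, PA: 5, SA: 10, SV: 25, RV: 0.5, LV: 0.5}

no_shunt: &no_shunt {s_RL: 0.0, s_LR: 0.0, mode: reciprocal}

presets:
  fig1_rabbit:
    description: >-
      Rabbit anaesthetized with isoflurane at 35 mmHg inspired for 30 min,
      followed by a 30-min washout; four-pool overview trace.
    agents: [isoflurane]
    params:
      Q_tot: 175
      V_dot_L: 500
      L: 75
      volumes: *standard_volumes
      shunt: *no_shunt
    protocol: {phases: [[30, 35], [30, 0]], output_grid: 0.01}
    metric: {compartment: SA, reference: inspired}

  fig2a_rabbit:
    description: >-
      Rabbit, 30-min anaesthesia at a 5% vaporizer setting (37.5 mmHg) with a
      30-min washout; halothane / isoflurane / sevoflurane compared.  The
      published equilibration times for this scenario are referenced to the
      surgical-plane arterial pressure (28 mmHg), not the inspired pressure
      (see docs/methods.md).
    agents: [halothane, isoflurane, sevoflurane]
    params:
      Q_tot: 175
      V_dot_L: 500
      L: 75
      volumes: *standard_volumes
      shunt: *no_shunt
    protocol: {phases: [[30, 37.5], [30, 0]], output_grid: 0.01}
    metric: {compartment: SA, reference: 28.0}

  fig2b_terrapin:
    description: >-
      Terrapin-like circulation used for the t90-versus-solubility curve;
      agents swept along a constant tissue-to-blood capacitance ratio.
    agents: [halothane, isoflurane, sevoflurane]
    params:
      Q_tot: 100
      V_dot_L: 100
      L: 150
      volumes: *terrapin_volumes
      shunt: *no_shunt
    protocol: {phases: [[600, 30]], output_grid: 0.01}
    metric: {compartment: SA, reference: inspired}

  fig3_mammal:
    description: >-
      Representative mammal (isoflurane, 30 mmHg): same tissue mass, blood
      volumes and solubilities as the reptile but mammalian convection.
    agents: [isoflurane]
    params:
      Q_tot: 300
      V_dot_L: 300
      L: 75
      volumes: *standard_volumes
      shunt: *no_shunt
    protocol: {phases: [[600, 30]], output_grid: 0.01}
    metric: {compartment: SA, reference: inspired}

  fig3_reptile:
    description: >-
      Representative reptile (isoflurane, 30 mmHg): fivefold lower cardiac
      output, tenfold lower ventilation and a doubled lung volume.
    agents: [isoflurane]
    params:
      Q_tot: 60
      V_dot_L: 30
      L: 150
      volumes: *standard_volumes
      shunt: *no_shunt
    protocol: {phases: [[600, 30]], output_grid: 0.01}
    metric: {compartment: SA, reference: inspired}

  fig4a_vent50:
    description: Typical reptilian minute ventilation (50 mL/min) at Q_tot 100.
    agents: [isoflurane]
    params:
      Q_tot: 100
      V_dot_L: 50
      L: 150
      volumes: *standard_volumes
      shunt: *no_shunt
    protocol: {phases: [[600, 30]], output_grid: 0.01}
    metric: {compartment: SA, reference: inspired}

  fig4a_vent300:
    description: Typical mammalian minute ventilation (300 mL/min) at Q_tot 100.
    agents: [isoflurane]
    params:
      Q_tot: 100
      V_dot_L: 300
      L: 150
      volumes: *standard_volumes
      shunt: *no_shunt
    protocol: {phases: [[600, 30]], output_grid: 0.01}
    metric: {compartment: SA, reference: inspired}

  fig4c_q50:
    description: Typical reptilian cardiac output (50 mL/min) at V_dot_L 100.
    agents: [isoflurane]
    params:
      Q_tot: 50
      V_dot_L: 100
      L: 150
      volumes: *standard_volumes
      shunt: *no_shunt
    protocol: {phases: [[600, 30]], output_grid: 0.01}
    metric: {compartment: SA, reference: inspired}

  fig4c_q300:
    description: Typical mammalian cardiac output (300 mL/min) at V_dot_L 100.
    agents: [isoflurane]
    params:
      Q_tot: 300
      V_dot_L: 100
      L: 150
      volumes: *standard_volumes
      shunt: *no_shunt
    protocol: {phases: [[600, 30]], output_grid: 0.01}
    metric: {compartment: SA, reference: inspired}

  fig5_shunt:
    description: >-
      Shunting reptilian-type circulation, no shunt baseline; the shunt
      severity axis of the companion sweep is the fractional reduction of
      pulmonary flow (see flows.pulmonary_bypass_to_srl).
    agents: [halothane, isoflurane, sevoflurane]
    params:
      Q_tot: 100
      V_dot_L: 100
      L: 150
      volumes: *standard_volumes
      shunt: *no_shunt
    protocol: {phases: [[600, 30]], output_grid: 0.01}
    metric: {compartment: SA, reference: inspired}

  fig5b_shunt05:
    description: >-
      As fig5_shunt with half of the blood bypassing the pulmonary
      circulation (pulmonary bypass fraction 0.5, i.e. s_RL = 2/3 under the
      reciprocal convention).
    agents: [isoflurane]
    params:
      Q_tot: 100
      V_dot_L: 100
      L: 150
      volumes: *standard_volumes
      shunt: {s_RL: 0.6666666666666666, s_LR: 0.0, mode: reciprocal}
    protocol: {phases: [[600, 30]], output_grid: 0.01}
    metric: {compartment: SA, reference: inspired}
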
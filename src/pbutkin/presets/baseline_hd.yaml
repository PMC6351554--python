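# Baseline single-session high-flux hemodialysis scenario.
# Every value is annotated with what it represents physically; the modality
# variants (HDF, adsorption, displacer) override only the prescription block.

patient:
  V_pl_L: 3.5            # initial plasma volume of an anuric HD patient
  V_is_L: 12.0           # interstitial fluid volume
  V_ic_L: 28.0           # intracellular toxin distribution volume (constant)
  hematocrit: 0.35       # sets plasma flow Q_pi = Q_b * (1 - Hct)
  K_ip_mL_min: 1135.0    # plasma <-> interstitial free-solute transfer
  K_ic_mL_min: 100.0     # interstitial <-> intracellular free-solute transfer
  albumin_pl_uM: 600.0   # total plasma albumin, ~4 g/dL
  albumin_is_uM: 300.0   # interstitial albumin, 50% of plasma concentration

solutes:
  - name: IS             # indoxyl sulfate, prototype Sudlow-II-bound toxin
    total_uM: 100.0      # pre-dialysis total plasma concentration (21.3 mg/L)
    free_fraction: 0.07  # 93% albumin-bound
    mol_weight: 213.21   # g/mol (acid form)
    generation_mg_min: 0.02477   # constant endogenous generation
  - name: pCS            # p-cresyl sulfate, more strongly bound
    total_uM: 150.0      # pre-dialysis total (28.2 mg/L)
    free_fraction: 0.05  # 95% bound
    mol_weight: 188.20   # g/mol
    generation_mg_min: 0.02557   # constant endogenous generation

dialyzer:
  n_fibers: 12300                    # F180NR-class 1.8 m^2 high-flux unit
  fiber_inner_radius_um: 105.0       # hollow-fiber lumen radius
  fiber_wall_um: 35.0                # membrane wall thickness
  fiber_length_m: 0.23               # effective fiber length
  blood_area_per_fiber_m2: 3.5e-8    # fiber lumen cross-section
  dialysate_area_per_fiber_m2: 4.1e-8  # annular space around one fiber
  housing_diameter_m: 0.04             # dialyzer casing
  KoA_mL_min: 600.0                  # membrane coefficient, solutes < 500 Da
  sigma_large: 0.999                 # albumin/complex reflection coefficient

tube:
  length_m: 0.5          # infusion site to dialyzer inlet
  area_m2: 1.81e-5       # 4.8 mm inner-diameter adult bloodline

prescription:
  modality: hd           # conventional hemodialysis (variants override)
  Q_b_mL_min: 300.0      # blood flow
  Q_di_mL_min: 800.0     # dialysate flow
  uf_volume_L: 2.4       # net fluid removal over the session
  duration_min: 240.0    # 4-hour session
  replacement_volume_L: 0.0  # HDF replacement fluid (unused in HD)

numerics:
  nx: 100                # dialyzer axial nodes
  nt: 20                 # tube segment nodes
  rtol: 1.0e-6           # integrator relative tolerance
  atol: 1.0e-12          # absolute tolerance on molar concentrations
  t_eval_step_min: 2.0   # output sampling interval
  seed: 0                # recorded for provenance; the model is deterministic

schedule:
  n_days: 28             # integer weeks for the periodic steady-state readout
  week_pattern: [0, 2, 4]  # thrice weekly, 2-2-3 day spacing
  intake_per_interval_L: null  # default: equals uf_volume_L (periodic fluid balance)

output:
  out_dir: out           # default output directory for CSV writers
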
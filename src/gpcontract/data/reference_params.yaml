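# Reference calibration produced by scripts/make_reference.py
# seed chain starting at 61 objective=7.596653
parameters:
  population: 10000000.0
  mobilization_rate: 0.03310734221703226
  wom_base_coefficient: 0.005681990330084055
  base_attractiveness: 1.0
  w_hcs: 4.326967926200557
  w_wdp: 4.863876924831798
  w_hec: 4.925755584609068
  gamma_min: 1.0
  drive_base: 1.0
  w_et: 0.20205416088963135
  w_jtp: 0.20620470256614026
  ii_lookup:
    x:
    - 150000.0
    - 206023.4268175646
    - 206031.1070061038
    - 214840.6902916896
    - 250804.82247532142
    y:
    - 0.09558768439143202
    - 0.09558768439143202
    - 0.6922538074976307
    - 0.6922538074976307
    - 0.6922538074976307
  idr_gp_weight: 0.5010000221297429
  reference_idr: 0.5
  delta_scale: 1.414213562373095
  panel_size: 800.0
  gp_adjust_time: 2.323227335762311
  contract_fee: 120.0
  gp_floor: 50.0
  base_income: 150000.0
  initial_contract_rate: 0.029908796024707397
  intervention_start_year: 2020.0
  supply_start_year: null
  year_start: 2015.0
  year_end: 2030.0
  dt: 0.08333333333333333
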
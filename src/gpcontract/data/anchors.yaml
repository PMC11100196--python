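# Published 2030 scenario outcomes used as calibration anchors.
# Levels are contract rates in percent; entries with a reference_scenario
# are differences in percentage points. Tolerances are the reproduction
# tolerances enforced by `gpcontract reproduce` and the test suite:
# 0.5 pp for exactly printed values, wider where the source says
# "approximately"/"around" (wdp_et ~48, mixed1-3 ~54, hcs ~2 pp below
# WDP/HEC, mixed4-6 within 58-68).
#
# Sources (2030 readouts): with/without the GP service package 57.8 / 42.3
# (+15.4 pp); WDP+ET and WDP+JTP ~48; WDP+II +10 pp over baseline; best
# HEC/HCS single-incentive combination ~52.5; all-incentives + one content
# ~54 (mixed 1-3); all-contents + one incentive 58-68 (mixed 4-6); all six
# factors +33.1 pp (mixed 7); IDR grid maximum 75.2 at 0.5, with 0.7 close
# behind 0.5 and 9 pp ahead of 0.3.
anchors:
  - {name: baseline_2030, scenario: baseline, year: 2030, target: 42.3, weight: 12}
  - {name: gpsp_2030, scenario: gpsp, year: 2030, target: 57.8, weight: 4}
  - {name: wdp_et_2030, scenario: wdp_et, year: 2030, target: 48.3, weight: 1.5}
  - {name: wdp_jtp_2030, scenario: wdp_jtp, year: 2030, target: 48.3, weight: 1.5}
  - {name: wdp_ii_gain, scenario: wdp_ii, year: 2030, target: 10.0,
     reference_scenario: baseline, weight: 5}
  - {name: hec_ii_2030, scenario: hec_ii, year: 2030, target: 52.5, weight: 3}
  - {name: hcs_ii_2030, scenario: hcs_ii, year: 2030, target: 50.4,
     tolerance: 0.75, weight: 1}
  - {name: mixed1_2030, scenario: mixed1, year: 2030, target: 54.0,
     tolerance: 1.0, weight: 1.0}
  - {name: mixed2_2030, scenario: mixed2, year: 2030, target: 54.0,
     tolerance: 1.0, weight: 1.5}
  - {name: mixed3_2030, scenario: mixed3, year: 2030, target: 54.0,
     tolerance: 1.0, weight: 1.0}
  - {name: mixed4_2030, scenario: mixed4, year: 2030, target: 58.0,
     cmp: ge, weight: 1.5}
  - {name: mixed5_2030, scenario: mixed5, year: 2030, target: 58.0,
     cmp: ge, weight: 1.5}
  - {name: mixed6_2030, scenario: mixed6, year: 2030, target: 68.0,
     cmp: le, tolerance: 1.0, weight: 1.5}
  - {name: mixed7_gain, scenario: mixed7, year: 2030, target: 33.1,
     reference_scenario: baseline, weight: 4}
  - {name: idr_05_2030, scenario: mixed7, year: 2030, target: 75.2,
     idr: 0.5, weight: 4}
  - {name: idr_07_minus_03, scenario: mixed7, year: 2030, target: 9.0,
     idr: 0.7, reference_scenario: mixed7, reference_idr: 0.3, weight: 3}
  - {name: idr_05_minus_07, scenario: mixed7, year: 2030, target: 2.0,
     idr: 0.5, reference_scenario: mixed7, reference_idr: 0.7, weight: 1}
  - {name: idr_05_above_07, scenario: mixed7, year: 2030, target: 0.3,
     cmp: ge, idr: 0.5, reference_scenario: mixed7, reference_idr: 0.7,
     weight: 6}
  - {name: idr_09_below_05, scenario: mixed7, year: 2030, target: -2.0,
     cmp: le, idr: 0.9, reference_scenario: mixed7, reference_idr: 0.5,
     weight: 1}
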
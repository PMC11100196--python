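{
  "seed": 61,
  "objective": 7.59665272261182,
  "feasible": false,
  "n_evaluations": 4519,
  "free_parameters": [
    "mobilization_rate",
    "wom_base_coefficient",
    "initial_contract_rate",
    "w_wdp",
    "w_hec",
    "w_hcs",
    "w_et",
    "w_jtp",
    "ii_y0",
    "ii_y1",
    "ii_y2",
    "ii_y3",
    "ii_y4",
    "ii_x1",
    "ii_x2",
    "ii_x3",
    "ii_x4",
    "idr_gp_weight",
    "gp_adjust_time"
  ],
  "residuals": [
    {
      "anchor": "baseline_2030",
      "scenario": "baseline",
      "cmp": "eq",
      "target": 42.3,
      "value": 42.197541885058136,
      "residual": -0.10245811494186086,
      "tolerance": 0.5,
      "weight": 12.0,
      "within": true
    },
    {
      "anchor": "gpsp_2030",
      "scenario": "gpsp",
      "cmp": "eq",
      "target": 57.8,
      "value": 57.657181003298746,
      "residual": -0.14281899670125142,
      "tolerance": 0.5,
      "weight": 4.0,
      "within": true
    },
    {
      "anchor": "wdp_et_2030",
      "scenario": "wdp_et",
      "cmp": "eq",
      "target": 48.3,
      "value": 48.63501777661589,
      "residual": 0.33501777661589216,
      "tolerance": 0.5,
      "weight": 1.5,
      "within": true
    },
    {
      "anchor": "wdp_jtp_2030",
      "scenario": "wdp_jtp",
      "cmp": "eq",
      "target": 48.3,
      "value": 48.6617154682667,
      "residual": 0.3617154682667021,
      "tolerance": 0.5,
      "weight": 1.5,
      "within": true
    },
    {
      "anchor": "wdp_ii_gain",
      "scenario": "wdp_ii",
      "cmp": "eq",
      "target": 10.0,
      "value": 9.62122214953451,
      "residual": -0.3787778504654895,
      "tolerance": 0.5,
      "weight": 5.0,
      "within": true
    },
    {
      "anchor": "hec_ii_2030",
      "scenario": "hec_ii",
      "cmp": "eq",
      "target": 52.5,
      "value": 51.9357249159223,
      "residual": -0.5642750840776998,
      "tolerance": 0.5,
      "weight": 3.0,
      "within": false
    },
    {
      "anchor": "hcs_ii_2030",
      "scenario": "hcs_ii",
      "cmp": "eq",
      "target": 50.4,
      "value": 50.73130036202224,
      "residual": 0.33130036202224034,
      "tolerance": 0.75,
      "weight": 1.0,
      "within": true
    },
    {
      "anchor": "mixed1_2030",
      "scenario": "mixed1",
      "cmp": "eq",
      "target": 54.0,
      "value": 54.50388070597633,
      "residual": 0.5038807059763286,
      "tolerance": 1.0,
      "weight": 1.0,
      "within": true
    },
    {
      "anchor": "mixed2_2030",
      "scenario": "mixed2",
      "cmp": "eq",
      "target": 54.0,
      "value": 54.65016036893464,
      "residual": 0.6501603689346425,
      "tolerance": 1.0,
      "weight": 1.5,
      "within": true
    },
    {
      "anchor": "mixed3_2030",
      "scenario": "mixed3",
      "cmp": "eq",
      "target": 54.0,
      "value": 53.23639403518342,
      "residual": -0.7636059648165769,
      "tolerance": 1.0,
      "weight": 1.0,
      "within": true
    },
    {
      "anchor": "mixed4_2030",
      "scenario": "mixed4",
      "cmp": "ge",
      "target": 58.0,
      "value": 61.08111966863062,
      "residual": 0.0,
      "tolerance": 0.5,
      "weight": 1.5,
      "within": true
    },
    {
      "anchor": "mixed5_2030",
      "scenario": "mixed5",
      "cmp": "ge",
      "target": 58.0,
      "value": 61.15101271880301,
      "residual": 0.0,
      "tolerance": 0.5,
      "weight": 1.5,
      "within": true
    },
    {
      "anchor": "mixed6_2030",
      "scenario": "mixed6",
      "cmp": "le",
      "target": 68.0,
      "value": 69.09061022760399,
      "residual": 1.0906102276039888,
      "tolerance": 1.0,
      "weight": 1.5,
      "within": false
    },
    {
      "anchor": "mixed7_gain",
      "scenario": "mixed7",
      "cmp": "eq",
      "target": 33.1,
      "value": 32.97397164497786,
      "residual": -0.12602835502214305,
      "tolerance": 0.5,
      "weight": 4.0,
      "within": true
    },
    {
      "anchor": "idr_05_2030",
      "scenario": "mixed7",
      "cmp": "eq",
      "target": 75.2,
      "value": 75.171513530036,
      "residual": -0.028486469964008165,
      "tolerance": 0.5,
      "weight": 4.0,
      "within": true
    },
    {
      "anchor": "idr_07_minus_03",
      "scenario": "mixed7",
      "cmp": "eq",
      "target": 9.0,
      "value": 9.00091873927687,
      "residual": 0.0009187392768694735,
      "tolerance": 0.5,
      "weight": 3.0,
      "within": true
    },
    {
      "anchor": "idr_05_minus_07",
      "scenario": "mixed7",
      "cmp": "eq",
      "target": 2.0,
      "value": 0.6143026236741633,
      "residual": -1.3856973763258367,
      "tolerance": 0.5,
      "weight": 1.0,
      "within": false
    },
    {
      "anchor": "idr_05_above_07",
      "scenario": "mixed7",
      "cmp": "ge",
      "target": 0.3,
      "value": 0.6143026236741633,
      "residual": 0.0,
      "tolerance": 0.5,
      "weight": 6.0,
      "within": true
    },
    {
      "anchor": "idr_09_below_05",
      "scenario": "mixed7",
      "cmp": "le",
      "target": -2.0,
      "value": -3.192450292653902,
      "residual": 0.0,
      "tolerance": 0.5,
      "weight": 1.0,
      "within": true
    }
  ]
}
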
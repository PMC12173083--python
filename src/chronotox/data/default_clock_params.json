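{
 "calibration": {
  "seed": 11,
  "n_random": 1200,
  "n_refine": 300,
  "bounds_decades": 0.4,
  "period_h": 23.99999295873864,
  "rel_amplitude_bmal1": 0.8874102165530721,
  "rel_amplitude_per2": 0.3379821482942633,
  "phase_gap_h": 11.452641543868983
 },
 "parameters": {
  "V1max": 1.9397812409626443,
  "V5max": 0.4274966737395943,
  "a": 2.819113301105851,
  "i": 5.920490619923242,
  "dy1": 1.5324840424325494,
  "dy5": 0.2017599456076164,
  "kt1": 0.8720369085296382,
  "ki1": 1.817531209693129,
  "kt5": 1.2690608486029633,
  "ki5": 7.175931125021812,
  "dx1": 0.02332859745958221,
  "dx2": 0.12963630699261938,
  "dx5": 0.28339292389768544,
  "dx6": 1.1616312937160411,
  "kiz9": 0.1324920908150096,
  "kex1": 0.02632313765890016,
  "kiz4": 3.224210580589059,
  "kex2": 0.0901558952604305,
  "kiz6": 0.17029941019467196,
  "kiz7": 0.4553149314138299,
  "h_exp": 6.0,
  "phi_protein": 20.0,
  "phi_apop": 14.0,
  "k_import": 0.4,
  "k_act": 0.5,
  "k_clear": 0.15,
  "k_damage": 0.5,
  "r_repair0": 0.25,
  "rho_repair": 0.8,
  "k_apop0": 0.05,
  "alpha_apop": 0.8
 }
}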
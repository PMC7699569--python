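{
  "_comment": "Per-variable moments of the emulated 14-country x 23-year European panel (1995-2017). The HEALTH row is corrected from the published summary table, whose printed mean 64.149 / sd 10.745 / variance 11.546 are mutually inconsistent with its coefficient of variation 16.75 and range 5.2; mean 6.4149 and sd 1.0745 restore consistency (variance 1.1546).",
  "n_countries": 14,
  "n_years": 23,
  "start_year": 1995,
  "persistence": 0.8,
  "variables": {
    "LEAB":   {"mean": 79.74,  "sd": 1.845,  "min": 75.3,   "max": 83.5},
    "GNI":    {"mean": 29.872, "sd": 10.954, "min": 9.151,  "max": 65.663},
    "LEDU":   {"mean": 62.493, "sd": 14.102, "min": 19.3,   "max": 82.3},
    "KOF":    {"mean": 84.089, "sd": 4.458,  "min": 68.112, "max": 91.313},
    "HEALTH": {"mean": 6.4149, "sd": 1.0745, "min": 3.7,    "max": 8.9},
    "SOPRO":  {"mean": 18.109, "sd": 3.685,  "min": 9.5,    "max": 25.5},
    "ENVIRO": {"mean": 0.7792, "sd": 0.3439, "min": 0.2,    "max": 1.7}
  }
}
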
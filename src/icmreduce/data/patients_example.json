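{
  "patient1": {
    "full_70keV": {"mean_hu": 212.1, "sd_hu": 12.1, "printed_cnr": 9.82},
    "reduced_70keV": {"mean_hu": 156.4, "sd_hu": 15.2, "printed_cnr": 2.89},
    "reduced_lowkeV": {"label": "reduced_61keV", "mean_hu": 211.1, "sd_hu": 19.1, "printed_cnr": 8.33}
  },
  "patient2": {
    "full_70keV": {"mean_hu": 215.6, "sd_hu": 17.4, "printed_cnr": 10.19},
    "reduced_70keV": {"mean_hu": 100.1, "sd_hu": 18.1, "printed_cnr": 3.39},
    "reduced_lowkeV": {"label": "reduced_45keV", "mean_hu": 218.1, "sd_hu": 37.3, "printed_cnr": 4.82}
  },
  "contrast_volume_ml": {"full": 150, "reduced": 100}
}
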
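{
  "finding_names": [
    "core_body_temperature",
    "pulse",
    "arterial_systolic_pressure",
    "diastolic_blood_pressure",
    "fio2",
    "frequency",
    "tidal_volume",
    "peep",
    "pso2",
    "ph",
    "po2",
    "pco2",
    "bicarbonate",
    "pressure_support",
    "volume_support"
  ],
  "tables": [
    {
      "disease": "COPD",
      "cohort_size": 30,
      "counts": [8, 5, 19, 11, 28, 17, 21, 18, 21, 23, 22, 17, 20, 22, 8]
    },
    {
      "disease": "ARDS",
      "cohort_size": 65,
      "counts": [48, 41, 13, 23, 50, 39, 49, 43, 48, 40, 39, 38, 34, 57, 8]
    },
    {
      "disease": "CVD",
      "cohort_size": 63,
      "counts": [52, 55, 26, 13, 49, 57, 43, 43, 54, 38, 28, 43, 46, 53, 10]
    }
  ]
}
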
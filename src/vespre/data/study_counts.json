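{
  "description": "Numerator/denominator pairs reported by the original 20-month VESPRE sepsis deployment (Oct 2017 - Jun 2019). Used to exercise the funnel/biorepository percentage conventions; the underlying encounter-level data are not reproducible and are replaced by the synthetic generator.",
  "ed_encounters": 42893,
  "flagged": 3428,
  "eligible_screened": 2199,
  "not_screened_cap": 1229,
  "enrolled": 1027,
  "clinical_lab_specimens": 3054644,
  "remnant_samples_identified": 12963,
  "patients_ge2_aliquots_any": 1021,
  "patients_ge2_citrate": 674,
  "patients_ge2_edta": 463,
  "patients_ge2_heparin": 518,
  "patients_ge2_sodium_fluoride": 581,
  "remnant_urine_samples": 1632,
  "nested_analysis_n": 549,
  "inpatient_deaths": 49,
  "mortality_90d": 94,
  "adjudicated_sample_n": 50,
  "adjudicated_sofa_ge2_n": 50
}
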
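# Default adult calcium reference intakes (mg/day) by sex and age band,
# following the Italian dietary reference intake convention of a higher
# allowance from age 60.  Override with a custom file for other references.
bands:
  - {sex: woman, age_min: 20, age_max: 59, calcium_mg: 1000}
  - {sex: woman, age_min: 60, age_max: 120, calcium_mg: 1200}
  - {sex: man, age_min: 20, age_max: 59, calcium_mg: 1000}
  - {sex: man, age_min: 60, age_max: 120, calcium_mg: 1200}
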
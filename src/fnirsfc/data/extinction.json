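{
 "description": "Molar extinction coefficients for oxy- and deoxyhemoglobin at the two measurement wavelengths, in mM^-1 cm^-1, rounded from standard published hemoglobin absorption spectra. Editable configuration; downstream correlation analyses are insensitive to these scalars.",
 "units": "mM^-1 cm^-1",
 "extinction": {
  "695": {"HbO": 0.320, "HbR": 1.900},
  "830": {"HbO": 0.974, "HbR": 0.693}
 }
}
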
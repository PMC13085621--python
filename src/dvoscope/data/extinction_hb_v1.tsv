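# Hemoglobin molar extinction coefficients, version 1.
# source: compiled in-vitro human hemoglobin extinction spectra
#         (values rounded from S. Prahl's OMLC tabulation of
#         oxy-/deoxyhemoglobin molar extinction coefficients).
# units: L mmol^-1 cm^-1 (base-10)
# wavelength_nm	eps_hbo	eps_hbd
670	0.294	2.795
780	0.710	1.075
808	0.860	0.830
850	1.058	0.691
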
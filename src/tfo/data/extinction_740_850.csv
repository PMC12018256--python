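# Molar extinction coefficients of human oxy-/deoxyhemoglobin (M^-1 cm^-1)
# at the two measurement wavelengths, taken from the widely used compiled
# hemoglobin absorption spectra (Prahl compilation, tabulated from
# W.B. Gratzer / N. Kollias data). Fetal and adult hemoglobin have very
# similar optical properties in the red/NIR window, so the adult table is
# used for both.
wavelength_nm,eps_o2hb,eps_rhb
740,446.0,1115.88
850,1058.0,691.32
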
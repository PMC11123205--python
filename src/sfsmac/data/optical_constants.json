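{
  "comment": "Optical constants used by the photon-transport model. Cauchy refractive-index coefficients (n = A + B/lambda^2 + C/lambda^4, lambda in nm) and the intralipid scattering power law are substitutions chosen from published ranges where the instrument literature cites but does not print values; they are versioned here so every simulation is reproducible.",
  "cauchy_index": {
    "brain_tissue": {"A": 1.3515, "B": 4000.0, "C": 1.6e8,
      "note": "gives n in [1.35, 1.38] over 450-790 nm, within reported soft-brain-tissue range"},
    "fused_silica_fiber": {"A": 1.4508, "B": 3100.0, "C": 0.0,
      "note": "matches fused silica to ~1e-3 over the visible"},
    "glycerine": {"A": 1.4600, "B": 4200.0, "C": 0.0,
      "note": "n(589) = 1.472"},
    "air": {"A": 1.0, "B": 0.0, "C": 0.0}
  },
  "intralipid": {
    "mu_s_power_law": {"prefactor_mm1": 16.0, "exponent": -2.4, "lambda_unit": "um",
      "note": "van-Staveren-style fit for Intralipid-10% stock: mu_s = 16 * lambda_um^-2.4 mm^-1"},
    "lipid_dilution": 0.2,
    "dilution_note": "fraction of stock; 0.2 emulates the standard 2%-lipid brain-tissue phantom, giving mu_s ~ 8-14 mm^-1 over 545-680 nm",
    "anisotropy": {"intercept": 1.1, "slope_per_nm": -0.00058,
      "note": "g(lambda) = 1.1 - 0.58e-3 * lambda_nm, valid ~400-790 nm"}
  },
  "whole_blood": {
    "hemoglobin_g_per_L": 150.0,
    "hemoglobin_molar_mass_g": 64500.0,
    "note": "whole-blood absorption mu_a[mm^-1] = ln(10) * eps[cm^-1/M] * (150/64500)[M] / 10"
  }
}
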
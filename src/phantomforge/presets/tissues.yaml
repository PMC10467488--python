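# Bundled literature parameter sets for breast-tissue phantom design at 405 nm.
#
# collagen_absorption: exponential fit to collagen type I absorption,
#   valid 300-600 nm.
# dense_breast_scattering: Mie power law for very dense (fibro-glandular)
#   breasts, reference 600 nm, with fit standard deviations.
# adipose_scattering_power_law / adipose_scattering_rayleigh_mie: the two
#   adipose scattering parameterisations (reference 500 nm) whose 405 nm
#   predictions bracket the adipose target.
models:
  collagen_absorption:
    kind: exponential_absorption
    amplitude: 416.51      # cm^-1
    decay: 0.014           # nm^-1
    valid_range: [300, 600]
    label: collagen type I absorption (connective tissue)
  dense_breast_scattering:
    kind: power_law
    a: 15.12               # cm^-1 at 600 nm
    b: 1.05
    delta_a: 2.24
    delta_b: 0.292
    lambda_ref: 600
    valid_range: [400, 1300]
    label: very dense breast reduced scattering
  adipose_scattering_power_law:
    kind: power_law
    a: 10.6                # cm^-1 at 500 nm
    b: 0.520
    delta_a: 0.0
    delta_b: 0.0
    lambda_ref: 500
    valid_range: [400, 1300]
    label: adipose breast reduced scattering (single power law)
  adipose_scattering_rayleigh_mie:
    kind: rayleigh_mie
    a_prime: 11.2          # cm^-1 at 500 nm
    f_ray: 0.29
    b_mie: 0.089
    lambda_ref: 500
    valid_range: [400, 1300]
    label: adipose breast reduced scattering (Rayleigh + Mie)

constants:
  # Effective molar extinction of 70%-saturated hemoglobin at 405 nm,
  # 0.7*eps_HbO2 + 0.3*eps_Hb, cm^-1 M^-1.
  hb_extinction_405nm: 310610.8
  hb_molecular_weight: 64500.0     # g/mol
  hb_saturation: 0.70
  # Linear slope of mu_s' versus intralipid concentration at 405 nm,
  # mm^-1 per % (v/v), from the stock-emulsion polynomial literature data.
  intralipid_slope_405nm: 1.9035
  # Multiplicative reduction of intralipid-derived mu_s' when mixed into
  # 8% gelatin (dimensionless factor < 1).
  gelatin_8pct_scatter_factor: 0.36363636363636365   # 80/220
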
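# Blood-gas correction coefficient sets.
#
# Each named set supplies: the temperature-correction slopes for pH/pCO2/pO2
# (from analyser temperature to patient body temperature), the CO2 solubility
# alphaCO2(T) = a0 + a1*(T - t_ref) + a2*(T - t_ref)^2 in mmol/l/mmHg, the
# apparent pK(T, pH) = const + t_slope*(T - t_ref) + ph_slope*(7.4 - pH), and
# the ionized-calcium pH-standardisation slope.  Every set carries a
# provenance label.  Null coefficients are deliberately unusable: the
# operation needing one raises a configuration error naming it.
version: "1.0.0"
sets:
  human-default:
    provenance: human-default
    temperature_correction:
      ph_slope_per_C: -0.0147     # additive, per degC
      pco2_log10_per_C: 0.019     # multiplicative, 10**(k * dT)
      po2_log10_per_C: 0.0052
    alpha_co2: {a0: 0.0307, a1: 0.0, a2: 0.0, t_ref: 37.0}
    pk: {const: 6.1, t_slope: 0.0, ph_slope: 0.0, t_ref: 37.0}
    ionized_calcium: {log10_slope: 0.24, ph_ref: 7.4}
    temp_range: [0.0, 40.0]
  # Placeholder for species-specific coefficients (sea-turtle blood-gas
  # literature).  Transcribe the published values here, or point the loader at
  # your own config file; the pipeline refuses to guess them.
  kemps-ridley:
    provenance: species-specific (user-supplied)
    temperature_correction:
      ph_slope_per_C: null
      pco2_log10_per_C: null
      po2_log10_per_C: null
    alpha_co2: null
    pk: null
    ionized_calcium: {log10_slope: null, ph_ref: 7.4}
    temp_range: [0.0, 40.0]
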
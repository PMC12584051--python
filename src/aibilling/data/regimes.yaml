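# Point-value regime presets.  euro_per_point values are quoted as strings
# so they load as exact decimals.
regimes:
  - name: goa
    euro_per_point: "0.0582873"
    factor_min: 1.0
    factor_max: 3.5
    typical_factor: 2.3
  - name: ebm-simplified
    euro_per_point: "0.12"
    factor_min: 1.0
    factor_max: 2.0
    typical_factor: 1.0
  - name: ebm-2025
    euro_per_point: "0.123934"
    factor_min: 1.0
    factor_max: 2.0
    typical_factor: 1.0
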
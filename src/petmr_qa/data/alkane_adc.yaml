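# Reference ADC of the vial liquids as a function of temperature.
# Format: substance -> list of [temperature degC, ADC mm^2/s] pairs,
# temperatures strictly increasing; linear interpolation between rows.
#
# REPLACE PER SITE: these defaults are approximations assembled from
# published alkane self-diffusion measurements (~2%/degC temperature
# coefficient around room temperature); a clinical deployment should
# substitute its own literature-traceable values in the same format.
nonane:
  - [16.0, 1.415e-3]
  - [18.0, 1.487e-3]
  - [20.0, 1.558e-3]
  - [22.0, 1.630e-3]
  - [24.0, 1.702e-3]
  - [26.0, 1.774e-3]
  - [28.0, 1.845e-3]
undecane:
  - [16.0, 0.955e-3]
  - [18.0, 1.003e-3]
  - [20.0, 1.052e-3]
  - [22.0, 1.100e-3]
  - [24.0, 1.148e-3]
  - [26.0, 1.197e-3]
  - [28.0, 1.245e-3]
tridecane:
  - [16.0, 0.660e-3]
  - [18.0, 0.693e-3]
  - [20.0, 0.727e-3]
  - [22.0, 0.760e-3]
  - [24.0, 0.793e-3]
  - [26.0, 0.827e-3]
  - [28.0, 0.860e-3]
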
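# Per-metal marginal summary statistics (mg/kg) of the demo urban-park soil
# survey: arithmetic mean, sample SD and observed range over 40 sites.
# Used as the target for matched synthetic-sample generation and as the
# concentration inputs of the demo risk runs.
#
# The Mn row is a stand-in for the reference element (not part of the
# published summary) so that enrichment factors can be demonstrated.
Cd: {mean: 2.52, sd: 4.31, min: 0.08, max: 17.32}
Cr: {mean: 58.74, sd: 20.18, min: 22.61, max: 109.54}
Cu: {mean: 31.39, sd: 11.77, min: 10.50, max: 60.23}
Zn: {mean: 186.28, sd: 66.92, min: 92.60, max: 398.83}
Ni: {mean: 27.00, sd: 10.49, min: 9.52, max: 59.27}
Pb: {mean: 34.89, sd: 13.60, min: 15.51, max: 66.08}
Mn: {mean: 710.0, sd: 150.0, min: 400.0, max: 1100.0}
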
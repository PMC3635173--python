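# Fallback normalized weighted CT dose index, n_CTDIw, in mGy per mAs,
# by scanner class and tube voltage. Used only when neither a reported
# CTDIw nor a calibrated scanner entry is available; provenance of any
# dose computed through this table records the fallback tier.
#
# Values are representative of era-typical scanners (single-slice
# ~1985-2000, multi-slice thereafter) for the standard 16 cm head and
# 32 cm body dosimetry phantoms.
version: 1
single_slice:
  head: {80: 0.065, 100: 0.120, 120: 0.190, 140: 0.270}
  body: {80: 0.030, 100: 0.058, 120: 0.095, 140: 0.140}
multi_slice:
  head: {80: 0.055, 100: 0.100, 120: 0.160, 140: 0.230}
  body: {80: 0.025, 100: 0.048, 120: 0.080, 140: 0.118}
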
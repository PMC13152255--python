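# Default prior probabilities of pathogenicity for BRCA2 variants.
#
# Keys are Align-GVGD grades (for graded missense variants) and variant
# types (for variants without a grade).  The magnitudes follow widely
# used published BRCA2 prior tables, but every value here is
# configuration: replace this file (or pass --config) to use priors from
# your own curation database.
align_gvgd_grade:
  C0: 0.02
  C15: 0.29
  C25: 0.29
  C35: 0.66
  C45: 0.66
  C55: 0.66
  C65: 0.81
variant_type:
  missense: 0.02
  synonymous: 0.02
  intronic: 0.02
  nonsense: 0.96
  canonical_splice: 0.96
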
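# Worked design: three-group longitudinal whole-blood study.
#
# Metadata columns: group in {Control, LTBI, TBP}, days = days since
# baseline (continuous). Subjects contribute a variable number of
# repeated samples; a random intercept per subject absorbs the
# within-subject correlation.
#
# Fixed-effect formula (pass as --fixed "group * days"):
#   log mu = b0 + b1*I[LTBI] + b2*I[TBP] + b3*days
#            + b4*I[LTBI]*days + b5*I[TBP]*days + b_subject
#
# Design columns, in order (reference levels Control / day 0):
#   Intercept, group[T.LTBI], group[T.TBP], days,
#   group[T.LTBI]:days, group[T.TBP]:days
#
# Contrasts of interest: per-group expression change per day, and the
# difference in change per day between the progressor (TBP) and latent
# (LTBI) groups.
- name: slope_control
  coefficients: [0, 0, 0, 1, 0, 0]
- name: slope_ltbi
  terms: "days + group[T.LTBI]:days"
- name: slope_tbp
  terms: "days + group[T.TBP]:days"
- name: slope_tbp_vs_ltbi
  terms: "group[T.TBP]:days - group[T.LTBI]:days"
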
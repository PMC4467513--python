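# Default cause hierarchies (evaluation order) for the two age strata.
#
# The full orders are RECONSTRUCTED following the specific-before-
# nonspecific principle; the machine-validated constraints baked into the
# engine are: in the child stratum ARI is evaluated before meningitis,
# meningitis before malaria, malaria before AIDS; the neonatal stratum
# contains neither malaria nor AIDS, and neonatal sepsis comes after the
# diarrhea/ARI screens.  Deaths matching no definition fall back to the
# "unspecified" cause.  In the child stratum measles, diarrhea and ARI
# form the multi-cause group: they may be assigned simultaneously and are
# later redistributed in proportion to pre-redistribution CSMFs.
fallback_cause: unspecified
neonate_0_27d:
  order:
    - tetanus
    - congenital_abnormalities
    - intrapartum_related
    - preterm_birth
    - pneumonia
    - diarrhea
    - neonatal_sepsis
    - other_neonatal
  multi_cause_group: []
child_1_59m:
  order:
    - measles
    - injury
    - diarrhea
    - ari
    - meningitis
    - malaria
    - aids
    - other_infections
  multi_cause_group: [measles, diarrhea, ari]
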
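# Default mapping from algorithm causes to CHERG-comparable reporting
# categories.  Neonatal pneumonia and child ARI pool into the shared
# "pneumonia" category; residual groups map to "other".
map:
  # neonatal causes
  pneumonia: pneumonia
  intrapartum_related: intrapartum_related
  preterm_birth: preterm_birth
  congenital_abnormalities: congenital_abnormalities
  neonatal_sepsis: sepsis
  tetanus: tetanus
  other_neonatal: other
  # child causes
  ari: pneumonia
  measles: measles
  injury: injury
  malaria: malaria
  aids: aids
  meningitis: meningitis
  other_infections: other
  # shared
  diarrhea: diarrhea
  unspecified: unspecified
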
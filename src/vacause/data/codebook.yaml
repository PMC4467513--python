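# Default VA symptom codebook: a WHO-style item vocabulary for neonatal and
# child (1-59 m) verbal autopsy questionnaires, covering the items referenced
# by the bundled case definitions.  Binary items accept 1/0 (and yes/no);
# the codes "", "9", "dk", "DK", "NA" parse to missing on every item.
items:
  # --- general signs (both questionnaires) ---
  - {id: fever, kind: binary}
  - {id: fever_duration_days, kind: duration_days}
  - {id: cough, kind: binary}
  - {id: cough_duration_days, kind: duration_days}
  - {id: trouble_breathing, kind: binary}
  - {id: breathing_difficulty_duration_days, kind: duration_days}
  - {id: fast_breathing, kind: binary}
  - {id: chest_indrawing, kind: binary}
  - {id: diarrhea_present, kind: binary}
  - {id: diarrhea_duration_days, kind: duration_days}
  - {id: stools_max_per_day, kind: count}
  - {id: jaundice, kind: binary}
  - {id: convulsions, kind: binary}
  - {id: coma_unconscious, kind: binary}
  - {id: skin_infection, kind: binary}
  - {id: abscess, kind: binary}
  # --- child questionnaire (1-59 m) ---
  - {id: rash, kind: binary}
  - {id: rash_duration_days, kind: duration_days}
  - {id: stiff_neck, kind: binary}
  - {id: paleness, kind: binary}
  - {id: hair_color_change, kind: binary}
  - {id: leg_edema, kind: binary}
  - {id: dry_scaly_skin, kind: binary}
  - {id: tb_diagnosis_recent, kind: binary}
  - {id: injury_accident, kind: binary}
  - {id: road_traffic_accident, kind: binary}
  - {id: fall, kind: binary}
  - {id: drowning, kind: binary}
  - {id: burn, kind: binary}
  - {id: poisoning_bite, kind: binary}
  # --- neonatal questionnaire (0-27 d) ---
  - {id: stopped_suckling, kind: binary}
  - {id: spasms, kind: binary}
  - {id: visible_malformation, kind: binary}
  - {id: malformation_head_spine, kind: binary}
  - {id: malformation_limb, kind: binary}
  - {id: malformation_other, kind: binary}
  - {id: did_not_cry_at_birth, kind: binary}
  - {id: did_not_breathe_at_birth, kind: binary}
  - {id: resuscitation_attempted, kind: binary}
  - {id: preterm_delivery, kind: binary}
  - {id: very_small_at_birth, kind: binary}
  - {id: lethargy, kind: binary}
  - {id: umbilical_infection, kind: binary}
  - {id: hypothermia, kind: binary}
  - {id: bulging_fontanelle, kind: binary}
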
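# Default case definitions for the hierarchical VA cause-assignment
# algorithm.
#
# PROVENANCE.  The AIDS definition is the published five-condition
# disjunction (jaundice; chronic diarrhea >1 month; chronic fever
# >1 month; wasting = at least one of paleness / hair-colour change /
# leg edema / dry scaly skin; cough or trouble breathing lasting 3-27
# days with fever and without a recent tuberculosis diagnosis), with
# ">1 month" read as >30 whole days.  Diarrhea requires loose/liquid
# stools AND 6 or more stools on the day symptoms were most severe.
# All OTHER definitions are RECONSTRUCTED: WHO-style VA indicator
# definitions written for this package, favouring conjunctions of signs
# (specificity) in keeping with the algorithm's specific-before-
# nonspecific hierarchy.  Edit freely; predicates are validated against
# the codebook at load time.
#
# Duration windows are closed intervals in whole days.
extends_builtin: false
definitions:
  # ----- neonates (0-27 days) -----
  tetanus:
    strata: [neonate_0_27d]
    predicate:
      all_of:
        - item_equals: {item: stopped_suckling, value: true}
        - any_of:
            - item_equals: {item: convulsions, value: true}
            - item_equals: {item: spasms, value: true}
  congenital_abnormalities:
    strata: [neonate_0_27d]
    predicate:
      all_of:
        - item_equals: {item: visible_malformation, value: true}
        - any_of:
            - item_equals: {item: malformation_head_spine, value: true}
            - item_equals: {item: malformation_limb, value: true}
            - item_equals: {item: malformation_other, value: true}
  intrapartum_related:
    strata: [neonate_0_27d]
    predicate:
      all_of:
        - item_equals: {item: did_not_cry_at_birth, value: true}
        - any_of:
            - item_equals: {item: did_not_breathe_at_birth, value: true}
            - item_equals: {item: resuscitation_attempted, value: true}
  preterm_birth:
    strata: [neonate_0_27d]
    predicate:
      all_of:
        - item_equals: {item: preterm_delivery, value: true}
        - item_equals: {item: very_small_at_birth, value: true}
  pneumonia:
    strata: [neonate_0_27d]
    predicate:
      all_of:
        - any_of:
            - item_equals: {item: cough, value: true}
            - item_equals: {item: trouble_breathing, value: true}
        - any_of:
            - item_equals: {item: fast_breathing, value: true}
            - item_equals: {item: chest_indrawing, value: true}
  neonatal_sepsis:
    strata: [neonate_0_27d]
    predicate:
      all_of:
        - any_of:
            - item_equals: {item: fever, value: true}
            - item_equals: {item: hypothermia, value: true}
        - any_of:
            - item_equals: {item: stopped_suckling, value: true}
            - item_equals: {item: lethargy, value: true}
            - item_equals: {item: umbilical_infection, value: true}
            - item_equals: {item: bulging_fontanelle, value: true}
  other_neonatal:
    strata: [neonate_0_27d]
    predicate:
      any_of:
        - item_equals: {item: jaundice, value: true}
        - item_equals: {item: skin_infection, value: true}
        - item_equals: {item: umbilical_infection, value: true}
  # ----- shared (both strata) -----
  diarrhea:
    strata: [neonate_0_27d, child_1_59m]
    predicate:
      all_of:
        - item_equals: {item: diarrhea_present, value: true}
        - item_at_least: {item: stools_max_per_day, count: 6}
  # ----- children (1-59 months) -----
  measles:
    strata: [child_1_59m]
    predicate:
      all_of:
        - item_equals: {item: fever, value: true}
        - item_equals: {item: rash, value: true}
        - duration_in_days: {item: rash_duration_days, min: 3, max: null}
  injury:
    strata: [child_1_59m]
    predicate:
      all_of:
        - item_equals: {item: injury_accident, value: true}
        - any_of:
            - item_equals: {item: road_traffic_accident, value: true}
            - item_equals: {item: fall, value: true}
            - item_equals: {item: drowning, value: true}
            - item_equals: {item: burn, value: true}
            - item_equals: {item: poisoning_bite, value: true}
  ari:
    strata: [child_1_59m]
    predicate:
      all_of:
        - any_of:
            - item_equals: {item: cough, value: true}
            - item_equals: {item: trouble_breathing, value: true}
        - any_of:
            - item_equals: {item: fast_breathing, value: true}
            - item_equals: {item: chest_indrawing, value: true}
  meningitis:
    strata: [child_1_59m]
    predicate:
      all_of:
        - item_equals: {item: fever, value: true}
        - item_equals: {item: stiff_neck, value: true}
  malaria:
    strata: [child_1_59m]
    predicate:
      all_of:
        - item_equals: {item: fever, value: true}
        - any_of:
            - item_equals: {item: convulsions, value: true}
            - item_equals: {item: coma_unconscious, value: true}
  aids:
    strata: [child_1_59m]
    predicate:
      any_of:
        # 1) jaundice
        - item_equals: {item: jaundice, value: true}
        # 2) chronic diarrhea lasting more than 1 month
        - all_of:
            - item_equals: {item: diarrhea_present, value: true}
            - duration_in_days: {item: diarrhea_duration_days, min: 31, max: null}
        # 3) chronic fever lasting more than 1 month
        - all_of:
            - item_equals: {item: fever, value: true}
            - duration_in_days: {item: fever_duration_days, min: 31, max: null}
        # 4) wasting: at least 1 of the following
        - any_of:
            - item_equals: {item: paleness, value: true}
            - item_equals: {item: hair_color_change, value: true}
            - item_equals: {item: leg_edema, value: true}
            - item_equals: {item: dry_scaly_skin, value: true}
        # 5) cough or trouble breathing lasting 3-27 days, with fever,
        #    without a recent tuberculosis diagnosis
        - all_of:
            - any_of:
                - all_of:
                    - item_equals: {item: cough, value: true}
                    - duration_in_days: {item: cough_duration_days, min: 3, max: 27}
                - all_of:
                    - item_equals: {item: trouble_breathing, value: true}
                    - duration_in_days: {item: breathing_difficulty_duration_days, min: 3, max: 27}
            - item_equals: {item: fever, value: true}
            - none_of:
                - item_equals: {item: tb_diagnosis_recent, value: true}
  other_infections:
    strata: [child_1_59m]
    predicate:
      any_of:
        - item_equals: {item: fever, value: true}
        - item_equals: {item: abscess, value: true}
        - item_equals: {item: skin_infection, value: true}
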
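# Default scale definitions: item sets, weights, reverse flags, duplicate links
# and risk-band breakpoints. Band tables are configuration, not code; edit or
# supply your own file to change any instrument. Bands are inclusive upper
# bounds on the total score, in ascending order; the last band is open-ended.
#
# duplicate_of links an item to the id it measures the same construct as
# (used when pooling SAD PERSONS / Modified SAD PERSONS items and, for the
# psychiatric-care cluster, when selecting items for a constructed scale).
scales:
  - scale_id: MSHR
    name: Manchester Self-Harm Rule
    rule: any-item
    items:
      - {id: lifetime_history_self_harm, domain: binary}
      - {id: prior_psychiatric_treatment, domain: binary}
      - {id: benzodiazepines, domain: binary}
      - {id: current_psychiatric_treatment, domain: binary}

  - scale_id: ReACT
    name: ReACT Self-Harm Rule
    rule: any-item
    items:
      - {id: self_harm_last_year, domain: binary}
      - {id: living_alone_or_homeless, domain: binary}
      - {id: cutting, domain: binary}
      - {id: current_psychiatric_treatment, domain: binary}

  - scale_id: SADP
    name: SAD PERSONS Scale
    rule: weighted-bands
    bands:
      - {label: low, max_score: 4}
      - {label: medium, max_score: 6}
      - {label: high}
    items:
      - {id: sex_male, domain: binary, weight: 1}
      - {id: age_high_risk, domain: binary, weight: 1}
      - {id: depression, domain: binary, weight: 1}
      - {id: previous_suicide_attempt, domain: binary, weight: 1,
         related_to: self_harm_last_year}
      - {id: previous_psychiatric_care, domain: binary, weight: 1,
         duplicate_of: prior_psychiatric_treatment}
      - {id: ethanol_abuse, domain: binary, weight: 1}
      - {id: rational_thinking_loss, domain: binary, weight: 1}
      - {id: social_supports_lacking, domain: binary, weight: 1}
      - {id: organized_plan, domain: binary, weight: 1}
      - {id: sickness, domain: binary, weight: 1}

  - scale_id: MSPS
    name: Modified SAD PERSONS Scale
    rule: weighted-bands
    bands:
      - {label: low, max_score: 5}
      - {label: medium, max_score: 8}
      - {label: high}
    items:
      - {id: sex_male, domain: binary, weight: 1}
      - {id: age_high_risk, domain: binary, weight: 1}
      - {id: depression_hopelessness, domain: binary, weight: 2}
      - {id: prev_attempt_or_psych_care, domain: binary, weight: 1,
         duplicate_of: prior_psychiatric_treatment}
      - {id: excessive_alcohol_or_drug_use, domain: binary, weight: 1}
      - {id: rational_thinking_loss, domain: binary, weight: 2}
      - {id: separated_divorced_widowed, domain: binary, weight: 1}
      - {id: organized_serious_attempt, domain: binary, weight: 2}
      - {id: social_supports_lacking, domain: binary, weight: 1}
      - {id: stated_future_intent, domain: binary, weight: 2}

  # Impulsiveness inventory: evaluated item-by-item only (after ordinal->binary
  # recoding); the instrument has no risk bands in this analysis. Representative
  # subset of the 30 items; ordinal responses 1-4, some reverse scored.
  - scale_id: BIS
    name: Barratt Impulsiveness Scale
    rule: items-only
    items:
      - {id: plan_things_carefully, domain: ordinal-1-4, reverse_scored: true}
      - {id: rarely_thinks_one_thing, domain: ordinal-1-4, reverse_scored: true}
      - {id: lots_of_extraneous_thought, domain: ordinal-1-4}
      - {id: rarely_self_controlled, domain: ordinal-1-4, reverse_scored: true}
      - {id: changes_hobbies_frequently, domain: ordinal-1-4}
      - {id: acts_on_spur_of_moment, domain: ordinal-1-4}

  - scale_id: clinician_global
    name: Clinician global estimate of risk
    rule: threshold
    cutoff: 6
    items:
      - {id: clinician_rating, domain: likert-1-10}

  - scale_id: patient_global
    name: Patient global estimate of risk
    rule: threshold
    cutoff: 6
    items:
      - {id: patient_rating, domain: likert-1-10}
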
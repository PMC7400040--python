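# Default DSM-5 criterion map for the 10 screened disorders.
#
# Each disorder lists its criterion symptoms; a criterion is met when at
# least one mapped item response falls on the severe side of its threshold
# (rescaled value < 0).  The published description of the mapper gives its
# structure (symptom type, a minimum symptom count, and mandatory "must
# have at least one of" sets) plus worked examples, but not the full table;
# this default reconstructs it from public DSM-5 criterion lists, keeps the
# per-disorder symptom totals consistent with the worked single-respondent
# output (depression 14, anxiety 11, bipolar 15, PTSD 20, OCD 6,
# schizophrenia 7, eating disorder 3, addiction 4, ADHD 8, ASD 9), and
# honors the two printed item->criterion examples.  Severity only: DSM
# frequency and duration qualifiers are outside what a single-sitting
# questionnaire can capture and are deliberately excluded.
# Every value is overridable via load_dsm5_rules().
version: "1.0-default"

disorders:
  depression:
    min_required: 5
    required_any:
      - [depressed_mood, diminished_interest]
    criteria:
      depressed_mood: [feelings_of_sadness_distress_and_hopelessness, outlook_and_optimism]
      diminished_interest: [curiosity_interest_and_enthusiasm, drive_and_motivation]
      appetite_or_weight_change: [appetite_regulation]
      sleep_disturbance: [sleep_quality]
      psychomotor_change: [restlessness_and_hyperactivity, confusion_or_slowed_thinking]
      fatigue: [energy_level]
      worthlessness: [self_worth_and_confidence]
      excessive_guilt: [guilt_and_blame]
      concentration_difficulty: [focus_and_concentration]
      indecisiveness: [decision_making_and_risk_taking]
      suicidal_ideation: [suicidal_thoughts_or_intentions]
      social_withdrawal: [avoidance_and_withdrawal]
      irritability: [anger_and_irritability]
      low_resilience: [emotional_resilience]

  anxiety:
    min_required: 4
    required_any:
      - [excessive_worry]
    criteria:
      excessive_worry: [fear_and_anxiety]
      restlessness: [restlessness_and_hyperactivity]
      easily_fatigued: [energy_level]
      concentration_difficulty: [focus_and_concentration]
      irritability: [anger_and_irritability]
      muscle_tension: [experience_of_pain]
      sleep_disturbance: [sleep_quality]
      avoidance: [avoidance_and_withdrawal]
      somatic_symptoms: [physical_health_issues]
      loss_of_calm: [stability_and_calmness]
      anxious_dreams: [nightmares]

  bipolar:
    min_required: 5
    required_any:
      - [elevated_or_irritable_mood]
    criteria:
      elevated_or_irritable_mood: [mood_swings]
      grandiosity: [self_image]
      decreased_need_for_sleep: [sleep_quality]
      pressured_speech: [speech_and_language]
      racing_thoughts: [unwanted_strange_or_obsessive_thoughts]
      distractibility: [selective_attention, focus_and_concentration]
      increased_activity: [restlessness_and_hyperactivity]
      risky_behavior: [decision_making_and_risk_taking]
      irritability: [anger_and_irritability]
      depressed_mood: [feelings_of_sadness_distress_and_hopelessness]
      fatigue: [energy_level]
      suicidal_ideation: [suicidal_thoughts_or_intentions]
      impulsivity: [self_control_and_impulsivity]
      emotional_lability: [emotional_control]
      appetite_change: [appetite_regulation]

  ptsd:
    min_required: 6
    required_any:
      - [flashbacks, nightmares, intrusive_memories, psychological_distress]
    criteria:
      flashbacks: [traumatic_flashbacks]
      nightmares: [nightmares]
      intrusive_memories: [unwanted_strange_or_obsessive_thoughts]
      psychological_distress: [fear_and_anxiety]
      avoidance_behavior: [avoidance_and_withdrawal]
      dissociation: [sense_of_being_detached_from_reality]
      negative_beliefs: [outlook_and_optimism]
      distorted_blame: [guilt_and_blame]
      persistent_negative_mood: [feelings_of_sadness_distress_and_hopelessness]
      diminished_interest: [curiosity_interest_and_enthusiasm]
      detachment_from_others: [relationships_with_others]
      restricted_affect: [emotional_resilience]
      irritable_aggression: [aggression_toward_others]
      anger_outbursts: [anger_and_irritability]
      reckless_behavior: [decision_making_and_risk_taking]
      hypervigilance: [sensory_sensitivity]
      exaggerated_startle: [stability_and_calmness]
      concentration_problems: [focus_and_concentration]
      sleep_disturbance: [sleep_quality]
      memory_gaps: [memory]

  ocd:
    min_required: 2
    required_any:
      - [obsessions, compulsions]
    criteria:
      obsessions: [unwanted_strange_or_obsessive_thoughts, self_control_and_impulsivity, emotional_control]
      compulsions: [repetitive_or_compulsive_actions]
      obsessional_distress: [fear_and_anxiety]
      avoidance_of_triggers: [avoidance_and_withdrawal]
      guilt_over_thoughts: [guilt_and_blame]
      restless_tension: [restlessness_and_hyperactivity]

  schizophrenia:
    min_required: 2
    required_any:
      - [hallucinations, delusions, disorganized_speech]
    criteria:
      hallucinations: [hallucinations]
      delusions: [unwanted_strange_or_obsessive_thoughts]
      disorganized_speech: [speech_and_language]
      disorganized_behavior: [confusion_or_slowed_thinking]
      avolition: [drive_and_motivation]
      social_withdrawal: [avoidance_and_withdrawal]
      reality_distortion: [sense_of_being_detached_from_reality]

  eating_disorder:
    min_required: 2
    required_any:
      - [disturbed_eating]
    criteria:
      disturbed_eating: [appetite_regulation]
      body_image_disturbance: [self_image]
      loss_of_control_eating: [self_control_and_impulsivity]

  addiction:
    min_required: 2
    required_any:
      - [craving_dependence]
    criteria:
      craving_dependence: [addictions]
      loss_of_control: [self_control_and_impulsivity]
      hazardous_use: [decision_making_and_risk_taking]
      relational_impairment: [relationships_with_others]

  adhd:
    min_required: 5
    required_any: []
    criteria:
      inattention: [focus_and_concentration]
      distractibility: [selective_attention]
      disorganization: [planning_and_organization]
      forgetfulness: [memory]
      hyperactivity: [restlessness_and_hyperactivity]
      impulsivity: [self_control_and_impulsivity]
      emotional_dysregulation: [emotional_control]
      task_avoidance: [drive_and_motivation]

  asd:
    min_required: 4
    required_any:
      - [social_reciprocity, relationship_difficulty, communication_difficulty]
    criteria:
      social_reciprocity: [social_interactions_and_cooperation]
      relationship_difficulty: [relationships_with_others]
      communication_difficulty: [speech_and_language]
      reduced_empathy: [empathy]
      restricted_interests: [curiosity_interest_and_enthusiasm]
      insistence_on_sameness: [adaptability_to_change]
      sensory_reactivity: [sensory_sensitivity]
      repetitive_behavior: [repetitive_or_compulsive_actions]
      social_avoidance: [avoidance_and_withdrawal]
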
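{
  "cdm_version": "5.3-subset",
  "tables": {
    "person": ["person_id", "gender_concept_id", "year_of_birth", "month_of_birth", "day_of_birth", "birth_datetime", "race_concept_id", "ethnicity_concept_id"],
    "condition_occurrence": ["condition_occurrence_id", "person_id", "condition_concept_id", "condition_start_date", "condition_end_date", "condition_type_concept_id"],
    "drug_exposure": ["drug_exposure_id", "person_id", "drug_concept_id", "drug_exposure_start_date", "drug_exposure_end_date", "drug_type_concept_id"],
    "procedure_occurrence": ["procedure_occurrence_id", "person_id", "procedure_concept_id", "procedure_date", "procedure_type_concept_id"],
    "measurement": ["measurement_id", "person_id", "measurement_concept_id", "measurement_date", "value_as_number", "unit_concept_id", "measurement_type_concept_id"],
    "observation": ["observation_id", "person_id", "observation_concept_id", "observation_date", "value_as_number", "value_as_string", "observation_type_concept_id"],
    "device_exposure": ["device_exposure_id", "person_id", "device_concept_id", "device_exposure_start_date", "device_exposure_end_date", "device_type_concept_id"],
    "visit_occurrence": ["visit_occurrence_id", "person_id", "visit_concept_id", "visit_start_date", "visit_end_date", "visit_type_concept_id"],
    "concept": ["concept_id", "concept_name", "domain_id", "vocabulary_id", "concept_class_id", "standard_concept", "concept_code"],
    "concept_ancestor": ["ancestor_concept_id", "descendant_concept_id", "min_levels_of_separation", "max_levels_of_separation"]
  },
  "join_keys": {
    "person": "person_id",
    "condition_occurrence": "person_id",
    "drug_exposure": "person_id",
    "procedure_occurrence": "person_id",
    "measurement": "person_id",
    "observation": "person_id",
    "device_exposure": "person_id",
    "visit_occurrence": "person_id"
  },
  "domain_rules": {
    "Condition": {"event_table": "condition_occurrence", "concept_column": "condition_concept_id", "date_column": "condition_start_date", "value_column": null},
    "Drug": {"event_table": "drug_exposure", "concept_column": "drug_concept_id", "date_column": "drug_exposure_start_date", "value_column": null},
    "Procedure": {"event_table": "procedure_occurrence", "concept_column": "procedure_concept_id", "date_column": "procedure_date", "value_column": null},
    "Measurement": {"event_table": "measurement", "concept_column": "measurement_concept_id", "date_column": "measurement_date", "value_column": "value_as_number"},
    "Observation": {"event_table": "observation", "concept_column": "observation_concept_id", "date_column": "observation_date", "value_column": "value_as_number"},
    "Device": {"event_table": "device_exposure", "concept_column": "device_concept_id", "date_column": "device_exposure_start_date", "value_column": null},
    "Visit": {"event_table": "visit_occurrence", "concept_column": "visit_concept_id", "date_column": "visit_start_date", "value_column": null},
    "Demographic": {"event_table": "person", "concept_column": "gender_concept_id", "date_column": "birth_datetime", "value_column": "year_of_birth"}
  }
}
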
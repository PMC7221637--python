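{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Wide alert-log table",
  "description": "One row per best-practice-advisory alert instance, denormalized with its encounter, clinician, and patient attributes. This wide table is the authoritative serialization (CSV or Parquet).",
  "type": "object",
  "required": [
    "alert_id", "encounter_id", "patient_id", "clinician_id",
    "timestamp", "service_date", "visit_type", "is_initial_primary_care",
    "clinician_role", "clinician_specialty", "clinician_age_band",
    "clinician_sex", "patient_age", "patient_sex", "prior_shingles_vaccine",
    "fired", "suppressed", "response_action", "order_placed"
  ],
  "properties": {
    "alert_id": {"type": "string", "description": "Opaque unique id of the alert instance."},
    "encounter_id": {"type": "string", "description": "Opaque id; exactly one alert event per alert-eligible encounter."},
    "patient_id": {"type": "string"},
    "clinician_id": {"type": "string", "description": "The single provider assigned to the encounter."},
    "timestamp": {"type": "string", "format": "date-time", "description": "ISO-8601 date-time of the alert instance."},
    "service_date": {"type": "string", "format": "date", "description": "Calendar date of the encounter (ISO-8601)."},
    "visit_type": {"enum": ["scheduled", "walk_in"]},
    "is_initial_primary_care": {"type": "boolean", "description": "Initial primary-care visits are excluded from suppression."},
    "clinician_role": {"enum": ["physician", "advanced_practice", "nurse", "other"]},
    "clinician_specialty": {"type": "string"},
    "clinician_age_band": {"type": "string"},
    "clinician_sex": {"type": "string"},
    "patient_age": {"type": "integer", "minimum": 0},
    "patient_sex": {"type": "string"},
    "prior_shingles_vaccine": {"type": "boolean"},
    "fired": {"type": "boolean", "description": "False when the alert was suppressed and never shown."},
    "suppressed": {"type": "boolean"},
    "response_action": {
      "enum": ["open_smartset", "override", "postpone", "none"],
      "description": "Clinician action on a fired alert; 'none' covers ignored or closed. Always 'none' for unfired alerts."
    },
    "order_placed": {"type": "boolean", "description": "Vaccine order signed through the order set; implies response_action == 'open_smartset'."}
  }
}
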
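{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Stroop trial table row",
  "description": "One timed response in the color-word matching Stroop task. CSV dialect: UTF-8, header row mandatory, '.' decimal separator; tempo_bpm is empty outside block 2 and one of {100, 140, 180} within it; each participant has exactly one tempo.",
  "type": "object",
  "properties": {
    "participant_id": {"type": "string", "minLength": 1},
    "gender": {"enum": ["male", "female"]},
    "phase": {"enum": ["menstrual", "folicular", "ovulatory", "luteal", "not_applicable"]},
    "tempo_bpm": {"anyOf": [{"enum": [100, 140, 180]}, {"type": "string", "maxLength": 0}]},
    "block": {"enum": [1, 2, 3]},
    "run": {"enum": ["neutral", "stroop"]},
    "congruent": {"enum": [0, 1]},
    "rt_s": {"type": "number", "exclusiveMinimum": 0}
  },
  "required": ["participant_id", "gender", "phase", "tempo_bpm", "block", "run", "congruent", "rt_s"],
  "additionalProperties": false
}
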
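{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Possession table row",
  "description": "One ball possession of one team during a third. CSV dialect: UTF-8, header row mandatory, '.' decimal separator, condition in {wR, Sy, nS}, goal in {0, 1}.",
  "type": "object",
  "properties": {
    "match_id": {"type": "string", "minLength": 1},
    "team_id": {"type": "string", "minLength": 1},
    "condition": {"enum": ["wR", "Sy", "nS"]},
    "order_index": {"type": "integer", "minimum": 0},
    "n_passes": {"type": "integer", "minimum": 0},
    "n_contacts": {"type": "integer", "minimum": 1},
    "goal": {"enum": [0, 1]}
  },
  "required": ["match_id", "team_id", "condition", "order_index", "n_passes", "n_contacts", "goal"],
  "additionalProperties": false,
  "x-invariants": ["n_passes <= n_contacts"]
}
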
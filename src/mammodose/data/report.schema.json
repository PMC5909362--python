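{
 "$schema": "http://json-schema.org/draft-07/schema#",
 "title": "mammodose dose report",
 "type": "object",
 "required": ["rows"],
 "properties": {
  "meta": {"type": "object"},
  "rows": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["exam_id", "combination", "kvp", "mas", "thickness_cm"],
    "properties": {
     "exam_id": {"type": "string"},
     "combination": {"type": "string"},
     "kvp": {"type": "number"},
     "mas": {"type": "number"},
     "thickness_cm": {"type": "number"},
     "hvl_mmal": {"type": ["number", "null"]},
     "age_years": {"type": ["number", "null"]},
     "glandularity_pct": {"type": ["number", "null"]},
     "k_ai_mgy": {"type": ["number", "null"]},
     "k_ai_sigma_mgy": {"type": ["number", "null"]},
     "two_abd_mgy": {"type": ["number", "null"]},
     "two_abd_sigma_mgy": {"type": ["number", "null"]},
     "agd_dance_mgy": {"type": ["number", "null"]},
     "agd_dance_sigma_mgy": {"type": ["number", "null"]},
     "agd_wu_mgy": {"type": ["number", "null"]},
     "agd_wu_sigma_mgy": {"type": ["number", "null"]},
     "overlap_dance": {"type": ["boolean", "null"]},
     "overlap_wu": {"type": ["boolean", "null"]},
     "warnings": {"type": "array", "items": {"type": "string"}},
     "error": {"type": ["string", "null"]}
    }
   }
  }
 }
}
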
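{
 "$defs": {
  "StageResult": {
   "properties": {
    "data": {
     "additionalProperties": true,
     "default": {},
     "title": "Data",
     "type": "object"
    },
    "error": {
     "anyOf": [
      {
       "type": "string"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Error"
    },
    "status": {
     "title": "Status",
     "type": "string"
    }
   },
   "required": [
    "status"
   ],
   "title": "StageResult",
   "type": "object"
  }
 },
 "properties": {
  "comparison": {
   "additionalProperties": true,
   "title": "Comparison",
   "type": "object"
  },
  "config": {
   "additionalProperties": true,
   "title": "Config",
   "type": "object"
  },
  "systems": {
   "additionalProperties": {
    "additionalProperties": {
     "$ref": "#/$defs/StageResult"
    },
    "type": "object"
   },
   "title": "Systems",
   "type": "object"
  }
 },
 "required": [
  "config",
  "systems",
  "comparison"
 ],
 "title": "Report",
 "type": "object"
}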
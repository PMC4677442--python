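{
 "$defs": {
  "AdvisoryRule": {
   "additionalProperties": false,
   "description": "A record finding that warrants attention without excluding\ntreatment (e.g. atrial fibrillation, dementia, heart failure).",
   "properties": {
    "label": {
     "minLength": 1,
     "title": "Label",
     "type": "string"
    },
    "predicate": {
     "anyOf": [
      {
       "$ref": "#/$defs/Exists"
      },
      {
       "$ref": "#/$defs/AllOf"
      },
      {
       "$ref": "#/$defs/AnyOf"
      }
     ],
     "title": "Predicate"
    }
   },
   "required": [
    "label",
    "predicate"
   ],
   "title": "AdvisoryRule",
   "type": "object"
  },
  "AllOf": {
   "additionalProperties": false,
   "properties": {
    "all": {
     "items": {
      "anyOf": [
       {
        "$ref": "#/$defs/Exists"
       },
       {
        "$ref": "#/$defs/AllOf"
       },
       {
        "$ref": "#/$defs/AnyOf"
       }
      ]
     },
     "minItems": 1,
     "title": "All",
     "type": "array"
    }
   },
   "required": [
    "all"
   ],
   "title": "AllOf",
   "type": "object"
  },
  "AnyOf": {
   "additionalProperties": false,
   "properties": {
    "any": {
     "items": {
      "anyOf": [
       {
        "$ref": "#/$defs/Exists"
       },
       {
        "$ref": "#/$defs/AllOf"
       },
       {
        "$ref": "#/$defs/AnyOf"
       }
      ]
     },
     "minItems": 1,
     "title": "Any",
     "type": "array"
    }
   },
   "required": [
    "any"
   ],
   "title": "AnyOf",
   "type": "object"
  },
  "CodeSystem": {
   "enum": [
    "ICD9",
    "ICD10",
    "LOCAL"
   ],
   "title": "CodeSystem",
   "type": "string"
  },
  "ConceptSet": {
   "additionalProperties": false,
   "description": "A named vocabulary bundle: condition/drug labels plus optional codes.",
   "properties": {
    "name": {
     "minLength": 1,
     "title": "Name",
     "type": "string"
    },
    "labels": {
     "default": [],
     "items": {
      "type": "string"
     },
     "title": "Labels",
     "type": "array",
     "uniqueItems": true
    },
    "codes": {
     "default": [],
     "items": {
      "maxItems": 2,
      "minItems": 2,
      "prefixItems": [
       {
        "$ref": "#/$defs/CodeSystem"
       },
       {
        "type": "string"
       }
      ],
      "type": "array"
     },
     "title": "Codes",
     "type": "array",
     "uniqueItems": true
    }
   },
   "required": [
    "name"
   ],
   "title": "ConceptSet",
   "type": "object"
  },
  "ContraindicationRule": {
   "additionalProperties": false,
   "description": "One numbered catalog item.\n\n``extractable`` items carry a predicate over record events;\nnon-extractable ones carry an ``on_site_note`` describing the bedside\nmeasurement instead (and are reported NOT_EXTRACTABLE by the screen).",
   "properties": {
    "item_id": {
     "maximum": 26,
     "minimum": 1,
     "title": "Item Id",
     "type": "integer"
    },
    "label": {
     "minLength": 1,
     "title": "Label",
     "type": "string"
    },
    "severity": {
     "$ref": "#/$defs/Severity",
     "default": "EXCLUSION"
    },
    "extractable": {
     "title": "Extractable",
     "type": "boolean"
    },
    "predicate": {
     "anyOf": [
      {
       "$ref": "#/$defs/Exists"
      },
      {
       "$ref": "#/$defs/AllOf"
      },
      {
       "$ref": "#/$defs/AnyOf"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Predicate"
    },
    "on_site_note": {
     "anyOf": [
      {
       "type": "string"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "On Site Note"
    }
   },
   "required": [
    "item_id",
    "label",
    "extractable"
   ],
   "title": "ContraindicationRule",
   "type": "object"
  },
  "Exists": {
   "additionalProperties": false,
   "properties": {
    "exists": {
     "$ref": "#/$defs/ExistsClause"
    }
   },
   "required": [
    "exists"
   ],
   "title": "Exists",
   "type": "object"
  },
  "ExistsClause": {
   "additionalProperties": false,
   "description": "Does an event of this source, in this concept set, exist within the\nlookback window ending at the index time?  ``lookback_days=None`` means\nunlimited (any time in the record).",
   "properties": {
    "source": {
     "$ref": "#/$defs/Source"
    },
    "concepts": {
     "$ref": "#/$defs/ConceptSet"
    },
    "lookback_days": {
     "anyOf": [
      {
       "minimum": 1,
       "type": "integer"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Lookback Days"
    }
   },
   "required": [
    "source",
    "concepts"
   ],
   "title": "ExistsClause",
   "type": "object"
  },
  "Severity": {
   "enum": [
    "EXCLUSION",
    "ADVISORY"
   ],
   "title": "Severity",
   "type": "string"
  },
  "Source": {
   "enum": [
    "DIAGNOSIS",
    "MEDICATION",
    "ADR"
   ],
   "title": "Source",
   "type": "string"
  }
 },
 "properties": {
  "items": {
   "items": {
    "$ref": "#/$defs/ContraindicationRule"
   },
   "title": "Items",
   "type": "array"
  },
  "advisories": {
   "default": [],
   "items": {
    "$ref": "#/$defs/AdvisoryRule"
   },
   "title": "Advisories",
   "type": "array"
  }
 },
 "required": [
  "items"
 ],
 "title": "Catalog",
 "type": "object"
}
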
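{
 "$defs": {
  "Evidence": {
   "description": "Provenance of one matching event: where, when, and what concept.",
   "properties": {
    "source": {
     "$ref": "#/$defs/Source"
    },
    "hospital_id": {
     "title": "Hospital Id",
     "type": "string"
    },
    "concept": {
     "title": "Concept",
     "type": "string"
    },
    "date": {
     "format": "date",
     "title": "Date",
     "type": "string"
    },
    "end_date": {
     "anyOf": [
      {
       "format": "date",
       "type": "string"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "End Date"
    },
    "code": {
     "anyOf": [
      {
       "type": "string"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Code"
    }
   },
   "required": [
    "source",
    "hospital_id",
    "concept",
    "date"
   ],
   "title": "Evidence",
   "type": "object"
  },
  "ImagingResult": {
   "additionalProperties": true,
   "properties": {
    "patient_id": {
     "minLength": 1,
     "title": "Patient Id",
     "type": "string"
    },
    "hospital_id": {
     "minLength": 1,
     "title": "Hospital Id",
     "type": "string"
    },
    "modality": {
     "minLength": 1,
     "title": "Modality",
     "type": "string"
    },
    "finding_summary": {
     "default": "",
     "title": "Finding Summary",
     "type": "string"
    },
    "acquired_at": {
     "format": "date-time",
     "title": "Acquired At",
     "type": "string"
    }
   },
   "required": [
    "patient_id",
    "hospital_id",
    "modality",
    "acquired_at"
   ],
   "title": "ImagingResult",
   "type": "object"
  },
  "LabResult": {
   "additionalProperties": true,
   "properties": {
    "patient_id": {
     "minLength": 1,
     "title": "Patient Id",
     "type": "string"
    },
    "hospital_id": {
     "minLength": 1,
     "title": "Hospital Id",
     "type": "string"
    },
    "analyte": {
     "minLength": 1,
     "title": "Analyte",
     "type": "string"
    },
    "value": {
     "title": "Value",
     "type": "number"
    },
    "units": {
     "default": "",
     "title": "Units",
     "type": "string"
    },
    "collected_at": {
     "format": "date-time",
     "title": "Collected At",
     "type": "string"
    }
   },
   "required": [
    "patient_id",
    "hospital_id",
    "analyte",
    "value",
    "collected_at"
   ],
   "title": "LabResult",
   "type": "object"
  },
  "ScreenFinding": {
   "properties": {
    "item_id": {
     "title": "Item Id",
     "type": "integer"
    },
    "status": {
     "$ref": "#/$defs/Status"
    },
    "evidence": {
     "default": [],
     "items": {
      "$ref": "#/$defs/Evidence"
     },
     "title": "Evidence",
     "type": "array"
    }
   },
   "required": [
    "item_id",
    "status"
   ],
   "title": "ScreenFinding",
   "type": "object"
  },
  "Source": {
   "enum": [
    "DIAGNOSIS",
    "MEDICATION",
    "ADR"
   ],
   "title": "Source",
   "type": "string"
  },
  "Status": {
   "enum": [
    "TRIGGERED",
    "CLEAR",
    "NOT_EXTRACTABLE"
   ],
   "title": "Status",
   "type": "string"
  }
 },
 "properties": {
  "patient_id": {
   "title": "Patient Id",
   "type": "string"
  },
  "index_datetime": {
   "format": "date-time",
   "title": "Index Datetime",
   "type": "string"
  },
  "snapshot_time": {
   "anyOf": [
    {
     "format": "date-time",
     "type": "string"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Snapshot Time"
  },
  "findings": {
   "items": {
    "$ref": "#/$defs/ScreenFinding"
   },
   "title": "Findings",
   "type": "array"
  },
  "advisories": {
   "default": [],
   "items": {
    "maxItems": 2,
    "minItems": 2,
    "prefixItems": [
     {
      "type": "string"
     },
     {
      "items": {
       "$ref": "#/$defs/Evidence"
      },
      "type": "array"
     }
    ],
    "type": "array"
   },
   "title": "Advisories",
   "type": "array"
  },
  "recent_labs": {
   "default": [],
   "items": {
    "$ref": "#/$defs/LabResult"
   },
   "title": "Recent Labs",
   "type": "array"
  },
  "recent_imaging": {
   "default": [],
   "items": {
    "$ref": "#/$defs/ImagingResult"
   },
   "title": "Recent Imaging",
   "type": "array"
  }
 },
 "required": [
  "patient_id",
  "index_datetime",
  "findings"
 ],
 "title": "ScreenReport",
 "type": "object"
}
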
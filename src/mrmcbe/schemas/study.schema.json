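{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "TwoRoundReaderStudy",
 "type": "object",
 "required": [
  "patients",
  "examinations",
  "images",
  "annotations"
 ],
 "properties": {
  "patients": {
   "type": "array",
   "items": {
    "properties": {
     "patient_id": {
      "title": "Patient Id",
      "type": "string"
     },
     "sex": {
      "anyOf": [
       {
        "enum": [
         "male",
         "female"
        ],
        "type": "string"
       },
       {
        "type": "null"
       }
      ],
      "default": null,
      "title": "Sex"
     },
     "age": {
      "anyOf": [
       {
        "type": "number"
       },
       {
        "type": "null"
       }
      ],
      "default": null,
      "title": "Age"
     }
    },
    "required": [
     "patient_id"
    ],
    "title": "PatientRecord",
    "type": "object"
   }
  },
  "examinations": {
   "type": "array",
   "items": {
    "properties": {
     "examination_id": {
      "title": "Examination Id",
      "type": "string"
     },
     "patient_id": {
      "title": "Patient Id",
      "type": "string"
     },
     "image_ids": {
      "items": {
       "type": "string"
      },
      "title": "Image Ids",
      "type": "array"
     }
    },
    "required": [
     "examination_id",
     "patient_id",
     "image_ids"
    ],
    "title": "ExaminationRecord",
    "type": "object"
   }
  },
  "images": {
   "type": "array",
   "items": {
    "properties": {
     "image_id": {
      "title": "Image Id",
      "type": "string"
     },
     "examination_id": {
      "title": "Examination Id",
      "type": "string"
     },
     "body_region": {
      "enum": [
       "upper_limb",
       "lower_limb",
       "pelvis"
      ],
      "title": "Body Region",
      "type": "string"
     },
     "width": {
      "title": "Width",
      "type": "number"
     },
     "height": {
      "title": "Height",
      "type": "number"
     }
    },
    "required": [
     "image_id",
     "examination_id",
     "body_region",
     "width",
     "height"
    ],
    "title": "ImageRecord",
    "type": "object"
   }
  },
  "annotations": {
   "type": "array",
   "items": {
    "$defs": {
     "BoundingBox": {
      "description": "Axis-aligned pixel rectangle; the unit of fracture localization.",
      "properties": {
       "x_min": {
        "title": "X Min",
        "type": "number"
       },
       "y_min": {
        "title": "Y Min",
        "type": "number"
       },
       "x_max": {
        "title": "X Max",
        "type": "number"
       },
       "y_max": {
        "title": "Y Max",
        "type": "number"
       }
      },
      "required": [
       "x_min",
       "y_min",
       "x_max",
       "y_max"
      ],
      "title": "BoundingBox",
      "type": "object"
     }
    },
    "description": "One bounding box drawn by one source on one image.\n\n``reader_id`` and ``round`` are present exactly for reader annotations.\nGround truth and readers always carry an acute/healing ``status``; the AI\nnever does (it cannot grade healing).  The optional ``certainty`` flag is\ncarried through untouched \u2014 every positive finding is treated as positive\nregardless of certainty.",
    "properties": {
     "image_id": {
      "title": "Image Id",
      "type": "string"
     },
     "source": {
      "enum": [
       "ground_truth",
       "reader",
       "ai"
      ],
      "title": "Source",
      "type": "string"
     },
     "reader_id": {
      "anyOf": [
       {
        "type": "string"
       },
       {
        "type": "null"
       }
      ],
      "default": null,
      "title": "Reader Id"
     },
     "round": {
      "anyOf": [
       {
        "enum": [
         "r1",
         "r2"
        ],
        "type": "string"
       },
       {
        "type": "null"
       }
      ],
      "default": null,
      "title": "Round"
     },
     "box": {
      "$ref": "#/$defs/BoundingBox"
     },
     "status": {
      "anyOf": [
       {
        "enum": [
         "acute",
         "healing"
        ],
        "type": "string"
       },
       {
        "type": "null"
       }
      ],
      "default": null,
      "title": "Status"
     },
     "certainty": {
      "anyOf": [
       {
        "enum": [
         "certain",
         "doubtful"
        ],
        "type": "string"
       },
       {
        "type": "null"
       }
      ],
      "default": null,
      "title": "Certainty"
     }
    },
    "required": [
     "image_id",
     "source",
     "box"
    ],
    "title": "Annotation",
    "type": "object"
   }
  }
 }
}
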
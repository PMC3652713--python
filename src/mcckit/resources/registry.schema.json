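{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "mcckit registry resource",
  "type": "object",
  "required": ["scheme", "version", "dialects", "conditions", "definitions", "schemes"],
  "properties": {
    "scheme": {"type": "string"},
    "version": {"type": "string"},
    "description": {"type": "string"},
    "mcc_threshold": {"type": "integer", "minimum": 1},
    "dialects": {
      "type": "array",
      "minItems": 5,
      "maxItems": 5,
      "items": {
        "type": "object",
        "required": ["dialect_id", "name", "unit_of_analysis", "condition_data_kind", "operator", "sampling_frame", "data_source"],
        "properties": {
          "dialect_id": {"enum": ["NHIS", "NAMCS", "MEPS", "NIS", "CMS"]},
          "unit_of_analysis": {"enum": ["individual", "visit", "hospitalization"]},
          "condition_data_kind": {"enum": ["self_report", "checkbox", "ccs_codes", "icd9_codes"]}
        }
      }
    },
    "conditions": {
      "type": "array",
      "minItems": 20,
      "maxItems": 20,
      "items": {
        "type": "object",
        "required": ["condition_id", "display_name", "rows"],
        "properties": {
          "condition_id": {"type": "string", "pattern": "^[a-z][a-z0-9_]*$"},
          "display_name": {"type": "string"},
          "scope_note": {"type": "string"},
          "rows": {
            "type": "array",
            "minItems": 1,
            "items": {
              "type": "object",
              "required": ["name", "cells"],
              "properties": {
                "name": {"type": "string"},
                "cells": {
                  "type": "object",
                  "required": ["NHIS", "NAMCS", "MEPS", "NIS", "CMS"],
                  "additionalProperties": {
                    "type": "object",
                    "required": ["cell"],
                    "properties": {
                      "cell": {"type": "string"},
                      "lenient": {"type": "boolean"},
                      "note": {"type": "string"}
                    }
                  }
                }
              }
            }
          },
          "availability_overrides": {
            "type": "object",
            "additionalProperties": {
              "type": "object",
              "required": ["state", "note"],
              "properties": {
                "state": {"enum": ["measured", "related_proxy", "unavailable"]},
                "synthesize_checkbox": {"type": "boolean"},
                "proxy_item_label": {"type": "string"},
                "note": {"type": "string"}
              }
            }
          }
        }
      }
    },
    "definitions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["source", "year", "duration_criterion", "functional_limitation", "ongoing_care"]
      }
    },
    "schemes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["scheme_name", "source", "first_year", "n_conditions", "method"]
      }
    }
  }
}
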
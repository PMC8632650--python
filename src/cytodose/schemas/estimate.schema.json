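{
  "properties": {
    "dose_gy": {
      "minimum": 0,
      "title": "Dose Gy",
      "type": "number"
    },
    "lower_gy": {
      "minimum": 0,
      "title": "Lower Gy",
      "type": "number"
    },
    "upper_gy": {
      "minimum": 0,
      "title": "Upper Gy",
      "type": "number"
    },
    "observed_count": {
      "minimum": 0,
      "title": "Observed Count",
      "type": "integer"
    },
    "n_cells": {
      "minimum": 1,
      "title": "N Cells",
      "type": "integer"
    },
    "observed_yield": {
      "minimum": 0,
      "title": "Observed Yield",
      "type": "number"
    },
    "conf_count": {
      "exclusiveMaximum": 1,
      "minimum": 0,
      "title": "Conf Count",
      "type": "number"
    },
    "conf_curve": {
      "exclusiveMaximum": 1,
      "minimum": 0,
      "title": "Conf Curve",
      "type": "number"
    },
    "curve_endpoint": {
      "title": "Curve Endpoint",
      "type": "string"
    },
    "upper_open": {
      "default": false,
      "title": "Upper Open",
      "type": "boolean"
    },
    "warnings": {
      "default": [],
      "items": {
        "type": "string"
      },
      "title": "Warnings",
      "type": "array"
    }
  },
  "required": [
    "dose_gy",
    "lower_gy",
    "upper_gy",
    "observed_count",
    "n_cells",
    "observed_yield",
    "conf_count",
    "conf_curve",
    "curve_endpoint"
  ],
  "title": "EstimateDocument",
  "type": "object"
}
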
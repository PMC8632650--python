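{
  "properties": {
    "endpoint": {
      "title": "Endpoint",
      "type": "string"
    },
    "C": {
      "minimum": 0,
      "title": "C",
      "type": "number"
    },
    "alpha": {
      "minimum": 0,
      "title": "Alpha",
      "type": "number"
    },
    "beta": {
      "minimum": 0,
      "title": "Beta",
      "type": "number"
    },
    "se_C": {
      "minimum": 0,
      "title": "Se C",
      "type": "number"
    },
    "se_alpha": {
      "minimum": 0,
      "title": "Se Alpha",
      "type": "number"
    },
    "se_beta": {
      "minimum": 0,
      "title": "Se Beta",
      "type": "number"
    },
    "vcov": {
      "items": {
        "type": "number"
      },
      "maxItems": 9,
      "minItems": 9,
      "title": "Vcov",
      "type": "array"
    },
    "dispersion_scale": {
      "minimum": 1.0,
      "title": "Dispersion Scale",
      "type": "number"
    },
    "alpha_beta_ratio": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Alpha Beta Ratio"
    },
    "n_points": {
      "minimum": 0,
      "title": "N Points",
      "type": "integer"
    },
    "degenerate": {
      "default": false,
      "title": "Degenerate",
      "type": "boolean"
    }
  },
  "required": [
    "endpoint",
    "C",
    "alpha",
    "beta",
    "se_C",
    "se_alpha",
    "se_beta",
    "vcov",
    "dispersion_scale",
    "n_points"
  ],
  "title": "CurveDocument",
  "type": "object"
}
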
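{
  "properties": {
    "test_name": {
      "title": "Test Name",
      "type": "string"
    },
    "statistic": {
      "title": "Statistic",
      "type": "number"
    },
    "p_value": {
      "maximum": 1,
      "minimum": 0,
      "title": "P Value",
      "type": "number"
    },
    "group_ids": {
      "items": {
        "type": "string"
      },
      "title": "Group Ids",
      "type": "array"
    },
    "dose_gy": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Dose Gy"
    },
    "endpoint": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Endpoint"
    }
  },
  "required": [
    "test_name",
    "statistic",
    "p_value",
    "group_ids"
  ],
  "title": "ComparisonDocument",
  "type": "object"
}
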
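{
  "$defs": {
    "TestEntry": {
      "properties": {
        "component": {
          "title": "Component",
          "type": "string"
        },
        "kind": {
          "enum": [
            "LRT",
            "Wald"
          ],
          "title": "Kind",
          "type": "string"
        },
        "statistic": {
          "title": "Statistic",
          "type": "number"
        },
        "df": {
          "title": "Df",
          "type": "integer"
        },
        "p_value": {
          "title": "P Value",
          "type": "number"
        },
        "note": {
          "default": "",
          "title": "Note",
          "type": "string"
        }
      },
      "required": [
        "component",
        "kind",
        "statistic",
        "df",
        "p_value"
      ],
      "title": "TestEntry",
      "type": "object"
    }
  },
  "description": "Schema of the JSON analysis report.",
  "properties": {
    "estimates": {
      "additionalProperties": {
        "type": "number"
      },
      "title": "Estimates",
      "type": "object"
    },
    "standard_errors": {
      "additionalProperties": {
        "anyOf": [
          {
            "type": "number"
          },
          {
            "type": "null"
          }
        ]
      },
      "title": "Standard Errors",
      "type": "object"
    },
    "shares": {
      "additionalProperties": {
        "type": "number"
      },
      "title": "Shares",
      "type": "object"
    },
    "icc": {
      "title": "Icc",
      "type": "number"
    },
    "sigma_eff2": {
      "title": "Sigma Eff2",
      "type": "number"
    },
    "icc2": {
      "title": "Icc2",
      "type": "number"
    },
    "loglik": {
      "title": "Loglik",
      "type": "number"
    },
    "converged": {
      "title": "Converged",
      "type": "boolean"
    },
    "boundary": {
      "items": {
        "type": "string"
      },
      "title": "Boundary",
      "type": "array"
    },
    "n_persons": {
      "title": "N Persons",
      "type": "integer"
    },
    "n_occasions": {
      "title": "N Occasions",
      "type": "integer"
    },
    "tests": {
      "items": {
        "$ref": "#/$defs/TestEntry"
      },
      "title": "Tests",
      "type": "array"
    },
    "seed": {
      "title": "Seed",
      "type": "integer"
    }
  },
  "required": [
    "estimates",
    "standard_errors",
    "shares",
    "icc",
    "sigma_eff2",
    "icc2",
    "loglik",
    "converged",
    "boundary",
    "n_persons",
    "n_occasions",
    "tests",
    "seed"
  ],
  "title": "AnalysisReport",
  "type": "object"
}
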
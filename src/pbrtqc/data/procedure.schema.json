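{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "MA procedure configuration",
  "type": "object",
  "allOf": [
    {
      "$defs": {
        "Formula": {
          "description": "Moving-average calculation formula.",
          "enum": [
            "simple",
            "ewma"
          ],
          "title": "Formula",
          "type": "string"
        }
      },
      "description": "Full parameterization of one moving-average control procedure.\n\nExactly one of ``block_size`` (simple MA) or ``weighting_factor``\n(EWMA) must be set, matching ``formula``. Control limits are in the\nanalyte's concentration units and are typically the min/max of the MA\nobserved on a stable training period. ``ewma_seed`` is the starting\nvalue z(0) of the EWMA recursion \u2014 the mean of the training population.",
      "properties": {
        "analyte_name": {
          "title": "Analyte Name",
          "type": "string"
        },
        "formula": {
          "$ref": "#/$defs/Formula"
        },
        "block_size": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Block Size"
        },
        "weighting_factor": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Weighting Factor"
        },
        "truncation_lower": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Truncation Lower"
        },
        "truncation_upper": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Truncation Upper"
        },
        "control_lower": {
          "title": "Control Lower",
          "type": "number"
        },
        "control_upper": {
          "title": "Control Upper",
          "type": "number"
        },
        "ewma_seed": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Ewma Seed"
        }
      },
      "required": [
        "analyte_name",
        "formula",
        "control_lower",
        "control_upper"
      ],
      "title": "MAProcedure",
      "type": "object"
    }
  ],
  "properties": {
    "analyte_config": {
      "description": "Per-analyte analytical performance configuration.\n\nParameters\n----------\nanalyte_name, units:\n    Test identity, e.g. ``sodium`` in ``mmol/L``.\ntea_pct:\n    Total allowable error in percent (CLIA-based, or a critical-\n    concentration percentage where CLIA publishes an absolute value).\nmin_tea_pct:\n    Optional biological-variation minimum allowable error in percent;\n    may be attainable in one direction only (sign carried by the user).\ndaily_volume:\n    Average number of tests per working day \u2014 the budget within which a\n    TEa-sized bias must be detected for a procedure to be acceptable.\ncvi, cvg:\n    Intra- and inter-individual biological coefficients of variation in\n    percent, used by the minimum-TEa formula.",
      "properties": {
        "analyte_name": {
          "title": "Analyte Name",
          "type": "string"
        },
        "units": {
          "default": "",
          "title": "Units",
          "type": "string"
        },
        "tea_pct": {
          "title": "Tea Pct",
          "type": "number"
        },
        "min_tea_pct": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Min Tea Pct"
        },
        "daily_volume": {
          "default": 1,
          "title": "Daily Volume",
          "type": "integer"
        },
        "cvi": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Cvi"
        },
        "cvg": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Cvg"
        }
      },
      "required": [
        "analyte_name",
        "tea_pct"
      ],
      "title": "AnalyteConfig",
      "type": "object"
    }
  }
}
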
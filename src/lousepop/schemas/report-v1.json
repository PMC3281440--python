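{
  "$comment": "Report schema, version 1. Checked by lousepop.io.validate_report.",
  "type": "object",
  "required": ["schema_version", "tool", "command", "seed", "config", "timestamp"],
  "properties": {
    "schema_version": {"type": "string"},
    "tool": {
      "type": "object",
      "required": ["name", "version"],
      "properties": {
        "name": {"type": "string"},
        "version": {"type": "string"}
      }
    },
    "command": {"type": "string"},
    "seed": {"type": ["integer", "null"]},
    "config": {"type": "object"},
    "inputs": {"type": "object"},
    "timestamp": {"type": "string"},
    "aggregation": {
      "type": ["object", "null"],
      "required": ["summary", "negbin", "discrepancy", "display"],
      "properties": {
        "summary": {
          "type": "object",
          "required": [
            "n_hosts", "n_infested", "prevalence", "total",
            "mean_abundance", "variance"
          ],
          "properties": {
            "n_hosts": {"type": "integer"},
            "n_infested": {"type": "integer"},
            "prevalence": {"type": "number"},
            "total": {"type": "integer"},
            "mean_intensity": {"type": ["number", "null"]},
            "mean_abundance": {"type": "number"},
            "variance": {"type": "number"},
            "variance_to_mean": {"type": ["number", "null"]}
          }
        },
        "negbin": {"type": "object"},
        "discrepancy": {
          "type": "object",
          "required": ["D"],
          "properties": {"D": {"type": "number"}}
        },
        "gof": {"type": ["object", "null"]},
        "display": {"type": "object"}
      }
    },
    "demography": {
      "type": ["object", "null"],
      "required": ["R0", "rm", "lambda", "display"],
      "properties": {
        "R0": {"type": "number"},
        "rm": {"type": "number"},
        "T": {"type": ["number", "null"]},
        "DT": {"type": ["number", "null"]},
        "lambda": {"type": "number"},
        "display": {"type": "object"}
      }
    }
  }
}
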
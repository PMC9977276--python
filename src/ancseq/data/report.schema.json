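{
  "$defs": {
    "NodeReport": {
      "properties": {
        "node": {
          "title": "Node",
          "type": "integer"
        },
        "descendants": {
          "items": {
            "type": "string"
          },
          "title": "Descendants",
          "type": "array"
        },
        "mean_pp": {
          "title": "Mean Pp",
          "type": "number"
        },
        "n_tied_sites": {
          "title": "N Tied Sites",
          "type": "integer"
        },
        "n_gap_sites": {
          "title": "N Gap Sites",
          "type": "integer"
        },
        "n_substitutions": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "N Substitutions"
        },
        "gene_fasta": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Gene Fasta"
        },
        "gene_seed": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Gene Seed"
        }
      },
      "required": [
        "node",
        "descendants",
        "mean_pp",
        "n_tied_sites",
        "n_gap_sites"
      ],
      "title": "NodeReport",
      "type": "object"
    }
  },
  "description": "Machine-readable run summary (the shipped JSON-schema's model).",
  "properties": {
    "version": {
      "title": "Version",
      "type": "string"
    },
    "config_hash": {
      "title": "Config Hash",
      "type": "string"
    },
    "input_checksums": {
      "additionalProperties": {
        "type": "string"
      },
      "title": "Input Checksums",
      "type": "object"
    },
    "seed": {
      "anyOf": [
        {
          "type": "integer"
        },
        {
          "type": "null"
        }
      ],
      "title": "Seed"
    },
    "model": {
      "title": "Model",
      "type": "string"
    },
    "alpha": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "title": "Alpha"
    },
    "log_likelihood": {
      "title": "Log Likelihood",
      "type": "number"
    },
    "n_leaves": {
      "title": "N Leaves",
      "type": "integer"
    },
    "n_sites": {
      "title": "N Sites",
      "type": "integer"
    },
    "nodes": {
      "items": {
        "$ref": "#/$defs/NodeReport"
      },
      "title": "Nodes",
      "type": "array"
    },
    "outputs": {
      "items": {
        "type": "string"
      },
      "title": "Outputs",
      "type": "array"
    }
  },
  "required": [
    "version",
    "config_hash",
    "input_checksums",
    "seed",
    "model",
    "alpha",
    "log_likelihood",
    "n_leaves",
    "n_sites",
    "nodes",
    "outputs"
  ],
  "title": "PipelineReport",
  "type": "object"
}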
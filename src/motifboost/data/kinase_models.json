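{
  "format_version": 1,
  "comment": "Position-specific log2-odds kinase motif models. Positions are relative to the phospho-acceptor (negative = N-terminal); residues absent from a position row score 0 (unconstrained). Matrices are transparent textbook consensi with invented magnitudes (+2 strong, +1 weak preference), not fitted models; replace with your own matrices for quantitative specificity work.",
  "width": 7,
  "models": [
    {
      "name": "CK2",
      "kinase_class": "acidophilic",
      "acceptor_residues": [
        "S",
        "T"
      ],
      "match_midpoint": 2.0,
      "match_slope": 4.0,
      "logodds": {
        "1": {
          "D": 1.0,
          "E": 1.0
        },
        "2": {
          "D": 1.0,
          "E": 1.0
        },
        "3": {
          "D": 2.0,
          "E": 2.0
        }
      }
    },
    {
      "name": "PKA",
      "kinase_class": "basophilic",
      "acceptor_residues": [
        "S",
        "T"
      ],
      "match_midpoint": 2.0,
      "match_slope": 4.0,
      "logodds": {
        "-3": {
          "R": 2.0,
          "K": 1.0
        },
        "-2": {
          "R": 2.0,
          "K": 1.0
        }
      }
    },
    {
      "name": "ERK2",
      "kinase_class": "pro_directed",
      "acceptor_residues": [
        "S",
        "T"
      ],
      "match_midpoint": 2.0,
      "match_slope": 4.0,
      "logodds": {
        "1": {
          "P": 2.0
        },
        "-2": {
          "P": 2.0
        }
      }
    },
    {
      "name": "JNK1",
      "kinase_class": "pro_directed",
      "acceptor_residues": [
        "S",
        "T"
      ],
      "match_midpoint": 3.0,
      "match_slope": 4.0,
      "logodds": {
        "1": {
          "P": 2.0
        },
        "3": {
          "P": 2.0
        },
        "2": {
          "L": 2.0
        }
      }
    },
    {
      "name": "p38a",
      "kinase_class": "pro_directed",
      "acceptor_residues": [
        "S",
        "T"
      ],
      "match_midpoint": 3.0,
      "match_slope": 4.0,
      "logodds": {
        "1": {
          "P": 2.0
        },
        "-1": {
          "V": 2.0
        },
        "-3": {
          "G": 2.0
        }
      }
    },
    {
      "name": "CDK1",
      "kinase_class": "pro_directed",
      "acceptor_residues": [
        "S",
        "T"
      ],
      "match_midpoint": 3.0,
      "match_slope": 4.0,
      "logodds": {
        "1": {
          "P": 2.0
        },
        "3": {
          "K": 2.0,
          "R": 2.0
        },
        "4": {
          "K": 2.0,
          "R": 2.0
        }
      }
    },
    {
      "name": "SRC",
      "kinase_class": "tyrosine",
      "acceptor_residues": [
        "Y"
      ],
      "match_midpoint": 1.75,
      "match_slope": 4.0,
      "logodds": {
        "-3": {
          "E": 1.5
        },
        "-2": {
          "D": 1.0,
          "E": 1.0
        },
        "1": {
          "I": 1.0
        }
      }
    },
    {
      "name": "EGFR",
      "kinase_class": "tyrosine",
      "acceptor_residues": [
        "Y"
      ],
      "match_midpoint": 1.75,
      "match_slope": 4.0,
      "logodds": {
        "-1": {
          "D": 1.0,
          "E": 1.0
        },
        "1": {
          "E": 1.5
        },
        "2": {
          "E": 1.0
        }
      }
    }
  ]
}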
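{
  "name": "PsAMRIS",
  "sites_per_joint": 2,
  "joints": [
    "MCP2", "MCP3", "MCP4", "MCP5",
    "PIP2", "PIP3", "PIP4", "PIP5",
    "DIP2", "DIP3", "DIP4", "DIP5"
  ],
  "features": [
    {"name": "synovitis", "score_min": 0, "score_max": 3},
    {"name": "flexor_tenosynovitis", "score_min": 0, "score_max": 3},
    {"name": "periarticular_inflammation", "score_min": 0, "score_max": 1},
    {"name": "bone_edema", "score_min": 0, "score_max": 3},
    {"name": "bone_erosion", "score_min": 0, "score_max": 10},
    {"name": "bone_proliferation", "score_min": 0, "score_max": 1}
  ]
}
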
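{
  "name": "sPsAMRIS",
  "sites_per_joint": 2,
  "joints": ["MCP3", "MCP4", "PIP4"],
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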
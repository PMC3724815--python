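{
  "version": 1,
  "temperature_c": 37,
  "duplex_initiation": 0.5,
  "internal_penalty": 0.5,
  "wobble_default": -1.1,
  "stacks": {
    "AA/UU": -0.93,
    "AU/UA": -1.1,
    "UA/AU": -1.33,
    "CU/GA": -2.08,
    "CA/GU": -2.11,
    "GU/CA": -2.24,
    "GA/CU": -2.35,
    "CG/GC": -2.36,
    "GG/CC": -3.26,
    "GC/CG": -3.42,
    "AG/UU": -0.55,
    "AU/UG": -1.36,
    "CG/GU": -1.41,
    "CU/GG": -2.11,
    "GG/CU": -1.53,
    "GU/CG": -2.51,
    "UG/AU": -1.0,
    "UU/AG": -0.76,
    "GU/UG": -0.5,
    "UG/GU": 0.3,
    "GG/UU": -0.5,
    "UU/GG": -0.5
  }
}
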
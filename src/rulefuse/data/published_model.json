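{
  "intercept": -0.3265,
  "coefficients": {
    "Rule1": -0.7705,
    "Rule2": -0.4823,
    "Rule3": -0.4478,
    "Rule4": -0.2747,
    "Rule5": -0.2537,
    "Rule6": 0.3795,
    "Rule7": 0.4433,
    "Rule8": -0.3869,
    "Rule9": 0.528,
    "Rule10": 0.5978,
    "Rule11": 0.4615,
    "Rule12": 0.6856,
    "Rule13": 0.4334,
    "Rule14": 0.5789,
    "Rule15": 0.3891
  },
  "threshold": 0.5,
  "outcome": "IAC (1) vs MIA/AIS (0)"
}
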
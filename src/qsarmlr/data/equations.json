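{
 "model1": {
  "name": "model1",
  "provenance": "published reference model 1 (uracil-coumarin MCF7 series)",
  "intercept": -4.3799,
  "coefficients": {
   "MAXDP": 0.8065,
   "SIC0": 14.2488,
   "JGI7": 35.9491
  }
 },
 "model2": {
  "name": "model2",
  "provenance": "published reference model 2 (best model, uracil-coumarin MCF7 series)",
  "intercept": 17.6885,
  "coefficients": {
   "AATS7s": -0.0831,
   "MATS2c": -3.6745,
   "SpMin3_Bhi": -8.2998,
   "MDEC-33": 0.2438
  }
 },
 "model3": {
  "name": "model3",
  "provenance": "published reference model 3 (uracil-coumarin MCF7 series)",
  "intercept": 18.2893,
  "coefficients": {
   "MATS2c": -3.1558,
   "SpMin3_Bhi": -8.6164,
   "ETA_EtaP_F": -0.3147,
   "MDEC-33": 0.2471
  }
 },
 "model4": {
  "name": "model4",
  "provenance": "published reference model 4 (uracil-coumarin MCF7 series)",
  "intercept": 20.1355,
  "coefficients": {
   "MATS2c": -2.8197,
   "SpMin3_Bhi": -9.3329,
   "IC1": -0.3066,
   "MDEC-33": 0.271
  }
 }
}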
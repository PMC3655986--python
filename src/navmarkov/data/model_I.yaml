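name: model_I
states:
- C1
- C2
- C3
- O
- I11
- I12
- I13
- I14
conducting: O
transitions:
- from: C1
  to: C2
  law: scaled
  param: alpha1
  by: c
  power: 1
- from: C2
  to: C1
  law: exp
  param: beta1
- from: C2
  to: C3
  law: exp
  param: alpha2
- from: C3
  to: C2
  law: exp
  param: beta2
- from: C3
  to: O
  law: scaled
  param: alpha1
  by: c
  power: 3
- from: O
  to: C3
  law: balance
  cycle:
  - C3
  - O
  - I14
  - I13
  - I12
  - I11
  - C1
  - C2
  - C3
- from: O
  to: I14
  law: exp
  param: rho2
- from: I14
  to: O
  law: scaled
  param: phi2
  by: c
  power: 1
- from: I11
  to: I12
  law: exp
  param: alpha1
- from: I12
  to: I11
  law: scaled
  param: beta1
  by: c
  power: -2
- from: I12
  to: I13
  law: scaled
  param: alpha2
  by: c
  power: -1
- from: I13
  to: I12
  law: scaled
  param: beta2
  by: c
  power: -3
- from: I13
  to: I14
  law: scaled
  param: alpha1
  by: c
  power: 2
- from: I14
  to: I13
  law: scaled
  param: beta2
  by: c
  power: -2
- from: I11
  to: C1
  law: exp
  param: phi1
- from: C1
  to: I11
  law: scaled
  param: rho1
  by: c
  power: 1
- from: I12
  to: C2
  law: exp
  param: phi2
- from: C2
  to: I12
  law: sigmoid
  param: rho1
- from: I13
  to: C3
  law: scaled
  param: phi2
  by: c
  power: 1
- from: C3
  to: I13
  law: sigmoid
  param: rho1
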
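# Bundled heart-disease feature schema (version 1).
# 13 predictors: 5 numeric with plausible clinical intervals, 8 integer-coded
# nominals; binary target (1 = disease present).  thal=0 is an accepted code
# but is counted as a missingness indicator by the validator.
version: "1"
predictors:
  - name: age
    kind: numeric
    domain: {low: 1.0, high: 120.0}
  - name: sex
    kind: nominal
    codes: [0, 1]
  - name: cp
    kind: nominal
    codes: [0, 1, 2, 3]
  - name: trestbps
    kind: numeric
    domain: {low: 60.0, high: 260.0}
  - name: chol
    kind: numeric
    domain: {low: 80.0, high: 700.0}
  - name: fbs
    kind: nominal
    codes: [0, 1]
  - name: restecg
    kind: nominal
    codes: [0, 1, 2]
  - name: thalach
    kind: numeric
    domain: {low: 50.0, high: 250.0}
  - name: exang
    kind: nominal
    codes: [0, 1]
  - name: oldpeak
    kind: numeric
    domain: {low: 0.0, high: 10.0}
  - name: slope
    kind: nominal
    codes: [0, 1, 2]
  - name: ca
    kind: nominal
    codes: [0, 1, 2, 3]
  - name: thal
    kind: nominal
    codes: [0, 1, 2, 3]
target:
  name: target
  kind: nominal
  codes: [0, 1]
missing_codes:
  thal: [0]
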
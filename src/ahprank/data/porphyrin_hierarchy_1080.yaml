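# Five-criterion variant of the porphyrin metalation hierarchy: reaction
# temperature promoted to an independent criterion with the three set
# points used in the study, giving the full 6 x 3 x 5 x 3 x 4 = 1080
# combination design space. Temperature priorities and weight are imputed
# (uniform / nominal): the study's AHP hierarchy never weighted
# temperature separately.
goal: Maximize metalloporphyrin yield (temperature as a fifth criterion)

criteria_weights:
  priorities:
    metal_salt: 331/1100
    mole_ratio: 331/1100
    solvent: 237/1100
    temperature: 100/1100
    duration: 101/1100

criteria:
  - name: metal_salt
    alternatives: [Pd(acac)2, Pd(OAc)2, PdCl2, Pt(acac)2, PtCl2, K2PtCl4]
    priorities:
      Pd(acac)2: 0.437
      Pd(OAc)2: 0.251
      PdCl2: 0.173
      Pt(acac)2: 0.050
      PtCl2: 89/2000
      K2PtCl4: 89/2000
    imputed: [PtCl2, K2PtCl4]

  - name: mole_ratio
    alternatives: ["1:3", "1:2.5", "1:2"]
    matrix:
      - [1, 9, 9]
      - [1/9, 1, 1]
      - [1/9, 1, 1]

  - name: solvent
    alternatives: [NMP, PhCN, Acetic acid, Pyridine, Chloroform-Methanol]
    priorities:
      NMP: 0.404
      PhCN: 0.219
      Acetic acid: 377/3000
      Pyridine: 377/3000
      Chloroform-Methanol: 377/3000
    imputed: [Acetic acid, Pyridine, Chloroform-Methanol]

  - name: temperature
    alternatives: [110 C, 180 C, 191 C]
    priorities:
      110 C: 1/3
      180 C: 1/3
      191 C: 1/3
    imputed: [110 C, 180 C, 191 C]

  - name: duration
    alternatives: [1 day, 45 min, 30 min, 15 min]
    priorities:
      1 day: 0.672
      45 min: 0.142
      30 min: 0.142
      15 min: 0.043
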
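# Porphyrin metalation study: AHP hierarchy for Pd(II)/Pt(II) insertion
# into free-base porphyrin.
#
# Criteria weights and most alternative priorities are the study's printed
# values (the underlying judgment matrices were never published). The
# mole-ratio criterion is the exception: its priorities (81.8/9.1/9.1) are
# exactly the eigenvector of the unique consistent strict-Saaty matrix
# below, so that matrix is reconstructed and shipped as such.
#
# Alternatives whose individual priorities were never printed (PtCl2 and
# K2PtCl4 among metal salts; acetic acid, pyridine and chloroform-methanol
# among solvents) share the leftover probability mass evenly and are
# flagged as imputed. Temperature is carried as an attribute of the
# solvent/duration choice here; see porphyrin_hierarchy_1080.yaml for the
# variant that treats it as a fifth criterion.
goal: Maximize metalloporphyrin yield for Pd(II)/Pt(II) insertion into free-base porphyrin

criteria_weights:
  priorities:
    metal_salt: 0.331
    mole_ratio: 0.331
    solvent: 0.237
    duration: 0.101

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

  - name: duration
    alternatives: [1 day, 45 min, 30 min, 15 min]
    priorities:
      1 day: 0.672
      45 min: 0.142
      30 min: 0.142
      15 min: 0.043
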
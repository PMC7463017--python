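{
  "groups": {
    "eec_stage_i": {
      "n": 57,
      "residual_excluded": 0,
      "counts": {
        "lymphadenectomy": 8,
        "radiotherapy": 15,
        "chemotherapy": 0,
        "figo_i": 57,
        "figo_ii": 0,
        "figo_iii": 0,
        "figo_iv": 0,
        "grade_1_2": 51,
        "grade_3": 6,
        "mi_lt_half": 42,
        "mi_ge_half": 15,
        "lvsi_no": 46,
        "lvsi_yes": 11,
        "recurrence_yes": 8,
        "recurrence_distant": 5,
        "recurrence_no": 49,
        "ec_death_yes": 4,
        "ec_death_no": 53
      },
      "printed_percent": {
        "lymphadenectomy": 14,
        "radiotherapy": 26,
        "figo_i": 100,
        "grade_1_2": 89,
        "grade_3": 11,
        "mi_lt_half": 74,
        "mi_ge_half": 26,
        "lvsi_no": 81,
        "lvsi_yes": 19,
        "recurrence_yes": 14,
        "recurrence_distant": 9,
        "recurrence_no": 86,
        "ec_death_yes": 7,
        "ec_death_no": 93
      }
    },
    "eec_stage_ii_iv": {
      "n": 12,
      "residual_excluded": 1,
      "counts": {
        "lymphadenectomy": 7,
        "radiotherapy": 10,
        "chemotherapy": 3,
        "figo_i": 0,
        "figo_ii": 4,
        "figo_iii": 5,
        "figo_iv": 3,
        "grade_1_2": 7,
        "grade_3": 5,
        "mi_lt_half": 3,
        "mi_ge_half": 9,
        "lvsi_no": 3,
        "lvsi_yes": 9,
        "recurrence_yes": 6,
        "recurrence_distant": 6,
        "recurrence_no": 5,
        "ec_death_yes": 5,
        "ec_death_no": 7
      },
      "printed_percent": {
        "lymphadenectomy": 58,
        "radiotherapy": 83,
        "chemotherapy": 25,
        "figo_ii": 33,
        "figo_iii": 42,
        "figo_iv": 25,
        "grade_1_2": 58,
        "grade_3": 42,
        "mi_lt_half": 25,
        "mi_ge_half": 75,
        "lvsi_no": 25,
        "lvsi_yes": 75,
        "recurrence_yes": 55,
        "recurrence_distant": 55,
        "recurrence_no": 46,
        "ec_death_yes": 42,
        "ec_death_no": 58
      }
    },
    "usc": {
      "n": 14,
      "residual_excluded": 4,
      "counts": {
        "lymphadenectomy": 12,
        "radiotherapy": 5,
        "chemotherapy": 8,
        "figo_i": 4,
        "figo_ii": 0,
        "figo_iii": 3,
        "figo_iv": 7,
        "grade_1_2": 0,
        "grade_3": 14,
        "mi_lt_half": 6,
        "mi_ge_half": 8,
        "lvsi_no": 5,
        "lvsi_yes": 8,
        "recurrence_yes": 6,
        "recurrence_distant": 5,
        "recurrence_no": 4,
        "ec_death_yes": 8,
        "ec_death_no": 6
      },
      "printed_percent": {
        "lymphadenectomy": 86,
        "radiotherapy": 36,
        "chemotherapy": 57,
        "figo_i": 29,
        "figo_iii": 21,
        "figo_iv": 50,
        "grade_3": 100,
        "mi_lt_half": 43,
        "mi_ge_half": 57,
        "lvsi_no": 36,
        "lvsi_yes": 57,
        "recurrence_yes": 60,
        "recurrence_distant": 60,
        "recurrence_no": 40,
        "ec_death_yes": 57,
        "ec_death_no": 43
      }
    }
  },
  "notes": [
    "USC recurrence is reported among the 10 patients without residual disease (4 excluded); EEC stage II-IV among 11 (1 excluded).",
    "Data erratum, kept verbatim: USC distant recurrence is printed as 60% although 5/10 = 50%.",
    "Data erratum, kept verbatim: USC LVSI rows (5 no + 8 yes) sum to 13 of 14 patients."
  ]
}
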
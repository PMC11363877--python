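{
  "version": "0.1.0",
  "seed": 3,
  "config": {
    "frame": "<path>",
    "t": 4531429,
    "adult_pop": 2820541,
    "e0": 321337,
    "n_known": 48,
    "rrt": {
      "p1": 0.8,
      "p2": 0.2
    },
    "bootstrap": {
      "B": 200,
      "level": 0.95,
      "rds_flavor": "chain"
    }
  },
  "digest": {
    "n_general": 1200,
    "n_general_excluded": 76,
    "n_rds": 200
  },
  "estimates": {
    "m0": {
      "point": 8.486654804270463,
      "ci_low": 8.120974199288257,
      "ci_high": 8.78672153024911
    },
    "c": {
      "point": 119.67707949305714,
      "ci_low": 114.52032599702676,
      "ci_high": 123.90855941611204
    },
    "m1": {
      "point": 0.8330436327188296,
      "ci_low": 0.6923888367637829,
      "ci_high": 0.9783999949922664
    },
    "e1": {
      "point": 31542.197483073163,
      "ci_low": 26406.005413801035,
      "ci_high": 37152.46733304922
    },
    "c_H": {
      "point": 87.14910271770758,
      "ci_low": 75.81977804276724,
      "ci_high": 100.41040854840583
    },
    "aware": {
      "point": 78.26497088726165,
      "ci_low": 66.34013917437146,
      "ci_high": 90.1360561302582
    },
    "delta": {
      "point": 0.7282021176223923,
      "ci_low": 0.6307403471745557,
      "ci_high": 0.8355045824103344
    },
    "tau": {
      "point": 0.8980582524271844,
      "ci_low": 0.8719348610511374,
      "ci_high": 0.9219132335450125
    },
    "adjusted": {
      "point": 48232.025550805505,
      "ci_low": 38294.527476797615,
      "ci_high": 59880.14461506163
    },
    "prevalence": {
      "point": 1.7100274575269605,
      "ci_low": 1.3577015004141977,
      "ci_high": 2.123002098358493
    },
    "m1_floored": {
      "point": 0.8330436327188296,
      "ci_low": null,
      "ci_high": null
    }
  },
  "diagnostics": {
    "name_proportion_r": 0.7529801325825016,
    "name_proportion_p": 6.675075305376447e-10,
    "name_proportion_r_general": 0.9374786653596567,
    "name_proportion_p_general": 1.0235283930475752e-22,
    "rrt_var_mu_s": 0.005447552387573729
  },
  "warnings": []
}
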
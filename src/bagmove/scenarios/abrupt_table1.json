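[
 {
  "name": "abrupt_high_n300",
  "path": "abrupt",
  "error": "high",
  "n": 300,
  "R": 500,
  "quantities": [
   {
    "name": "d8",
    "kind": "displacement",
    "params": {
     "t_a": 10080.0,
     "t_b": 11520.0
    }
   },
   {
    "name": "p200",
    "kind": "proportion_within",
    "params": {
     "r": 200.0,
     "geometry": "roadways",
     "grid_step": 5.0
    }
   }
  ],
  "learner_kind": "knn",
  "k": null,
  "k_grid": [
   3,
   5,
   9,
   15
  ],
  "B": 100,
  "B_select": 20,
  "scheme": "blocked",
  "n_blocks": null,
  "level": 0.95,
  "seed": 2025,
  "path_config": {},
  "ci_mode": "ensemble"
 },
 {
  "name": "abrupt_high_n100",
  "path": "abrupt",
  "error": "high",
  "n": 100,
  "R": 500,
  "quantities": [
   {
    "name": "d8",
    "kind": "displacement",
    "params": {
     "t_a": 10080.0,
     "t_b": 11520.0
    }
   },
   {
    "name": "p200",
    "kind": "proportion_within",
    "params": {
     "r": 200.0,
     "geometry": "roadways",
     "grid_step": 5.0
    }
   }
  ],
  "learner_kind": "knn",
  "k": null,
  "k_grid": [
   3,
   5,
   9,
   15
  ],
  "B": 100,
  "B_select": 20,
  "scheme": "blocked",
  "n_blocks": null,
  "level": 0.95,
  "seed": 2026,
  "path_config": {},
  "ci_mode": "ensemble"
 },
 {
  "name": "abrupt_low_n300",
  "path": "abrupt",
  "error": "low",
  "n": 300,
  "R": 500,
  "quantities": [
   {
    "name": "d8",
    "kind": "displacement",
    "params": {
     "t_a": 10080.0,
     "t_b": 11520.0
    }
   },
   {
    "name": "p200",
    "kind": "proportion_within",
    "params": {
     "r": 200.0,
     "geometry": "roadways",
     "grid_step": 5.0
    }
   }
  ],
  "learner_kind": "knn",
  "k": null,
  "k_grid": [
   3,
   5,
   9,
   15
  ],
  "B": 100,
  "B_select": 20,
  "scheme": "blocked",
  "n_blocks": null,
  "level": 0.95,
  "seed": 2027,
  "path_config": {},
  "ci_mode": "ensemble"
 },
 {
  "name": "abrupt_low_n100",
  "path": "abrupt",
  "error": "low",
  "n": 100,
  "R": 500,
  "quantities": [
   {
    "name": "d8",
    "kind": "displacement",
    "params": {
     "t_a": 10080.0,
     "t_b": 11520.0
    }
   },
   {
    "name": "p200",
    "kind": "proportion_within",
    "params": {
     "r": 200.0,
     "geometry": "roadways",
     "grid_step": 5.0
    }
   }
  ],
  "learner_kind": "knn",
  "k": null,
  "k_grid": [
   3,
   5,
   9,
   15
  ],
  "B": 100,
  "B_select": 20,
  "scheme": "blocked",
  "n_blocks": null,
  "level": 0.95,
  "seed": 2028,
  "path_config": {},
  "ci_mode": "ensemble"
 }
]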
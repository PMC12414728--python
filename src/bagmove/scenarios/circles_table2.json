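[
 {
  "name": "circles_high_n150",
  "path": "circles",
  "error": "high",
  "n": 150,
  "R": 500,
  "quantities": [
   {
    "name": "dbar",
    "kind": "mean_displacement",
    "params": {
     "boundaries": [
      0.0,
      1500.0,
      60.0
     ]
    }
   },
   {
    "name": "p100",
    "kind": "proportion_within",
    "params": {
     "r": 100.0,
     "geometry": "turbines",
     "grid_step": 1.0
    }
   }
  ],
  "learner_kind": "weighted_knn",
  "k": 3,
  "k_grid": null,
  "B": 100,
  "B_select": 20,
  "scheme": "blocked",
  "n_blocks": null,
  "level": 0.95,
  "seed": 4025,
  "path_config": {},
  "ci_mode": "ensemble"
 },
 {
  "name": "circles_high_n30",
  "path": "circles",
  "error": "high",
  "n": 30,
  "R": 500,
  "quantities": [
   {
    "name": "dbar",
    "kind": "mean_displacement",
    "params": {
     "boundaries": [
      0.0,
      1500.0,
      60.0
     ]
    }
   },
   {
    "name": "p100",
    "kind": "proportion_within",
    "params": {
     "r": 100.0,
     "geometry": "turbines",
     "grid_step": 1.0
    }
   }
  ],
  "learner_kind": "weighted_knn",
  "k": 3,
  "k_grid": null,
  "B": 100,
  "B_select": 20,
  "scheme": "blocked",
  "n_blocks": null,
  "level": 0.95,
  "seed": 4026,
  "path_config": {},
  "ci_mode": "ensemble"
 },
 {
  "name": "circles_low_n150",
  "path": "circles",
  "error": "low",
  "n": 150,
  "R": 500,
  "quantities": [
   {
    "name": "dbar",
    "kind": "mean_displacement",
    "params": {
     "boundaries": [
      0.0,
      1500.0,
      60.0
     ]
    }
   },
   {
    "name": "p100",
    "kind": "proportion_within",
    "params": {
     "r": 100.0,
     "geometry": "turbines",
     "grid_step": 1.0
    }
   }
  ],
  "learner_kind": "weighted_knn",
  "k": 3,
  "k_grid": null,
  "B": 100,
  "B_select": 20,
  "scheme": "blocked",
  "n_blocks": null,
  "level": 0.95,
  "seed": 4027,
  "path_config": {},
  "ci_mode": "ensemble"
 },
 {
  "name": "circles_low_n30",
  "path": "circles",
  "error": "low",
  "n": 30,
  "R": 500,
  "quantities": [
   {
    "name": "dbar",
    "kind": "mean_displacement",
    "params": {
     "boundaries": [
      0.0,
      1500.0,
      60.0
     ]
    }
   },
   {
    "name": "p100",
    "kind": "proportion_within",
    "params": {
     "r": 100.0,
     "geometry": "turbines",
     "grid_step": 1.0
    }
   }
  ],
  "learner_kind": "weighted_knn",
  "k": 3,
  "k_grid": null,
  "B": 100,
  "B_select": 20,
  "scheme": "blocked",
  "n_blocks": null,
  "level": 0.95,
  "seed": 4028,
  "path_config": {},
  "ci_mode": "ensemble"
 }
]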
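{
  "stages": [
    {
      "stage": "simulate-plate",
      "outputs": {"plate": "demo_plate.png", "landmarks": "demo_landmarks.json", "truth": "demo_truth.json"},
      "params": {"punctum_density": 0.02, "rotation_asymmetry": 0.5, "speckle_rate": 0.0005, "tone_gradient": 0.15},
      "seed": 2
    },
    {
      "stage": "isolate",
      "inputs": {"plate": "demo_plate.png"},
      "outputs": {"density": "demo_density.png"},
      "params": {"k_frac": 0.87, "sigma_px": 10.0, "tone_correction": 1}
    },
    {
      "stage": "symmetrize",
      "inputs": {"density": "demo_density.png", "landmarks": "demo_landmarks.json"},
      "outputs": {"symmetric": "demo_symmetric.png"},
      "params": {"reference_side": "left", "blend": "max"}
    },
    {
      "stage": "composite",
      "inputs": {
        "density0": "demo_symmetric.png", "landmarks0": "demo_landmarks.json",
        "density1": "demo_density.png", "landmarks1": "demo_landmarks.json"
      },
      "outputs": {"composite": "demo_composite.png"},
      "params": {"alpha": 0.33, "blend": "additive"}
    },
    {
      "stage": "simulate-matrix",
      "outputs": {"nexus": "demo_matrix.nex", "tree": "demo_true_tree.nwk"},
      "params": {"n_taxa": 7, "n_chars": 60, "branch_length": 0.15, "missing_frac": 0.05},
      "seed": 11
    },
    {
      "stage": "pars",
      "inputs": {"nexus": "demo_matrix.nex"},
      "outputs": {"results": "demo_parsimony.json"},
      "params": {"n_replicates": 20},
      "seed": 42
    },
    {
      "stage": "mklnl",
      "inputs": {"nexus": "demo_matrix.nex", "tree": "demo_true_tree.nwk"},
      "outputs": {"results": "demo_mkv.json"},
      "params": {"conditioning": "variable"}
    }
  ]
}
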
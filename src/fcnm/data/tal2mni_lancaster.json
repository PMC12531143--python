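{
  "name": "lancaster",
  "note": "Pooled icbm_spm2tal affine (MNI->Talairach); the tal->mni transform is its inverse, computed at load. Swappable: any 4x4 row-major matrix mapping MNI->Talairach may replace it.",
  "direction": "mni_to_tal",
  "matrix": [
    [0.9254, 0.0024, -0.0118, -1.0207],
    [-0.0048, 0.9316, -0.0871, -1.7667],
    [0.0152, 0.0883, 0.8924, 4.0926],
    [0.0, 0.0, 0.0, 1.0]
  ]
}
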
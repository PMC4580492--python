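# Minimal pipeline configuration: synthetic six-play input scaled to 100
# catchments per play.  Paths are resolved relative to this file.
seed: 1
output_dir: out
synthetic:
  plays:
    Bakken: {n_catchments: 100}
    Barnett: {n_catchments: 100}
    Fayetteville: {n_catchments: 100}
    Hilliard: {n_catchments: 100}
    Marcellus: {n_catchments: 100}
    Mowry: {n_catchments: 100}
screening:
  threshold: 0.6
clustering:
  k_range: [2, 6]
  max_points: 300
comparison:
  alpha: 0.016
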
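alternative,accuracy,precision,recall,f1
"image_only (lr=0.001, adam)",93.85,79.09,93.85,85.84
"image_only (lr=0.0001, adam)",83.85,82.73,83.85,83.29
"image_only (lr=0.001, sgd)",86.35,86.35,86.35,86.35
"image_only (lr=0.0001, sgd)",86.92,83.24,86.92,85.04
"cell_density_only (lr=0.001, adam)",95.77,97.08,95.77,96.42
"cell_density_only (lr=0.0001, adam)",98.08,92.06,98.08,94.97
"cell_density_only (lr=0.001, sgd)",96.35,94.0,96.35,95.16
"cell_density_only (lr=0.0001, sgd)",97.5,95.3,97.5,96.39
"fused (lr=0.001, adam)",96.73,97.1,96.73,96.92
"fused (lr=0.0001, adam)",97.69,91.7,97.69,94.6
"fused (lr=0.001, sgd)",96.35,95.98,96.35,96.16
"fused (lr=0.0001, sgd)",97.88,94.09,97.88,95.95
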
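alternative,accuracy,precision,recall,f1
"image_only (lr=0.001, adam)",85.9,91.76,85.9,88.74
"image_only (lr=0.0001, adam)",82.6,85.42,82.6,83.99
"image_only (lr=0.001, sgd)",92.51,78.65,92.51,85.02
"image_only (lr=0.0001, sgd)",80.4,84.88,80.4,82.58
"cell_density_only (lr=0.001, adam)",93.61,97.93,93.61,95.72
"cell_density_only (lr=0.0001, adam)",94.05,96.39,94.05,95.21
"cell_density_only (lr=0.001, sgd)",91.63,98.81,91.63,95.09
"cell_density_only (lr=0.0001, sgd)",97.58,93.66,97.58,95.58
"fused (lr=0.001, adam)",97.8,97.16,97.8,97.48
"fused (lr=0.0001, adam)",95.81,97.1,95.81,96.45
"fused (lr=0.001, sgd)",91.41,99.05,91.41,95.07
"fused (lr=0.0001, sgd)",94.93,97.29,94.93,96.1
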
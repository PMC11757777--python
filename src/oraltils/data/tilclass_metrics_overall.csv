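alternative,accuracy,precision,recall,f1
"image_only (lr=0.001, adam)",83.11,83.66,83.11,83.02
"image_only (lr=0.0001, adam)",79.13,79.33,79.13,79.22
"image_only (lr=0.001, sgd)",81.13,80.46,81.13,80.44
"image_only (lr=0.0001, sgd)",79.22,79.45,79.22,79.3
"cell_density_only (lr=0.001, adam)",94.91,95.2,94.91,95.02
"cell_density_only (lr=0.0001, adam)",93.5,93.65,93.5,93.52
"cell_density_only (lr=0.001, sgd)",93.6,94.06,93.6,93.77
"cell_density_only (lr=0.0001, sgd)",94.81,94.67,94.81,94.69
"fused (lr=0.001, adam)",96.37,96.34,96.37,96.35
"fused (lr=0.0001, adam)",94.02,94.15,94.02,94.03
"fused (lr=0.001, sgd)",94.3,94.82,94.3,94.48
"fused (lr=0.0001, sgd)",94.76,94.89,94.76,94.8
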
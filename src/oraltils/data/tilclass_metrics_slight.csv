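alternative,accuracy,precision,recall,f1
"image_only (lr=0.001, adam)",69.57,80.13,69.57,74.48
"image_only (lr=0.0001, adam)",70.93,69.85,70.93,70.38
"image_only (lr=0.001, sgd)",64.53,76.38,64.53,69.96
"image_only (lr=0.0001, sgd)",70.35,70.21,70.35,70.28
"cell_density_only (lr=0.001, adam)",95.35,90.61,95.35,92.92
"cell_density_only (lr=0.0001, adam)",88.37,92.49,88.37,90.39
"cell_density_only (lr=0.001, sgd)",92.83,89.37,92.83,91.06
"cell_density_only (lr=0.0001, sgd)",89.34,95.05,89.34,92.11
"fused (lr=0.001, adam)",94.57,94.76,94.57,94.67
"fused (lr=0.0001, adam)",88.57,93.65,88.57,91.04
"fused (lr=0.001, sgd)",95.16,89.44,95.16,92.21
"fused (lr=0.0001, sgd)",91.47,93.28,91.47,92.37
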
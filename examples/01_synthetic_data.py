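"""Generate seeded histology-like tiles and graded fields of view.

Prints the realized per-class nucleus pixel fractions of one tile and the
TIL fraction of one field of view per infiltration grade — the quantity
that defines the three classes (none-to-very-less / slight /
moderate-to-marked via the band edges).
"""

from oraltils.synthetic import SynthConfig, generate_cell_tile, generate_fov_sample

config = SynthConfig(tile_size=64, cell_radius_range=(3, 6), fov_size=128)

tile = generate_cell_tile(config, seed=0)
print("one 64x64 tile, realized vs target nucleus pixel fractions:")
for cls, name in [(1, "tumour"), (2, "tils"), (3, "stroma"), (4, "others")]:
    realized = (tile.mask == cls).mean()
    target = config.per_class_target_fraction.get(cls, 0.0)
    print(f"  {name:7s} realized {realized:.3f}  target {target:.3f}")
print(f"  distance map range [{tile.distance.min():.2f}, {tile.distance.max():.2f}]")

print("\n128x128 fields of view, TIL pixel fraction per grade "
      f"(band edges {config.til_band_edges}):")
for grade, name in enumerate(["none_to_very_less", "slight", "moderate_to_marked"]):
    fov = generate_fov_sample(config, grade, seed=7)
    print(f"  grade {grade} ({name:18s}) TIL fraction {(fov.mask == 2).mean():.3f}")
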
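"""Entropy-weighted TOPSIS ranking of the bundled classifier comparison.

Loads the reference decision matrices (accuracy/precision/recall/F1 of
twelve classifier configurations per infiltration grade and overall),
computes information-entropy criterion weights and TOPSIS closeness, and
prints the top of each ranking.  Closeness 1 means the configuration
coincides with the ideal on every criterion.
"""

from oraltils.evaluation import REFERENCE_BLOCKS, entropy_weights, load_reference_matrix, rank_models

for block in REFERENCE_BLOCKS:
    matrix = load_reference_matrix(block)
    weights = entropy_weights(matrix)
    ranking = rank_models(matrix)
    print(f"\n{block}  (criterion weights: "
          + ", ".join(f"{c}={w:.3f}" for c, w in weights.items()) + ")")
    for name, row in ranking.head(3).iterrows():
        print(f"  rank {int(row['rank'])}: closeness {row['closeness']:.3f}  {name}")
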
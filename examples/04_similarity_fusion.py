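"""Integrating several similarity matrices into one.

Three noisy views of the same drug-drug similarity are fused by each of
the four integrators; SNF cross-diffusion reinforces neighbourhoods the
views agree on.
"""

import numpy as np

from lmdti import FusionConfig, SimilarityMatrix, fuse_similarities

rng = np.random.default_rng(0)
ids = [f"D{i}" for i in range(8)]
truth = np.where(np.add.outer(np.arange(8) % 2, np.arange(8) % 2) % 2 == 0, 0.8, 0.2)

views = []
for _ in range(3):
    noisy = np.clip(truth + rng.normal(0, 0.1, (8, 8)), 0, 1)
    noisy = (noisy + noisy.T) / 2
    np.fill_diagonal(noisy, 1.0)
    views.append(SimilarityMatrix("drug", ids, noisy))

for method in ("AVG", "GeoM", "MAX", "SNF"):
    fused = fuse_similarities(views, FusionConfig(method=method, snf_neighbors=3, snf_iterations=10))
    same = fused.values[0, 2]  # both even-indexed: same block
    cross = fused.values[0, 1]  # even vs odd: different block
    print(f"{method:>4}: same-block sim {same:.3f}  cross-block sim {cross:.3f}")
# All methods preserve the block contrast; SNF's min-max rescaling spreads
# the fused values over the full [0, 1] range.
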
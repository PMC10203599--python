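"""Meta-path scores on a 3-drug / 1-target toy network.

d2 has no direct edge to t1, but two drug-drug-target paths reach it:
through d1 (similarity 0.5) and through d3 (similarity 0.4).  The Sum
score adds the two path products (0.9); the Max keeps the best (0.5).
"""

from lmdti import compute_path_scores, generate_toy_fixture, pair_path_features

sub = generate_toy_fixture()
scores = compute_path_scores(sub, exclude_direct=True)

names = [f"{p}_{s}" for p in ("P1", "P2", "P3", "P4", "P5", "P6") for s in ("Sum", "Max")]
feats = pair_path_features(scores, sub.drug_ids.index("d2"), sub.target_ids.index("t1"))
print("pair (d2, t1):")
for name, value in zip(names, feats):
    print(f"  {name:>6} = {value:.3f}")
# Only the D-D-T structure has any path for this pair, so the other ten
# features are zero; a classifier sees exactly how (and how strongly) a
# candidate pair is connected through the network.
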
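"""Validation statistics: agreement tables, correlation, t tests, loss.

Compares two allocations of the same beads level by level (as when a
human rater checks the automated workflow), then shows the count
statistics used to qualify the detector against manual counts.
"""

import numpy as np

from embolocate import synthetic_data as sd
from embolocate.validation_stats import (
    agreement_by_level,
    loss_percentage,
    pearson_r,
    percent_agreement,
    t_test,
)

ontology, _ = sd.generate_toy_atlas(depth=6, branching=2, shape=(32, 32, 32),
                                    voxel_size_um=100.0, seed=8)

# reference allocation: 60 beads in random leaves; the "test" rater gets a
# few of them wrong by sliding to a sibling region
rng = np.random.default_rng(0)
leaves = [n for n in ontology.nodes if ontology.is_leaf(n)]
reference = {i: int(rng.choice(leaves)) for i in range(60)}
test = dict(reference)
for i in rng.choice(60, 6, replace=False):
    siblings = ontology.children(ontology.parent(reference[i])) or leaves
    test[int(i)] = int(rng.choice([s for s in siblings if s != reference[i]] or leaves))

table = agreement_by_level(reference, test, ontology, levels=range(1, 7))
print(table[["level", "agreement", "not_at_level", "sum_of_agreement",
             "disagreement", "sum_of_agreement_pct"]].to_string(index=False))
print("sum of agreement = correctly allocated up to that level; it can only")
print("fall as the level deepens.")
print()

# detector qualification: per-section automated vs manual counts
n_sections = 65
manual = rng.poisson(5, n_sections)
automated = np.clip(manual + rng.integers(-1, 2, n_sections), 0, None)
r, r2, p = pearson_r(manual, automated)
t, df, pt, sig = t_test(automated, manual, mode="paired")
print(f"manual vs automated counts over {n_sections} sections:")
print(f"  r = {r:.3f} (r^2 = {r2:.3f}, p = {p:.2e}); "
      f"paired t({df}) = {t:.3f}, p = {pt:.3f} -> "
      f"{'different' if sig else 'no significant difference'}")
print(f"  overall agreement if 995 of 1060 match: "
      f"{percent_agreement(995, 1060)}%")
print(f"  sectioning loss if 185 of 200 beads remain on slides: "
      f"{loss_percentage(200, 185)}%")
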
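"""Score a small synthetic decoy set and print the per-model ranking.

Generates a fixture tree (PDB decoys plus secondary-structure, accessibility
and contact predictions for each target), extracts the six feature penalties
for every model, combines them with the published weights, and prints the
ranking for one target. The native-derived decoy (m000) should come first.
"""

import tempfile
from pathlib import Path

from poorqa.pipeline import load_tree, pool_table
from poorqa.scoring import PUBLISHED_WEIGHTS
from poorqa.synthetic import FixtureSpec, write_fixture_tree

with tempfile.TemporaryDirectory() as tmp:
    root = Path(tmp)
    spec = FixtureSpec(n_targets=2, decoys_per_target=6, corruption_rate=0.0,
                       seed=11)
    targets = write_fixture_tree(root, spec, n_res=30, sasa_points=240)
    print(f"wrote fixture tree with targets: {targets}")

    pools = load_tree(root, sasa_points=240)
    table = pool_table(pools, PUBLISHED_WEIGHTS)

    first = table[table.target_id == targets[0]]
    cols = ["model_id", "rank", "E", "e_ss_h", "e_ss_e", "e_sa", "e_contact",
            "gdt_ts"]
    print(first[cols].to_string(index=False))
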
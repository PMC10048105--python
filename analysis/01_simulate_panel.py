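#!/usr/bin/env python
"""Generate the synthetic 18-gene okra-style CT experiment.

Draws one seeded realization of the full design — 3 tissues x 3 stresses
(cold, salt, drought) x 4 timepoints (0/6/12/24 h) x 3 biological
replicates = 108 samples — with HIS6, Eif and UBQ designated stable
(sigma = 0.2 cycles, no condition bias), a noise ladder over the rest, a
cold-induced TUB-a and a drought-repressed GAPDH. Writes the CT table,
design table, generating spec and ground truth under results/synthetic/.
"""

import json
from pathlib import Path

from refstab import okra_design_preset, simulate_ct, write_ct_table
from refstab.synthetic import save_spec

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = okra_design_preset(seed=SEED)
    table, design, truth = simulate_ct(spec)
    write_ct_table(table, OUT / "ct_wide.csv", layout="wide")
    design.table.reset_index(drop=True).to_csv(OUT / "design.csv", index=False)
    (OUT / "truth.json").write_text(json.dumps(truth.as_dict(), indent=2, sort_keys=True))
    save_spec(spec, OUT / "spec_used.yaml")
    print(f"simulated {table.n_genes()} genes x {table.n_samples()} samples")
    print(f"CT range: {table.ct.min().min():.2f} .. {table.ct.max().max():.2f}")
    print(f"designed stable set: {truth.stable_genes}")
    print(f"wrote {OUT}/ct_wide.csv, design.csv, truth.json, spec_used.yaml")


if __name__ == "__main__":
    main()
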
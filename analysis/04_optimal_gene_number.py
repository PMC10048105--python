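#!/usr/bin/env python
"""How many reference genes are enough? The V(n/n+1) decision.

Applies the pairwise-variation rule (smallest n with V(n/n+1) <= 0.15) to
(a) the published all-sample V series for the okra panel — V(2/3)=0.123,
V(3/4)=0.152, V(4/5)=0.141 — and (b) the V series computed on the
synthetic experiment from 01/03. Writes results/gene_number_decision.json.
"""

import json
import warnings
from pathlib import Path

from refstab import ct_to_quantity, genorm, read_ct_table, recommend_n

BASE = Path(__file__).resolve().parent.parent / "results"

PUBLISHED_V = {2: 0.123, 3: 0.152, 4: 0.141}


def main() -> None:
    n_pub, _ = recommend_n(PUBLISHED_V, threshold=0.15)
    print(f"published all-sample V series {PUBLISHED_V} -> n = {n_pub}")

    table, _ = read_ct_table(BASE / "synthetic" / "ct_wide.csv", layout="wide")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = genorm(ct_to_quantity(table))
    v_head = {n: round(v, 4) for n, v in list(res.v.items())[:4]}
    print(f"synthetic V series (first entries) {v_head} -> n = {res.recommended_n}")

    out = {
        "published_v_series": {str(k): v for k, v in PUBLISHED_V.items()},
        "published_recommended_n": n_pub,
        "synthetic_v_series": {str(k): round(v, 6) for k, v in res.v.items()},
        "synthetic_recommended_n": res.recommended_n,
        "threshold": 0.15,
    }
    (BASE / "gene_number_decision.json").write_text(json.dumps(out, indent=2))
    print(f"wrote {BASE}/gene_number_decision.json")


if __name__ == "__main__":
    main()
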
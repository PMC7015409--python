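#!/usr/bin/env python
"""Test every cell against Arrhenius-style reaction-order decay.

Rate laws (orders 0, 1, 2 and a general-order grid) are fitted on the real
weeks axis; a cell conforms when its best decay fit has k > 0 and a good fit
and the trajectory shows no interior maximum. The rise-then-fall 52C cells
are the expected non-conformers — the behaviour that motivates the quadratic
shelf-life construction.
"""

from pathlib import Path

import pandas as pd

from phytoshelf import conformity_test, read_samples, to_series

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    samples = read_samples(RESULTS / "synthetic_assays_noise_free.csv")
    rows = []
    cells = sorted(
        samples[["compound", "drying_temp_C", "condition"]]
        .drop_duplicates().itertuples(index=False, name=None)
    )
    for cell in cells:
        means = to_series(samples, cell, "per_time_means")
        v = conformity_test(means.time_weeks, means.y)
        b = v.best_order
        rows.append({
            "compound": cell[0], "drying_temp_C": cell[1], "condition": cell[2],
            "conforms": v.conforms, "reason": v.reason,
            "best_order_n": b.order_n if b else None,
            "k_per_week": b.k if b else None,
            "r2": b.r_squared if b else None,
        })
        print(f"{cell}: {'conforms' if v.conforms else 'NON-conforming'} — {v.reason}")
    out = RESULTS / "arrhenius_conformity.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
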
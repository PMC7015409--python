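#!/usr/bin/env python
"""Derive shelf-lives via the parabola-symmetry construction.

Prints the worked example on the one printed fitted parabola
(-0.0594 x^2 + 0.2275 x + 0.3876) — extremum 1.9150, roots (-1.2776, 5.1075),
x3 = 3.8300, antilog 3^3.83 ~ 67 weeks — then applies the same construction
to every positive-quadratic cell of the noise-free synthetic study.
"""

from pathlib import Path

import pandas as pd

from phytoshelf import (
    QuadraticModel, classify_relation, estimate, read_samples, to_series,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    printed = QuadraticModel(a=-0.0594, b=0.2275, c=0.3876,
                             r_squared=1.0, n_points=6, sse=0.0, sst=1.0)
    from phytoshelf.fitting import POSITIVE_QUADRATIC, RelationClass

    demo = estimate(RelationClass(POSITIVE_QUADRATIC, printed, x_max=5.0))
    print(f"worked example: extremum {demo.extremum_x:.4f}, "
          f"roots ({demo.root_neg:.4f}, {demo.root_pos:.4f}), "
          f"x3 {demo.x3:.4f}, shelf-life {demo.shelf_life_weeks:.1f} weeks")

    samples = read_samples(RESULTS / "synthetic_assays_noise_free.csv")
    rows = []
    cells = sorted(
        samples[["compound", "drying_temp_C", "condition"]]
        .drop_duplicates().itertuples(index=False, name=None)
    )
    for cell in cells:
        rel = classify_relation(to_series(samples, cell, "replicate_level"))
        sl = estimate(rel)
        rows.append({
            "compound": cell[0], "drying_temp_C": cell[1], "condition": cell[2],
            "label": rel.label, "predictable": sl.predictable,
            "x3": sl.x3, "shelf_life_weeks": sl.shelf_life_weeks,
            "extrapolated": sl.extrapolated, "reason": sl.reason,
        })
        if sl.predictable:
            flag = " (extrapolated beyond the 243-week grid)" if sl.extrapolated else ""
            print(f"{cell}: shelf-life {sl.shelf_life_weeks:.1f} weeks{flag}")
        else:
            print(f"{cell}: not predictable — {sl.reason}")
    out = RESULTS / "shelf_life.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
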
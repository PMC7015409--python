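#!/usr/bin/env python
"""Fit and classify the storage-time relation of every treatment cell.

Reads the assay tables written by 01_simulate_study.py and reports, per cell,
the OLS quadratic and linear fits on per-time means of the log3 axis and the
resulting relation label. The expected pattern: 52C-dried material shows real
structure (rise-then-fall parabolas; a linear decline for chilled cuA), 100C
material is flat.
"""

from pathlib import Path

import pandas as pd

from phytoshelf import classify_relation, read_samples, to_series

RESULTS = Path(__file__).resolve().parents[1] / "results"


def relation_table(samples: pd.DataFrame) -> pd.DataFrame:
    rows = []
    cells = sorted(
        samples[["compound", "drying_temp_C", "condition"]]
        .drop_duplicates().itertuples(index=False, name=None)
    )
    for cell in cells:
        rel = classify_relation(to_series(samples, cell, "replicate_level"))
        q, l = rel.quadratic, rel.linear
        rows.append({
            "compound": cell[0], "drying_temp_C": cell[1], "condition": cell[2],
            "label": rel.label, "anova_p": rel.anova_p,
            "quad_a": q.a if q else None, "quad_b": q.b if q else None,
            "quad_c": q.c if q else None, "quad_r2": q.r_squared if q else None,
            "lin_slope": l.slope if l else None, "lin_r2": l.r_squared if l else None,
        })
    return pd.DataFrame(rows)


def main() -> None:
    for tag, fname in [("noisy", "synthetic_assays.csv"),
                       ("noise_free", "synthetic_assays_noise_free.csv")]:
        samples = read_samples(RESULTS / fname)
        table = relation_table(samples)
        out = RESULTS / f"relations_{tag}.csv"
        table.to_csv(out, index=False)
        pattern = ", ".join(
            f"{r.compound}/{r.drying_temp_C}/{r.condition}={r.label}"
            for r in table.itertuples()
        )
        print(f"[{tag}] {pattern}")
        print(f"[{tag}] wrote {out}")


if __name__ == "__main__":
    main()
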
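# phytoshelf

Shelf-life analysis for cucurbitacin-containing phytonematicides — plant
extracts whose active ingredients (cucurbitacin A and B, ug/ml by HPLC) do
not decay the way the Arrhenius framework assumes. Under fixed storage
conditions their concentrations *rise before they fall*, so none of the
classical reaction orders (n = 0, 1, 2, x) fits and k-based shelf-life
prediction fails. This package implements the alternative: fit the storage
trajectory on a log3-transformed geometric time grid, and read the
shelf-life off the fitted parabola by symmetry.

For a positive quadratic y = ax² + bx + c (a < 0, b > 0) fitted on
x = log₃(weeks), the shelf-life coordinate is where the concentration
returns to its initial level c:

    x₂ = −b/2a            (vertex / extremum)
    x′ₙ, x′ₚ = (−b ± √(b² − 4ac)) / 2a     (roots)
    x₃ = x′ₚ − |x′ₙ| = −b/a = 2·x₂         (shelf-life coordinate)
    shelf-life = 3^x₃  real weeks          (base-3 antilog)

The package is organised as an analysis project: the library under
`src/phytoshelf/` (time encoding, OLS trajectory fits and relation typing,
the shelf-life construction, an Arrhenius reaction-order comparator, one-way
ANOVA with %TTV, a synthetic-data generator emulating the 2×2×2×6×10 storage
trial, and a CLI), with numbered drivers under `analysis/` that run the
study end to end and write tables under `results/`. It is aimed at
stability/shelf-life analysts who need the non-Arrhenius construction as
tested, reusable code.

## Worked example

```sh
$ phytoshelf demo
quadratic: y = -0.0594 x^2 + 0.2275 x + 0.3876
extremum (vertex)     x2 = 1.9150
roots                    (-1.2776, 5.1075)
shelf-life coordinate x3 = 3.8300  (= -b/a = 2 * extremum)
shelf-life            3^x3 = 67.2 weeks (~67 weeks)
concentration at x3   y3 = 0.3876 (= c, the initial level)
```

The parabola peaks at x₂ = 1.915 (≈ 8.2 weeks), crosses the x-axis at
−1.2776 and 5.1075, and returns to its initial concentration 0.3876 ug/ml at
x₃ = 3.83, i.e. after about 67 weeks of storage — the product's shelf-life
under these conditions. Monotone-decline and flat cells get
`predictable = False` with a reason instead of a number.

Run the full synthetic study:

```sh
python analysis/01_simulate_study.py     # 480-row assay table (+ noise-free copy)
python analysis/02_fit_relations.py      # per-cell fits and relation labels
python analysis/03_shelf_life.py         # shelf-life per positive-quadratic cell
python analysis/04_arrhenius_conformity.py
python analysis/05_anova_ttv.py
```

On the noise-free data this prints shelf-lives of 67.2 weeks
(cuA/52 °C/tropical), 825 weeks (cuB/52 °C/tropical, extrapolated beyond the
243-week grid) and 35 weeks (cuB/52 °C/chilled); the chilled cuA cell
declines monotonically (no prediction) and every 100 °C cell is flat. All
three rise-then-fall cells are flagged non-conforming to Arrhenius decay
("interior concentration maximum"), while the monotone chilled decline
conforms.

Or as one pipeline call:

```sh
phytoshelf generate --seed 1 --output assays.csv
phytoshelf analyze --input assays.csv --output report.json
```

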
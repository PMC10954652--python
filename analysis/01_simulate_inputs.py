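"""Generate the synthetic inputs used by the downstream analysis drivers.

Produces, under results/synthetic/: a two-date 120x120 landscape with four
zones and a prescribed transition structure (plus its realized ground
truth), a 30-respondent expert survey, zero-inflated milkweed plot
samples, and a 25-year seasonal greenness series with a known trend.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from habitatshift.change import ClassScheme
from habitatshift.raster import write_grid
from habitatshift.synthetic import (LandscapeSpec, SeriesSpec,
                                    gen_landscape_pair, gen_plot_samples,
                                    gen_seasonal_stack, gen_survey)
from habitatshift.trends import series_from_stacks

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 20240320

scheme = ClassScheme.from_labels(
    "synthetic4", ["shrub", "crop", "urban", "water"])
P = [[0.90, 0.05, 0.04, 0.01],
     [0.02, 0.95, 0.03, 0.00],
     [0.00, 0.00, 1.00, 0.00],
     [0.05, 0.00, 0.00, 0.95]]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    spec = LandscapeSpec(scheme, shape=(120, 120), mixing=(0.5, 0.25, 0.15, 0.1),
                         transition=tuple(map(tuple, P)), n_zones=4)
    g0, g1, truth = gen_landscape_pair(spec, seed=SEED)
    write_grid(OUT / "landscape_t0.csv", g0)
    write_grid(OUT / "landscape_t1.csv", g1)
    np.savetxt(OUT / "zones.csv", g0.zones, fmt="%d", delimiter=",")
    truth.area.to_csv(OUT / "true_transitions.csv")
    changed = 1 - np.trace(truth.area.values) / truth.area.values.sum()
    print(f"landscape: {g0.values.size} cells, {changed:.1%} changed class")

    survey = gen_survey({"shrub": 0.45, "crop": 0.30, "urban": 0.40,
                         "water": 0.10}, n_respondents=30, dispersion=0.15,
                        seed=SEED + 1)
    survey.to_csv(OUT / "survey.csv", index=False)
    print(f"survey: {survey['respondent_id'].nunique()} respondents x "
          f"{survey['class_id'].nunique()} classes")

    plots = gen_plot_samples(
        {"shrub": (0.80, {"lam": 6.0}), "crop": (0.91, {"lam": 2.0}),
         "urban": (0.75, {"mu": 9.0, "alpha": 1.2}),
         "grass": (0.60, {"mu": 25.0, "alpha": 0.9})},
        n_per_class=150, seed=SEED + 2)
    plots.to_csv(OUT / "plot_samples.csv", index=False)
    zf = plots.groupby("class_id")["density"].apply(lambda d: (d == 0).mean())
    print("plots: zero fractions", dict(zf.round(2)))

    rows = []
    for season, slope in (("fall", 0.0026), ("spring", 0.0)):
        stack, _ = gen_seasonal_stack(
            SeriesSpec(n_years=25, start_year=1997, slope=slope, intercept=0.45,
                       noise_sd=0.01, obs_per_season=11, season=season,
                       pixel_sd=0.02), seed=SEED + 3)
        series = series_from_stacks(stack, season)
        rows.append(pd.DataFrame({"variable": "ndvi", "season": season,
                                  "year": series.index, "value": series.values}))
    pd.concat(rows).to_csv(OUT / "seasonal_series.csv", index=False)
    print("series: 25-year fall (trending) and spring (null) greenness written")


if __name__ == "__main__":
    main()
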
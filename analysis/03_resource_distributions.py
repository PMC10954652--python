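"""Per-class resource distributions.

Aggregates the synthetic expert survey into normal score distributions,
translates them to a second classification scheme through a random
agreement matrix, fits zero-inflated count families to the synthetic
milkweed plots (AIC selection), and applies the sparse-data special
rules. Writes the distribution registries under results/.
"""

from pathlib import Path

import pandas as pd

from habitatshift.resources import (aggregate_survey, apply_special_rules,
                                    crosswalk_distributions,
                                    fit_count_distribution, registry_to_frame)
from habitatshift.synthetic import gen_agreement_matrix

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SYN = RESULTS / "synthetic"
SEED = 20240320


def main() -> None:
    survey = pd.read_csv(SYN / "survey.csv")
    classes = sorted(survey["class_id"].unique())
    dists = {c: aggregate_survey(survey, c, "spring", "nectar") for c in classes}
    registry_to_frame(dists).to_csv(RESULTS / "survey_registry.csv", index=False)
    print("survey scores:", {c: round(d.mean, 3) for c, d in dists.items()})

    am = gen_agreement_matrix(3, len(classes), concentration=8.0, seed=SEED,
                              source_ids=classes,
                              target_ids=["t_shrubland", "t_agriculture",
                                          "t_developed"])
    target = crosswalk_distributions(dists, am, "spring", "nectar")
    registry_to_frame(target).to_csv(RESULTS / "crosswalked_registry.csv",
                                     index=False)
    print("crosswalked means:", {c: round(d.mean, 3) for c, d in target.items()})

    plots = pd.read_csv(SYN / "plot_samples.csv")
    fits = {c: fit_count_distribution(plots, class_id=c)
            for c in sorted(plots["class_id"].unique())}
    for c, f in fits.items():
        print(f"milkweed {c}: best {f.best.family} "
              f"(mean {f.best.mean:.1f} plants/ha, {f.zero_proportion:.0%} zeros)")
    best = {c: f.best for c, f in fits.items()}
    final = apply_special_rules(best, zero_classes=("water",),
                                midpoint_rules={})
    reg = registry_to_frame(final)
    reg.to_csv(RESULTS / "milkweed_registry.csv", index=False)
    print(f"wrote {len(reg)} milkweed distributions "
          "(water forced to zero by the special rules)")


if __name__ == "__main__":
    main()
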
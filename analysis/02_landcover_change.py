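"""Land-cover change accounting.

Builds the per-class change tables for the Mexico (2000-2020) and Texas
(2001-2019) study extents from the bundled published areas, and verifies
the same accounting on the synthetic landscape from 01 (where the truth
is known exactly).
"""

from pathlib import Path

import numpy as np

from habitatshift.change import compute_transition_matrix, summarize_change, transitions_long
from habitatshift.pipeline import published_change_summary
from habitatshift.raster import read_grid

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SYN = RESULTS / "synthetic"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    for region in ("mexico", "texas"):
        table = published_change_summary(region)
        table.round(2).to_csv(RESULTS / f"landcover_change_{region}.csv")
        biggest = table["net"].abs().idxmax()
        print(f"{region}: largest net change {biggest} "
              f"{table.loc[biggest, 'net']:,.0f} km² "
              f"({table.loc[biggest, 'percent_total']:.1f}%)")

    if (SYN / "landscape_t0.csv").exists():
        g0 = read_grid(SYN / "landscape_t0.csv", cell_area=0.0009,
                       zones_path=SYN / "zones.csv")
        g1 = read_grid(SYN / "landscape_t1.csv", cell_area=0.0009,
                       scheme=g0.scheme)
        tm = compute_transition_matrix(g0, g1, 2000, 2020)
        summ = summarize_change(tm)
        transitions_long(tm).to_csv(RESULTS / "synthetic_transitions_long.csv",
                                    index=False)
        assert abs(summ["net"].sum()) < 1e-9
        print(f"synthetic: net change sums to zero over "
              f"{tm.total_area:,.1f} km² as required")
    else:
        print("synthetic landscape not found - run 01_simulate_inputs.py first")


if __name__ == "__main__":
    main()
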
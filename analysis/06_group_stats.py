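"""Statistical comparison of the simulated conditions.

Applies the gated parametric ladder (Shapiro-Wilk normality, F-ratio
variance gate, Student/Welch t-test; ANOVA + Tukey for >2 groups) to the
per-cell correlation means from 02_spot_correlation.py and to the
flat-lattice occupancies from 03_morphometry.py.
"""

from dataclasses import asdict
from pathlib import Path

import pandas as pd

from nanomap import io
from nanomap.stats import compare_groups

OUT = Path(__file__).resolve().parent.parent / "results"


def _report(title: str, samples: dict) -> dict:
    rep = compare_groups(samples)
    print(f"{title}:")
    for g in rep.groups:
        print(f"  {g.label}: n={g.n} mean={g.mean:.4f} sd={g.sd:.4f}")
    print(f"  test={rep.test_used} statistic={rep.statistic:.4g} "
          f"p={rep.p_value:.3g} significant={rep.significant} "
          f"(normality ok: {rep.normality_ok})\n")
    payload = {
        "groups": [asdict(g) for g in rep.groups],
        "test_used": rep.test_used,
        "statistic": rep.statistic,
        "p_value": rep.p_value,
        "significant": rep.significant,
        "normality_ok": rep.normality_ok,
        "variances_equal": rep.variances_equal,
    }
    if rep.pairwise is not None:
        payload["pairwise"] = rep.pairwise.to_dict(orient="records")
    return payload


def main() -> None:
    per_cell = pd.read_csv(OUT / "correlation_per_cell.csv")
    occupancy = pd.read_csv(OUT / "morpho_occupancy.csv")

    reports = {}
    reports["correlation_mean_r"] = _report(
        "receptor-clathrin correlation (per-cell mean r)",
        {str(g): grp.mean_r.to_numpy() for g, grp in per_cell.groupby("condition")},
    )
    reports["flat_occupancy"] = _report(
        "flat-lattice percent occupancy (per cell)",
        {str(g): grp.occupancy_flat.to_numpy() for g, grp in occupancy.groupby("condition")},
    )
    # three-group example: stimulated spot r vs its null vs control spot r
    # (keep_default_na: the kind value "null" is data, not a missing cell)
    spots = pd.read_csv(OUT / "correlation_per_spot.csv", keep_default_na=False)
    spots["r"] = spots["r"].astype(float)
    egf = spots[spots.condition == "egf"]
    reports["spot_vs_null"] = _report(
        "stimulated spots vs their randomized null vs control spots (per-spot r)",
        {
            "egf_spots": egf[egf.kind == "spot"].r.to_numpy(),
            "egf_null": egf[egf.kind == "null"].r.to_numpy(),
            "ctrl_spots": spots[(spots.condition == "ctrl") & (spots.kind == "spot")].r.to_numpy(),
        },
    )
    io.write_json(OUT / "stats_reports.json", reports)
    print(f"reports written to {OUT / 'stats_reports.json'}")


if __name__ == "__main__":
    main()
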
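"""Four-year individuals X-charts per unit and axis.

Computes control limits over each full archive, counts points beyond the
SPC limits and beyond the ±2 mm action band, and tests whole-archive
normality (long multi-regime archives should fail it).  Writes
results/four_year_charts.csv and X-chart PNGs under scratch/figures/.
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
import common

from tomospc import AXES, ad_test, chart_limits, flag_points, read_qa_log, to_series
from tomospc.plotting import plot_xchart


def main():
    common.ensure_dirs()
    paths = common.ensure_logs()
    rows = []
    for unit in ("T1", "T2"):
        records = read_qa_log(paths[unit])
        for axis in AXES:
            series = to_series(records, unit, axis)
            limits = chart_limits(series)
            flags = flag_points(series, limits, action_limit_mm=2.0)
            ad = ad_test(series.values)
            rows.append(
                {
                    "unit": unit,
                    "axis": axis,
                    "n": series.n,
                    "CL_mm": round(limits.CL, 4),
                    "UCL_mm": round(limits.UCL, 4),
                    "LCL_mm": round(limits.LCL, 4),
                    "sigma_within_mm": round(limits.sigma_within, 4),
                    "n_beyond_spc": flags.n_beyond_spc,
                    "n_beyond_action_2mm": flags.n_beyond_action,
                    "ad_h": ad.h,
                    "ad_p": round(ad.p_value, 5),
                }
            )
            plot_xchart(
                series,
                limits,
                action_limit_mm=2.0,
                path=os.path.join(common.FIGURES_DIR, f"{unit}_{axis}_4yr.png"),
                title=f"{unit} {axis} — 4-year individuals chart",
            )
    table = pd.DataFrame(rows)
    out = os.path.join(common.RESULTS_DIR, "four_year_charts.csv")
    table.to_csv(out, index=False)
    print(table.to_string(index=False))
    print(f"\n-> {out}; charts under {common.FIGURES_DIR}")
    faulty = table[table.n_beyond_spc > 0]
    print(
        f"\n{len(faulty)}/{len(table)} unit-axes show out-of-control points; "
        "whole-archive normality fails wherever fault segments or setup errors "
        f"were injected (ad_h = 1 on {int(table.ad_h.sum())} of {len(table)})."
    )


if __name__ == "__main__":
    main()
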
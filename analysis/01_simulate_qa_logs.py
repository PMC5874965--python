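"""Build the synthetic clinic: 4-year QA archives for units T1 and T2 and an
applied-offset experiment table, all with known ground truth.

Writes CSVs under scratch/data/ and a ground-truth summary under results/.
"""

import json
import os
import sys

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
import common

from tomospc import AXES, ExperimentSpec, generate_experiment, write_experiment


def main():
    common.ensure_dirs()
    paths = common.ensure_logs()

    truth_summary = {}
    for unit in ("T1", "T2"):
        for axis in AXES:
            series, truth = common.four_year_series(unit, axis)
            spec = common.four_year_spec(unit, axis)
            truth_summary[f"{unit}/{axis}"] = {
                "n": series.n,
                "true_mean_mm": spec.mean_mm,
                "true_sd_mm": spec.sd_mm,
                "n_outliers": int(truth.outlier.sum()),
                "fault_segments": [
                    {"start": f.start, "end": f.end, "shift_mm": f.shift_mm}
                    for f in spec.fault_segments
                ],
            }
        print(f"{unit}: wrote {paths[unit]}")

    exp_path = os.path.join(common.DATA_DIR, "offset_experiment.csv")
    trials, exp_truth = generate_experiment(ExperimentSpec(seed=common.BASE_SEED))
    write_experiment(trials, exp_path)
    print(f"offset experiment: {len(trials)} trials -> {exp_path}")

    out = os.path.join(common.RESULTS_DIR, "simulation_truth.json")
    with open(out, "w") as fh:
        json.dump({"series": truth_summary, "experiment": exp_truth}, fh, indent=2)
    print(f"ground truth -> {out}")


if __name__ == "__main__":
    main()
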
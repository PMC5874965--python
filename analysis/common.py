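"""Shared study design for the analysis scripts.

Defines one reproducible synthetic "clinic": two treatment units observed
over four years of daily couch-offset QA, parameterized at the published
per-axis operating points, with the documented fault episodes injected:

* unit T1, vertical (IECZ) axis: an encoder fault spanning observations
  400-600 that shifts the process by ~0.9 mm (still inside the ±2 mm action
  band) until repaired;
* unit T2, longitudinal (IECY) axis: a sustained systematic segment over
  observations 650-1100;
* sporadic setup-error outliers (>1.3 mm) on every axis;
* extra setup-error contamination on T1's lateral and vertical axes, which
  is what breaks normality in their three-monthly windows.

Data are (re)generated into scratch/data/ on demand; scripts only commit
small summary tables under results/.
"""

import os

from tomospc import (
    AXES,
    FOUR_YEAR_N,
    FaultSegment,
    preset_spec,
    generate_series,
    series_to_records,
    write_qa_log,
)

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
DATA_DIR = os.path.join(ROOT, "scratch", "data")
RESULTS_DIR = os.path.join(ROOT, "results")
FIGURES_DIR = os.path.join(ROOT, "scratch", "figures")

BASE_SEED = 20170721

#: per-(unit, axis) fault injections for the 4-year archive
FOUR_YEAR_FAULTS = {
    ("T1", "IECZ"): (FaultSegment(400, 600, shift_mm=-0.9),),
    ("T2", "IECY"): (FaultSegment(650, 1100, shift_mm=0.6),),
}

#: setup-error outlier rates; T1 X/Z carry the extra contamination that
#: makes their three-monthly windows fail the normality test
OUTLIER_RATES = {
    ("T1", "IECX"): 0.03,
    ("T1", "IECZ"): 0.03,
}
DEFAULT_OUTLIER_RATE = 0.008


def series_seed(unit, axis):
    return BASE_SEED + 1000 * (unit == "T2") + 10 * AXES.index(axis)


def four_year_spec(unit, axis):
    return preset_spec(
        unit,
        axis,
        n=FOUR_YEAR_N[unit],
        seed=series_seed(unit, axis),
        fault_segments=FOUR_YEAR_FAULTS.get((unit, axis), ()),
        outlier_rate=OUTLIER_RATES.get((unit, axis), DEFAULT_OUTLIER_RATE),
        outlier_scale_mm=1.3,
    )


def four_year_series(unit, axis):
    series, truth = generate_series(four_year_spec(unit, axis))
    return series, truth


def log_path(unit):
    return os.path.join(DATA_DIR, f"{unit}_four_year.csv")


def ensure_logs():
    """Materialize the 4-year CSV archives (idempotent)."""
    os.makedirs(DATA_DIR, exist_ok=True)
    paths = {}
    for unit in ("T1", "T2"):
        path = log_path(unit)
        if not os.path.exists(path):
            records = []
            for axis in AXES:
                series, _ = four_year_series(unit, axis)
                records.extend(series_to_records(series))
            write_qa_log(records, path)
        paths[unit] = path
    return paths


def ensure_dirs():
    os.makedirs(RESULTS_DIR, exist_ok=True)
    os.makedirs(FIGURES_DIR, exist_ok=True)
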
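#!/usr/bin/env python
"""Validate the fitted surface against the held-out field-years.

Estimates RGR on the test surveys, predicts it from the fitted parameters
and the test weather/phenology, and reports the bisector R², the
origin-constrained regression slope, residual shape and the sign-error
matrix.  Writes results/validation.json.
"""

import json
import sys
import warnings
from pathlib import Path

from aphidrgr import io as aio
from aphidrgr.pipeline import assemble_dataset, validate_fit
from aphidrgr.surface import RGRParams

SEED = 1


def main() -> None:
    data_dir = Path("results/data")
    fit_path = Path("results/fit.json")
    if not fit_path.exists():
        print("run analysis/03_fit_surface.py first", file=sys.stderr)
        return 1
    params = RGRParams.from_dict(json.loads(fit_path.read_text())["params"])

    surveys, temps = [], []
    for p in sorted(data_dir.glob("survey_test_*.csv")):
        for s in aio.read_survey_csv(p):
            surveys.append(s)
            temps.append(aio.read_weather_csv(data_dir / f"weather_test_{s.field_id}.csv"))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        data = assemble_dataset(surveys, temps)
        report = validate_fit(params, data)
    print(report.to_text())
    aio.write_json({"validation": report.to_dict()}, "results/validation.json",
                   meta={"seed": SEED})
    print("wrote results/validation.json")


if __name__ == "__main__":
    sys.exit(main())
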
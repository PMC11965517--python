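#!/usr/bin/env python
"""Predict each individual's clinical manifestation at the typical time of
diagnosis.

Aligns every outcome series on the common disease timescale (s = t + shift),
fits linear / cumulative-logit / logistic mixed models per outcome, and
predicts the outcome at s = 0.  Writes results/manifestation/<name>.csv in
long format (individual_id, outcome, predicted_value, extrapolated,
scale_kind).
"""

from pathlib import Path

import pandas as pd

from pdelay.manifestation import build_manifestation_matrix

import importlib.util

_spec = importlib.util.spec_from_file_location(
    "fit_step", Path(__file__).with_name("02_fit_ltjmm.py")
)
fit_step = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(fit_step)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out_dir = ROOT / "manifestation"
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in fit_step.COHORTS:
        prepared = fit_step.load_prepared(name)
        shifts = pd.read_csv(
            ROOT / "ltjmm" / name / "timeshifts.csv", index_col="individual_id"
        )
        matrix, flags, log = build_manifestation_matrix(prepared, shifts)
        rows = []
        for outcome in matrix.columns:
            kind = prepared.spec(outcome).scale_kind
            for ind, val in matrix[outcome].dropna().items():
                rows.append(
                    {
                        "individual_id": ind,
                        "outcome": outcome,
                        "predicted_value": val,
                        "extrapolated": bool(flags.loc[ind, outcome]),
                        "scale_kind": kind,
                    }
                )
        pd.DataFrame(rows).to_csv(out_dir / f"{name}.csv", index=False)
        ok = [k for k, v in log.items() if v["status"] == "ok"]
        skipped = {k: v["status"] for k, v in log.items() if v["status"] != "ok"}
        print(f"{name}: {len(ok)} outcomes predicted at s=0; skipped: {skipped or '-'}")


if __name__ == "__main__":
    main()
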
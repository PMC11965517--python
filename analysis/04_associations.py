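#!/usr/bin/env python
"""Associate time shifts with demographics, subtypes and initial symptoms.

Outcome-level correlations (Pearson / Kendall tau-b / point-biserial by
scale) are pooled into symptom domains with the three-level random-effects
meta-analysis and Benjamini-Hochberg correction.  Also compares time-shift
distributions between the fast/slow progression subtypes (Cohen's d) and
correlates shifts with predicted age at diagnosis using the simplified
(covariate-free) fits.

Writes results/associations/{associations,domains_meta,groups,forest}.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pdelay.association import (
    UndefinedCorrelationError,
    adjust_multiplicity,
    coefficient_kind_for,
    compare_groups,
    correlate_age,
    correlate_with_shifts,
    pool_domain,
)

import importlib.util

_spec = importlib.util.spec_from_file_location(
    "fit_step", Path(__file__).with_name("02_fit_ltjmm.py")
)
fit_step = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(fit_step)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out_dir = ROOT / "associations"
    out_dir.mkdir(parents=True, exist_ok=True)

    results = []
    groups_rows = []
    domain_map = {}
    for name in fit_step.COHORTS:
        prepared = fit_step.load_prepared(name)
        shifts = pd.read_csv(
            ROOT / "ltjmm" / name / "timeshifts.csv", index_col="individual_id"
        )["point"]
        manifest = pd.read_csv(ROOT / "manifestation" / f"{name}.csv")
        wide = manifest.pivot(
            index="individual_id", columns="outcome", values="predicted_value"
        )
        for outcome in wide.columns:
            spec = prepared.spec(outcome)
            if spec.domain is None:
                continue
            domain_map[outcome] = spec.domain
            common = wide[outcome].dropna().index.intersection(shifts.index)
            try:
                res = correlate_with_shifts(
                    wide.loc[common, outcome], shifts.loc[common],
                    coefficient_kind_for(spec.scale_kind),
                    outcome=outcome, cohort=name,
                )
            except UndefinedCorrelationError as exc:
                print(f"{name}/{outcome}: skipped ({exc})")
                continue
            results.append(res)

        # subtype comparison (fast vs slow progression)
        sub = prepared.individuals["progression_subtype"].dropna()
        common = sub.index.intersection(shifts.index)
        cmp = compare_groups(
            shifts.loc[common], sub.loc[common], grouping="progression_subtype"
        )
        groups_rows.append(
            {"cohort": name, "grouping": cmp.grouping, "groups": "/".join(cmp.groups),
             "test": cmp.test_used, "statistic": cmp.statistic, "p": cmp.p,
             "cohens_d": cmp.cohens_d}
        )

        # age at common-timescale diagnosis, simplified fits
        simp = pd.read_csv(
            ROOT / "ltjmm" / name / "timeshifts_simplified.csv",
            index_col="individual_id",
        )["point"]
        ages = prepared.individuals.loc[simp.index, "age_at_diagnosis"]
        age_res = correlate_age(simp, ages)
        print(
            f"{name}: corr(shift, predicted age at diagnosis) "
            f"rho={age_res.coefficient:.2f} (p={age_res.p:.2g}); "
            f"subtype d={cmp.cohens_d:.2f} (p={cmp.p:.3f}, {cmp.test_used})"
        )

    pd.DataFrame(
        [
            {"outcome": r.outcome, "cohort": r.cohort, "coefficient": r.coefficient,
             "kind": r.coefficient_kind, "n": r.n, "p": r.p}
            for r in results
        ]
    ).to_csv(out_dir / "associations.csv", index=False)

    metas = adjust_multiplicity(pool_domain(results, domain_map))
    pd.DataFrame(
        [
            {"domain": m.domain, "pooled_r": m.pooled_coefficient,
             "ci_low": m.ci_low, "ci_high": m.ci_high, "p": m.p,
             "p_adjusted": m.p_adjusted, "significant": m.significant,
             "n_outcomes": m.n_outcomes, "n_cohorts": m.n_cohorts,
             "tau2_between": m.tau2_between}
        for m in metas
        ]
    ).to_csv(out_dir / "domains_meta.csv", index=False)

    forest = []
    for m in metas:
        for row in m.per_cohort.itertuples(index=False):
            forest.append(
                {"domain": m.domain, "cohort": row.cohort,
                 "effect": float(np.tanh(row.effect_z)), "se_z": row.se_z,
                 "level": "cohort"}
            )
        forest.append(
            {"domain": m.domain, "cohort": "pooled",
             "effect": m.pooled_coefficient, "se_z": m.pooled_se_z,
             "level": "pooled"}
        )
    pd.DataFrame(forest).to_csv(out_dir / "forest.csv", index=False)
    pd.DataFrame(groups_rows).to_csv(out_dir / "groups.csv", index=False)

    sig = [m for m in metas if m.significant]
    print(f"{len(metas)} domains pooled; significant after BH: "
          f"{[m.domain for m in sig] or 'none'}")


if __name__ == "__main__":
    main()
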
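#!/usr/bin/env python
"""Internal-consistency check of the double-list design.

The two lists interrogate the same sensitive trait on the same people, so
their prevalence estimates should agree. Tests beta_A = beta_B overall and
within each generated subgroup, using the stacked respondent-clustered
Wald contrast.
"""

from pathlib import Path

import pandas as pd

from listcount import estimate_single_list, read_survey, to_long, wald_equal_lists

ROOT = Path(__file__).resolve().parents[1] / "results"

SUBGROUPS = {
    "senegal_style": ["registered", "high_hiv_knowledge"],
    "burkina_style": ["polygamous", "attended_school"],
}


def main() -> None:
    out = ROOT / "consistency"
    out.mkdir(parents=True, exist_ok=True)
    for name, subgroups in SUBGROUPS.items():
        survey = read_survey(ROOT / "data" / f"{name}.csv")
        long = to_long(survey)
        est_a = estimate_single_list(long.restrict("A"))
        est_b = estimate_single_list(long.restrict("B"))
        rows = [{
            "subgroup": "All observations", "N": survey.n,
            "prevalence_A": round(est_a.beta, 3), "prevalence_B": round(est_b.beta, 3),
            "difference": round((w := wald_equal_lists(long)).difference, 3),
            "p": round(w.p_value, 3),
        }]
        for sub in subgroups:
            w = wald_equal_lists(long, subgroup=sub)
            rows.append({
                "subgroup": sub, "N": int((survey.df[sub] == 1).sum()),
                "prevalence_A": None, "prevalence_B": None,
                "difference": round(w.difference, 3), "p": round(w.p_value, 3),
            })
        table = pd.DataFrame(rows)
        table.to_csv(out / f"{name}.csv", index=False)
        print(f"\n{name}: no between-list difference should be significant")
        print(table.to_string(index=False))


if __name__ == "__main__":
    main()
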
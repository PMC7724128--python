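#!/usr/bin/env python
"""Generate the two synthetic study cohorts.

Draws one cohort per study design — 495 respondents with an over-reported
behaviour (true prevalence 0.80, direct reports near 0.97) and 1706
respondents with an under-reported behaviour (true prevalence 0.24, direct
reports near 0.05) — and writes them as wide CSVs under results/data/.
"""

from pathlib import Path

from listcount import burkina_config, senegal_config, simulate_survey

SEED = 20260928
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name, factory in (("senegal_style", senegal_config), ("burkina_style", burkina_config)):
        survey = simulate_survey(factory(seed=SEED))
        path = OUT / f"{name}.csv"
        survey.write_csv(path)
        direct = survey.df["direct_report"].mean()
        print(f"{name}: n={survey.n}, mean direct report {direct:.3f} -> {path}")


if __name__ == "__main__":
    main()
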
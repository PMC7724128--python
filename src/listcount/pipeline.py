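"""End-to-end study pipeline.

Runs, in order: validation, assumption diagnostics, per-list prevalence
estimation, the pooled double-list fit, subgroup analyses, internal-
consistency Wald tests, double-list efficiency accounting, and the
bias-variance minimum-sample-size computation; and renders the four
standard study tables:

* table 1 — prevalence and misreporting per list and pooled;
* table 2 — internal consistency of the two lists, overall and by subgroup;
* table 3 — SE reduction from pooling the two lists;
* table 4 — minimum sample size for the list experiment to beat the direct
  question in MSE, per subgroup (list A convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design as design_tools
from . import estimation
from .data import LongDataset, SurveyDataset, read_survey, to_long
from .diagnostics import DiagnosticsReport, run_diagnostics
from .simulate import SimulationConfig, burkina_config, senegal_config, simulate_survey

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    input_path: str | None = None
    sim: SimulationConfig | None = None
    subgroups: list[str] = field(default_factory=list)
    outdir: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.sim is None):
            raise ValueError("set exactly one of input_path and sim")


@dataclass
class StudyReport:
    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    diagnostics: DiagnosticsReport
    n: int


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML pipeline configuration.

    Keys: ``seed`` (required for simulation), ``input`` (CSV path) *or*
    ``simulate`` (``study: senegal|burkina`` plus optional ``n``),
    ``subgroups``, ``output``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    seed = raw.get("seed")
    sim = None
    if "simulate" in raw:
        spec = raw["simulate"] or {}
        study = spec.get("study", "burkina")
        if seed is None:
            raise ValueError("simulation requires an explicit seed")
        factory = {"senegal": senegal_config, "burkina": burkina_config}[study]
        kwargs = {"seed": int(seed)}
        if "n" in spec:
            kwargs["n"] = int(spec["n"])
        sim = factory(**kwargs)
    return PipelineConfig(
        input_path=raw.get("input"),
        sim=sim,
        subgroups=list(raw.get("subgroups", [])),
        outdir=raw.get("output"),
        seed=seed,
    )


def _subgroup_mask(survey: SurveyDataset, name: str) -> np.ndarray:
    return survey.df[name].to_numpy(dtype=float) == 1.0


def run_pipeline(config: PipelineConfig) -> StudyReport:
    """Execute all analysis stages. Deterministic given seed and input."""
    if config.sim is not None:
        sim = config.sim
        if config.seed is not None and config.seed != sim.seed:
            from dataclasses import replace

            sim = replace(sim, seed=config.seed)
        logger.info("stage simulate: n=%d seed=%d", sim.n, sim.seed)
        survey = simulate_survey(sim)
    else:
        logger.info("stage load: %s", config.input_path)
        survey = read_survey(config.input_path)
    n = survey.n
    long = to_long(survey)
    logger.info("stage reshape: %d respondents -> %d long rows", n, len(long.df))

    j = survey.designs[0].n_items
    diag = run_diagnostics(survey, long, covariates=config.subgroups or None, j=j)
    logger.info("stage diagnostics: %d flags", len(diag.flags))

    direct = survey.df["direct_report"].to_numpy(dtype=float)
    direct_mean = float(direct.mean())

    long_a, long_b = long.restrict("A"), long.restrict("B")
    est_a = estimation.estimate_single_list(long_a)
    est_b = estimation.estimate_single_list(long_b)
    est_pooled = estimation.estimate_pooled(long)
    logger.info(
        "stage estimate: beta_A=%.3f beta_B=%.3f pooled=%.3f",
        est_a.beta, est_b.beta, est_pooled.beta,
    )

    rows1 = []
    for label, est in (("List A", est_a), ("List B", est_b), ("Lists A & B", est_pooled)):
        wald = estimation.wald_vs_direct(est, survey)
        rows1.append(
            {
                "scope": label,
                "N": est.n_obs,
                "mean_treated": est.arm_means[0],
                "mean_control": est.arm_means[1],
                "prevalence": est.beta,
                "se": est.se,
                "ci_low": est.ci95[0],
                "ci_high": est.ci95[1],
                "direct_mean": direct_mean,
                "misreporting": abs(wald.difference),
                "p_value": wald.p_value,
            }
        )
    table1 = pd.DataFrame(rows1)

    rows2 = [
        {
            "subgroup": "All observations",
            "N": n,
            "prevalence_A": est_a.beta,
            "se_A": est_a.se,
            "prevalence_B": est_b.beta,
            "se_B": est_b.se,
            "difference": (w := estimation.wald_equal_lists(long)).difference,
            "p_value": w.p_value,
        }
    ]
    sub_ests: dict[str, tuple] = {}
    for name in config.subgroups:
        sub_a = estimation.estimate_subgroup(long_a, name)
        sub_b = estimation.estimate_subgroup(long_b, name)
        sub_pooled = estimation.estimate_subgroup(long, name, pooled=True)
        w = estimation.wald_equal_lists(long, subgroup=name)
        n_sub = int(_subgroup_mask(survey, name).sum())
        sub_ests[name] = (sub_a, sub_b, sub_pooled, n_sub)
        rows2.append(
            {
                "subgroup": name,
                "N": n_sub,
                "prevalence_A": sub_a.prevalence_s1,
                "se_A": sub_a.se_prevalence_s1,
                "prevalence_B": sub_b.prevalence_s1,
                "se_B": sub_b.se_prevalence_s1,
                "difference": w.difference,
                "p_value": w.p_value,
            }
        )
    table2 = pd.DataFrame(rows2)

    rows3 = [
        {
            "subgroup": "All observations",
            "N": est_pooled.n_obs,
            "prevalence": est_pooled.beta,
            "se": est_pooled.se,
            "reduction_vs_A": design_tools.se_reduction(est_pooled.se, est_a.se),
            "reduction_vs_B": design_tools.se_reduction(est_pooled.se, est_b.se),
        }
    ]
    for name, (sub_a, sub_b, sub_pooled, n_sub) in sub_ests.items():
        rows3.append(
            {
                "subgroup": name,
                "N": 2 * n_sub,
                "prevalence": sub_pooled.prevalence_s1,
                "se": sub_pooled.se_prevalence_s1,
                "reduction_vs_A": design_tools.se_reduction(
                    sub_pooled.se_prevalence_s1, sub_a.se_prevalence_s1
                ),
                "reduction_vs_B": design_tools.se_reduction(
                    sub_pooled.se_prevalence_s1, sub_b.se_prevalence_s1
                ),
            }
        )
    table3 = pd.DataFrame(rows3)

    # table 4: list-A convention, per subgroup sample
    def t4_row(label, mask):
        sub_survey = survey.df[mask]
        sub_long_a = LongDataset(long_a.df[long_a.df["respondent_id"].isin(sub_survey["respondent_id"])].copy())
        est = estimation.estimate_single_list(sub_long_a)
        dmean = float(sub_survey["direct_report"].mean())
        n_sub = len(sub_survey)
        problem = design_tools.bias_from_estimates(est, dmean, control_data=sub_long_a)
        row = {
            "subgroup": label,
            "var_y0": problem.var_y0,
            "pi_star": problem.pi_star,
            "se_list": est.se,
            "direct_mean": dmean,
            "se_direct": float(np.sqrt(dmean * (1 - dmean) / n_sub)),
            "B": problem.bias,
            "n_min": np.nan,
            "n_survey": n_sub,
        }
        try:
            row["n_min"] = design_tools.nmin_solve(problem).n_min
        except design_tools.NoFiniteSolutionError:
            logger.warning("no finite minimum sample size for %s (zero bias)", label)
        return row

    rows4 = [t4_row("All observations", np.ones(n, dtype=bool))]
    for name in config.subgroups:
        rows4.append(t4_row(name, _subgroup_mask(survey, name)))
    table4 = pd.DataFrame(rows4)

    logger.info("stage samplesize: %d rows", len(table4))
    return StudyReport(table1, table2, table3, table4, diag, n)


def _format_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def render_tables(report: StudyReport, outdir: str | Path, formats: tuple[str, ...] = ("csv", "text")) -> list[Path]:
    """Write each table as full-precision CSV and/or 3-decimal text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    tables = {
        "table1": report.table1,
        "table2": report.table2,
        "table3": report.table3,
        "table4": report.table4,
    }
    for name, df in tables.items():
        if "csv" in formats:
            path = outdir / f"{name}.csv"
            df.to_csv(path, index=False)
            written.append(path)
        if "text" in formats:
            disp = df.copy()
            for col in disp.columns:
                if col == "p_value":
                    disp[col] = disp[col].map(_format_p)
                elif disp[col].dtype.kind == "f":
                    disp[col] = disp[col].map(
                        lambda v: "" if pd.isna(v) else (f"{v:.0f}" if float(v).is_integer() and abs(v) > 10 else f"{v:.3f}")
                    )
            path = outdir / f"{name}.txt"
            path.write_text(disp.to_string(index=False) + "\n")
            written.append(path)
    diag_path = outdir / "diagnostics.txt"
    diag_path.write_text(format_diagnostics(report.diagnostics))
    written.append(diag_path)
    return written


def format_diagnostics(diag: DiagnosticsReport) -> str:
    lines = ["Assumption diagnostics", "======================", ""]
    if diag.balance:
        lines.append("Randomisation balance (group 1 vs group 2):")
        for row in diag.balance:
            lines.append(
                f"  {row.covariate:<30s} diff={row.difference:+.3f}  p={row.p_value:.3f}"
            )
        if diag.balance_joint_p is not None:
            lines.append(f"  joint F-test p={diag.balance_joint_p:.3f}")
        lines.append("")
    lines.append("No-design-effect inequality tests (Bonferroni-corrected min p):")
    for list_id, res in diag.design_effect.items():
        lines.append(f"  list {list_id}: min p={res.min_p:.3g}, corrected={res.bonferroni_p:.3g}")
    lines.append("")
    lines.append("Floor / ceiling proportions in the control arm:")
    for list_id in diag.floor_prop:
        lines.append(
            f"  list {list_id}: Pr(Y=0)={diag.floor_prop[list_id]:.3f}, "
            f"Pr(Y=J)={diag.ceiling_prop[list_id]:.3f}"
        )
    if diag.flags:
        lines.append("")
        lines.append("Flags:")
        lines.extend(f"  - {f}" for f in diag.flags)
    return "\n".join(lines) + "\n"
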
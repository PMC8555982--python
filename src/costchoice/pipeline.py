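"""End-to-end analysis pipeline and report generation.

Stages, in order: per-session behavioral fit; decision-variable
construction; task-relatedness screen (two 3-way ANOVAs, p < 0.001); ANCOVA
tuning classification of the task-related responses (parallel/horizontal
models, p < 0.05); stepwise and best-subset variable selection; dimensional
integration (dR2 between the chosen-value variants); session-level
parameter tests. Each stage is importable on its own; this module wires
them together and writes summary tables.
"""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import ancova, behavior, integration, selection, stats, task, windows


@dataclass
class PipelineConfig:
    hemisphere_by_session: dict = field(default_factory=dict)  # session_id -> left/right
    default_hemisphere: str = "left"
    screen_alpha: float = 0.001
    explain_alpha: float = 0.05
    stop_fraction: float = 0.02
    ancova_level: str = "means"
    min_per_cell: int = 2

    def hemisphere(self, session_id: str) -> str:
        return self.hemisphere_by_session.get(session_id, self.default_hemisphere)


@dataclass
class PipelineResult:
    behavior_fits: pd.DataFrame
    param_tests: pd.DataFrame | None
    screen: pd.DataFrame
    factor_counts: pd.DataFrame
    ancova_fits: pd.DataFrame
    classifications: pd.DataFrame
    explained_matrix: pd.DataFrame
    best_fit_matrix: pd.DataFrame
    stepwise: selection.SelectionResult | None
    best_subset: selection.SelectionResult | None
    delta_r2: pd.DataFrame
    integration: integration.IntegrationResult | None


def _log(msg: str, t0: float) -> None:
    print(f"[costchoice +{time.perf_counter() - t0:6.1f}s] {msg}", file=sys.stderr)


def run_pipeline(
    trials: pd.DataFrame,
    rates: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full analysis on (possibly multi-session) trial and rate tables."""
    cfg = config or PipelineConfig()
    t0 = time.perf_counter()
    trials = task.add_indicators(trials)

    fits = behavior.fit_sessions(trials)
    _log(f"fitted {len(fits)} session(s)", t0)
    param_tests = stats.session_param_tests(fits) if len(fits) >= 6 else None

    screen_parts, fit_parts, cls_parts, dr2_parts = [], [], [], []
    for sid, sdf in trials.groupby("session_id", sort=True):
        srates = rates[rates["session_id"] == sid] if "session_id" in rates.columns else rates
        row = fits[fits["session_id"] == str(sid)].iloc[0]
        variables = task.variable_table(
            sdf, rho=row["rho"], xi=row["xi"], hemisphere=cfg.hemisphere(str(sid))
        )
        screen = windows.screen_task_related(srates, sdf, alpha=cfg.screen_alpha)
        screen.insert(0, "session_id", sid)
        screen_parts.append(screen)
        related = screen[screen["task_related"]]
        afits, cls = ancova.analyze_population(
            srates, sdf, variables, responses=related,
            level=cfg.ancova_level, min_per_cell=cfg.min_per_cell,
        )
        fit_parts.append(afits)
        cls_parts.append(cls)
        dr2 = integration.delta_r2_table(
            srates, sdf, variables, rho=row["rho"], xi=row["xi"], responses=related,
            level=cfg.ancova_level, min_per_cell=cfg.min_per_cell,
        )
        dr2_parts.append(dr2)
        _log(f"session {sid}: {len(related)} task-related responses", t0)

    screen = pd.concat(screen_parts, ignore_index=True) if screen_parts else pd.DataFrame()
    factor_counts = windows.factor_count_table(screen, alpha=cfg.screen_alpha) if len(screen) else pd.DataFrame()
    ancova_fits = pd.concat(fit_parts, ignore_index=True) if fit_parts else pd.DataFrame()
    classifications = pd.concat(cls_parts, ignore_index=True) if cls_parts else pd.DataFrame()
    if len(classifications):
        explained_m, best_m = ancova.count_matrices(classifications)
        stepwise = selection.stepwise_select(classifications, stop_fraction=cfg.stop_fraction)
        # the two procedures are compared at the same set size
        best_sub = selection.best_subset_select(
            classifications,
            stop_fraction=cfg.stop_fraction,
            size=min(len(stepwise.selected), selection.MAX_SUBSET_SIZE),
        )
    else:
        explained_m = best_m = pd.DataFrame()
        stepwise = best_sub = None
    delta = pd.concat(dr2_parts, ignore_index=True) if dr2_parts else pd.DataFrame()
    integ = integration.epoch_summary(delta) if len(delta) else None
    _log("pipeline complete", t0)
    return PipelineResult(
        fits, param_tests, screen, factor_counts, ancova_fits, classifications,
        explained_m, best_m, stepwise, best_sub, delta, integ,
    )


def build_report(result: PipelineResult, outdir: str | Path) -> Path:
    """Write summary CSVs and a plain-text report; returns the report path.

    Missing stages are noted explicitly rather than failing.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    lines = ["costchoice analysis report", "=" * 30, ""]

    result.behavior_fits.to_csv(out / "behavior_fits.csv", index=False)
    lines.append(f"Sessions fitted: {len(result.behavior_fits)}")
    if result.param_tests is not None:
        result.param_tests.to_csv(out / "param_tests.csv", index=False)
        lines.append("Across-session parameter medians (Wilcoxon signed-rank vs 0):")
        for _, r in result.param_tests.iterrows():
            p = "n/a" if pd.isna(r["p"]) else f"{r['p']:.3g}"
            lines.append(f"  {r['parameter']:>8s}: median = {r['median']:+.3f}  (n={r['n']}, p={p})")
    else:
        lines.append("Parameter tests: skipped (fewer than 6 sessions)")
    lines.append("")

    if len(result.screen):
        result.screen.to_csv(out / "screen.csv", index=False)
        result.factor_counts.to_csv(out / "factor_counts.csv")
        n_resp = int(result.screen["task_related"].sum())
        n_neur = result.screen.loc[result.screen["task_related"], "neuron_id"].nunique()
        lines.append(f"Task-related responses: {n_resp} ({n_neur} neurons)")
    else:
        lines.append("Screen: no rate data provided")
    lines.append("")

    if len(result.classifications):
        result.ancova_fits.to_csv(out / "ancova_fits.csv", index=False)
        result.classifications.to_csv(out / "classifications.csv", index=False)
        result.explained_matrix.to_csv(out / "explained_matrix.csv")
        result.best_fit_matrix.to_csv(out / "best_fit_matrix.csv")
        for res in (result.stepwise, result.best_subset):
            if res is None:
                continue
            names = [task.VARIABLES.get(v, str(v)) for v in sorted(res.selected)]
            lines.append(f"{res.method} selection: {names} ({res.stop_reason})")
            res.trace.to_csv(out / f"selection_{res.method}.csv", index=False)
    else:
        lines.append("Tuning classification: no task-related responses")
    lines.append("")

    if result.integration is not None:
        result.delta_r2.to_csv(out / "delta_r2.csv", index=False)
        d = result.integration.to_dict()
        lines.append(
            "Dimensional integration (dR2 = R2_cost_affected - R2_cost_independent):"
        )
        lines.append(
            f"  early: n={d['n_early']}, mean={d['mean_early']:+.4f}, p={d['p_early']:.3g}"
        )
        lines.append(
            f"  late:  n={d['n_late']}, mean={d['mean_late']:+.4f}, p={d['p_late']:.3g}"
        )
        lines.append(f"  early vs late (rank-sum): p={d['p_between']:.3g}")
    else:
        lines.append("Dimensional integration: no qualifying chosen-value responses")

    report = out / "report.txt"
    report.write_text("\n".join(lines) + "\n")
    return report
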
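"""Scenario orchestration: base case, discount variants, sensitivity runs.

The suite mirrors the published analysis plan: a base case (5%/yr
discounting, prevented fraction 0.43 applied to the two early caries
transitions), 0% and 3.5% discount variants, and three scenarios —

1. efficacy extended to DentineDecay -> Filling,
2. further extended to Filling -> RepeatFilling,
3. base-case efficacy with two varnish applications per 6-month cycle
   (quarterly application; doubles the intervention cost only).

Each scenario is run at the central prevented fraction and at its 95%
bounds (0.30, 0.57), the bound runs forming the reported interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .cohort_engine import run_cohort
from .economics import ArmResult, IcerResult, accumulate_arm, compute_icer
from .model_core import ModelConfig
from .transitions import (
    LifeTable,
    TransitionModel,
    apply_prevented_fraction,
    augment_with_mortality,
)

__all__ = [
    "BASE_AFFECTED_TRANSITIONS",
    "ScenarioConfig",
    "ScenarioResult",
    "Report",
    "build_scenario_suite",
    "run_scenario",
    "run_suite",
    "render_report",
    "plot_ce_plane",
]

#: Transitions inhibited by varnish in the base case: early caries onset
#: and enamel-to-dentine progression.  Once a molar is filled the varnish
#: confers no further benefit.
BASE_AFFECTED_TRANSITIONS: tuple[tuple[str, str], ...] = (
    ("NoDisease", "EnamelDecay"),
    ("EnamelDecay", "DentineDecay"),
)


@dataclass(frozen=True)
class ScenarioConfig:
    label: str
    pf: float
    pf_bounds: tuple[float, float]
    discount_rate: float
    affected_transitions: tuple[tuple[str, str], ...]
    applications_per_cycle: int = 1

    def __post_init__(self) -> None:
        if self.applications_per_cycle not in (1, 2):
            raise ValueError("applications_per_cycle must be 1 or 2")
        low, high = self.pf_bounds
        if not 0.0 <= low <= self.pf <= high <= 1.0:
            raise ValueError("require 0 <= low <= pf <= high <= 1")


def build_scenario_suite(core: ModelConfig) -> list[ScenarioConfig]:
    """The six named analyses: base case, two discount variants, scenarios 1-3."""
    p = core.params
    pf, bounds = p.prevented_fraction, (
        p.prevented_fraction_low,
        p.prevented_fraction_high,
    )
    base = BASE_AFFECTED_TRANSITIONS
    s1 = base + (("DentineDecay", "Filling"),)
    s2 = s1 + (("Filling", "RepeatFilling"),)
    return [
        ScenarioConfig("base_case", pf, bounds, 0.05, base),
        ScenarioConfig("discount_0pct", pf, bounds, 0.0, base),
        ScenarioConfig("discount_3.5pct", pf, bounds, 0.035, base),
        ScenarioConfig("scenario_1_dentine_filling", pf, bounds, 0.05, s1),
        ScenarioConfig("scenario_2_repeat_fillings", pf, bounds, 0.05, s2),
        ScenarioConfig(
            "scenario_3_quarterly_applications", pf, bounds, 0.05, base,
            applications_per_cycle=2,
        ),
    ]


@dataclass
class BoundRun:
    pf: float
    intervention: ArmResult
    icer_dmft: IcerResult
    icer_qaly: IcerResult

    def icer(self, effect: str) -> IcerResult:
        return self.icer_dmft if effect == "prevented_dmft" else self.icer_qaly


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    comparator: ArmResult
    intervention: ArmResult
    icer_dmft: IcerResult
    icer_qaly: IcerResult
    bounds: dict[str, BoundRun] = field(default_factory=dict)  # "low"/"high"

    def icer(self, effect: str) -> IcerResult:
        return self.icer_dmft if effect == "prevented_dmft" else self.icer_qaly

    def icer_interval(self, effect: str) -> tuple[float, float]:
        """(min, max) of the ICERs across the PF-bound runs."""
        vals = [b.icer(effect).icer for b in self.bounds.values()]
        return (min(vals), max(vals)) if vals else (float("nan"), float("nan"))


def run_scenario(
    cfg: ScenarioConfig,
    model: TransitionModel | None,
    core: ModelConfig,
    life_table: LifeTable | None = None,
) -> ScenarioResult:
    """Run comparator and intervention arms (central PF and both bounds).

    ``model`` is the comparator tooth-state model *without* mortality
    (defaults to ``core.transitions``); mortality from ``life_table``
    (default ``core.life_table``) is folded in here so the prevented
    fraction acts on the clinical transitions only.
    """
    model = model if model is not None else core.transitions
    life_table = life_table if life_table is not None else core.life_table
    if model is None:
        raise ValueError("no transition model available")
    p = core.params

    def mortal(m: TransitionModel) -> TransitionModel:
        if life_table is None:
            return m
        return augment_with_mortality(m, life_table, p.cycle_length, int(p.end_age))

    comp_trace = run_cohort(mortal(model), core.initial_distribution, p)
    comparator = accumulate_arm(
        comp_trace, core.states, p, include_intervention_cost=False,
        arm_label="current_practice", discount_rate=cfg.discount_rate,
    )

    def intervention_arm(pf: float) -> ArmResult:
        adj = apply_prevented_fraction(model, pf, cfg.affected_transitions)
        trace = run_cohort(mortal(adj), core.initial_distribution, p)
        return accumulate_arm(
            trace, core.states, p, include_intervention_cost=True,
            applications_per_cycle=cfg.applications_per_cycle,
            arm_label="intervention", discount_rate=cfg.discount_rate,
        )

    central = intervention_arm(cfg.pf)
    result = ScenarioResult(
        config=cfg,
        comparator=comparator,
        intervention=central,
        icer_dmft=compute_icer(comparator, central, "prevented_dmft", p.wtp_threshold),
        icer_qaly=compute_icer(comparator, central, "qaly_gained", p.wtp_threshold),
    )
    for name, pf in zip(("low", "high"), cfg.pf_bounds):
        arm = intervention_arm(pf)
        result.bounds[name] = BoundRun(
            pf=pf,
            intervention=arm,
            icer_dmft=compute_icer(comparator, arm, "prevented_dmft", p.wtp_threshold),
            icer_qaly=compute_icer(comparator, arm, "qaly_gained", p.wtp_threshold),
        )
    return result


def run_suite(core: ModelConfig) -> list[ScenarioResult]:
    """Run the full six-scenario suite on a loaded configuration."""
    return [run_scenario(cfg, None, core) for cfg in build_scenario_suite(core)]


@dataclass
class Report:
    arm_totals: pd.DataFrame
    icers: pd.DataFrame
    ce_plane: pd.DataFrame
    summary: str

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.arm_totals.to_csv(out / "arm_totals.csv", index=False)
        self.icers.to_csv(out / "icers.csv", index=False)
        self.ce_plane.to_csv(out / "ce_plane.csv", index=False)
        (out / "summary.txt").write_text(self.summary)


def render_report(results: list[ScenarioResult]) -> Report:
    """Tabulate per-arm totals, ICERs with PF-bound intervals, CE-plane points."""
    if not results:
        raise ValueError("no scenario results to report")
    arm_rows, icer_rows, ce_rows = [], [], []
    for r in results:
        for arm in (r.comparator, r.intervention):
            arm_rows.append(
                {
                    "scenario": r.config.label,
                    "arm": arm.arm_label,
                    "discount_rate": r.config.discount_rate,
                    "total_cost": arm.total_cost,
                    "treatment_cost": arm.treatment_cost,
                    "intervention_cost": arm.intervention_cost,
                    "dmft": arm.dmft,
                    "qaly": arm.qaly,
                }
            )
        for effect in ("prevented_dmft", "qaly_gained"):
            ic = r.icer(effect)
            lo, hi = r.icer_interval(effect)
            icer_rows.append(
                {
                    "scenario": r.config.label,
                    "effect_measure": effect,
                    "delta_cost": ic.delta_cost,
                    "delta_effect": ic.delta_effect,
                    "icer": ic.icer,
                    "icer_low": lo,
                    "icer_high": hi,
                    "quadrant": ic.quadrant,
                    "verdict": ic.verdict,
                }
            )
            ce_rows.append(
                {
                    "scenario": r.config.label,
                    "effect_measure": effect,
                    "delta_effect": ic.delta_effect,
                    "delta_cost": ic.delta_cost,
                }
            )
    arm_totals = pd.DataFrame(arm_rows)
    icers = pd.DataFrame(icer_rows)
    ce_plane = pd.DataFrame(ce_rows)
    summary = "\n\n".join(
        [
            "Per-arm discounted totals (AUD; DMFT-time and QALY per molar"
            " average):",
            arm_totals.to_string(index=False, float_format=lambda v: f"{v:,.2f}"),
            "ICERs (interval = prevented-fraction 95% bound reruns):",
            icers.to_string(index=False, float_format=lambda v: f"{v:,.2f}"),
        ]
    )
    return Report(arm_totals, icers, ce_plane, summary)


def plot_ce_plane(report: Report, path: str | Path, effect: str = "qaly_gained") -> None:
    """Scatter the scenarios on the cost-effectiveness plane."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.ce_plane[report.ce_plane["effect_measure"] == effect]
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(df["delta_effect"], df["delta_cost"])
    for _, row in df.iterrows():
        ax.annotate(row["scenario"], (row["delta_effect"], row["delta_cost"]),
                    fontsize=7, xytext=(3, 3), textcoords="offset points")
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    unit = "QALY gained" if effect == "qaly_gained" else "prevented DMFT"
    ax.set_xlabel(f"Incremental effect ({unit})")
    ax.set_ylabel("Incremental cost (AUD)")
    ax.set_title("Cost-effectiveness plane")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
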
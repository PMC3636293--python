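"""Incremental cost-effectiveness, net monetary benefit and bootstrap CEAC.

For each pair of strategies, the incremental cost-effectiveness ratio
ICER = (C_i - C_c) / (E_i - E_c) compares the extra cost per extra unit
of effect; its quadrant on the cost-effectiveness plane determines
dominance (cheaper and more effective = dominant; costlier and less
effective = dominated).  Because ratios only compare two strategies,
multi-arm comparison uses the net monetary benefit
NMB = (E_i - E_c) x WTP - (C_i - C_c) at a willingness-to-pay threshold
WTP.  Sampling uncertainty is quantified by nonparametric bootstrap
resampling of participants within arms; cost-effectiveness
acceptability curves (CEAC) report, per WTP, the fraction of bootstrap
replicates in which each arm attains the highest NMB.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from trialcea.costing import intervention_cost

#: Accepted Dutch willingness-to-pay cutoff per QALY, euros.
WTP_DEFAULT = 18_000.0

DEFAULT_WTP_GRID = np.arange(0.0, 100_500.0, 500.0)

REPS_COST_CI = 5000  # annual-cost percentile CIs
REPS_CEAC = 1000  # CEAC / CUAC curves


@dataclass(frozen=True)
class ArmSummary:
    """Per-arm mean annual cost and mean effect.

    The effect is a probability of abstinence in [0, 1] or a mean QALY,
    depending on the outcome scale of the analysis.
    """

    arm: str
    cost: float
    effect: float
    n: int

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("arm size must be positive")


@dataclass(frozen=True)
class IncrementalResult:
    """Pairwise incremental comparison on the cost-effectiveness plane."""

    label: str
    delta_cost: float
    delta_effect: float
    ratio: float | None  # euro per effect unit; None when delta_effect == 0
    classification: str  # dominant | dominated | tradeoff_NE | tradeoff_SW | equivalent


def _classify(dc: float, de: float) -> str:
    if de > 0:
        return "dominant" if dc < 0 else "tradeoff_NE"
    if de < 0:
        return "dominated" if dc > 0 else "tradeoff_SW"
    # equal effects: ranking reduces to costs
    if dc > 0:
        return "dominated"
    if dc < 0:
        return "dominant"
    return "equivalent"


def incremental(treat: ArmSummary, ref: ArmSummary) -> IncrementalResult:
    """Incremental cost, effect and ICER of ``treat`` over ``ref``.

    The ratio is undefined when the effect difference is zero; the
    classification then follows the cost sign alone.  On the NE quadrant
    (costlier, more effective) the ratio is the price of one extra
    effect unit; dominance labels, not ratio signs, carry direction.
    """
    dc = treat.cost - ref.cost
    de = treat.effect - ref.effect
    ratio = dc / de if de != 0 else None
    return IncrementalResult(
        label=f"{treat.arm} vs {ref.arm}",
        delta_cost=dc,
        delta_effect=de,
        ratio=ratio,
        classification=_classify(dc, de),
    )


def nmb(delta_effect: float, delta_cost: float, wtp: float) -> float:
    """Net monetary benefit of the effect/cost differences at a WTP."""
    if wtp < 0:
        raise ValueError("willingness to pay must be non-negative")
    return delta_effect * wtp - delta_cost


@dataclass
class BootstrapReplicates:
    """Within-arm bootstrap replicates of per-arm means.

    ``costs`` and each entry of ``effects`` are (n_reps, n_arms) arrays
    aligned with ``arms``.
    """

    arms: tuple[str, ...]
    costs: np.ndarray
    effects: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_reps(self) -> int:
        return self.costs.shape[0]


def bootstrap_arms(
    table: pd.DataFrame,
    n_reps: int,
    seed,
    cost_col: str = "cost",
    effect_cols=("effect",),
    arm_col: str = "arm",
) -> BootstrapReplicates:
    """Bootstrap per-arm mean cost and effects, stratified by arm.

    Each replicate resamples participants with replacement within every
    arm, preserving arm sizes (the randomized design), and recomputes
    the per-arm means.  Rows with NaN in a column are excluded from that
    column's resampling pool (per-outcome availability).  Deterministic
    given ``seed`` (an int or :class:`numpy.random.Generator`).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    arms = tuple(dict.fromkeys(table[arm_col]))
    if not arms:
        raise ValueError("table has no participants in any arm")
    cols = [cost_col] + [c for c in effect_cols]
    costs = np.empty((n_reps, len(arms)))
    effects = {c: np.empty((n_reps, len(arms))) for c in effect_cols}
    for a_i, arm in enumerate(arms):
        sub = table[table[arm_col] == arm]
        if len(sub) == 0:
            raise ValueError(f"arm {arm!r} is empty")
        for col in cols:
            vals = sub[col].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            if len(vals) == 0:
                raise ValueError(f"arm {arm!r} has no data for {col!r}")
            idx = rng.integers(0, len(vals), size=(n_reps, len(vals)))
            means = vals[idx].mean(axis=1)
            if col == cost_col:
                costs[:, a_i] = means
            else:
                effects[col][:, a_i] = means
    return BootstrapReplicates(arms=arms, costs=costs, effects=effects)


def percentile_ci(replicates, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed percentile interval of a bootstrap distribution."""
    x = np.asarray(replicates, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 replicates for a percentile CI")
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(x, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


@dataclass
class CeacCurve:
    """Per-arm probability of highest NMB along a willingness-to-pay grid."""

    wtp: np.ndarray
    probabilities: pd.DataFrame  # one column per arm, rows follow wtp

    def to_frame(self) -> pd.DataFrame:
        out = self.probabilities.copy()
        out.insert(0, "wtp", self.wtp)
        return out


def ceac(replicates: BootstrapReplicates, wtp_grid,
         effect: str = "effect") -> CeacCurve:
    """Cost-effectiveness acceptability curve over a WTP grid.

    Per replicate and WTP, each arm's net benefit is E x WTP - C (any
    common reference cancels when ranking); the arm with the strictly
    highest value wins the replicate, exact ties splitting equally among
    the tied arms.  Probabilities therefore sum to one at every WTP.
    """
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("the willingness-to-pay grid is empty")
    eff = replicates.effects[effect]
    n_reps, n_arms = eff.shape
    probs = np.zeros((wtp_grid.size, n_arms))
    for i, w in enumerate(wtp_grid):
        nb = eff * w - replicates.costs  # (reps, arms)
        best = nb.max(axis=1, keepdims=True)
        winners = nb == best
        probs[i] = (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)
    return CeacCurve(
        wtp=wtp_grid,
        probabilities=pd.DataFrame(probs, columns=list(replicates.arms)),
    )


@dataclass
class EvaluationConfig:
    """Knobs of :func:`evaluate` (sampling, thresholds, scenario)."""

    wtp_threshold: float = WTP_DEFAULT
    wtp_grid: np.ndarray = field(default_factory=lambda: DEFAULT_WTP_GRID.copy())
    reps_cost: int = REPS_COST_CI
    reps_ceac: int = REPS_CEAC
    seed: int = 0
    scenario: str = "primary"
    reference_arm: str = "UC"


def _arm_summaries(analysis: pd.DataFrame, cost_col: str,
                   effect_col: str) -> list[ArmSummary]:
    out = []
    for arm, g in analysis.groupby("arm", sort=False):
        sub = g[[cost_col, effect_col]].dropna(how="all")
        out.append(ArmSummary(
            arm=arm,
            cost=float(g[cost_col].mean()),
            effect=float(g[effect_col].mean()),
            n=int(sub[effect_col].notna().sum()),
        ))
    return out


def _pairwise(summaries: list[ArmSummary], reference: str):
    by_arm = {s.arm: s for s in summaries}
    ref = by_arm[reference]
    others = [s for s in summaries if s.arm != reference]
    results = [incremental(s, ref) for s in others]
    # remaining head-to-head comparisons among non-reference arms
    for i in range(len(others)):
        for j in range(i + 1, len(others)):
            results.append(incremental(others[i], others[j]))
    return results


def evaluate(analysis: pd.DataFrame, config: EvaluationConfig | None = None) -> dict:
    """Run the full economic evaluation on a valued, imputed dataset.

    ``analysis`` has one row per participant with columns ``arm``,
    ``health_cost`` (annual euros), ``abstinent`` (0/1) and ``qaly``;
    NaN marks participants unavailable for that outcome.  Intervention
    costs for the configured scenario are added per arm.  Returns a
    bundle with arm summaries, pairwise incrementals on both outcome
    scales, cost CIs, CEAC/CUAC curves, the probability table at the
    WTP threshold, and the same bundle recomputed under the sensitivity
    scenario (program costs inflated by patient time and travel).
    """
    if config is None:
        config = EvaluationConfig()
    df = analysis.copy()
    df["total_cost"] = df["health_cost"] + df["arm"].map(
        lambda a: intervention_cost(a, config.scenario)
    )

    ss = np.random.SeedSequence(int(config.seed))
    seed_cost, seed_ceac = ss.spawn(2)

    summaries_cea = _arm_summaries(df, "total_cost", "abstinent")
    summaries_cua = _arm_summaries(df, "total_cost", "qaly")

    reps_ci = bootstrap_arms(
        df, config.reps_cost, np.random.default_rng(seed_cost),
        cost_col="total_cost", effect_cols=("abstinent", "qaly"),
    )
    arms = list(reps_ci.arms)
    ci_rows = []
    for i in range(len(arms)):
        for j in range(len(arms)):
            if i == j:
                continue
            diff = reps_ci.costs[:, i] - reps_ci.costs[:, j]
            lo, hi = percentile_ci(diff, 0.95)
            ci_rows.append({
                "comparison": f"{arms[i]}-{arms[j]}",
                "mean_diff": float(diff.mean()), "lo": lo, "hi": hi,
            })
    cost_ci = pd.DataFrame(ci_rows)

    reps_curve = bootstrap_arms(
        df, config.reps_ceac, np.random.default_rng(seed_ceac),
        cost_col="total_cost", effect_cols=("abstinent", "qaly"),
    )
    curve_cea = ceac(reps_curve, config.wtp_grid, effect="abstinent")
    curve_cua = ceac(reps_curve, config.wtp_grid, effect="qaly")
    at_wtp = pd.DataFrame({
        "outcome": ["abstinent", "qaly"],
        **{
            arm: [
                float(ceac(reps_curve, [config.wtp_threshold], effect=e)
                      .probabilities[arm].iloc[0])
                for e in ("abstinent", "qaly")
            ]
            for arm in arms
        },
    })

    bundle = {
        "scenario": config.scenario,
        "arm_summaries": pd.DataFrame([
            {"arm": s.arm, "outcome": outc, "mean_cost": s.cost,
             "mean_effect": s.effect, "n": s.n}
            for outc, group in (("abstinent", summaries_cea), ("qaly", summaries_cua))
            for s in group
        ]),
        "incrementals": pd.DataFrame([
            {"outcome": outc, "comparison": r.label, "delta_cost": r.delta_cost,
             "delta_effect": r.delta_effect, "icer": r.ratio,
             "classification": r.classification}
            for outc, summ in (("abstinent", summaries_cea), ("qaly", summaries_cua))
            for r in _pairwise(summ, config.reference_arm)
        ]),
        "cost_ci": cost_ci,
        "ceac": curve_cea.to_frame(),
        "cuac": curve_cua.to_frame(),
        "probabilities_at_wtp": at_wtp,
        "wtp_threshold": config.wtp_threshold,
    }

    if config.scenario == "primary":
        sens = EvaluationConfig(
            wtp_threshold=config.wtp_threshold,
            wtp_grid=config.wtp_grid,
            reps_cost=config.reps_cost,
            reps_ceac=config.reps_ceac,
            seed=config.seed,
            scenario="sensitivity",
            reference_arm=config.reference_arm,
        )
        bundle["sensitivity"] = evaluate(analysis, sens)
    return bundle
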
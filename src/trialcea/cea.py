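"""Monte Carlo cost-effectiveness propagation.

Builds (ΔC, ΔE) draw clouds from the fitted cost/effect regressions —
by default a patient-level cluster bootstrap with model refits, which
preserves the within-patient cost–effect correlation; alternatively
independent parametric normal draws per coefficient — and summarises them as
ICERs, cost-effectiveness-plane quadrant distributions, and acceptability
curves. Also hosts the CEAC-stability sample-size simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from trialcea.constants import ARM_BLENDED
from trialcea.costing import perspective_costs
from trialcea.errors import ConfigurationError, ModelError
from trialcea.models import CeaEstimates, fit_random_intercept

EFFECT_KINDS = ("response", "episode", "qaly")
PERSPECTIVES = ("societal", "provider")

#: Default willingness-to-pay grid: €0–80,000 in €1000 steps.
DEFAULT_WTP_GRID = tuple(range(0, 80001, 1000))

#: Default per-arm sizes for the CEAC-stability simulation (includes the
#: n=75 design point at which curves are expected to stabilise).
DEFAULT_STABILITY_N_GRID = (10, 25, 50, 75, 100, 150, 250, 500)

_MAX_REDRAW = 10
_MAX_DROP_FRACTION = 0.01


# ---------------------------------------------------------------------------
# analysis frame
# ---------------------------------------------------------------------------


@dataclass
class CeaFrame:
    """Follow-up rows ready for the paired cost/effect regressions.

    Columns: patient_id, treat, week, cost, effect, cost_baseline and
    (optionally) effect_baseline. The cost outcome is the cumulative cost at
    each follow-up rescaled to the full study horizon (cumulative × horizon /
    week), so ΔC is interpretable as the incremental cost over the whole
    study; likewise for QALYs.
    """

    df: pd.DataFrame
    perspective: str
    effect_kind: str
    horizon_weeks: float
    effect_baseline: str | None


def build_cea_frame(
    outcome_panel: pd.DataFrame,
    cost_panel: pd.DataFrame,
    perspective: str,
    effect_kind: str,
    exclude_inpatient: bool = False,
    indirect_only: bool = False,
    scale_to_horizon: bool = True,
) -> CeaFrame:
    """Merge the derived outcome and cost panels into one analysis frame."""
    if effect_kind not in EFFECT_KINDS:
        raise ConfigurationError("effect_kind", f"got {effect_kind!r}")
    if perspective not in PERSPECTIVES:
        raise ConfigurationError("perspective", f"got {perspective!r}")

    cost_col = perspective_costs(
        cost_panel, perspective, exclude_inpatient, indirect_only
    )
    costs = cost_panel[["patient_id", "week"]].copy()
    costs["cum_cost"] = cost_col.to_numpy()
    win_key = "win_societal" if perspective == "societal" else "win_direct_medical"
    baseline_win = (
        cost_panel.loc[cost_panel["week"] == 0, ["patient_id", win_key]]
        .rename(columns={win_key: "cost_baseline"})
    )

    df = outcome_panel.merge(costs, on=["patient_id", "week"], how="left").merge(
        baseline_win, on="patient_id", how="left"
    )
    df = df[df["week"] != 0].copy()
    df["treat"] = (df["arm"] == ARM_BLENDED).astype(float)
    horizon = float(df["week"].max())
    scale = (horizon / df["week"]) if scale_to_horizon else 1.0

    df["cost"] = df["cum_cost"] * scale
    if effect_kind == "response":
        df["effect"] = df["response"]
        effect_baseline = "baseline_ids"
    elif effect_kind == "episode":
        # effect = episode avoided, so a positive ΔE favours the blended arm
        df["effect"] = 1.0 - df["episode"]
        effect_baseline = None  # all patients share the baseline state
    else:
        df["effect"] = df["qaly_cum"] * scale
        effect_baseline = "baseline_utility"

    keep = ["patient_id", "treat", "week", "cost", "effect", "cost_baseline"]
    if effect_baseline:
        keep.append(effect_baseline)
    return CeaFrame(
        df=df[keep].reset_index(drop=True),
        perspective=perspective,
        effect_kind=effect_kind,
        horizon_weeks=horizon,
        effect_baseline=effect_baseline,
    )


def estimate_frame(frame: CeaFrame, reml: bool = True) -> CeaEstimates:
    """Point estimates of (ΔC, ΔE) for an analysis frame."""
    from trialcea.models import estimate_cea_effects

    est = estimate_cea_effects(
        frame.df,
        cost_outcome="cost",
        effect_outcome="effect",
        cost_baseline="cost_baseline",
        effect_baseline=frame.effect_baseline,
        reml=reml,
    )
    est.perspective = frame.perspective
    est.effect_kind = frame.effect_kind
    return est


# ---------------------------------------------------------------------------
# Monte Carlo pair sets
# ---------------------------------------------------------------------------


@dataclass
class CEPairSet:
    """Monte Carlo draws of (incremental cost, incremental effect)."""

    delta_cost: np.ndarray
    delta_effect: np.ndarray
    perspective: str
    effect_kind: str
    seed: int
    method: str
    point: CeaEstimates | None = None
    n_failed: int = 0

    def __post_init__(self) -> None:
        self.delta_cost = np.asarray(self.delta_cost, dtype=float)
        self.delta_effect = np.asarray(self.delta_effect, dtype=float)
        if self.delta_cost.shape != self.delta_effect.shape:
            raise ConfigurationError("draws", "cost and effect draws differ in length")
        if not (
            np.all(np.isfinite(self.delta_cost))
            and np.all(np.isfinite(self.delta_effect))
        ):
            raise ConfigurationError("draws", "non-finite (ΔC, ΔE) pairs")

    @property
    def n_draws(self) -> int:
        return len(self.delta_cost)


def draw_ce_pairs(
    frame: CeaFrame,
    n_draws: int = 5000,
    seed: int = 0,
    method: str = "cluster_bootstrap",
) -> CEPairSet:
    """Monte Carlo (ΔC, ΔE) pairs for one perspective × effect measure.

    ``cluster_bootstrap`` resamples patients with replacement within arm and
    refits both regressions on every replicate; replicates that fail to fit
    are redrawn up to 10 times and then dropped (more than 1% drops aborts
    the run). ``parametric`` draws independently from the normal sampling
    distributions of the two fitted group coefficients — faster, but blind
    to the within-patient cost–effect correlation. Identical seeds yield
    bit-identical pair sets.
    """
    if method not in ("cluster_bootstrap", "parametric"):
        raise ConfigurationError("method", f"got {method!r}")
    if n_draws < 1:
        raise ConfigurationError("n_draws", "must be >= 1")
    point = estimate_frame(frame)
    rng = np.random.default_rng(seed)

    if method == "parametric":
        dc = rng.normal(point.cost.group_estimate, point.cost.group_se, n_draws)
        de = rng.normal(point.effect.group_estimate, point.effect.group_se, n_draws)
        return CEPairSet(
            dc, de, frame.perspective, frame.effect_kind, seed, method, point
        )

    df = frame.df.sort_values(["patient_id", "week"]).reset_index(drop=True)
    pid_codes, _ = pd.factorize(df["patient_id"])
    n_pat = pid_codes.max() + 1
    rows_by_patient = [np.flatnonzero(pid_codes == i) for i in range(n_pat)]
    counts = np.array([len(r) for r in rows_by_patient])
    treat_of = np.array(
        [df["treat"].iloc[rows_by_patient[i][0]] for i in range(n_pat)]
    )
    arm_idx = [np.flatnonzero(treat_of == v) for v in (1.0, 0.0)]

    cost_cols = ["treat", "cost_baseline"]
    eff_cols = ["treat"] + ([frame.effect_baseline] if frame.effect_baseline else [])
    ones = np.ones(len(df))
    Xc = np.column_stack([ones] + [df[c].to_numpy(dtype=float) for c in cost_cols])
    Xe = np.column_stack([ones] + [df[c].to_numpy(dtype=float) for c in eff_cols])
    yc = df["cost"].to_numpy(dtype=float)
    ye = df["effect"].to_numpy(dtype=float)

    dc = np.empty(n_draws)
    de = np.empty(n_draws)
    n_failed = 0
    for b in range(n_draws):
        ok = False
        for _ in range(_MAX_REDRAW):
            sampled = np.concatenate(
                [rng.choice(idx, size=len(idx), replace=True) for idx in arm_idx]
            )
            rows = np.concatenate([rows_by_patient[p] for p in sampled])
            groups = np.repeat(np.arange(len(sampled)), counts[sampled])
            try:
                fc = fit_random_intercept(Xc[rows], yc[rows], groups)
                fe = fit_random_intercept(Xe[rows], ye[rows], groups)
            except ModelError:
                continue
            dc[b] = fc.params.iloc[1]
            de[b] = fe.params.iloc[1]
            ok = True
            break
        if not ok:
            n_failed += 1
            dc[b] = np.nan
            de[b] = np.nan
    if n_failed:
        keep = np.isfinite(dc)
        dc, de = dc[keep], de[keep]
        if n_failed > _MAX_DROP_FRACTION * n_draws:
            raise ModelError(
                f"{n_failed}/{n_draws} bootstrap replicates failed to fit (> 1%)"
            )
    return CEPairSet(
        dc, de, frame.perspective, frame.effect_kind, seed, method, point, n_failed
    )


# ---------------------------------------------------------------------------
# ICER, plane, CEAC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IcerResult:
    """ICER with its quadrant label; a bare ratio is sign-ambiguous."""

    value: float
    quadrant: str
    dominance: str
    defined: bool = True


def icer(delta_cost: float, delta_effect: float) -> IcerResult:
    """Incremental cost-effectiveness ratio ΔC/ΔE with quadrant attached.

    ΔE = 0 yields an undefined-ICER signal (``defined=False``, NaN value)
    rather than an infinity. Quadrant convention: ΔE > 0 is east, ΔC > 0 is
    north; ΔE = 0 counts west and ΔC = 0 counts south.
    """
    if not (np.isfinite(delta_cost) and np.isfinite(delta_effect)):
        raise ConfigurationError("icer", "inputs must be finite")
    east = delta_effect > 0
    north = delta_cost > 0
    quadrant = ("N" if north else "S") + ("E" if east else "W")
    dominance = {
        "NE": "tradeoff-NE",
        "SE": "dominant",
        "NW": "dominated",
        "SW": "tradeoff-SW",
    }[quadrant]
    if delta_effect == 0:
        return IcerResult(float("nan"), quadrant, dominance, defined=False)
    return IcerResult(delta_cost / delta_effect, quadrant, dominance)


@dataclass(frozen=True)
class PlaneSummary:
    """Quadrant proportions of a pair cloud plus its central ICER."""

    proportions: Mapping[str, float]
    icer: IcerResult

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("proportions", f"sum to {total}, not 1")


def plane_distribution(pairs: CEPairSet) -> PlaneSummary:
    """Fraction of draws per cost-effectiveness-plane quadrant.

    Boundary convention (documented, measure-zero for continuous draws):
    ΔE > 0 is east, ΔC > 0 is north; ΔE = 0 counts west, ΔC = 0 south.
    """
    if pairs.n_draws == 0:
        raise ConfigurationError("pairs", "empty pair set")
    east = pairs.delta_effect > 0
    north = pairs.delta_cost > 0
    n = pairs.n_draws
    props = {
        "NE": float(np.sum(east & north)) / n,
        "NW": float(np.sum(~east & north)) / n,
        "SE": float(np.sum(east & ~north)) / n,
        "SW": float(np.sum(~east & ~north)) / n,
    }
    central = icer(float(np.mean(pairs.delta_cost)), float(np.mean(pairs.delta_effect)))
    return PlaneSummary(props, central)


@dataclass(frozen=True)
class CEACCurve:
    """Acceptability probabilities over a willingness-to-pay grid."""

    wtp_grid: np.ndarray
    probability: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "wtp_grid", np.asarray(self.wtp_grid, dtype=float))
        object.__setattr__(
            self, "probability", np.asarray(self.probability, dtype=float)
        )
        if np.any(np.diff(self.wtp_grid) <= 0):
            raise ConfigurationError("wtp_grid", "must be strictly increasing")
        if np.any((self.probability < 0) | (self.probability > 1)):
            raise ConfigurationError("probability", "outside [0, 1]")

    def at(self, wtp: float) -> float:
        idx = np.flatnonzero(self.wtp_grid == wtp)
        if len(idx) == 0:
            raise KeyError(f"willingness-to-pay {wtp} not on the grid")
        return float(self.probability[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp_grid, "probability": self.probability})


def ceac(pairs: CEPairSet, wtp_grid: Sequence[float] = DEFAULT_WTP_GRID) -> CEACCurve:
    """Acceptability curve: P(λ·ΔE − ΔC > 0) at each ceiling λ.

    Strict inequality — a draw whose net monetary benefit ties at zero
    counts as not cost-effective (conservative).
    """
    grid = np.asarray(wtp_grid, dtype=float)
    nmb = grid[:, None] * pairs.delta_effect[None, :] - pairs.delta_cost[None, :]
    prob = np.mean(nmb > 0, axis=1)
    return CEACCurve(grid, prob)


def summarize(
    pairs: CEPairSet, wtp_grid: Sequence[float] = DEFAULT_WTP_GRID
) -> dict:
    """One row of the results table for a pair set.

    ΔC/ΔE central estimates come from the fitted models when available
    (otherwise the draw means); uncertainty intervals are reported both as
    percentile bootstrap intervals (default) and Wald intervals.
    """
    plane = plane_distribution(pairs)
    point = pairs.point
    if point is not None:
        dc, de = point.delta_cost, point.delta_effect
        wald_c, wald_e = point.cost.group_ci(), point.effect.group_ci()
    else:
        dc, de = float(np.mean(pairs.delta_cost)), float(np.mean(pairs.delta_effect))
        wald_c = wald_e = (float("nan"), float("nan"))
    pct = lambda a: tuple(np.percentile(a, [2.5, 97.5]))
    ci_c, ci_e = pct(pairs.delta_cost), pct(pairs.delta_effect)
    central = icer(dc, de)
    return {
        "perspective": pairs.perspective,
        "effect_kind": pairs.effect_kind,
        "method": pairs.method,
        "n_draws": pairs.n_draws,
        "delta_cost": dc,
        "delta_cost_ci_low": ci_c[0],
        "delta_cost_ci_high": ci_c[1],
        "delta_cost_wald_low": wald_c[0],
        "delta_cost_wald_high": wald_c[1],
        "delta_effect": de,
        "delta_effect_ci_low": ci_e[0],
        "delta_effect_ci_high": ci_e[1],
        "delta_effect_wald_low": wald_e[0],
        "delta_effect_wald_high": wald_e[1],
        "icer": central.value,
        "icer_quadrant": central.quadrant,
        "dominance": central.dominance,
        "pct_ne": plane.proportions["NE"] * 100,
        "pct_nw": plane.proportions["NW"] * 100,
        "pct_se": plane.proportions["SE"] * 100,
        "pct_sw": plane.proportions["SW"] * 100,
    }


def sensitivity_suite(
    outcome_panel: pd.DataFrame,
    cost_panel: pd.DataFrame,
    variants: Sequence[str],
    effect_kind: str = "response",
    n_draws: int = 1000,
    seed: int = 0,
    method: str = "cluster_bootstrap",
    wtp_grid: Sequence[float] = DEFAULT_WTP_GRID,
) -> dict[str, dict]:
    """Re-run the societal analysis under alternative cost aggregates.

    Variants: ``exclude_inpatient`` strips inpatient items before
    aggregation; ``indirect_only`` analyses absenteeism/presenteeism costs
    alone.
    """
    known = {"exclude_inpatient", "indirect_only"}
    unknown = set(variants) - known
    if unknown:
        raise ConfigurationError("variants", f"unknown: {sorted(unknown)}")
    out = {}
    for variant in variants:
        frame = build_cea_frame(
            outcome_panel,
            cost_panel,
            perspective="societal",
            effect_kind=effect_kind,
            exclude_inpatient=(variant == "exclude_inpatient"),
            indirect_only=(variant == "indirect_only"),
        )
        pairs = draw_ce_pairs(frame, n_draws=n_draws, seed=seed, method=method)
        summary = summarize(pairs, wtp_grid)
        summary["variant"] = variant
        out[variant] = summary
    return out


# ---------------------------------------------------------------------------
# CEAC-stability sample-size simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationParams:
    """Fixed population-level cost/effect distributions for the power study.

    Per-arm (blended, comparator) normal means and SDs of per-patient total
    cost (€) and effect, with an optional within-patient cost–effect
    correlation.
    """

    cost_mean: tuple[float, float] = (5200.0, 4500.0)
    cost_sd: tuple[float, float] = (3500.0, 3000.0)
    effect_mean: tuple[float, float] = (0.45, 0.35)
    effect_sd: tuple[float, float] = (0.50, 0.48)
    correlation: float = -0.2

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.cost_sd + self.effect_sd):
            raise ConfigurationError("population", "SDs must be >= 0")
        if not -1.0 <= self.correlation <= 1.0:
            raise ConfigurationError("correlation", "must be in [-1, 1]")


@dataclass
class StabilityResult:
    """Across-trial CEAC dispersion per sample size and ceiling ratio."""

    table: pd.DataFrame  # columns: n, wtp, prob_mean, dispersion
    reps: int
    seed: int

    def dispersion_by_n(self) -> pd.Series:
        """Maximum dispersion over the ceiling grid, per n."""
        return self.table.groupby("n")["dispersion"].max()

    def smallest_stable_n(self, threshold: float = 0.05) -> int | None:
        """Smallest per-arm n whose max CEAC dispersion is below threshold."""
        by_n = self.dispersion_by_n()
        stable = by_n[by_n < threshold]
        return int(stable.index[0]) if len(stable) else None


def _simulate_trial_ceac(
    rng: np.random.Generator,
    pop: PopulationParams,
    n: int,
    wtp: np.ndarray,
    n_draws: int,
) -> np.ndarray:
    # draw correlated (cost, effect) per patient per arm
    deltas = []
    for arm in (0, 1):
        cov = pop.correlation * pop.cost_sd[arm] * pop.effect_sd[arm]
        sigma = np.array(
            [[pop.cost_sd[arm] ** 2, cov], [cov, pop.effect_sd[arm] ** 2]]
        )
        mean = np.array([pop.cost_mean[arm], pop.effect_mean[arm]])
        if np.all(sigma == 0):
            sample = np.tile(mean, (n, 1))
        else:
            sample = rng.multivariate_normal(mean, sigma, size=n, method="cholesky")
        deltas.append(sample)
    diff_mean = deltas[0].mean(axis=0) - deltas[1].mean(axis=0)
    se = np.sqrt(deltas[0].var(ddof=1, axis=0) / n + deltas[1].var(ddof=1, axis=0) / n)
    # degenerate populations: floating noise in the variance of constant
    # samples must not smear the (deterministic) net-benefit sign
    se[se < 1e-9 * (1.0 + np.abs(diff_mean))] = 0.0
    dc = rng.normal(diff_mean[0], se[0], n_draws)
    de = rng.normal(diff_mean[1], se[1], n_draws)
    nmb = wtp[:, None] * de[None, :] - dc[None, :]
    return np.mean(nmb > 0, axis=1)


def ceac_stability(
    population: PopulationParams | None = None,
    n_grid: Sequence[int] = DEFAULT_STABILITY_N_GRID,
    reps: int = 100,
    wtp_grid: Sequence[float] = DEFAULT_WTP_GRID,
    seed: int = 0,
    n_draws_per_trial: int = 200,
) -> StabilityResult:
    """CEAC-stability simulation over a grid of per-arm sample sizes.

    For each n, ``reps`` trials are simulated from the fixed population
    cost/effect distributions, each trial's acceptability curve is computed,
    and the across-trial standard deviation of the probability at each
    ceiling ratio is reported. Dispersion shrinking with n identifies the
    smallest design at which the curve is stable.
    """
    if population is None:
        population = PopulationParams()
    n_grid = list(n_grid)
    if any(b <= a for a, b in zip(n_grid, n_grid[1:])):
        raise ConfigurationError("n_grid", "must be strictly increasing")
    if reps < 2:
        raise ConfigurationError("reps", "need at least 2 repetitions")
    wtp = np.asarray(wtp_grid, dtype=float)
    rng = np.random.default_rng(seed)
    records = []
    for n in n_grid:
        probs = np.empty((reps, len(wtp)))
        for r in range(reps):
            probs[r] = _simulate_trial_ceac(
                rng, population, n, wtp, n_draws_per_trial
            )
        records.append(
            pd.DataFrame(
                {
                    "n": n,
                    "wtp": wtp,
                    "prob_mean": probs.mean(axis=0),
                    "dispersion": probs.std(axis=0, ddof=1),
                }
            )
        )
    return StabilityResult(pd.concat(records, ignore_index=True), reps, seed)


# ---------------------------------------------------------------------------
# plotting (optional artifacts)
# ---------------------------------------------------------------------------


def plot_plane(pairs: CEPairSet, path) -> None:
    """Scatter the pair cloud on the cost-effectiveness plane."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(pairs.delta_effect, pairs.delta_cost, s=4, alpha=0.3)
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel(f"incremental effect ({pairs.effect_kind})")
    ax.set_ylabel("incremental cost (€)")
    ax.set_title(f"{pairs.perspective} perspective")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(curves: Mapping[str, CEACCurve], path) -> None:
    """Plot one or more acceptability curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, curve in curves.items():
        ax.plot(curve.wtp_grid, curve.probability, label=label)
    ax.set_xlabel("willingness-to-pay ceiling (€ per effect unit)")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
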
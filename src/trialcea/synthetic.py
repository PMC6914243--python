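"""Synthetic two-arm trial generator.

Produces long-format per-patient-per-assessment datasets with the joint
structure the downstream analysis assumes: a depression score trajectory with
arm and time effects, utilities negatively linked to severity, right-skewed
window costs with rare high-cost inpatient events, per-patient session and
feedback counts, and covariate-dependent (age, employment) missingness at
follow-up assessments.

The generator is fully deterministic given ``seed``: all randomness flows
from one :class:`numpy.random.SeedSequence` through named substreams.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from trialcea.constants import (
    ARM_BLENDED,
    ARM_STANDARD,
    ARMS,
    DEFAULT_ASSESSMENT_WEEKS,
    RESOURCE_PREFIX,
)
from trialcea.errors import ConfigurationError

IDS_MIN, IDS_MAX = 0, 84
UTILITY_MIN, UTILITY_MAX = -0.33, 1.0

#: Columns of the long-format trial dataset, in canonical order.
DATASET_COLUMNS = [
    "patient_id",
    "arm",
    "age",
    "employed",
    "week",
    "ids_sr",
    "utility",
    "episode",
    f"{RESOURCE_PREFIX}gp_visit",
    f"{RESOURCE_PREFIX}specialist_visit",
    f"{RESOURCE_PREFIX}prescription",
    f"{RESOURCE_PREFIX}psychiatric_inpatient_day",
    f"{RESOURCE_PREFIX}informal_care_hour",
    f"{RESOURCE_PREFIX}productivity_hour",
    "n_f2f_sessions",
    "n_online_sessions",
    "n_feedback_messages",
]

#: Columns blanked out when a follow-up assessment is missing. Session counts
#: are administrative data and survive questionnaire non-response.
ASSESSMENT_COLUMNS = [
    "ids_sr",
    "utility",
    "episode",
    f"{RESOURCE_PREFIX}gp_visit",
    f"{RESOURCE_PREFIX}specialist_visit",
    f"{RESOURCE_PREFIX}prescription",
    f"{RESOURCE_PREFIX}psychiatric_inpatient_day",
    f"{RESOURCE_PREFIX}informal_care_hour",
    f"{RESOURCE_PREFIX}productivity_hour",
]


@dataclass(frozen=True)
class UtilityLink:
    """Linear map from depression score to EQ-5D-style utility.

    utility = intercept - slope * score + N(0, noise_sd), clamped to
    [-0.33, 1] (national-tariff floor).
    """

    intercept: float = 0.90
    slope: float = 0.012
    noise_sd: float = 0.12


@dataclass(frozen=True)
class CostCategoryParams:
    """Gamma(shape, scale) for one cost category's 4-week window total (€)."""

    shape: float
    scale: float

    @property
    def mean(self) -> float:
        return self.shape * self.scale


@dataclass(frozen=True)
class CostParams:
    """Window-cost distributions per category plus rare inpatient events.

    Right-skewed gamma totals reproduce the heavy-tailed cost pattern;
    an independent Bernoulli inpatient event adds a fixed high cost to the
    direct-medical category.
    """

    direct_medical: CostCategoryParams = CostCategoryParams(0.45, 1200.0)
    direct_nonmedical: CostCategoryParams = CostCategoryParams(0.40, 850.0)
    indirect_nonmedical: CostCategoryParams = CostCategoryParams(0.30, 2500.0)
    inpatient_prob: float = 0.015
    inpatient_cost: float = 5100.0


@dataclass(frozen=True)
class DropoutModel:
    """Per-visit logistic missingness model in age and employment.

    logit P(missing) = intercept + age_coef * (age - age_ref)
                       + employed_coef * employed

    ``monotone=True`` makes dropout absorbing (no return after a missed
    assessment); the default allows intermittent missingness.
    """

    intercept: float = -1.1
    age_coef: float = -0.04
    employed_coef: float = -0.5
    age_ref: float = 40.0
    monotone: bool = False


@dataclass(frozen=True)
class SessionParams:
    """Truncated-normal session/feedback count parameters per arm."""

    blended_online: tuple[float, float, float, float] = (9.6, 4.4, 0, 16)
    blended_f2f: tuple[float, float, float, float] = (10.0, 4.6, 0, 16)
    blended_feedback: tuple[float, float, float, float] = (8.4, 4.2, 0, 15)
    standard_f2f: tuple[float, float, float, float] = (13.3, 6.3, 0, 27)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterisation of the synthetic trial generator.

    Defaults emulate the published two-arm baseline structure
    (n = 53/49, baseline score 45.2 (12.1) vs 41.5 (11.6), utilities around
    0.36/0.46, skewed window costs with rare inpatient spikes) and
    follow-up missingness associated with younger age and unemployment.
    """

    n_per_arm: tuple[int, int] = (53, 49)
    assessment_weeks: tuple[int, ...] = DEFAULT_ASSESSMENT_WEEKS
    baseline_ids_mean_sd: tuple[tuple[float, float], tuple[float, float]] = (
        (45.2, 12.1),
        (41.5, 11.6),
    )
    #: Mean score change per assessment step at follow-up (cumulative).
    time_effect: float = -7.13
    #: Additive arm (blended) effect on follow-up scores.
    group_effect: float = 0.0
    #: Between-patient random-intercept SD of the follow-up trajectory.
    #: The source trial reports no between-assessment correlation; this
    #: default is a guess and should be treated as such.
    random_intercept_sd: float = 6.0
    #: Within-patient residual SD at follow-up.
    residual_sd: float = 6.0
    utility_link: UtilityLink = field(default_factory=UtilityLink)
    cost_params: CostParams = field(default_factory=CostParams)
    #: Additive arm (blended) effect on follow-up direct-medical window costs (€).
    group_cost_effect: float = 0.0
    #: Episode model: logit P(episode) = intercept + time_logor * step
    #: (+ group_logor for blended); baseline is always an episode.
    episode_intercept: float = 0.9
    episode_time_logor: float = -1.47
    episode_group_logor: float = 0.0
    dropout_model: DropoutModel = field(default_factory=DropoutModel)
    session_params: SessionParams = field(default_factory=SessionParams)
    age_mean_sd: tuple[float, float] = (38.8, 10.9)
    employed_prob: float = 0.58
    seed: int = 0

    def __post_init__(self) -> None:
        for i, n in enumerate(self.n_per_arm):
            if int(n) != n or n <= 0:
                raise ConfigurationError(
                    "n_per_arm", f"arm {i} size must be a positive integer, got {n!r}"
                )
        weeks = tuple(self.assessment_weeks)
        if len(weeks) < 2:
            raise ConfigurationError(
                "assessment_weeks", "need at least baseline and one follow-up"
            )
        if weeks[0] != 0:
            raise ConfigurationError("assessment_weeks", "first assessment must be week 0")
        if any(b <= a for a, b in zip(weeks, weeks[1:])):
            raise ConfigurationError("assessment_weeks", "weeks must be strictly increasing")
        for arm_i, (_, sd) in enumerate(self.baseline_ids_mean_sd):
            if sd <= 0:
                raise ConfigurationError(
                    "baseline_ids_mean_sd", f"arm {arm_i} SD must be > 0, got {sd!r}"
                )
        if self.random_intercept_sd < 0:
            raise ConfigurationError("random_intercept_sd", "must be >= 0")
        if self.residual_sd < 0:
            raise ConfigurationError("residual_sd", "must be >= 0")
        if self.utility_link.noise_sd < 0:
            raise ConfigurationError("utility_link.noise_sd", "must be >= 0")
        cp = self.cost_params
        for name in ("direct_medical", "direct_nonmedical", "indirect_nonmedical"):
            cat = getattr(cp, name)
            if cat.shape <= 0 or cat.scale <= 0:
                raise ConfigurationError(
                    f"cost_params.{name}", "gamma shape and scale must be > 0"
                )
        if not 0.0 <= cp.inpatient_prob <= 1.0:
            raise ConfigurationError("cost_params.inpatient_prob", "must be in [0, 1]")
        if cp.inpatient_cost < 0:
            raise ConfigurationError("cost_params.inpatient_cost", "must be >= 0")
        if not 0.0 <= self.employed_prob <= 1.0:
            raise ConfigurationError("employed_prob", "must be in [0, 1]")
        if self.age_mean_sd[1] <= 0:
            raise ConfigurationError("age_mean_sd", "SD must be > 0")

    @property
    def n_followups(self) -> int:
        return len(self.assessment_weeks) - 1

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        nested = {
            "utility_link": UtilityLink,
            "dropout_model": DropoutModel,
            "session_params": SessionParams,
        }
        for key, typ in nested.items():
            if key in d and isinstance(d[key], Mapping):
                d[key] = typ(**d[key])
        if "cost_params" in d and isinstance(d["cost_params"], Mapping):
            cp = dict(d["cost_params"])
            for cat in ("direct_medical", "direct_nonmedical", "indirect_nonmedical"):
                if cat in cp and isinstance(cp[cat], Mapping):
                    cp[cat] = CostCategoryParams(**cp[cat])
                elif cat in cp and isinstance(cp[cat], Sequence):
                    cp[cat] = CostCategoryParams(*cp[cat])
            d["cost_params"] = CostParams(**cp)
        for key in ("n_per_arm", "assessment_weeks", "age_mean_sd"):
            if key in d and isinstance(d[key], Sequence):
                d[key] = tuple(d[key])
        if "baseline_ids_mean_sd" in d:
            d["baseline_ids_mean_sd"] = tuple(
                tuple(pair) for pair in d["baseline_ids_mean_sd"]
            )
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigurationError("generator", str(exc)) from exc

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneratorConfig":
        """Load from a YAML or JSON key-value file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise ConfigurationError("generator", f"{path} does not contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    """Truncated-normal draw via inverse CDF so the support is exact."""
    from scipy import stats

    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = rng.random(size)
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def _clamp_round_score(x: np.ndarray) -> np.ndarray:
    """Clamp to the instrument range before rounding to integer points."""
    return np.round(np.clip(x, IDS_MIN, IDS_MAX))


def generate_trial(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a complete (no missingness) long-format trial dataset.

    Returns one row per patient × assessment week with columns
    :data:`DATASET_COLUMNS`. Apply :func:`apply_missingness` afterwards to
    impose the follow-up dropout mechanism.
    """
    ss = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("covariates", "scores", "utility", "costs", "sessions", "episode"),
            ss.spawn(6),
        )
    }

    weeks = np.asarray(config.assessment_weeks)
    n_weeks = len(weeks)
    n_total = sum(config.n_per_arm)
    arm_of = np.repeat(np.arange(2), config.n_per_arm)  # 0=blended, 1=standard
    is_blended = (arm_of == 0).astype(float)

    rng = streams["covariates"]
    age = np.clip(rng.normal(*config.age_mean_sd, size=n_total), 18, 70)
    employed = rng.random(n_total) < config.employed_prob

    # Score trajectories: baseline + cumulative time effect + arm effect
    # + patient random intercept + residual noise at follow-ups.
    rng = streams["scores"]
    base_mean = np.array([m for m, _ in config.baseline_ids_mean_sd])[arm_of]
    base_sd = np.array([s for _, s in config.baseline_ids_mean_sd])[arm_of]
    baseline_latent = rng.normal(base_mean, base_sd)
    b_i = rng.normal(0.0, config.random_intercept_sd, size=n_total)
    scores = np.empty((n_total, n_weeks))
    scores[:, 0] = baseline_latent
    for k in range(1, n_weeks):
        eps = rng.normal(0.0, config.residual_sd, size=n_total)
        scores[:, k] = (
            baseline_latent
            + k * config.time_effect
            + config.group_effect * is_blended
            + b_i
            + eps
        )
    scores = _clamp_round_score(scores)

    rng = streams["utility"]
    link = config.utility_link
    util = (
        link.intercept
        - link.slope * scores
        + rng.normal(0.0, link.noise_sd, size=scores.shape)
    )
    util = np.clip(util, UTILITY_MIN, UTILITY_MAX)

    # Window costs: per-category gamma € totals translated into item counts
    # at the default unit prices, so that costing reconstructs the drawn
    # amounts exactly. Counts are continuous-valued usage intensities.
    rng = streams["costs"]
    cp = config.cost_params
    dm = rng.gamma(cp.direct_medical.shape, cp.direct_medical.scale, size=scores.shape)
    dm[:, 1:] += config.group_cost_effect * is_blended[:, None]
    dm = np.clip(dm, 0.0, None)
    dnm = rng.gamma(cp.direct_nonmedical.shape, cp.direct_nonmedical.scale, size=scores.shape)
    inm = rng.gamma(
        cp.indirect_nonmedical.shape, cp.indirect_nonmedical.scale, size=scores.shape
    )
    inpatient = rng.random(scores.shape) < cp.inpatient_prob

    # Default unit prices used to express € budgets as counts; must stay in
    # sync with costing.default_unit_cost_table().
    from trialcea.costing import (
        DEFAULT_DISPENSING_FEE,
        DEFAULT_PRICES,
    )

    p_gp = DEFAULT_PRICES["gp_visit"]
    p_spec = DEFAULT_PRICES["specialist_visit"]
    p_rx = DEFAULT_PRICES["prescription"] + DEFAULT_DISPENSING_FEE
    p_inp = DEFAULT_PRICES["psychiatric_inpatient_day"]
    p_informal = DEFAULT_PRICES["informal_care_hour"]
    p_prod = DEFAULT_PRICES["productivity_hour"]

    ru = {
        "gp_visit": dm * 0.45 / p_gp,
        "specialist_visit": dm * 0.35 / p_spec,
        "prescription": dm * 0.20 / p_rx,
        "psychiatric_inpatient_day": inpatient * (cp.inpatient_cost / p_inp),
        "informal_care_hour": dnm / p_informal,
        "productivity_hour": inm / p_prod,
    }

    rng = streams["sessions"]
    sp = config.session_params
    n_online = np.where(
        arm_of == 0,
        np.round(_truncnorm(rng, *sp.blended_online, n_total)),
        0,
    ).astype(int)
    f2f_blended = np.round(_truncnorm(rng, *sp.blended_f2f, n_total))
    f2f_standard = np.round(_truncnorm(rng, *sp.standard_f2f, n_total))
    n_f2f = np.where(arm_of == 0, f2f_blended, f2f_standard).astype(int)
    n_feedback = np.where(
        arm_of == 0,
        np.round(_truncnorm(rng, *sp.blended_feedback, n_total)),
        0,
    ).astype(int)

    # Episode status: always present at baseline, declining odds at follow-up.
    rng = streams["episode"]
    steps = np.arange(n_weeks)
    logit = (
        config.episode_intercept
        + config.episode_time_logor * steps[None, :]
        + config.episode_group_logor * is_blended[:, None]
    )
    p_episode = 1.0 / (1.0 + np.exp(-logit))
    episode = (rng.random(scores.shape) < p_episode).astype(float)
    episode[:, 0] = 1.0

    pid = np.repeat(np.arange(1, n_total + 1), n_weeks)
    rows = {
        "patient_id": pid,
        "arm": np.repeat(np.array(ARMS)[arm_of], n_weeks),
        "age": np.repeat(np.round(age, 1), n_weeks),
        "employed": np.repeat(employed, n_weeks),
        "week": np.tile(weeks, n_total),
        "ids_sr": scores.ravel(),
        "utility": util.ravel(),
        "episode": episode.ravel(),
    }
    for item, counts in ru.items():
        rows[f"{RESOURCE_PREFIX}{item}"] = counts.ravel()
    rows["n_f2f_sessions"] = np.repeat(n_f2f, n_weeks)
    rows["n_online_sessions"] = np.repeat(n_online, n_weeks)
    rows["n_feedback_messages"] = np.repeat(n_feedback, n_weeks)

    return pd.DataFrame(rows, columns=DATASET_COLUMNS)


def apply_missingness(data: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Blank follow-up assessments according to the configured dropout model.

    Baseline rows are never touched. Missingness probability per follow-up
    visit follows the logistic model in (centred) age and employment; with
    ``monotone=True`` a patient never returns after the first missed visit.
    A degenerate model with all-zero coefficients yields MCAR at the rate
    implied by the intercept.
    """
    dm = config.dropout_model
    out = data.copy()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(7)[-1])

    patients = out.drop_duplicates("patient_id")[["patient_id", "age", "employed"]]
    eta = (
        dm.intercept
        + dm.age_coef * (patients["age"].to_numpy() - dm.age_ref)
        + dm.employed_coef * patients["employed"].to_numpy().astype(float)
    )
    with np.errstate(over="ignore"):
        p_miss = 1.0 / (1.0 + np.exp(-eta))

    n_fu = config.n_followups
    miss = rng.random((len(patients), n_fu)) < p_miss[:, None]
    if dm.monotone:
        miss = np.maximum.accumulate(miss, axis=1)

    weeks = list(config.assessment_weeks)
    fu_index = {w: k - 1 for k, w in enumerate(weeks) if k > 0}
    pid_pos = {pid: i for i, pid in enumerate(patients["patient_id"].to_numpy())}

    is_fu = out["week"] != 0
    rows_pid = out.loc[is_fu, "patient_id"].map(pid_pos).to_numpy()
    rows_fu = out.loc[is_fu, "week"].map(fu_index).to_numpy()
    blank = miss[rows_pid, rows_fu]

    idx = out.index[is_fu][blank]
    out.loc[idx, ASSESSMENT_COLUMNS] = np.nan
    return out


def write_dataset(data: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    """Write the long-format CSV plus a JSON metadata sidecar."""
    path = Path(path)
    data.to_csv(path, index=False)
    meta = {
        "format": "trialcea long-format trial dataset v1",
        "columns": list(data.columns),
        "n_rows": int(len(data)),
        "n_patients": int(data["patient_id"].nunique()),
        "seed": seed,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_dataset(path: str | Path) -> pd.DataFrame:
    """Read a long-format trial dataset CSV."""
    df = pd.read_csv(path)
    missing = [c for c in ("patient_id", "arm", "week", "ids_sr") if c not in df.columns]
    if missing:
        raise ConfigurationError("dataset", f"{path}: missing columns {missing}")
    if "employed" in df.columns:
        df["employed"] = df["employed"].astype(bool)
    return df
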
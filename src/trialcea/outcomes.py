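"""Clinical and utility outcome derivation.

Reliable change, treatment response, remission, severity classes, completer
status, and cumulative QALYs from interpolated utilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from trialcea.constants import WEEKS_PER_YEAR
from trialcea.errors import ConfigurationError

#: Score-range upper bounds of the severity classes, inclusive:
#: none ≤ 13 < mild ≤ 25 < moderate ≤ 38 < severe ≤ 48 < very severe.
DEFAULT_SEVERITY_CUTPOINTS = (13, 25, 38, 48)
SEVERITY_LABELS = ("none", "mild", "moderate", "severe", "very severe")

#: Sessions in the standard protocol and the completer fraction.
PROTOCOL_SESSIONS = 18
COMPLETER_FRACTION = 0.75


@dataclass(frozen=True)
class RciParams:
    """Reliable-change parameters.

    ``se_diff`` is the published standard error of the difference scores
    (4.78 at Cronbach alpha 0.84) used as-is rather than recomputed from a
    baseline SD; ``cronbach_alpha`` is metadata only.
    """

    se_diff: float = 4.78
    rci_cutoff: float = -1.96
    remission_score_cutoff: float = 13.0
    cronbach_alpha: float = 0.84

    def __post_init__(self) -> None:
        if self.se_diff <= 0:
            raise ConfigurationError("se_diff", "must be > 0")
        if self.rci_cutoff >= 0:
            raise ConfigurationError("rci_cutoff", "must be < 0")


_DEFAULT = RciParams()


def compute_rci(baseline_score, followup_score, params: RciParams = _DEFAULT):
    """Reliable change index: (follow-up − baseline) / se_diff.

    Accepts scalars or arrays; missing inputs (NaN) propagate to a missing
    result rather than being treated as zero change.
    """
    baseline = np.asarray(baseline_score, dtype=float)
    followup = np.asarray(followup_score, dtype=float)
    rci = (followup - baseline) / params.se_diff
    if rci.ndim == 0:
        return float(rci)
    return rci


def classify_response(rci, params: RciParams = _DEFAULT):
    """Treatment response present iff RCI < cutoff (strict; −1.96 is absent)."""
    arr = np.asarray(rci, dtype=float)
    out = arr < params.rci_cutoff
    if arr.ndim == 0:
        return bool(out) if not math.isnan(float(arr)) else np.nan
    return np.where(np.isnan(arr), np.nan, out.astype(float))


def classify_remission(rci, followup_score, params: RciParams = _DEFAULT):
    """Remission = reliable improvement AND follow-up score below the
    no-depression cutoff (both strict inequalities)."""
    arr_r = np.asarray(rci, dtype=float)
    arr_s = np.asarray(followup_score, dtype=float)
    out = (arr_r < params.rci_cutoff) & (arr_s < params.remission_score_cutoff)
    if arr_r.ndim == 0 and arr_s.ndim == 0:
        if math.isnan(float(arr_r)) or math.isnan(float(arr_s)):
            return np.nan
        return bool(out)
    return np.where(np.isnan(arr_r) | np.isnan(arr_s), np.nan, out.astype(float))


def completer_threshold(
    protocol_sessions: int = PROTOCOL_SESSIONS, fraction: float = COMPLETER_FRACTION
) -> int:
    """Smallest whole number of sessions ≥ fraction × protocol (⌈0.75×18⌉ = 14)."""
    return math.ceil(fraction * protocol_sessions)


def classify_completer(n_total_sessions: int, threshold: int | None = None) -> bool:
    """Treatment completer iff total sessions ≥ threshold (default 14)."""
    if n_total_sessions < 0:
        raise ValueError(f"session count must be >= 0, got {n_total_sessions}")
    if threshold is None:
        threshold = completer_threshold()
    return n_total_sessions >= threshold


def classify_severity(
    score: float, cutpoints: Sequence[float] = DEFAULT_SEVERITY_CUTPOINTS
) -> str:
    """Map a total score to a severity class by inclusive upper cutpoints."""
    if not 0 <= score <= 84:
        raise ValueError(f"score out of range [0, 84]: {score}")
    idx = int(sum(score > c for c in cutpoints))
    return SEVERITY_LABELS[idx]


def compute_qaly(utilities: Sequence[tuple[float, float]]) -> float:
    """Cumulative QALYs from (week, utility) points by linear interpolation.

    The piecewise-linear utility curve is integrated with the trapezoid rule
    over weeks and converted to years (÷ 365.25/7). Missing (NaN) points are
    skipped, so interpolation spans interior gaps. Returns NaN when fewer
    than two non-missing points (including week 0) are available.
    """
    pts = [(w, u) for w, u in utilities if u is not None and not math.isnan(float(u))]
    if len(pts) < 2 or pts[0][0] != 0:
        return float("nan")
    weeks = np.array([w for w, _ in pts], dtype=float)
    if np.any(np.diff(weeks) <= 0):
        raise ValueError("weeks must be strictly increasing")
    vals = np.array([u for _, u in pts], dtype=float)
    return float(np.trapezoid(vals, weeks) / WEEKS_PER_YEAR)


def _qaly_cum_series(weeks: np.ndarray, utils: np.ndarray) -> np.ndarray:
    """Cumulative QALY at each assessment week; NaN past the last observed
    utility and everywhere if week 0 is missing."""
    out = np.full(len(weeks), np.nan)
    ok = ~np.isnan(utils)
    if ok.sum() < 1 or not ok[0]:
        return out
    w_ok, u_ok = weeks[ok], utils[ok]
    out[0] = 0.0
    last = w_ok[-1]
    for j in range(1, len(weeks)):
        t = weeks[j]
        if t > last:
            continue
        # integrate the interpolant from 0 to t
        grid = np.unique(np.concatenate([w_ok[w_ok <= t], [t]]))
        vals = np.interp(grid, w_ok, u_ok)
        out[j] = np.trapezoid(vals, grid) / WEEKS_PER_YEAR
    return out


def derive_outcomes(data: pd.DataFrame, params: RciParams = _DEFAULT) -> pd.DataFrame:
    """Build the per-patient × follow-up outcome panel from a trial dataset.

    Columns: rci, response, remission, episode, qaly_cum (cumulative from
    week 0 through interpolated utilities), completer (patient-level,
    repeated), plus baseline_ids and baseline_utility carried along for
    baseline-adjusted modelling.
    """
    frames = []
    for pid, grp in data.sort_values(["patient_id", "week"]).groupby(
        "patient_id", sort=True
    ):
        weeks = grp["week"].to_numpy(dtype=float)
        scores = grp["ids_sr"].to_numpy(dtype=float)
        utils = grp["utility"].to_numpy(dtype=float)
        if weeks[0] != 0:
            raise ConfigurationError(
                "dataset", f"patient {pid} has no baseline (week 0) row"
            )
        baseline = scores[0]
        rci = (scores - baseline) / params.se_diff
        qaly = _qaly_cum_series(weeks, utils)
        n_sessions = int(
            grp["n_f2f_sessions"].iloc[0] + grp["n_online_sessions"].iloc[0]
        ) if {"n_f2f_sessions", "n_online_sessions"} <= set(grp.columns) else 0
        fu = grp["week"] != 0
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": pid,
                    "arm": grp["arm"].iloc[0],
                    "week": weeks[fu.to_numpy()],
                    "rci": rci[fu.to_numpy()],
                    "response": classify_response(rci[fu.to_numpy()], params),
                    "remission": classify_remission(
                        rci[fu.to_numpy()], scores[fu.to_numpy()], params
                    ),
                    "episode": grp.loc[fu, "episode"].to_numpy(dtype=float)
                    if "episode" in grp.columns
                    else np.nan,
                    "qaly_cum": qaly[fu.to_numpy()],
                    "completer": classify_completer(n_sessions),
                    "baseline_ids": baseline,
                    "baseline_utility": utils[0],
                }
            )
        )
    panel = pd.concat(frames, ignore_index=True)
    return panel
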
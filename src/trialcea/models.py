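"""Baseline-adjusted mixed models for clinical, utility, and cost outcomes.

Two estimation routes are provided deliberately:

* :func:`fit_lmm` / :func:`fit_logistic_mixed` wrap statsmodels (``MixedLM``
  with restricted maximum likelihood; ``GLM``/Bayes mixed GLM for binomial
  outcomes) and support the descriptive specifications with categorical time
  and group×time interactions.
* :func:`fit_random_intercept` is a self-contained profiled-REML fitter for
  the random-intercept-only Gaussian model used by the cost-effectiveness
  regressions. Profiling the variance ratio reduces each fit to a bounded
  one-dimensional optimisation, which makes thousands of cluster-bootstrap
  refits affordable. Its agreement with ``MixedLM`` is enforced by tests.

Missing outcomes are handled by likelihood (rows with a missing response are
omitted; patients with partial data stay in), matching the MAR assumption of
the design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from trialcea.constants import ARM_BLENDED
from trialcea.errors import ConfigurationError, ModelError

Z975 = 1.959963984540054  # Phi^{-1}(0.975)


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one mixed model.

    ``time_categorical`` enters assessment week as a categorical fixed
    effect; ``baseline_covariate`` names a column used for baseline
    adjustment; ``random_intercept=False`` collapses the Gaussian model to
    OLS and the binomial model to a plain logistic regression (appropriate
    when all patients share the same baseline state).
    """

    outcome: str
    family: str = "gaussian"
    time_categorical: bool = True
    group_time_interaction: bool = False
    baseline_covariate: str | None = None
    random_intercept: bool = True
    reml: bool = True

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "binomial"):
            raise ConfigurationError("family", f"got {self.family!r}")
        if self.family == "binomial" and self.reml:
            object.__setattr__(self, "reml", False)


@dataclass
class ModelEstimate:
    """Fitted fixed effects with their covariance and metadata."""

    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    group_term: str
    family: str
    converged: bool
    n_obs: int
    n_groups: int
    var_e: float = float("nan")
    var_b: float = float("nan")
    notes: tuple[str, ...] = ()

    @property
    def group_estimate(self) -> float:
        return float(self.params[self.group_term])

    @property
    def group_se(self) -> float:
        return float(self.bse[self.group_term])

    def group_ci(self) -> tuple[float, float]:
        est, se = self.group_estimate, self.group_se
        return est - Z975 * se, est + Z975 * se

    def group_or(self) -> tuple[float, float, float]:
        """Odds ratio (with CI) for binomial models."""
        if self.family != "binomial":
            raise ModelError("odds ratios only apply to binomial models")
        lo, hi = self.group_ci()
        return float(np.exp(self.group_estimate)), float(np.exp(lo)), float(np.exp(hi))

    def tidy(self, model_id: str = "") -> pd.DataFrame:
        lo = self.params - Z975 * self.bse
        hi = self.params + Z975 * self.bse
        return pd.DataFrame(
            {
                "model": model_id,
                "term": self.params.index,
                "estimate": self.params.to_numpy(),
                "se": self.bse.to_numpy(),
                "ci_low": lo.to_numpy(),
                "ci_high": hi.to_numpy(),
            }
        )


# ---------------------------------------------------------------------------
# fast profiled-REML random-intercept fitter
# ---------------------------------------------------------------------------


@dataclass
class _RIProfile:
    """Per-theta sufficient statistics of the random-intercept model."""

    XtX: np.ndarray
    Xty: np.ndarray
    yty: float
    Sx: np.ndarray  # per-cluster column sums of X (G × p)
    sy: np.ndarray  # per-cluster sums of y (G)
    n_i: np.ndarray  # cluster sizes (G)
    n: int
    p: int

    def solve(self, theta: float):
        w = theta / (1.0 + theta * self.n_i)
        A = self.XtX - self.Sx.T @ (w[:, None] * self.Sx)
        c = self.Xty - self.Sx.T @ (w * self.sy)
        yVy = self.yty - float(w @ (self.sy**2))
        try:
            beta = np.linalg.solve(A, c)
        except np.linalg.LinAlgError as exc:
            raise ModelError(f"singular design in random-intercept fit: {exc}") from exc
        q = yVy - float(c @ beta)
        return A, beta, max(q, 0.0)

    def criterion(self, theta: float, reml: bool) -> float:
        A, _, q = self.solve(theta)
        q = max(q, 1e-300)
        logdet_v = float(np.sum(np.log1p(theta * self.n_i)))
        sign, logdet_a = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        if reml:
            return logdet_v + logdet_a + (self.n - self.p) * np.log(q)
        return logdet_v + self.n * np.log(q)


def fit_random_intercept(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    term_names: Sequence[str] | None = None,
    group_term: str = "treat",
    reml: bool = True,
) -> ModelEstimate:
    """REML fit of y = Xβ + b_cluster + ε with a single random intercept.

    The variance ratio θ = σ_b²/σ_ε² is profiled out and found by bounded
    scalar optimisation; β and σ_ε² then follow in closed form. Rows with
    non-finite y or X are dropped before fitting.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    X, y = X[keep], y[keep]
    codes, _ = pd.factorize(np.asarray(groups)[keep])
    n, p = X.shape
    if n <= p:
        raise ModelError(f"too few observations ({n}) for {p} fixed effects")
    if np.linalg.matrix_rank(X) < p:
        raise ModelError("singular fixed-effect design matrix")
    if term_names is None:
        term_names = [f"x{j}" for j in range(p)]

    G = codes.max() + 1
    Sx = np.zeros((G, p))
    np.add.at(Sx, codes, X)
    sy = np.bincount(codes, weights=y, minlength=G)
    n_i = np.bincount(codes, minlength=G).astype(float)
    prof = _RIProfile(X.T @ X, X.T @ y, float(y @ y), Sx, sy, n_i, n, p)

    # perfect fit (degenerate noise-free data): OLS is exact
    _, beta0, q0 = prof.solve(0.0)
    if q0 <= 1e-10 * (1.0 + prof.yty):
        zeros = np.zeros((p, p))
        return ModelEstimate(
            params=pd.Series(beta0, index=term_names),
            bse=pd.Series(np.zeros(p), index=term_names),
            cov=pd.DataFrame(zeros, index=term_names, columns=term_names),
            group_term=group_term,
            family="gaussian",
            converged=True,
            n_obs=n,
            n_groups=int(G),
            var_e=0.0,
            var_b=0.0,
            notes=("perfect fit; variance components degenerate",),
        )

    res = minimize_scalar(
        lambda phi: prof.criterion(np.exp(phi), reml),
        bounds=(-12.0, 8.0),
        method="bounded",
        options={"xatol": 1e-8},
    )
    theta = float(np.exp(res.x))
    if prof.criterion(0.0, reml) <= res.fun:
        theta = 0.0
    A, beta, q = prof.solve(theta)
    dof = (n - p) if reml else n
    var_e = q / dof
    cov = var_e * np.linalg.inv(A)
    bse = np.sqrt(np.diag(cov))
    return ModelEstimate(
        params=pd.Series(beta, index=term_names),
        bse=pd.Series(bse, index=term_names),
        cov=pd.DataFrame(cov, index=term_names, columns=term_names),
        group_term=group_term,
        family="gaussian",
        converged=bool(res.success),
        n_obs=n,
        n_groups=int(G),
        var_e=float(var_e),
        var_b=float(theta * var_e),
    )


# ---------------------------------------------------------------------------
# statsmodels-backed general fitters
# ---------------------------------------------------------------------------


def _prepare(data: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, str]:
    df = data.copy()
    if "treat" not in df.columns:
        if "arm" not in df.columns:
            raise ConfigurationError("data", "need an 'arm' or 'treat' column")
        df["treat"] = (df["arm"] == ARM_BLENDED).astype(float)
    terms = ["treat"]
    if spec.time_categorical and df["week"].nunique() > 1:
        terms.append("C(week)")
        if spec.group_time_interaction:
            terms.append("treat:C(week)")
    if spec.baseline_covariate:
        terms.append(spec.baseline_covariate)
    formula = f"{spec.outcome} ~ " + " + ".join(terms)
    used = [spec.outcome, "treat", "week", "patient_id"]
    if spec.baseline_covariate:
        used.append(spec.baseline_covariate)
    df = df.dropna(subset=[c for c in used if c in df.columns])
    if df.empty:
        raise ModelError(f"no complete observations for outcome '{spec.outcome}'")
    return df, formula


def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> ModelEstimate:
    """Gaussian linear mixed model (REML) with a patient random intercept.

    Missing outcomes are omitted row-wise (likelihood-based MAR handling);
    non-convergence is retried once with a different optimiser and flagged,
    never silent.
    """
    import statsmodels.formula.api as smf

    if spec.family != "gaussian":
        raise ConfigurationError("family", "fit_lmm requires a gaussian family")
    df, formula = _prepare(data, spec)

    if not spec.random_intercept:
        res = smf.ols(formula, data=df).fit()
        fe = res.params
        return ModelEstimate(
            params=fe,
            bse=res.bse[fe.index],
            cov=pd.DataFrame(
                np.asarray(res.cov_params().loc[fe.index, fe.index]),
                index=fe.index,
                columns=fe.index,
            ),
            group_term="treat",
            family="gaussian",
            converged=True,
            n_obs=int(res.nobs),
            n_groups=int(df["patient_id"].nunique()),
            var_e=float(res.mse_resid),
            var_b=0.0,
            notes=("no random intercept: ordinary least squares",),
        )

    model = smf.mixedlm(formula, data=df, groups=df["patient_id"])
    converged = True
    notes: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=spec.reml, method="lbfgs")
        except Exception:
            res = None
        if res is None or not getattr(res, "converged", False):
            try:
                res = model.fit(reml=spec.reml, method="powell", maxiter=500)
            except Exception as exc:
                raise ModelError(f"mixed model failed to fit: {exc}") from exc
            if not getattr(res, "converged", False):
                converged = False
                notes.append("optimizer did not converge after two attempts")
    fe = res.fe_params
    cov = pd.DataFrame(
        np.asarray(res.cov_params().loc[fe.index, fe.index]),
        index=fe.index,
        columns=fe.index,
    )
    return ModelEstimate(
        params=fe,
        bse=res.bse_fe[fe.index],
        cov=cov,
        group_term="treat",
        family="gaussian",
        converged=converged,
        n_obs=int(res.nobs),
        n_groups=int(df["patient_id"].nunique()),
        var_e=float(res.scale),
        var_b=float(np.asarray(res.cov_re).ravel()[0]) if res.cov_re is not None else 0.0,
        notes=tuple(notes),
    )


def fit_logistic_mixed(data: pd.DataFrame, spec: ModelSpec) -> ModelEstimate:
    """Logistic model for binary outcomes at follow-up.

    With ``random_intercept=False`` (the default analysis when all patients
    share the baseline state) this is a plain logistic GLM. With a random
    intercept a variational Bayes binomial mixed GLM is used and flagged as
    approximate. Complete separation raises :class:`ModelError`; an outcome
    with no variation returns a zero group effect with an infinite SE,
    flagged in ``notes``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if spec.family != "binomial":
        raise ConfigurationError("family", "fit_logistic_mixed requires binomial family")
    df, formula = _prepare(data, spec)
    y = df[spec.outcome].astype(float)
    if y.nunique() <= 1:
        idx = pd.Index(["Intercept", "treat"])
        inf = pd.Series([np.inf, np.inf], index=idx)
        return ModelEstimate(
            params=pd.Series([0.0, 0.0], index=idx),
            bse=inf,
            cov=pd.DataFrame(np.full((2, 2), np.inf), index=idx, columns=idx),
            group_term="treat",
            family="binomial",
            converged=True,
            n_obs=len(df),
            n_groups=int(df["patient_id"].nunique()),
            notes=("degenerate: outcome has no variation; infinite SE",),
        )

    if spec.random_intercept:
        from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = BinomialBayesMixedGLM.from_formula(
                formula, {"patient": "0 + C(patient_id)"}, df
            )
            res = md.fit_vb()
        names = list(md.exog_names)
        params = pd.Series(res.fe_mean, index=names)
        bse = pd.Series(res.fe_sd, index=names)
        cov = pd.DataFrame(np.diag(bse**2), index=names, columns=names)
        return ModelEstimate(
            params=params,
            bse=bse,
            cov=cov,
            group_term="treat",
            family="binomial",
            converged=True,
            n_obs=len(df),
            n_groups=int(df["patient_id"].nunique()),
            notes=("variational Bayes approximation for the random intercept",),
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = smf.glm(formula, data=df, family=sm.families.Binomial()).fit()
        except Exception as exc:
            raise ModelError(f"logistic fit failed (possible separation): {exc}") from exc
    if not np.all(np.isfinite(res.bse)) or np.any(np.abs(res.params) > 15):
        raise ModelError("complete separation detected in logistic model")
    fe = res.params
    return ModelEstimate(
        params=fe,
        bse=res.bse[fe.index],
        cov=pd.DataFrame(
            np.asarray(res.cov_params().loc[fe.index, fe.index]),
            index=fe.index,
            columns=fe.index,
        ),
        group_term="treat",
        family="binomial",
        converged=bool(res.converged),
        n_obs=int(res.nobs),
        n_groups=int(df["patient_id"].nunique()),
    )


# ---------------------------------------------------------------------------
# paired cost/effect estimation for the economic evaluation
# ---------------------------------------------------------------------------


@dataclass
class CeaEstimates:
    """Paired incremental-cost and incremental-effect estimates."""

    cost: ModelEstimate
    effect: ModelEstimate
    perspective: str = ""
    effect_kind: str = ""

    @property
    def delta_cost(self) -> float:
        return self.cost.group_estimate

    @property
    def delta_effect(self) -> float:
        return self.effect.group_estimate


def _cea_design(
    df: pd.DataFrame, outcome: str, baseline: str | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    cols = ["treat"] + ([baseline] if baseline else [])
    y = df[outcome].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in cols]
    )
    names = ["Intercept"] + cols
    return X, y, df["patient_id"].to_numpy(), names


def estimate_cea_effects(
    frame: pd.DataFrame,
    cost_outcome: str,
    effect_outcome: str,
    cost_baseline: str | None = None,
    effect_baseline: str | None = None,
    reml: bool = True,
) -> CeaEstimates:
    """One ΔC and one ΔE across all follow-ups (no time terms).

    Both are Gaussian random-intercept regressions of the outcome on group
    (plus an optional baseline covariate), so a binary effect outcome yields
    a risk difference, and the cost outcome a mean cost difference — the
    quantities the ICER consumes. Rows with missing outcome values drop out
    of the respective model only.
    """
    df = frame.copy()
    if "treat" not in df.columns:
        df["treat"] = (df["arm"] == ARM_BLENDED).astype(float)
    Xc, yc, gc, names_c = _cea_design(df, cost_outcome, cost_baseline)
    Xe, ye, ge, names_e = _cea_design(df, effect_outcome, effect_baseline)
    cost = fit_random_intercept(Xc, yc, gc, names_c, reml=reml)
    effect = fit_random_intercept(Xe, ye, ge, names_e, reml=reml)
    return CeaEstimates(cost=cost, effect=effect)
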
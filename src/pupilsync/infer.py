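"""Statistical linkage of entrainment to behaviour and dyadic synchrony.

* ``performance_regression``: OLS of d' on the (standardized) session
  entrainment score.
* ``feature_regression``: multiple regression of an outcome on the three
  trial-response features (amplitude, latency, width), with optional
  Benjamini-Hochberg correction of the coefficient p-values.
* ``synchrony_mixed_model``: linear mixed model of story-level pupillary
  synchrony on entrainment, with crossed random intercepts for
  participant and story (statsmodels MixedLM; falls back to OLS on
  participant story-means for degenerate designs).
* ``permutation_test``: participant-level shuffle of the entrainment
  scores with a full mixed-model refit per shuffle.  The refits use a
  compact profiled-REML solver for the two-variance-component model
  (cross-checked against statsmodels in the test suite) so that
  1000-shuffle nulls stay cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg, optimize, stats
from statsmodels.regression.mixed_linear_model import MixedLM, VCSpec
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, InsufficientDataError

__all__ = [
    "InferenceResult",
    "performance_regression",
    "feature_regression",
    "synchrony_mixed_model",
    "permutation_test",
]


@dataclass
class InferenceResult:
    """A fitted effect: standardized beta with uncertainty and context."""

    beta: float | None
    se: float | None
    t: float | None
    df: float | None
    p: float | None
    adj_r2: float | None = None
    f_stat: float | None = None
    f_p: float | None = None
    coef_table: pd.DataFrame | None = None
    null_betas: np.ndarray | None = None
    p_perm: float | None = None
    n_obs: int = 0
    method: str = ""
    flags: list[str] = field(default_factory=list)


def _standardize(x: np.ndarray, what: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0.0:
        raise ConfigurationError(f"{what} has zero variance")
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# regressions
# ---------------------------------------------------------------------------


def performance_regression(
    dprimes: Sequence[float], scores: Sequence[float]
) -> InferenceResult:
    """OLS of task performance (d') on the entrainment-synchrony score.

    Both variables are standardized, so the slope is a standardized beta.
    """
    y = np.asarray(dprimes, dtype=float)
    x = np.asarray(scores, dtype=float)
    if len(y) != len(x) or len(y) < 3:
        raise InsufficientDataError("need at least 3 paired observations")
    y = _standardize(y, "outcome (d')")
    x = _standardize(x, "predictor (entrainment score)")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return InferenceResult(
        beta=float(res.params[1]),
        se=float(res.bse[1]),
        t=float(res.tvalues[1]),
        df=float(res.df_resid),
        p=float(res.pvalues[1]),
        adj_r2=float(res.rsquared_adj),
        f_stat=float(res.fvalue),
        f_p=float(res.f_pvalue),
        n_obs=len(y),
        method="ols",
    )


FEATURE_NAMES = ("amplitude", "latency", "width")


def feature_regression(
    features: pd.DataFrame,
    outcome: Sequence[float],
    fdr: bool = True,
    cond_threshold: float = 1e3,
) -> InferenceResult:
    """Multiple regression of an outcome on trial-response features.

    ``features`` must hold columns amplitude/latency/width (one row per
    participant).  Constant columns are dropped with a flag; a large design
    condition number flags possible collinearity.  Coefficient p-values are
    Benjamini-Hochberg adjusted when ``fdr`` is set.
    """
    missing = [c for c in FEATURE_NAMES if c not in features.columns]
    if missing:
        raise ConfigurationError(f"features table lacks columns {missing}")
    y = np.asarray(outcome, dtype=float)
    if len(y) != len(features):
        raise InsufficientDataError("outcome and features must align")
    flags: list[str] = []
    cols = []
    for c in FEATURE_NAMES:
        x = features[c].to_numpy(dtype=float)
        if np.std(x) == 0.0 or not np.all(np.isfinite(x)):
            flags.append(f"dropped_constant_or_nonfinite:{c}")
        else:
            cols.append(c)
    if not cols:
        raise ConfigurationError("all feature columns are degenerate")
    X = np.column_stack([_standardize(features[c].to_numpy(float), c) for c in cols])
    y = _standardize(y, "outcome")
    exog = sm.add_constant(X)
    cond = float(np.linalg.cond(exog))
    if cond > cond_threshold:
        flags.append(f"collinear_design:cond={cond:.3g}")
    res = sm.OLS(y, exog).fit()
    pvals = res.pvalues[1:]
    p_adj = multipletests(pvals, method="fdr_bh")[1] if fdr else pvals
    coef_table = pd.DataFrame(
        {
            "feature": cols,
            "beta": res.params[1:],
            "se": res.bse[1:],
            "t": res.tvalues[1:],
            "p": pvals,
            "p_fdr": p_adj,
        }
    )
    return InferenceResult(
        beta=None,
        se=None,
        t=None,
        df=float(res.df_resid),
        p=None,
        adj_r2=float(res.rsquared_adj),
        f_stat=float(res.fvalue),
        f_p=float(res.f_pvalue),
        coef_table=coef_table,
        n_obs=len(y),
        method="ols_features",
        flags=flags,
    )


# ---------------------------------------------------------------------------
# crossed random-intercepts mixed model
# ---------------------------------------------------------------------------


def _design(
    table: pd.DataFrame, scores: Mapping | pd.Series
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Merge the story table with participant scores into model arrays.

    Returns (y, score_by_row, pid codes, sid codes, standardized
    participant-level score vector).  The predictor is standardized over
    participants; the outcome keeps its own scale so a known generative
    coefficient is recovered as-is.
    """
    df = table.dropna(subset=["story_value"]).copy()
    if isinstance(scores, Mapping):
        scores = pd.Series(scores)
    df = df[df["participant"].isin(scores.index)]
    if df.empty:
        raise InsufficientDataError("no rows after merging scores with story table")
    participants, pid = np.unique(df["participant"].to_numpy(), return_inverse=True)
    _, sid = np.unique(df["story"].to_numpy(), return_inverse=True)
    score_vec = _standardize(
        scores.loc[participants].to_numpy(dtype=float), "entrainment score"
    )
    y = df["story_value"].to_numpy(dtype=float)
    return y, score_vec[pid], pid, sid, score_vec


class CrossedREML:
    """Profiled REML for y = X b + u_participant + u_story + e.

    The covariance is V = s2 * (I + g_p Z_p Z_p' + g_s Z_s Z_s'); the two
    variance ratios are profiled out and optimized by Nelder-Mead.  For a
    complete balanced participant x story design the solver works in the
    joint eigenbasis of the two random-effect Gram matrices, which makes a
    single fit cheap enough to refit inside 1000-shuffle permutation nulls.
    An incomplete design falls back to dense Cholesky factorizations.
    """

    def __init__(self, pid: np.ndarray, sid: np.ndarray):
        self.pid = np.asarray(pid)
        self.sid = np.asarray(sid)
        self.n = len(pid)
        self.n_p = int(pid.max()) + 1
        self.n_s = int(sid.max()) + 1
        counts = np.zeros((self.n_p, self.n_s), dtype=int)
        np.add.at(counts, (pid, sid), 1)
        self.balanced = bool(np.all(counts == 1))
        if self.balanced:
            order = np.lexsort((sid, pid))
            self.order = order
            Qp = self._helmert(self.n_p)
            Qs = self._helmert(self.n_s)
            self.T = np.kron(Qp, Qs).T
            u = np.repeat(np.arange(self.n_p), self.n_s)
            v = np.tile(np.arange(self.n_s), self.n_p)
            self.ap = np.where(v == 0, float(self.n_s), 0.0)  # eig of Zp Zp'
            self.asd = np.where(u == 0, float(self.n_p), 0.0)  # eig of Zs Zs'
        else:
            Zp = np.zeros((self.n, self.n_p))
            Zp[np.arange(self.n), pid] = 1.0
            Zs = np.zeros((self.n, self.n_s))
            Zs[np.arange(self.n), sid] = 1.0
            self.Gp = Zp @ Zp.T
            self.Gs = Zs @ Zs.T
            self.I = np.eye(self.n)

    @staticmethod
    def _helmert(m: int) -> np.ndarray:
        """Orthonormal basis whose first column is the constant vector."""
        Q = np.zeros((m, m))
        Q[:, 0] = 1.0 / np.sqrt(m)
        for k in range(1, m):
            Q[:k, k] = 1.0
            Q[k, k] = -k
            Q[:, k] /= np.linalg.norm(Q[:, k])
        return Q

    def _crit_balanced(self, theta, yt, Xt):
        gp, gs = np.exp(theta)
        d = 1.0 + gp * self.ap + gs * self.asd
        w = 1.0 / d
        if Xt.shape[1] == 2:  # hand-rolled 2x2 GLS: the permutation hot path
            x0, x1 = Xt[:, 0], Xt[:, 1]
            a = float(x0 @ (x0 * w))
            b = float(x0 @ (x1 * w))
            c = float(x1 @ (x1 * w))
            r0 = float(x0 @ (yt * w))
            r1 = float(x1 @ (yt * w))
            det = a * c - b * b
            beta = np.array([(c * r0 - b * r1) / det, (a * r1 - b * r0) / det])
            resid = yt - x0 * beta[0] - x1 * beta[1]
            s2 = float(resid @ (resid * w)) / (self.n - 2)
            crit = (self.n - 2) * np.log(s2) + np.log(d).sum() + np.log(det)
            XtViX = np.array([[a, b], [b, c]])
            return crit, beta, s2, XtViX
        Xd = Xt * w[:, None]
        XtViX = Xt.T @ Xd
        beta = np.linalg.solve(XtViX, Xd.T @ yt)
        r = yt - Xt @ beta
        s2 = float(r @ (r * w)) / (self.n - Xt.shape[1])
        crit = (
            (self.n - Xt.shape[1]) * np.log(s2)
            + np.log(d).sum()
            + np.linalg.slogdet(XtViX)[1]
        )
        return crit, beta, s2, XtViX

    def _crit_dense(self, theta, y, X):
        gp, gs = np.exp(theta)
        V = self.I + gp * self.Gp + gs * self.Gs
        c = linalg.cho_factor(V, lower=True)
        logdetV = 2.0 * np.sum(np.log(np.diag(c[0])))
        ViX = linalg.cho_solve(c, X)
        Viy = linalg.cho_solve(c, y)
        XtViX = X.T @ ViX
        beta = linalg.solve(XtViX, X.T @ Viy, assume_a="pos")
        r = y - X @ beta
        s2 = float(r @ linalg.cho_solve(c, r)) / (self.n - X.shape[1])
        crit = (
            (self.n - X.shape[1]) * np.log(s2)
            + logdetV
            + np.log(np.linalg.det(XtViX))
        )
        return crit, beta, s2, XtViX

    def reml_criterion(self, gamma_p: float, gamma_s: float, y, X) -> float:
        """-2 profiled REML log-likelihood (up to a constant)."""
        theta = np.log([max(gamma_p, 1e-12), max(gamma_s, 1e-12)])
        if self.balanced:
            yt = self.T @ y[self.order]
            Xt = self.T @ X[self.order]
            return float(self._crit_balanced(theta, yt, Xt)[0])
        return float(self._crit_dense(theta, y, X)[0])

    def fit(self, y: np.ndarray, X: np.ndarray, x0: np.ndarray | None = None):
        """Returns (beta, se, gamma=(g_p, g_s), sigma2).

        ``x0`` warm-starts the variance-ratio search (log scale), which the
        permutation loop uses to cut optimizer iterations.
        """
        if self.balanced:
            yt = self.T @ y[self.order]
            Xt = self.T @ X[self.order]
            full = lambda th: self._crit_balanced(th, yt, Xt)
        else:
            full = lambda th: self._crit_dense(th, y, X)
        crit = lambda th: full(th)[0]
        res = optimize.minimize(
            crit,
            np.log([0.3, 0.3]) if x0 is None else x0,
            method="Nelder-Mead",
            options=dict(xatol=1e-4, fatol=1e-8, maxiter=400),
        )
        _, beta, s2, XtViX = full(res.x)
        cov = s2 * np.linalg.inv(XtViX)
        se = np.sqrt(np.diag(cov))
        return beta, se, np.exp(res.x), s2, res.x


def _bw_df(n_participants: int, n_fixed: int) -> float:
    """Between-within denominator df for a participant-level predictor."""
    return float(max(n_participants - n_fixed, 1))


def synchrony_mixed_model(
    table: pd.DataFrame,
    scores: Mapping | pd.Series,
    df_method: str = "between-within",
    engine: str = "statsmodels",
) -> InferenceResult:
    """Mixed model of story-level synchrony on the entrainment score.

    Random intercepts for participant and story (crossed); the fixed
    entrainment effect is standardized.  ``df_method`` is
    ``"between-within"`` (t on n_participants - 2 df, the default) or
    ``"normal"``.  Designs with fewer than two stories, or fits that fail,
    fall back to OLS on participant story-means (flagged).
    """
    if df_method not in ("between-within", "normal"):
        raise ConfigurationError(f"unknown df_method {df_method!r}")
    if engine not in ("statsmodels", "reml2"):
        raise ConfigurationError(f"unknown engine {engine!r}")
    y, x, pid, sid, score_vec = _design(table, scores)
    n_p = int(pid.max()) + 1
    n_s = int(sid.max()) + 1
    if n_p < 3:
        raise InsufficientDataError("need at least 3 participants")
    X = np.column_stack([np.ones_like(y), x])

    if n_s < 2:
        return _story_mean_fallback(y, x, pid, "degenerate_story_variance")

    beta = se = None
    flags: list[str] = []
    if engine == "reml2":
        b, s, _, _, _ = CrossedREML(pid, sid).fit(y, X)
        beta, se = float(b[1]), float(s[1])
        method = "mixed_reml2"
    else:
        try:
            Zp = (pid[:, None] == np.arange(n_p)[None, :]).astype(float)
            Zs = (sid[:, None] == np.arange(n_s)[None, :]).astype(float)
            vcs = VCSpec(
                ["participant", "story"],
                [[[f"p{i}" for i in range(n_p)]], [[f"s{i}" for i in range(n_s)]]],
                [[Zp], [Zs]],
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = MixedLM(y, X, groups=np.zeros(len(y), dtype=int), exog_vc=vcs)
                fit = model.fit(reml=True, method="lbfgs", disp=False)
            if not np.all(np.isfinite([fit.fe_params[1], fit.bse_fe[1]])):
                raise np.linalg.LinAlgError("non-finite mixed-model estimate")
            beta, se = float(fit.fe_params[1]), float(fit.bse_fe[1])
            method = "mixed_statsmodels"
        except (np.linalg.LinAlgError, ValueError) as exc:
            warnings.warn(f"mixed model failed ({exc}); using story-mean OLS")
            return _story_mean_fallback(y, x, pid, "singular_fit")

    t = beta / se
    if df_method == "between-within":
        df = _bw_df(n_p, 2)
        p = 2.0 * stats.t.sf(abs(t), df)
    else:
        df = float("inf")
        p = 2.0 * stats.norm.sf(abs(t))
    return InferenceResult(
        beta=beta, se=se, t=float(t), df=df, p=float(p),
        n_obs=len(y), method=method, flags=flags,
    )


def _story_mean_fallback(y, x, pid, flag: str) -> InferenceResult:
    n_p = int(pid.max()) + 1
    ybar = np.array([y[pid == i].mean() for i in range(n_p)])
    xbar = np.array([x[pid == i].mean() for i in range(n_p)])
    res = sm.OLS(ybar, sm.add_constant(xbar)).fit()
    return InferenceResult(
        beta=float(res.params[1]),
        se=float(res.bse[1]),
        t=float(res.tvalues[1]),
        df=float(res.df_resid),
        p=float(res.pvalues[1]),
        adj_r2=float(res.rsquared_adj),
        n_obs=n_p,
        method="story_mean_ols",
        flags=[flag],
    )


def permutation_test(
    table: pd.DataFrame,
    scores: Mapping | pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
    df_method: str = "between-within",
) -> InferenceResult:
    """Participant-level permutation null for the mixed-model effect.

    The participant-level score vector is shuffled across participants
    (each participant keeps one shuffled value for all their stories, so
    within-participant story structure is never broken) and the mixed
    model is refit per shuffle with the profiled-REML solver.
    p_perm = (1 + #{|null beta| >= |observed beta|}) / (n_perm + 1),
    two-sided; its floor is 1/(n_perm + 1) by construction.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; null distribution will be coarse")
    y, x, pid, sid, score_vec = _design(table, scores)
    n_p = int(pid.max()) + 1
    if n_p < 3:
        raise InsufficientDataError("need at least 3 participants")
    if int(sid.max()) + 1 < 2:
        raise InsufficientDataError("permutation test needs at least 2 stories")
    solver = CrossedREML(pid, sid)
    X = np.column_stack([np.ones_like(y), x])
    beta_obs, se_obs, _, _, theta_obs = solver.fit(y, X)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    Xp = X.copy()
    for k in range(n_perm):
        perm = rng.permutation(score_vec)
        Xp[:, 1] = perm[pid]
        b, _, _, _, _ = solver.fit(y, Xp, x0=theta_obs)
        null[k] = b[1]
    obs = float(beta_obs[1])
    p_perm = (1.0 + np.sum(np.abs(null) >= abs(obs))) / (n_perm + 1.0)
    t = obs / se_obs[1]
    df = _bw_df(n_p, 2) if df_method == "between-within" else float("inf")
    return InferenceResult(
        beta=obs,
        se=float(se_obs[1]),
        t=float(t),
        df=df,
        p=float(p_perm),
        null_betas=null,
        p_perm=float(p_perm),
        n_obs=len(y),
        method="permutation_mixed_reml2",
    )
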
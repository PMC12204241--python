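"""Cross-population random-effects meta-analysis and the conservation filter.

Per-group slopes for each (subcluster, region, trait) are pooled with a
random-effects model: tau^2 estimated by restricted maximum likelihood via
Fisher scoring, coefficient tests with the Hartung-Knapp-Sidik-Jonkman
adjustment (t on k-1 df). Fits that fail to converge fall through a restart
cascade — REML with more iterations and damped steps, then maximum
likelihood, then a fixed-effect model with a t-test. An association is
*conserved* across the population groups when its BH-adjusted pooled p-value
is below alpha, the per-group slopes share one sign, and I^2 < 50%.

Pooling three groups is a small-k meta-analysis; REML's tau^2 is noisy at
k = 3, which is exactly why the HKSJ t-test rather than a normal test is
used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

REML_MAX_ITER = 50
DEFAULT_SCHEDULE = (
    ("REML", REML_MAX_ITER, 1.0),
    ("REML", 2 * REML_MAX_ITER, 0.5),
    ("REML", 4 * REML_MAX_ITER, 0.25),
    ("ML", 100, 1.0),
    ("FE", 0, 1.0),
)


class MetaConvergenceError(RuntimeError):
    """tau^2 estimation failed to converge within its iteration cap."""


@dataclass
class MetaResult:
    """Pooled estimate with heterogeneity, HKSJ inference and conservation flag."""

    pooled_beta: float
    tau2: float
    Q: float
    I2: float
    se_hksj: float
    t_stat: float
    p_value: float
    method_used: str
    k: int
    p_adj: float = np.nan
    conserved: bool = False
    group_betas: tuple[float, ...] = ()
    loo_estimates: tuple[float, ...] = ()


def _check(estimates: Sequence[float], ses: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(estimates, dtype=float)
    s = np.asarray(ses, dtype=float)
    if y.size == 0:
        raise ValueError("at least one estimate is required")
    if y.shape != s.shape:
        raise ValueError("estimates and ses must have equal length")
    if (s <= 0).any():
        raise ValueError("all standard errors must be positive")
    return y, s


def _tau2_reml(
    y: np.ndarray, v: np.ndarray, max_iter: int = REML_MAX_ITER, step: float = 1.0,
    tol: float = 1e-10,
) -> float:
    """REML tau^2 by Fisher scoring on the profiled restricted likelihood.

    Score = -(1/2)[tr(P) - y'PPy], information = (1/2)tr(PP) with
    P = W - W 1 (1'W1)^{-1} 1' W; the estimate is floored at zero.
    """
    k = y.size
    if k == 1:
        return 0.0
    tau2 = max(0.0, float(np.var(y, ddof=1) - np.mean(v)))
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        sw = w.sum()
        mu = float(np.sum(w * y) / sw)
        py = w * (y - mu)
        tr_p = sw - np.sum(w**2) / sw
        # tr(PP) = sum w^2 - 2 sum w^3 / sum w + (sum w^2)^2 / (sum w)^2
        tr_pp = np.sum(w**2) - 2 * np.sum(w**3) / sw + (np.sum(w**2) ** 2) / sw**2
        # y'PPy = (Py)'(Py) since P is symmetric
        score = -0.5 * (tr_p - float(py @ py))
        info = 0.5 * tr_pp
        delta = step * score / info
        new = max(0.0, tau2 + delta)
        if abs(new - tau2) < tol * (tau2 + 1e-8):
            return new
        tau2 = new
    raise MetaConvergenceError(f"REML did not converge in {max_iter} iterations")


def _tau2_ml(
    y: np.ndarray, v: np.ndarray, max_iter: int = 100, step: float = 1.0,
    tol: float = 1e-10,
) -> float:
    """Maximum-likelihood tau^2 by Fisher scoring, floored at zero."""
    k = y.size
    if k == 1:
        return 0.0
    tau2 = max(0.0, float(np.var(y, ddof=1) - np.mean(v)))
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        mu = float(np.sum(w * y) / w.sum())
        score = 0.5 * float(np.sum(w**2 * (y - mu) ** 2) - np.sum(w))
        info = 0.5 * float(np.sum(w**2))
        new = max(0.0, tau2 + step * score / info)
        if abs(new - tau2) < tol * (tau2 + 1e-8):
            return new
        tau2 = new
    raise MetaConvergenceError(f"ML did not converge in {max_iter} iterations")


def heterogeneity(estimates: Sequence[float], ses: Sequence[float]) -> tuple[float, float]:
    """Cochran's Q against the fixed-effect mean and I^2 = max(0, (Q-df)/Q)*100."""
    y, s = _check(estimates, ses)
    if y.size < 2:
        raise ValueError("heterogeneity requires at least 2 studies")
    w = 1.0 / s**2
    beta_fe = float(np.sum(w * y) / w.sum())
    Q = float(np.sum(w * (y - beta_fe) ** 2))
    I2 = 0.0 if Q == 0 else max(0.0, (Q - (y.size - 1)) / Q) * 100.0
    return Q, I2


def pool_random_effects(
    estimates: Sequence[float],
    ses: Sequence[float],
    method: str = "REML",
    max_iter: int = REML_MAX_ITER,
    step: float = 1.0,
    truncate_hksj: bool = False,
) -> MetaResult:
    """Pool per-group estimates; HKSJ t-test on k-1 df.

    With ``method="FE"`` tau^2 is fixed at zero and the plain inverse-variance
    t-test is used instead of HKSJ. By default the HKSJ scaling factor q is
    not truncated at 1, matching the adjustment's standard form;
    ``truncate_hksj=True`` applies max(q, 1).
    """
    y, s = _check(estimates, ses)
    k = y.size
    v = s**2
    if method == "REML":
        tau2 = _tau2_reml(y, v, max_iter=max_iter, step=step)
    elif method == "ML":
        tau2 = _tau2_ml(y, v, max_iter=max_iter, step=step)
    elif method == "FE":
        tau2 = 0.0
    else:
        raise ValueError(f"unknown method {method!r}")

    w = 1.0 / (v + tau2)
    sw = float(w.sum())
    pooled = float(np.sum(w * y) / sw)
    if k >= 2:
        Q, I2 = heterogeneity(y, s)
    else:
        Q, I2 = 0.0, 0.0

    if k == 1:
        se = float(s[0])
        t = pooled / se
        p = 2.0 * stats.norm.sf(abs(t))
    elif method == "FE":
        se = float(np.sqrt(1.0 / sw))
        t = pooled / se
        p = 2.0 * stats.t.sf(abs(t), k - 1)
    else:
        q = float(np.sum(w * (y - pooled) ** 2) / (k - 1))
        if truncate_hksj:
            q = max(q, 1.0)
        se = float(np.sqrt(q / sw))
        if se == 0.0:  # perfectly homogeneous estimates
            t = 0.0 if pooled == 0 else np.inf * np.sign(pooled)
            p = 0.0 if pooled != 0 else 1.0
        else:
            t = pooled / se
            p = 2.0 * stats.t.sf(abs(t), k - 1)

    return MetaResult(
        pooled_beta=pooled,
        tau2=float(tau2),
        Q=Q,
        I2=I2,
        se_hksj=se,
        t_stat=float(t),
        p_value=float(p),
        method_used=method,
        k=k,
        group_betas=tuple(float(b) for b in y),
    )


def restart_cascade(
    estimates: Sequence[float],
    ses: Sequence[float],
    schedule: Sequence[tuple[str, int, float]] = DEFAULT_SCHEDULE,
    truncate_hksj: bool = False,
    _pool: Callable[..., MetaResult] | None = None,
) -> MetaResult:
    """Try each (method, max_iter, step) in order; first success wins.

    The terminal fixed-effect attempt cannot fail, so the cascade always
    returns. ``_pool`` is a test hook replacing the pooling routine.
    """
    if not schedule:
        raise ValueError("schedule must be nonempty")
    pool = _pool or pool_random_effects
    last_err: Exception | None = None
    for method, max_iter, step in schedule:
        try:
            return pool(
                estimates, ses, method=method, max_iter=max_iter, step=step,
                truncate_hksj=truncate_hksj,
            )
        except MetaConvergenceError as err:
            last_err = err
    raise MetaConvergenceError(
        f"every attempt in the schedule failed (last: {last_err}); "
        "include a terminal ('FE', 0, 1.0) attempt"
    )


def leave_one_out(
    estimates: Sequence[float], ses: Sequence[float], **kwargs
) -> tuple[float, ...]:
    """Pooled estimate omitting each study in turn (restart cascade per subset)."""
    y, s = _check(estimates, ses)
    if y.size < 2:
        raise ValueError("leave-one-out requires at least 2 studies")
    out = []
    for i in range(y.size):
        keep = np.arange(y.size) != i
        out.append(restart_cascade(y[keep], s[keep], **kwargs).pooled_beta)
    return tuple(out)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def adjust_and_flag(
    results: list[MetaResult],
    alpha: float = 0.05,
    i2_max: float = 50.0,
) -> list[MetaResult]:
    """BH-adjust over the full result family and set conservation flags.

    Conserved requires p_adj < alpha, a shared sign of the per-group slopes
    (zero slopes break conservation), and I^2 strictly below ``i2_max``.
    """
    if not results:
        return []
    p_adj = benjamini_hochberg([r.p_value for r in results])
    out = []
    for r, pa in zip(results, p_adj):
        signs = {np.sign(b) for b in r.group_betas}
        same_sign = len(signs) == 1 and 0.0 not in signs
        conserved = bool((pa < alpha) and same_sign and (r.I2 < i2_max))
        out.append(replace(r, p_adj=float(pa), conserved=conserved))
    return out


def meta_analyze_table(
    fits: pd.DataFrame,
    alpha: float = 0.05,
    i2_max: float = 50.0,
    truncate_hksj: bool = False,
) -> pd.DataFrame:
    """Pool a stacked per-group fit table over (subcluster, region, trait).

    ``fits`` is the output of :func:`popcellmeta.composition.fit_group_table`
    (or a factor-association table with the same columns). Combinations
    present in fewer than one group are skipped; BH runs across the full
    family of pooled results.
    """
    keys = ["broad_class", "region", "subcluster", "trait"]
    results: list[MetaResult] = []
    meta_rows: list[dict] = []
    for key, grp in fits.groupby(keys, sort=True):
        res = restart_cascade(
            grp["beta_hat"].to_numpy(), grp["robust_se"].to_numpy(),
            truncate_hksj=truncate_hksj,
        )
        if len(grp) >= 2:
            res = replace(res, loo_estimates=leave_one_out(
                grp["beta_hat"].to_numpy(), grp["robust_se"].to_numpy(),
                truncate_hksj=truncate_hksj,
            ))
        results.append(res)
        meta_rows.append(dict(zip(keys, key)))
    results = adjust_and_flag(results, alpha=alpha, i2_max=i2_max)
    for row, r in zip(meta_rows, results):
        row.update(
            pooled_beta=r.pooled_beta, tau2=r.tau2, Q=r.Q, I2=r.I2,
            se_hksj=r.se_hksj, t_stat=r.t_stat, p_value=r.p_value,
            p_adj=r.p_adj, method_used=r.method_used, k=r.k,
            conserved=r.conserved,
            loo_min=min(r.loo_estimates) if r.loo_estimates else np.nan,
            loo_max=max(r.loo_estimates) if r.loo_estimates else np.nan,
        )
    return pd.DataFrame(meta_rows)
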
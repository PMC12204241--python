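"""Per-population-group compositional association models.

Within each broad cell class, the proportion of every subcluster is modeled
per (population group, region) as

    proportion ~ trait + age_at_death + sex + pmi            (pathological)
    proportion ~ trait + age_at_death + sex + pmi + education (cognitive)

by a quasibinomial logistic GLM with sandwich robust standard errors
(:mod:`.glm`). A subcluster enters the analysis only if it has at least one
more complete observation than the model has terms. Model calibration is
assessed by refitting on permuted responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import check_seed, stage_rng
from .config import encode_trait
from .datatypes import COGNITIVE_TRAITS, GROUPS, REGIONS, CompositionTable
from .glm import QuasiBinomialFit, fit_quasibinomial_glm

PATHOLOGICAL_COVARIATES = ("age_at_death", "sex", "pmi")
COGNITIVE_COVARIATES = ("age_at_death", "sex", "pmi", "education")


@dataclass(frozen=True)
class RegressionSpec:
    """One model: a subcluster proportion against one trait in one group/region."""

    response: str
    variable_of_interest: str
    group: str
    region: str
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        cognitive = self.variable_of_interest in COGNITIVE_TRAITS
        has_edu = "education" in self.covariates
        if cognitive != has_edu:
            raise ValueError(
                "education must be a covariate exactly for cognitive traits "
                f"(trait={self.variable_of_interest!r}, covariates={self.covariates})"
            )

    @property
    def n_terms(self) -> int:
        """Model terms: intercept + variable of interest + covariates."""
        return 2 + len(self.covariates)


def make_spec(response: str, trait: str, group: str, region: str) -> RegressionSpec:
    covs = COGNITIVE_COVARIATES if trait in COGNITIVE_TRAITS else PATHOLOGICAL_COVARIATES
    return RegressionSpec(
        response=response, variable_of_interest=trait, group=group, region=region,
        covariates=covs,
    )


@dataclass
class GroupFitResult:
    """Slope of the variable of interest from one per-group quasibinomial fit."""

    beta_hat: float
    robust_se: float
    ci_low: float
    ci_high: float
    t_stat: float
    p_value: float
    dispersion_phi: float
    n_samples: int
    converged: bool
    spec: RegressionSpec | None = None


def normalize_proportions(counts: CompositionTable) -> pd.DataFrame:
    """Within-broad-class proportions: each sample row rescaled to sum to 1."""
    totals = counts.counts.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("every sample must have a positive nucleus total")
    return counts.counts.div(totals, axis=0)


def _design(
    spec: RegressionSpec,
    proportions: pd.Series,
    denominators: pd.Series,
    covariate_table: pd.DataFrame,
    contrasts: dict | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble (X, y, w) for one fit, dropping incomplete samples."""
    donors = proportions.index.get_level_values("donor_id")
    cols = {"__y__": proportions.to_numpy(), "__w__": denominators.to_numpy()}
    cols[spec.variable_of_interest] = encode_trait(
        spec.variable_of_interest, covariate_table.loc[donors, spec.variable_of_interest], contrasts
    )
    for c in spec.covariates:
        v = covariate_table.loc[donors, c]
        cols[c] = (v == "M").astype(float).to_numpy() if c == "sex" else v.to_numpy(dtype=float)
    tab = pd.DataFrame(cols, index=proportions.index).dropna()
    y = tab["__y__"].to_numpy()
    w = tab["__w__"].to_numpy()
    X = np.column_stack(
        [np.ones(len(tab)), tab[spec.variable_of_interest].to_numpy()]
        + [tab[c].to_numpy() for c in spec.covariates]
    )
    return X, y, w


def _select_samples(
    spec: RegressionSpec, counts: CompositionTable, covariate_table: pd.DataFrame
) -> pd.DataFrame:
    tab = counts.counts
    regions = tab.index.get_level_values("region")
    donors = tab.index.get_level_values("donor_id")
    in_group = covariate_table.loc[donors, "group"].to_numpy() == spec.group
    return tab.loc[in_group & np.asarray(regions == spec.region)]


def fit_quasibinomial(
    spec: RegressionSpec,
    counts: CompositionTable,
    covariate_table: pd.DataFrame,
    weighted: bool = True,
    hc: str = "HC3",
    contrasts: dict | None = None,
) -> GroupFitResult:
    """Fit one subcluster-trait model within one (group, region).

    ``covariate_table`` is a cohort frame indexed by donor_id (see
    :func:`popcellmeta.datatypes.cohort_frame`). With ``weighted=True``
    (default) samples carry their broad-class nucleus totals as binomial
    denominators; ``weighted=False`` regresses bare proportions.
    """
    sub = _select_samples(spec, counts, covariate_table)
    props = sub[spec.response] / sub.sum(axis=1)
    denom = sub.sum(axis=1)
    X, y, w = _design(spec, props, denom, covariate_table, contrasts)
    fit = fit_quasibinomial_glm(X, y, w if weighted else None, hc=hc)
    return _package(fit, spec, len(y))


def _package(fit: QuasiBinomialFit, spec: RegressionSpec, n: int) -> GroupFitResult:
    t, p = fit.t_test(1)
    lo, hi = fit.conf_int(1)
    return GroupFitResult(
        beta_hat=float(fit.coef[1]),
        robust_se=float(fit.se_robust[1]),
        ci_low=lo,
        ci_high=hi,
        t_stat=t,
        p_value=p,
        dispersion_phi=fit.dispersion,
        n_samples=n,
        converged=fit.converged,
        spec=spec,
    )


def eligible_subclusters(
    counts: CompositionTable,
    spec: RegressionSpec,
    covariate_table: pd.DataFrame,
) -> list[str]:
    """Subclusters with at least one more complete observation than model terms."""
    sub = _select_samples(spec, counts, covariate_table)
    donors = sub.index.get_level_values("donor_id")
    need = [spec.variable_of_interest, *spec.covariates]
    complete = covariate_table.loc[donors, need].notna().all(axis=1).to_numpy()
    n_complete = int(complete.sum())
    return list(counts.counts.columns) if n_complete >= spec.n_terms + 1 else []


def fit_group_table(
    counts: CompositionTable,
    covariate_table: pd.DataFrame,
    traits: list[str],
    groups: tuple[str, ...] = GROUPS,
    regions: tuple[str, ...] = REGIONS,
    weighted: bool = True,
    hc: str = "HC3",
    contrasts: dict | None = None,
) -> pd.DataFrame:
    """All eligible per-group fits, one row per (group, region, subcluster, trait)."""
    rows = []
    for group in groups:
        for region in regions:
            for trait in traits:
                spec0 = make_spec(counts.counts.columns[0], trait, group, region)
                elig = eligible_subclusters(counts, spec0, covariate_table)
                for sub in elig:
                    spec = replace(spec0, response=sub)
                    try:
                        res = fit_quasibinomial(
                            spec, counts, covariate_table,
                            weighted=weighted, hc=hc, contrasts=contrasts,
                        )
                    except (ValueError, np.linalg.LinAlgError):
                        continue
                    rows.append(
                        {
                            "broad_class": counts.broad_class,
                            "group": group,
                            "region": region,
                            "subcluster": sub,
                            "trait": trait,
                            "beta_hat": res.beta_hat,
                            "robust_se": res.robust_se,
                            "ci_low": res.ci_low,
                            "ci_high": res.ci_high,
                            "t_stat": res.t_stat,
                            "p_value": res.p_value,
                            "dispersion_phi": res.dispersion_phi,
                            "n_samples": res.n_samples,
                            "converged": res.converged,
                        }
                    )
    return pd.DataFrame(rows)


@dataclass
class CalibrationResult:
    """Empirical type-I error of the model under response permutation."""

    rejection_rates: dict[float, float]
    p_values: np.ndarray = field(repr=False)
    n_perm: int = 0


def permutation_calibration(
    spec: RegressionSpec,
    counts: CompositionTable,
    covariate_table: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    alphas: tuple[float, ...] = (0.01, 0.05, 0.10),
    weighted: bool = True,
    hc: str = "HC3",
) -> CalibrationResult:
    """Refit after shuffling (proportion, denominator) pairs across samples.

    Shuffling breaks any proportion-trait association while preserving the
    marginal distribution of the response, so the fraction of permuted fits
    with p < alpha estimates the model's type-I error rate.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    seed = check_seed(seed)
    sub = _select_samples(spec, counts, covariate_table)
    props = (sub[spec.response] / sub.sum(axis=1)).to_numpy()
    denom = sub.sum(axis=1).to_numpy()
    rng = stage_rng(seed, "permutation_calibration")
    pvals = np.empty(n_perm)
    index = sub.index
    for b in range(n_perm):
        order = rng.permutation(len(props))
        y = pd.Series(props[order], index=index)
        w = pd.Series(denom[order], index=index)
        X, yv, wv = _design(spec, y, w, covariate_table, None)
        if np.ptp(yv) == 0:  # constant response: slope is exactly 0, no rejection
            pvals[b] = 1.0
            continue
        fit = fit_quasibinomial_glm(X, yv, wv if weighted else None, hc=hc)
        pvals[b] = fit.t_test(1)[1]
    return CalibrationResult(
        rejection_rates={a: float(np.mean(pvals < a)) for a in alphas},
        p_values=pvals,
        n_perm=n_perm,
    )
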
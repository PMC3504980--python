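"""Maximum-likelihood fitting of the log-linear variants and LRTs.

Counts over the 45 (or 15) cells are treated as independent Poisson
observations with log mean ``X @ beta + offset``; the kernel
log-likelihood ``sum(y * eta - exp(eta))`` is maximized by Newton
iteration with step halving.  The Poisson likelihood is equivalent to
the multinomial likelihood conditional on the total, so likelihood-ratio
statistics between nested specs agree with the conditional analysis.

Effects are tested by refitting with the effect's free parameters
removed and all nuisance terms retained; the statistic is twice the
log-likelihood difference, referred to chi-square with as many degrees
of freedom as parameters removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .cell_table import (
    CellTable,
    Design,
    LOCUS2_MAIN,
    ModelSpec,
    RHO,
    build_design_matrix,
)
from .exceptions import (
    AliasingWarning,
    ConfigurationError,
    FrequencyWarning,
    IdentifiabilityError,
    NonConvergenceWarning,
)

MAX_ITER = 100
SCORE_TOL = 1e-8
DEVIANCE_TOL = 1e-10


@dataclass
class FitResult:
    """Poisson MLE of one model spec on one count table."""

    coefficients: dict[str, float]
    covariance: np.ndarray
    log_likelihood: float
    converged: bool
    n_iterations: int
    labels: list[str]
    dropped: tuple[str, ...] = ()
    fitted: np.ndarray | None = None
    spec: ModelSpec | None = None
    n_excluded_families: int = 0

    def coef(self, label: str) -> float:
        return self.coefficients[label]

    def relative_risk(self, label: str) -> float:
        """exp of a log-scale coefficient."""
        return float(np.exp(self.coefficients[label]))

    def se(self, label: str) -> float:
        i = self.labels.index(label)
        return float(np.sqrt(self.covariance[i, i]))


@dataclass
class LRTResult:
    """Likelihood-ratio test of one effect against the full model."""

    effect: str
    statistic: float
    df: int
    p_value: float
    estimable: bool = True

    def __post_init__(self):
        if self.estimable and self.statistic < -1e-6:
            raise ConfigurationError(
                f"negative LRT statistic {self.statistic}; optimization failure"
            )


def _counts_array(counts) -> np.ndarray:
    if isinstance(counts, CellTable):
        return counts.counts
    return np.asarray(counts, dtype=float)


def _alias_scan(X: np.ndarray, y: np.ndarray, labels):
    """Estimable columns, dropped labels, and cells driven to zero.

    A column whose nonzero entries all fall on zero-count cells has its
    MLE at -inf (all design columns are nonnegative): the fitted means
    of the cells it supports tend to zero and those cells drop out of
    the likelihood.  The column is removed and its support cells are
    excluded, which realizes that limit exactly.  Remaining rank
    deficiency is a structural identifiability failure.
    """
    informative = y > 0
    keep, dropped = [], []
    excluded = np.zeros(y.shape[0], dtype=bool)
    for j in range(X.shape[1]):
        if np.any(X[:, j] != 0) and not np.any(X[informative, j] != 0):
            dropped.append(labels[j])
            excluded |= X[:, j] != 0
        else:
            keep.append(j)
    keep = np.array(keep, dtype=int)
    rank = np.linalg.matrix_rank(X[np.ix_(~excluded, keep)]) if keep.size else 0
    if rank < keep.size:
        # identify aliased columns via pivoted QR
        _, _, piv = linalg.qr(X[np.ix_(~excluded, keep)], mode="economic", pivoting=True)
        aliased = [labels[keep[j]] for j in piv[rank:]]
        raise IdentifiabilityError(aliased)
    return keep, dropped, excluded


def _newton_poisson(X: np.ndarray, y: np.ndarray, offset: np.ndarray,
                    max_iter: int = MAX_ITER):
    """Newton-Raphson on the Poisson kernel log-likelihood from beta = 0."""
    n, p = X.shape
    beta = np.zeros(p)

    def loglik(b):
        eta = X @ b + offset
        with np.errstate(over="ignore"):
            return float(y @ eta - np.exp(eta).sum())

    ll = loglik(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta + offset, -700, 60)
        mu = np.exp(eta)
        score = X.T @ (y - mu)
        hess = (X * mu[:, None]).T @ X
        try:
            step = linalg.solve(hess, score, assume_a="pos")
        except linalg.LinAlgError:
            step = linalg.lstsq(hess, score)[0]
        # step halving: the kernel is concave, so a decrease means overshoot
        new_beta = beta + step
        new_ll = loglik(new_beta)
        halvings = 0
        while not np.isfinite(new_ll) or (new_ll < ll - 1e-12):
            halvings += 1
            if halvings > 40:
                break
            step = step / 2.0
            new_beta = beta + step
            new_ll = loglik(new_beta)
        beta, prev_ll, ll = new_beta, ll, new_ll
        if np.max(np.abs(score)) < SCORE_TOL * max(1.0, y.sum()):
            converged = True
            break
        if abs(ll - prev_ll) < DEVIANCE_TOL * max(1.0, abs(ll)):
            # likelihood has plateaued (possibly an infinite-MLE direction)
            converged = np.max(np.abs(score)) < 1e-4 * max(1.0, y.sum())
            break
    eta = np.clip(X @ beta + offset, -700, 60)
    mu = np.exp(eta)
    hess = (X * mu[:, None]).T @ X
    try:
        cov = linalg.inv(hess)
    except linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return beta, cov, ll, converged, it, mu


def fit_design(design: Design, counts, warn: bool = True) -> FitResult:
    """Fit a prebuilt design; used by the fitting, EM, and power modules."""
    y = _counts_array(counts)
    if y.shape[0] != design.X.shape[0]:
        raise ConfigurationError(
            f"counts have {y.shape[0]} cells but the design expects {design.X.shape[0]}"
        )
    if not np.any(y > 0):
        raise ConfigurationError("all cell counts are zero; nothing to fit")
    keep, dropped, excluded = _alias_scan(design.X, y, design.labels)
    if dropped and warn:
        warnings.warn(
            "parameters with no informative cells removed (fitted cells -> 0): "
            + ", ".join(dropped),
            AliasingWarning,
            stacklevel=2,
        )
    X = design.X[np.ix_(~excluded, keep)]
    beta, cov, ll, converged, it, mu_sub = _newton_poisson(X, y[~excluded],
                                                           design.offset[~excluded])
    mu = np.zeros(y.shape[0])
    mu[~excluded] = mu_sub
    if not converged and warn:
        warnings.warn(
            f"fit did not meet tolerances after {it} iterations", NonConvergenceWarning,
            stacklevel=2,
        )
    labels = [design.labels[j] for j in keep]
    return FitResult(
        coefficients=dict(zip(labels, beta.tolist())),
        covariance=cov,
        log_likelihood=ll,
        converged=converged,
        n_iterations=it,
        labels=labels,
        dropped=tuple(dropped),
        fitted=mu,
        spec=design.spec,
    )


def fit_model(counts, spec: ModelSpec, warn: bool = True) -> FitResult:
    """Poisson MLE of one model spec on a cell-count table.

    Deterministic given inputs.  Counts may be fractional (EM weights).
    """
    return fit_design(build_design_matrix(spec), counts, warn=warn)


def lrt(counts, full: ModelSpec, effect: str, warn: bool = True) -> LRTResult:
    """LRT of one effect: full model vs. the model excluding the effect.

    Nuisance parameters (mating-type strata, EQ2 lambda columns, and all
    other included effects) are re-estimated in both fits on identical
    counts and offsets.
    """
    if effect not in full.included_effects:
        raise ConfigurationError(f"effect {effect!r} is not in the full model")
    design = build_design_matrix(full)
    y = _counts_array(counts)
    fit_full = fit_design(design, y, warn=warn)
    return _lrt_from_full(design, y, fit_full, effect, warn=warn)


def _lrt_from_full(design: Design, y: np.ndarray, fit_full: FitResult,
                   effect: str, warn: bool = True) -> LRTResult:
    effect_cols = design.effect_columns(effect)
    tested = [design.labels[j] for j in effect_cols]
    tested_kept = [lab for lab in tested if lab in fit_full.labels]
    if not tested_kept:
        return LRTResult(effect=effect, statistic=float("nan"), df=0,
                         p_value=float("nan"), estimable=False)
    reduced_design = _drop_columns(design, effect_cols)
    fit_red = fit_design(reduced_design, y, warn=warn)
    stat = 2.0 * (fit_full.log_likelihood - fit_red.log_likelihood)
    df = len(tested_kept)
    stat = max(stat, 0.0) if stat > -1e-6 else stat
    return LRTResult(effect=effect, statistic=stat, df=df,
                     p_value=float(stats.chi2.sf(stat, df)))


def _drop_columns(design: Design, cols) -> Design:
    keep = [j for j in range(design.X.shape[1]) if j not in set(cols)]
    mapping = {j: i for i, j in enumerate(keep)}
    columns = {
        eff: [mapping[j] for j in idx if j in mapping]
        for eff, idx in design.columns.items()
    }
    columns = {eff: idx for eff, idx in columns.items() if idx}
    return Design(
        X=design.X[:, keep],
        labels=[design.labels[j] for j in keep],
        columns=columns,
        offset=design.offset,
        spec=design.spec,
    )


def test_locus2_main(counts, spec: ModelSpec, warn: bool = True) -> LRTResult:
    """LRT of the locus-2 maternal main effect delta under EQ1.

    Valid only when the specified genotype frequencies are correct: the
    delta estimate absorbs any discrepancy between the true and the
    specified frequencies, so a misspecified distribution inflates this
    test even though the interaction tests are unaffected.
    """
    if spec.variant not in ("eq1", "eq1_hwe"):
        raise ConfigurationError("the locus-2 main effect test requires specified frequencies (EQ1)")
    if LOCUS2_MAIN not in spec.included_effects:
        raise ConfigurationError("spec must include the locus-2 main effect")
    if warn:
        warnings.warn(
            "the locus-2 main-effect test is valid only if the specified genotype "
            "frequencies match the population; a small misspecification inflates it",
            FrequencyWarning,
            stacklevel=2,
        )
    return lrt(counts, spec, LOCUS2_MAIN, warn=warn)


def fit_single_locus(counts, spec: ModelSpec, warn: bool = True) -> FitResult:
    """Fit the single-locus model (EQ3) on the 15 locus-1 cells."""
    if spec.variant != "eq3":
        raise ConfigurationError("fit_single_locus requires an eq3 spec")
    y = counts.collapse_locus2() if isinstance(counts, CellTable) and counts.two_locus else counts
    return fit_model(y, spec, warn=warn)


# ---------------------------------------------------------------------------
# Result serialization
# ---------------------------------------------------------------------------


def effects_table(fit: FitResult, lrts: dict[str, LRTResult] | None = None):
    """Tab-friendly effects summary: RR estimates, 95% CI, LRT columns."""
    import pandas as pd

    z = stats.norm.ppf(0.975)
    rows = []
    lrts = lrts or {}
    by_effect = {}
    if fit.spec is not None:
        design = build_design_matrix(fit.spec)
        for eff in design.columns:
            for j in design.columns[eff]:
                by_effect[design.labels[j]] = eff
    for lab in fit.labels:
        est = fit.coefficients[lab]
        se = fit.se(lab)
        eff = by_effect.get(lab, "")
        res = lrts.get(eff)
        rows.append({
            "effect": eff,
            "parameter": lab,
            "relative_risk": float(np.exp(est)),
            "ci_low": float(np.exp(est - z * se)),
            "ci_high": float(np.exp(est + z * se)),
            "lrt_statistic": res.statistic if res else np.nan,
            "lrt_df": res.df if res else np.nan,
            "lrt_p": res.p_value if res else np.nan,
        })
    return pd.DataFrame(rows)


def fit_record(fit: FitResult, lrts: dict[str, LRTResult] | None = None) -> dict:
    """Machine-readable JSON-serializable fit record."""
    rec = {
        "variant": fit.spec.variant if fit.spec else None,
        "coefficients": fit.coefficients,
        "log_likelihood": fit.log_likelihood,
        "converged": fit.converged,
        "n_iterations": fit.n_iterations,
        "dropped": list(fit.dropped),
        "n_excluded_families": fit.n_excluded_families,
    }
    if lrts:
        rec["tests"] = {
            eff: {
                "statistic": r.statistic,
                "df": r.df,
                "p_value": r.p_value,
                "estimable": r.estimable,
            }
            for eff, r in lrts.items()
        }
    return rec
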
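"""EM fitting of the log-linear models with missing parental genotypes.

An incompletely genotyped family is compatible with every cell whose
(M, F, C, M2) agrees with its observed entries under Mendelian rules.
The E-step distributes each such family fractionally over its
compatible cells in proportion to the current fitted cell means
(offsets included, so the locus-2 frequency information enters for
families missing M2); the M-step refits the Poisson model on the
fractional counts.  Iteration maximizes the observed-data
log-likelihood

    sum_families ln( sum_{compatible cells} mu_cell ) - sum_cells mu_cell

which is monotone nondecreasing across EM iterations.

Families whose mother is missing (both her loci, per the design of the
data) carry almost no information on locus 2 and are excluded by
default, as are case-only records; an explicit flag retains them.
Likelihood-ratio tests compare observed-data log-likelihoods of nested
specs, each maximized by its own EM run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .cell_table import (
    CONFIGURATIONS,
    MISSING,
    ModelSpec,
    N_CELLS,
    build_design_matrix,
    cell_index,
)
from .exceptions import (
    ConfigurationError,
    DataError,
    MendelianError,
    NonConvergenceWarning,
)
from .fitting import Design, FitResult, LRTResult, fit_design

EM_MAX_ITER = 500
EM_TOL = 1e-8

# completeness classes
FULL = "FULL"
CASE_MOTHER = "CASE_MOTHER"  # father missing
CASE_FATHER = "CASE_FATHER"  # mother missing at both loci
CASE_ONLY = "CASE_ONLY"


@dataclass(frozen=True)
class IncompleteFamily:
    """One family's genotypes, risk-allele coded, MISSING where unobserved."""

    m: int
    f: int
    c: int
    m2: int
    family_id: str = ""

    def __post_init__(self):
        for name, v in (("m", self.m), ("f", self.f), ("c", self.c), ("m2", self.m2)):
            if v not in (0, 1, 2, MISSING):
                raise DataError(
                    f"family {self.family_id or '?'}: genotype {name}={v!r} "
                    "must be 0, 1, 2 or MISSING"
                )
        if self.c == MISSING:
            raise DataError(
                f"family {self.family_id or '?'}: the case genotype cannot be missing"
            )

    @property
    def completeness_class(self) -> str:
        mother_missing = self.m == MISSING
        father_missing = self.f == MISSING
        if mother_missing and father_missing:
            return CASE_ONLY
        if mother_missing:
            return CASE_FATHER
        if father_missing:
            return CASE_MOTHER
        return FULL

    @property
    def is_complete(self) -> bool:
        return MISSING not in (self.m, self.f, self.c, self.m2)


_CELL_GENOTYPES = [
    (cfg.m, cfg.f, cfg.c, k) for cfg in CONFIGURATIONS for k in range(3)
]


def compatible_cells(fam: IncompleteFamily) -> tuple[int, ...]:
    """Flat indices of every cell consistent with the observed genotypes."""
    cells = tuple(
        idx
        for idx, (m, f, c, k) in enumerate(_CELL_GENOTYPES)
        if (fam.m == MISSING or fam.m == m)
        and (fam.f == MISSING or fam.f == f)
        and fam.c == c
        and (fam.m2 == MISSING or fam.m2 == k)
    )
    if not cells:
        raise MendelianError(
            f"family {fam.family_id or '?'}: observed genotypes "
            f"(M={fam.m}, F={fam.f}, C={fam.c}, M2={fam.m2}) are "
            "Mendelian-inconsistent"
        )
    return cells


@dataclass
class EMDiagnostics:
    """Per-run bookkeeping of family classes and exclusions."""

    n_families: int = 0
    class_counts: dict = field(default_factory=dict)
    n_excluded: int = 0
    n_iterations: int = 0
    loglik_path: list = field(default_factory=list)


def family_diagnostics(families) -> list[dict]:
    """Per-family table: id, completeness class, number of compatible cells."""
    return [
        {
            "family_id": fam.family_id,
            "completeness_class": fam.completeness_class,
            "n_compatible_cells": len(compatible_cells(fam)),
        }
        for fam in families
    ]


def _partition(families, include_case_father: bool):
    """Base counts for single-cell families plus grouped ambiguity patterns."""
    base = np.zeros(N_CELLS)
    patterns: dict[tuple[int, ...], float] = {}
    class_counts: dict[str, int] = {}
    n_excluded = 0
    for fam in families:
        cls = fam.completeness_class
        class_counts[cls] = class_counts.get(cls, 0) + 1
        if cls in (CASE_FATHER, CASE_ONLY) and not include_case_father:
            n_excluded += 1
            continue
        cells = compatible_cells(fam)
        if len(cells) == 1:
            base[cells[0]] += 1
        else:
            patterns[cells] = patterns.get(cells, 0.0) + 1.0
    return base, patterns, class_counts, n_excluded


def _observed_loglik(mu: np.ndarray, base: np.ndarray, patterns) -> float:
    """Poisson observed-data kernel log-likelihood."""
    with np.errstate(divide="ignore"):
        ll = float(base @ np.log(np.where(base > 0, mu, 1.0)) - mu.sum())
    for cells, n in patterns.items():
        ll += n * np.log(mu[list(cells)].sum())
    return ll


def em_fit(families, spec: ModelSpec, include_case_father: bool = False,
           max_iter: int = EM_MAX_ITER, tol: float = EM_TOL,
           warn: bool = True) -> FitResult:
    """Fit a model spec to complete and incomplete families jointly.

    With no incomplete families this reduces to a single complete-data
    fit and returns exactly the same result as :func:`fitting.fit_model`.
    """
    families = list(families)
    if not families:
        raise DataError("no families to analyze")
    if spec.variant == "eq3":
        raise ConfigurationError(
            "EM fitting is defined for the two-locus cell space; collapse "
            "complete data for the single-locus model instead"
        )
    design = build_design_matrix(spec)
    base, patterns, class_counts, n_excluded = _partition(families, include_case_father)
    if n_excluded and warn:
        warnings.warn(
            f"excluded {n_excluded} families with a missing mother "
            "(case-father pairs / case-only records) from the analysis",
            UserWarning,
            stacklevel=2,
        )
    if base.sum() == 0 and not patterns:
        raise DataError("no usable families after exclusions")

    if not patterns:
        fit = fit_design(design, base, warn=warn)
        fit.n_excluded_families = n_excluded
        return fit

    # initial allocation: uniform over each family's compatible cells
    y = base.copy()
    for cells, n in patterns.items():
        y[list(cells)] += n / len(cells)
    fit = fit_design(design, y, warn=False)
    ll = _observed_loglik(fit.fitted, base, patterns)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = fit.fitted
        y = base.copy()
        for cells, n in patterns.items():
            idx = list(cells)
            total = mu[idx].sum()
            if total <= 0:  # degenerate support; fall back to uniform
                w = np.full(len(idx), 1.0 / len(idx))
            else:
                w = mu[idx] / total
            y[idx] += n * w
        fit = fit_design(design, y, warn=False)
        new_ll = _observed_loglik(fit.fitted, base, patterns)
        if new_ll < ll - 1e-9:
            raise ConfigurationError(
                f"observed-data log-likelihood decreased at EM iteration {it} "
                f"({ll} -> {new_ll}); this indicates a defective M-step"
            )
        delta, ll = new_ll - ll, new_ll
        if abs(delta) < tol:
            converged = True
            break
    if not converged and warn:
        warnings.warn(
            f"EM did not converge within {max_iter} iterations", NonConvergenceWarning,
            stacklevel=2,
        )
    result = FitResult(
        coefficients=fit.coefficients,
        covariance=fit.covariance,  # complete-data curvature; see em_standard_errors
        log_likelihood=ll,
        converged=converged and fit.converged,
        n_iterations=it,
        labels=fit.labels,
        dropped=fit.dropped,
        fitted=fit.fitted,
        spec=spec,
        n_excluded_families=n_excluded,
    )
    return result


def em_lrt(families, full: ModelSpec, effect: str,
           include_case_father: bool = False, warn: bool = True) -> LRTResult:
    """Observed-data LRT of one effect with incomplete families.

    Twice the difference of the observed-data log-likelihoods of the
    full and the reduced spec, each maximized by its own EM run; on
    complete data this equals the complete-data LRT exactly.
    """
    if effect not in full.included_effects:
        raise ConfigurationError(f"effect {effect!r} is not in the full model")
    fit_full = em_fit(families, full, include_case_father, warn=warn)
    design = build_design_matrix(full)
    tested = [design.labels[j] for j in design.effect_columns(effect)]
    tested_kept = [lab for lab in tested if lab in fit_full.labels]
    if not tested_kept:
        return LRTResult(effect=effect, statistic=float("nan"), df=0,
                         p_value=float("nan"), estimable=False)
    fit_red = em_fit(families, full.drop(effect), include_case_father, warn=warn)
    stat = 2.0 * (fit_full.log_likelihood - fit_red.log_likelihood)
    stat = max(stat, 0.0) if stat > -1e-6 else stat
    df = len(tested_kept)
    return LRTResult(effect=effect, statistic=stat, df=df,
                     p_value=float(stats.chi2.sf(stat, df)))


def em_standard_errors(families, spec: ModelSpec, fit: FitResult,
                       include_case_father: bool = False,
                       step: float = 1e-5) -> np.ndarray:
    """Observed-data covariance after EM by numerical information.

    Central second differences of the observed-data log-likelihood at
    the EM solution; the LRT remains the primary inference.
    """
    design = build_design_matrix(spec)
    keep = [design.labels.index(lab) for lab in fit.labels]
    X = design.X[:, keep]
    base, patterns, _, _ = _partition(list(families), include_case_father)
    beta = np.array([fit.coefficients[lab] for lab in fit.labels])

    def obs_ll(b):
        mu = np.exp(X @ b + design.offset)
        return _observed_loglik(mu, base, patterns)

    p = beta.size
    hess = np.empty((p, p))
    f0 = obs_ll(beta)
    for a in range(p):
        for b_i in range(a, p):
            ea = np.zeros(p); ea[a] = step
            eb = np.zeros(p); eb[b_i] = step
            fpp = obs_ll(beta + ea + eb)
            fpm = obs_ll(beta + ea - eb)
            fmp = obs_ll(beta - ea + eb)
            fmm = obs_ll(beta - ea - eb)
            hess[a, b_i] = hess[b_i, a] = (fpp - fpm - fmp + fmm) / (4 * step * step)
    return linalg.inv(-hess)
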
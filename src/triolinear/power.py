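"""Monte-Carlo replicate engine: type-I error, power, and estimate summaries.

Each replicate simulates one ascertained dataset, fits the analysis
spec (EM when missingness is present, complete-data Poisson otherwise),
runs the requested likelihood-ratio tests, and records a rejection when
the p-value is strictly below alpha.  Rejection fractions come with the
binomial Monte-Carlo standard error sqrt(f(1-f)/n_replicates).

Replicate r of a study uses seed base_seed + r, so a study is exactly
reproducible from its design, and per-replicate decisions can be
compared across analysis variants run on the same simulated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cell_table import CellTable, ModelSpec, build_design_matrix, tabulate_families
from .em_missing import em_fit, em_lrt
from .exceptions import ConfigurationError, TriolinearError
from .fitting import _lrt_from_full, fit_design
from .simulator import Scenario, simulate_cell_counts, simulate_trios

_SEED_MOD = 2**31


@dataclass
class StudyDesign:
    """A simulation scenario paired with an analysis model."""

    scenario: Scenario
    analysis: ModelSpec
    effects_to_test: tuple[str, ...]
    n_replicates: int = 1000
    alpha: float = 0.05
    base_seed: int = 0
    include_case_father: bool = False

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be at least 1")
        if not 0 < self.alpha <= 1:
            raise ConfigurationError("alpha must lie in (0, 1]")
        self.effects_to_test = tuple(self.effects_to_test)
        for e in self.effects_to_test:
            if e not in self.analysis.included_effects:
                raise ConfigurationError(f"tested effect {e!r} is not in the analysis model")


@dataclass
class EffectPower:
    """Monte-Carlo summary for one tested effect."""

    effect: str
    rejection_fraction: float
    monte_carlo_se: float
    n_replicates: int
    n_rejected: int
    n_not_estimable: int
    p_values: np.ndarray
    statistics: np.ndarray


@dataclass
class PowerResult:
    """Aggregate of one study: per-effect power plus estimate summaries."""

    design: StudyDesign
    effects: dict[str, EffectPower]
    estimate_means: dict[str, float]
    estimate_sds: dict[str, float]
    n_failed: int

    def rejection_fraction(self, effect: str) -> float:
        return self.effects[effect].rejection_fraction


def _replicate_seed(base_seed: int, r: int) -> int:
    return (base_seed + r) % _SEED_MOD


def run_study(d: StudyDesign, progress=None) -> PowerResult:
    """Run simulate -> fit -> LRT across replicates and tabulate.

    Replicates where the fit fails outright are counted in ``n_failed``
    and excluded; tests whose parameters are not estimable in a sparse
    replicate count as non-rejections and are tallied separately.
    """
    scen = d.scenario
    spec = d.analysis
    missing = scen.missing_father_rate > 0 or scen.missing_mother_rate > 0
    design = build_design_matrix(spec)
    single_locus = spec.variant == "eq3"

    pvals = {e: [] for e in d.effects_to_test}
    stats_ = {e: [] for e in d.effects_to_test}
    not_est = {e: 0 for e in d.effects_to_test}
    est_paths: dict[str, list[float]] = {}
    n_failed = 0

    for r in range(d.n_replicates):
        seed = _replicate_seed(d.base_seed, r)
        try:
            if missing:
                fams = simulate_trios(scen, seed)
                fit = em_fit(fams, spec, d.include_case_father, warn=False)
                results = {
                    e: em_lrt(fams, spec, e, d.include_case_father, warn=False)
                    for e in d.effects_to_test
                }
            else:
                counts = simulate_cell_counts(scen, seed)
                if single_locus:
                    counts = CellTable(counts).collapse_locus2().counts
                fit = fit_design(design, counts, warn=False)
                results = {
                    e: _lrt_from_full(design, counts, fit, e, warn=False)
                    for e in d.effects_to_test
                }
        except TriolinearError:
            n_failed += 1
            continue
        for lab, v in fit.coefficients.items():
            est_paths.setdefault(lab, []).append(v)
        for e, res in results.items():
            if not res.estimable:
                not_est[e] += 1
                pvals[e].append(np.nan)
                stats_[e].append(np.nan)
            else:
                pvals[e].append(res.p_value)
                stats_[e].append(res.statistic)
        if progress is not None and (r + 1) % 100 == 0:
            progress(r + 1, d.n_replicates)

    if n_failed > 0.01 * d.n_replicates:
        import warnings

        warnings.warn(
            f"{n_failed} of {d.n_replicates} replicates failed to fit and were excluded",
            UserWarning,
            stacklevel=2,
        )

    effects = {}
    for e in d.effects_to_test:
        p = np.asarray(pvals[e])
        n = p.size
        # a non-estimable test never rejects; p == alpha counts as non-rejection
        rejected = int(np.nansum(p < d.alpha))
        frac = rejected / n if n else float("nan")
        effects[e] = EffectPower(
            effect=e,
            rejection_fraction=frac,
            monte_carlo_se=float(np.sqrt(frac * (1 - frac) / n)) if n else float("nan"),
            n_replicates=n,
            n_rejected=rejected,
            n_not_estimable=not_est[e],
            p_values=p,
            statistics=np.asarray(stats_[e]),
        )
    means = {lab: float(np.mean(v)) for lab, v in est_paths.items()}
    sds = {lab: float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
           for lab, v in est_paths.items()}
    return PowerResult(design=d, effects=effects, estimate_means=means,
                       estimate_sds=sds, n_failed=n_failed)


def restricted_model_study(d: StudyDesign) -> PowerResult:
    """Run a study whose analysis spec is reduced to the effects of interest.

    A locus-2 interaction in the analysis requires the locus-2 main
    effect as a nuisance term (EQ1) so that the test does not depend on
    the specified genotype frequencies; this is enforced here.
    """
    spec = d.analysis
    has_l2_interaction = "mxm_theta" in spec.included_effects or "mxo_phi" in spec.included_effects
    if spec.variant in ("eq1", "eq1_hwe") and has_l2_interaction:
        if "locus2_main_delta" not in spec.included_effects:
            raise ConfigurationError(
                "a restricted model with a locus-2 interaction must retain the "
                "locus-2 main-effect nuisance terms"
            )
    return run_study(d)


def result_table(res: PowerResult):
    """One row per tested effect, mirroring a power/type-I-error table."""
    import pandas as pd

    d = res.design
    rows = []
    for e, ep in res.effects.items():
        rows.append({
            "scenario": d.scenario.name,
            "n_families": d.scenario.n_families,
            "variant": d.analysis.variant,
            "effect": e,
            "rejection_pct": 100 * ep.rejection_fraction,
            "mc_se_pct": 100 * ep.monte_carlo_se,
            "n_replicates": ep.n_replicates,
            "n_not_estimable": ep.n_not_estimable,
            "n_failed": res.n_failed,
        })
    return pd.DataFrame(rows)


def result_record(res: PowerResult) -> dict:
    """JSON-serializable study record with per-replicate decisions."""
    d = res.design
    return {
        "scenario": d.scenario.name,
        "n_families": d.scenario.n_families,
        "n_replicates": d.n_replicates,
        "alpha": d.alpha,
        "base_seed": d.base_seed,
        "variant": d.analysis.variant,
        "n_failed": res.n_failed,
        "effects": {
            e: {
                "rejection_fraction": ep.rejection_fraction,
                "monte_carlo_se": ep.monte_carlo_se,
                "n_not_estimable": ep.n_not_estimable,
                "p_values": [None if np.isnan(p) else float(p) for p in ep.p_values],
            }
            for e, ep in res.effects.items()
        },
        "estimate_means": res.estimate_means,
        "estimate_sds": res.estimate_sds,
    }
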
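"""Ascertained case-parent trio simulator.

Trios are sampled conditional on an affected child.  The probability of
an ordered (M, F, C, M2) cell is proportional to

    P(M) * P(F) * P(C | M, F) * P(M2) * baseline * relative_risk(M, C, M2)

with parental genotypes drawn from sex-specific (possibly mixture)
Hardy-Weinberg distributions at locus 1, Mendelian transmission to the
child, and the maternal locus-2 genotype independent of locus 1.

Two interchangeable samplers are provided: a fast multinomial draw over
the 45 cells, and an individual-level rejection sampler that simulates
families prospectively and accepts each with probability equal to the
child's disease risk.  The two agree in distribution; the rejection
sampler serves as the cross-validation oracle for the cell algebra.

Named presets reproduce the study conditions of the power evaluation:
dominant models 1-10 and codominant models 11-14 (plus asymmetric-mating
variants 11a-14a), all with baseline incidence 0.1 and risk-allele
frequency 0.3 at both loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cell_table import (
    CONFIGURATIONS,
    MISSING,
    N_CELLS,
    PopulationParams,
    RiskModel,
    cell_index,
)
from .em_missing import IncompleteFamily
from .exceptions import ConfigurationError


def transmission_prob(m: int, f: int, c: int) -> float:
    """P(child = c | mother = m, father = f) under Mendelian transmission."""
    pm = (1 - m / 2, m / 2)  # P(transmit 0 or 1 risk allele)
    pf = (1 - f / 2, f / 2)
    prob = 0.0
    for am in (0, 1):
        for af in (0, 1):
            if am + af == c:
                prob += pm[am] * pf[af]
    return prob


@dataclass(frozen=True)
class Scenario:
    """One fully specified simulation condition."""

    risk: RiskModel
    pop: PopulationParams
    n_families: int
    missing_father_rate: float = 0.0
    missing_mother_rate: float = 0.0
    name: str = ""

    def __post_init__(self):
        if self.n_families < 1:
            raise ConfigurationError("n_families must be at least 1")
        for rate in (self.missing_father_rate, self.missing_mother_rate):
            if not 0 <= rate <= 1:
                raise ConfigurationError("missingness rates must lie in [0, 1]")
        if self.missing_father_rate + self.missing_mother_rate > 1:
            raise ConfigurationError("missingness rates must sum to at most 1")
        # penetrance validity: the riskiest category must have risk <= 1
        max_risk = max(
            self.risk.baseline_incidence * self.risk.relative_risk(i, j, k)
            for i in range(3)
            for j in range(3)
            for k in range(3)
        )
        if max_risk > 1:
            raise ConfigurationError(
                f"baseline incidence times the maximum relative-risk product is "
                f"{max_risk:.3f} > 1; the scenario is not a valid penetrance model"
            )


def cell_sampling_probabilities(s: Scenario) -> np.ndarray:
    """Normalized sampling probability of each of the 45 ordered cells."""
    pm = s.pop.mother_genotype_dist()
    pf = s.pop.father_genotype_dist()
    p2 = np.asarray(s.pop.p)
    out = np.empty(N_CELLS)
    for ci, cfg in enumerate(CONFIGURATIONS):
        trio = pm[cfg.m] * pf[cfg.f] * transmission_prob(cfg.m, cfg.f, cfg.c)
        for k in range(3):
            out[cell_index(ci, k)] = trio * p2[k] * s.risk.relative_risk(cfg.m, cfg.c, k)
    return out / out.sum()


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_cell_counts(s: Scenario, seed) -> np.ndarray:
    """Multinomial cell counts for one replicate (no missingness applied)."""
    rng = _rng(seed)
    return rng.multinomial(s.n_families, cell_sampling_probabilities(s)).astype(float)


def _apply_missingness(families: list[IncompleteFamily], s: Scenario,
                       rng: np.random.Generator) -> list[IncompleteFamily]:
    """Blank parents completely at random, one uniform draw per family.

    The father is blanked when u < missing_father_rate; the mother (both
    loci) when the draw falls in the next interval, so the two events
    are mutually exclusive within a family.
    """
    if s.missing_father_rate == 0 and s.missing_mother_rate == 0:
        return families
    u = rng.uniform(size=len(families))
    out = []
    for fam, ui in zip(families, u):
        if ui < s.missing_father_rate:
            out.append(replace(fam, f=MISSING))
        elif ui < s.missing_father_rate + s.missing_mother_rate:
            out.append(replace(fam, m=MISSING, m2=MISSING))
        else:
            out.append(fam)
    return out


_CELL_GENOTYPES = [
    (cfg.m, cfg.f, cfg.c, k) for cfg in CONFIGURATIONS for k in range(3)
]


def simulate_trios(s: Scenario, seed) -> list[IncompleteFamily]:
    """Simulate one ascertained dataset by multinomial cell sampling.

    Deterministic given the seed; missingness is applied per family.
    """
    rng = _rng(seed)
    counts = rng.multinomial(s.n_families, cell_sampling_probabilities(s))
    families = []
    fid = 0
    for cell, n in enumerate(counts):
        m, f, c, k = _CELL_GENOTYPES[cell]
        for _ in range(n):
            fid += 1
            families.append(IncompleteFamily(m=m, f=f, c=c, m2=k, family_id=f"fam{fid:05d}"))
    return _apply_missingness(families, s, rng)


def simulate_individual_level(s: Scenario, seed, batch: int = 8192) -> list[IncompleteFamily]:
    """Rejection sampler: prospective families accepted with the child's risk.

    Parents are drawn from the sex-specific genotype distributions,
    the child by Mendelian transmission, the maternal locus-2 genotype
    from its population distribution; the family is kept with
    probability baseline * relative_risk(M, C, M2).
    """
    rng = _rng(seed)
    pm = s.pop.mother_genotype_dist()
    pf = s.pop.father_genotype_dist()
    p2 = np.asarray(s.pop.p)
    risk_grid = np.array([
        [[s.risk.baseline_incidence * s.risk.relative_risk(i, j, k) for k in range(3)]
         for j in range(3)]
        for i in range(3)
    ])
    mean_acceptance = float(
        sum(
            pm[i] * pf[f] * transmission_prob(i, f, j) * p2[k] * risk_grid[i, j, k]
            for i in range(3) for f in range(3) for j in range(3) for k in range(3)
        )
    )
    if mean_acceptance < 1e-6:
        raise ConfigurationError(
            f"mean acceptance probability {mean_acceptance:.2e} is below 1e-6; "
            "the scenario is impractical for rejection sampling"
        )
    families: list[IncompleteFamily] = []
    fid = 0
    while len(families) < s.n_families:
        m = rng.choice(3, size=batch, p=pm)
        f = rng.choice(3, size=batch, p=pf)
        # child = one allele from each parent
        c = (rng.uniform(size=batch) < m / 2).astype(int) + (
            rng.uniform(size=batch) < f / 2
        ).astype(int)
        m2 = rng.choice(3, size=batch, p=p2)
        accept = rng.uniform(size=batch) < risk_grid[m, c, m2]
        for mi, fi, ci, ki in zip(m[accept], f[accept], c[accept], m2[accept]):
            if len(families) >= s.n_families:
                break
            fid += 1
            families.append(
                IncompleteFamily(m=int(mi), f=int(fi), c=int(ci), m2=int(ki),
                                 family_id=f"fam{fid:05d}")
            )
    return _apply_missingness(families, s, rng)


# ---------------------------------------------------------------------------
# Presets: the simulated study conditions
# ---------------------------------------------------------------------------

BASELINE_INCIDENCE = 0.1
RAF = 0.3
#: asymmetric-mating male strata: equal mixture of HWE subpopulations
ASYMMETRIC_MALE_STRATA = ((0.1, 0.5), (0.5, 0.5))

_SYMMETRIC_POP = PopulationParams.hwe(RAF, RAF)
_ASYMMETRIC_POP = PopulationParams(
    raf1_female=RAF, raf1_male=ASYMMETRIC_MALE_STRATA, raf2=RAF
)


def _risk(**kw) -> RiskModel:
    return RiskModel(baseline_incidence=BASELINE_INCIDENCE, **kw)


_CODOM_PHI = ((1.3, 1.69), (1.69, 2.197))
_CODOM_THETA = ((1.4, 1.96), (1.96, 2.744))

#: name -> (RiskModel, asymmetric mating?)
PRESET_RISKS: dict[str, tuple[RiskModel, bool]] = {
    "model1": (_risk(), False),
    "model2": (_risk(theta=1.5), False),
    "model3": (_risk(theta=2.0), False),
    "model4": (_risk(phi=1.5), False),
    "model5": (_risk(phi=2.0), False),
    "model6": (_risk(r=1.5, s=1.5), False),
    "model7": (_risk(theta=1.5, phi=1.5), False),
    "model8": (_risk(theta=2.0, phi=2.0), False),
    "model9": (_risk(rho=1.5), False),
    "model10": (_risk(rho=2.0), False),
    "model11": (_risk(phi=_CODOM_PHI), False),
    "model12": (_risk(theta=_CODOM_THETA), False),
    "model13": (_risk(phi=_CODOM_PHI, theta=_CODOM_THETA), False),
    "model14": (_risk(r=(1.3, 1.69), s=(1.4, 1.96)), False),
    "model11a": (_risk(phi=_CODOM_PHI), True),
    "model12a": (_risk(theta=_CODOM_THETA), True),
    "model13a": (_risk(phi=_CODOM_PHI, theta=_CODOM_THETA), True),
    "model14a": (_risk(r=(1.3, 1.69), s=(1.4, 1.96)), True),
}

PRESET_NAMES = tuple(PRESET_RISKS)

#: effects simulated under the alternative in each preset (for restricted fits)
PRESET_TRUE_EFFECTS: dict[str, tuple[str, ...]] = {
    "model1": (),
    "model2": ("mxm_theta",),
    "model3": ("mxm_theta",),
    "model4": ("mxo_phi",),
    "model5": ("mxo_phi",),
    "model6": ("maternal_main_S", "child_main_R"),
    "model7": ("mxm_theta", "mxo_phi"),
    "model8": ("mxm_theta", "mxo_phi"),
    "model9": ("rho",),
    "model10": ("rho",),
    "model11": ("mxo_phi",),
    "model12": ("mxm_theta",),
    "model13": ("mxm_theta", "mxo_phi"),
    "model14": ("maternal_main_S", "child_main_R"),
}


def scenario(name: str, n_families: int, missing_father_rate: float = 0.0,
             missing_mother_rate: float = 0.0) -> Scenario:
    """Build a named preset scenario with the stated sample size."""
    try:
        risk, asymmetric = PRESET_RISKS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown scenario {name!r}; available: {', '.join(PRESET_RISKS)}"
        ) from None
    pop = _ASYMMETRIC_POP if asymmetric else _SYMMETRIC_POP
    return Scenario(
        risk=risk,
        pop=pop,
        n_families=n_families,
        missing_father_rate=missing_father_rate,
        missing_mother_rate=missing_mother_rate,
        name=name,
    )


def true_locus2_frequencies() -> tuple[float, float, float]:
    """(p0, p1, p2) of the simulated maternal locus-2 genotypes."""
    return _SYMMETRIC_POP.p
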
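"""The two-locus trio cell space and its log-linear parameterization.

A case-parent trio is genotyped at a first biallelic locus (mother M,
father F, child C, coded 0/1/2 risk alleles) and the mother additionally
at a second, unlinked locus (M2).  Under mating symmetry the Mendelian-
consistent (M, F, C) triples fall into 15 ordered configurations spanning
six mating types; stratifying each on M2 gives 45 cells.  The expected
count of an ascertained trio in a cell factorizes as

    mult * p_k * tau_k * theta_{ik} * phi_{jk} * S_i * R_j * mu_m

where i = M, j = C, k = M2, p_k are the maternal locus-2 genotype
frequencies, S_i / R_j are maternal / child locus-1 relative risks,
theta_{ik} is the maternal-maternal (MxM) interaction, phi_{jk} the
maternal-offspring (MxO) interaction, tau_k the maternal locus-2 main
effect, mu_m the mating-type scaling factor, and mult = 2 for the
double-heterozygote configuration (both parents and child heterozygous),
which arises in two equally likely ways.

Taking logs makes the model linear, with ln p_k and ln(mult) entering as
fixed offsets.  This module enumerates the cell space, evaluates the
expected proportions, and builds the offset vectors and design matrices
for the model variants:

EQ1       locus-2 genotype frequencies specified in the offset; the
          locus-2 main effect delta_k = ln tau_k is estimable.
EQ2       frequencies estimated through free nuisance columns
          lambda_k = ln(p_k / p_0); delta is then not estimable.
EQ1_HWE   EQ1 with the six mating-type parameters replaced by a
          Hardy-Weinberg parameterization in one allele frequency.
EQ3       single-locus model on the 15 locus-1 cells with a
          maternal-by-child interaction rho_{ij} at the same locus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ConfigurationError, MendelianError

#: Sentinel for an unobserved genotype.
MISSING = -1

# ---------------------------------------------------------------------------
# Trio configurations
# ---------------------------------------------------------------------------

#: (index, mating_type, M, F, C, mendel_multiplicity)
_CONFIG_ROWS = (
    (1, 1, 2, 2, 2, 1),
    (2, 2, 2, 1, 2, 1),
    (3, 2, 2, 1, 1, 1),
    (4, 2, 1, 2, 2, 1),
    (5, 2, 1, 2, 1, 1),
    (6, 3, 2, 0, 1, 1),
    (7, 3, 0, 2, 1, 1),
    (8, 4, 1, 1, 2, 1),
    (9, 4, 1, 1, 1, 2),
    (10, 4, 1, 1, 0, 1),
    (11, 5, 1, 0, 1, 1),
    (12, 5, 1, 0, 0, 1),
    (13, 5, 0, 1, 1, 1),
    (14, 5, 0, 1, 0, 1),
    (15, 6, 0, 0, 0, 1),
)


@dataclass(frozen=True)
class TrioConfiguration:
    """One ordered Mendelian-consistent (M, F, C) locus-1 configuration."""

    index: int
    mating_type: int
    m: int
    f: int
    c: int
    mendel_multiplicity: int


CONFIGURATIONS: tuple[TrioConfiguration, ...] = tuple(
    TrioConfiguration(*row) for row in _CONFIG_ROWS
)

N_CONFIGURATIONS = 15
N_CELLS = 45  # 15 configurations x 3 locus-2 strata

_TRIO_TO_CONFIG = {(c.m, c.f, c.c): i for i, c in enumerate(CONFIGURATIONS)}

#: total parental risk-allele count per mating type m = 1..6
MATING_TYPE_ALLELES = (4, 3, 2, 2, 1, 0)


def enumerate_configurations() -> tuple[TrioConfiguration, ...]:
    """Return the 15 trio configurations in canonical row order."""
    return CONFIGURATIONS


def config_of(m: int, f: int, c: int) -> int:
    """0-based configuration index of an (M, F, C) triple.

    Raises
    ------
    MendelianError
        If the child genotype cannot arise from the parental pair.
    """
    try:
        return _TRIO_TO_CONFIG[(m, f, c)]
    except KeyError:
        raise MendelianError(
            f"genotypes M={m}, F={f}, C={c} are not Mendelian-consistent"
        ) from None


def cell_index(config: int, k: int) -> int:
    """Flat index of (0-based configuration, locus-2 genotype k)."""
    return config * 3 + k


def cell_labels() -> list[str]:
    return [
        f"cfg{cfg.index}_M{cfg.m}F{cfg.f}C{cfg.c}_M2={k}"
        for cfg in CONFIGURATIONS
        for k in range(3)
    ]


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


def _as_pair(x) -> tuple[float, float]:
    if np.isscalar(x):
        return (float(x), float(x))
    a, b = x
    return (float(a), float(b))


def _as_2x2(x) -> tuple[tuple[float, float], tuple[float, float]]:
    if np.isscalar(x):
        v = float(x)
        return ((v, v), (v, v))
    arr = np.asarray(x, dtype=float)
    if arr.shape != (2, 2):
        raise ConfigurationError("interaction parameters need a scalar or a 2x2 array")
    return ((arr[0, 0], arr[0, 1]), (arr[1, 0], arr[1, 1]))


@dataclass(frozen=True)
class RiskModel:
    """Relative-risk parameterization of offspring disease risk.

    Index 0 of every effect is the reference category with relative risk
    1; interaction entries with any index 0 are likewise 1.  ``theta``
    and ``phi`` are indexed [i-1][k-1] (maternal locus-1 x maternal
    locus-2) and [j-1][k-1] (child locus-1 x maternal locus-2);
    ``rho`` is the single-locus maternal-by-child interaction [i-1][j-1].
    Scalars broadcast to all four entries (a dominant effect).
    """

    s: tuple[float, float] = (1.0, 1.0)
    r: tuple[float, float] = (1.0, 1.0)
    theta: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 1.0), (1.0, 1.0))
    phi: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 1.0), (1.0, 1.0))
    tau: tuple[float, float] = (1.0, 1.0)
    rho: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 1.0), (1.0, 1.0))
    baseline_incidence: float = 0.1

    def __post_init__(self):
        object.__setattr__(self, "s", _as_pair(self.s))
        object.__setattr__(self, "r", _as_pair(self.r))
        object.__setattr__(self, "tau", _as_pair(self.tau))
        object.__setattr__(self, "theta", _as_2x2(self.theta))
        object.__setattr__(self, "phi", _as_2x2(self.phi))
        object.__setattr__(self, "rho", _as_2x2(self.rho))
        vals = (
            *self.s, *self.r, *self.tau,
            *(v for row in self.theta for v in row),
            *(v for row in self.phi for v in row),
            *(v for row in self.rho for v in row),
        )
        if any(v <= 0 for v in vals):
            raise ConfigurationError("all relative risks must be strictly positive")
        if not 0 < self.baseline_incidence <= 1:
            raise ConfigurationError("baseline incidence must lie in (0, 1]")

    def s_at(self, i: int) -> float:
        return 1.0 if i == 0 else self.s[i - 1]

    def r_at(self, j: int) -> float:
        return 1.0 if j == 0 else self.r[j - 1]

    def tau_at(self, k: int) -> float:
        return 1.0 if k == 0 else self.tau[k - 1]

    def theta_at(self, i: int, k: int) -> float:
        return 1.0 if i == 0 or k == 0 else self.theta[i - 1][k - 1]

    def phi_at(self, j: int, k: int) -> float:
        return 1.0 if j == 0 or k == 0 else self.phi[j - 1][k - 1]

    def rho_at(self, i: int, j: int) -> float:
        return 1.0 if i == 0 or j == 0 else self.rho[i - 1][j - 1]

    def relative_risk(self, i: int, j: int, k: int) -> float:
        """Joint relative risk of the (M=i, C=j, M2=k) category."""
        return (
            self.s_at(i)
            * self.r_at(j)
            * self.theta_at(i, k)
            * self.phi_at(j, k)
            * self.tau_at(k)
            * self.rho_at(i, j)
        )


def hwe_genotype_frequencies(q: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype frequencies ((1-q)^2, 2q(1-q), q^2)."""
    if not 0 < q < 1:
        raise ConfigurationError(f"allele frequency must lie in (0, 1), got {q}")
    return ((1 - q) ** 2, 2 * q * (1 - q), q**2)


def hwe_mating_mu(q: float) -> tuple[float, ...]:
    """Mating-type scaling factors mu_m under HWE, ordered-pair convention.

    mu_m = q^{a_m} (1-q)^{4-a_m} where a_m is the parents' total
    risk-allele count (4, 3, 2, 2, 1, 0 for m = 1..6).  Each ordered
    parental pair of the type carries this same factor, so that under
    the null the 45 cells sum to one.
    """
    return tuple(q**a * (1 - q) ** (4 - a) for a in MATING_TYPE_ALLELES)


@dataclass(frozen=True)
class PopulationParams:
    """Population genotype structure at both loci.

    ``raf1_male`` is either a single allele frequency or a sequence of
    (frequency, weight) strata, allowing asymmetric mating where the
    male genotype distribution is a mixture of Hardy-Weinberg strata.
    ``p`` is the maternal locus-2 genotype frequency triple (p0, p1, p2)
    ordered by risk-allele count.  ``mu`` optionally overrides the
    mating-type scaling factors; by default they are the ordered-pair
    HWE values for ``raf1_female``.
    """

    raf1_female: float = 0.3
    raf1_male: float | tuple = 0.3
    raf2: float = 0.3
    p: tuple[float, float, float] | None = None
    mu: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.p is None:
            object.__setattr__(self, "p", hwe_genotype_frequencies(self.raf2))
        p = tuple(float(v) for v in self.p)
        if len(p) != 3 or any(v < 0 for v in p):
            raise ConfigurationError("p must be three nonnegative frequencies")
        if abs(sum(p) - 1.0) > 1e-12:
            raise ConfigurationError(f"locus-2 genotype frequencies sum to {sum(p)}, not 1")
        object.__setattr__(self, "p", p)
        if self.mu is not None:
            mu = tuple(float(v) for v in self.mu)
            if len(mu) != 6 or any(v <= 0 for v in mu):
                raise ConfigurationError("mu must be six positive scaling factors")
            object.__setattr__(self, "mu", mu)

    @classmethod
    def hwe(cls, raf1: float = 0.3, raf2: float = 0.3) -> "PopulationParams":
        """Symmetric mating with HWE at both loci."""
        return cls(raf1_female=raf1, raf1_male=raf1, raf2=raf2)

    @property
    def symmetric(self) -> bool:
        return np.isscalar(self.raf1_male) and float(self.raf1_male) == self.raf1_female

    def male_strata(self) -> tuple[tuple[float, float], ...]:
        """(allele frequency, weight) strata of the male population."""
        if np.isscalar(self.raf1_male):
            return ((float(self.raf1_male), 1.0),)
        strata = tuple((float(q), float(w)) for q, w in self.raf1_male)
        total = sum(w for _, w in strata)
        if abs(total - 1.0) > 1e-12:
            raise ConfigurationError("male stratum weights must sum to 1")
        return strata

    def mother_genotype_dist(self) -> np.ndarray:
        return np.array(hwe_genotype_frequencies(self.raf1_female))

    def father_genotype_dist(self) -> np.ndarray:
        dist = np.zeros(3)
        for q, w in self.male_strata():
            dist += w * np.array(hwe_genotype_frequencies(q))
        return dist

    def mating_mu(self) -> tuple[float, ...]:
        if self.mu is not None:
            return self.mu
        return hwe_mating_mu(self.raf1_female)


# ---------------------------------------------------------------------------
# Expected cell proportions (the tabulated model)
# ---------------------------------------------------------------------------


def expected_cell_proportions(risk: RiskModel, pop: PopulationParams) -> np.ndarray:
    """Expected relative cell magnitudes over the 45 cells.

    Each cell carries mult * p_k * tau_k * theta_{ik} * phi_{jk} * S_i
    * R_j * mu_m.  The result is not normalized in general; under an
    all-null risk model with HWE-consistent mu it sums to one.
    """
    mu = pop.mating_mu()
    out = np.empty(N_CELLS)
    for ci, cfg in enumerate(CONFIGURATIONS):
        base = cfg.mendel_multiplicity * risk.s_at(cfg.m) * risk.r_at(cfg.c) * mu[cfg.mating_type - 1]
        for k in range(3):
            out[cell_index(ci, k)] = (
                base
                * pop.p[k]
                * risk.tau_at(k)
                * risk.theta_at(cfg.m, k)
                * risk.phi_at(cfg.c, k)
            )
    return out


# ---------------------------------------------------------------------------
# Model specification and design matrices
# ---------------------------------------------------------------------------


class GeneticCoding(str, Enum):
    """Constraint linking the two non-reference genotype categories.

    DOMINANT ties index-1 and index-2 parameters (one free parameter per
    effect), MULTIPLICATIVE sets the index-2 log coefficient to twice
    the index-1 one, CODOMINANT (= UNCONSTRAINED) leaves both free.
    """

    DOMINANT = "dominant"
    CODOMINANT = "codominant"
    MULTIPLICATIVE = "multiplicative"
    UNCONSTRAINED = "unconstrained"


# Effect labels
MATERNAL_MAIN = "maternal_main_S"
CHILD_MAIN = "child_main_R"
LOCUS2_MAIN = "locus2_main_delta"
MXM = "mxm_theta"
MXO = "mxo_phi"
RHO = "rho"

TWO_LOCUS_EFFECTS = (MATERNAL_MAIN, CHILD_MAIN, LOCUS2_MAIN, MXM, MXO)
SINGLE_LOCUS_EFFECTS = (MATERNAL_MAIN, CHILD_MAIN, RHO)

VARIANTS = ("eq1", "eq2", "eq1_hwe", "eq3")


@dataclass(frozen=True)
class ModelSpec:
    """Which variant, genetic codings, and effects are fitted.

    ``coding`` is a single :class:`GeneticCoding` applied to every
    tested effect, or a mapping from effect label to coding.  The
    locus-2 main effect delta is always fitted with two free parameters
    (delta_1, delta_2); so are the EQ2 nuisance frequency columns
    lambda_1, lambda_2.
    """

    variant: str
    included_effects: tuple[str, ...]
    coding: GeneticCoding | Mapping[str, GeneticCoding] = GeneticCoding.CODOMINANT
    specified_p: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"unknown model variant {self.variant!r}")
        valid = SINGLE_LOCUS_EFFECTS if self.variant == "eq3" else TWO_LOCUS_EFFECTS
        effects = tuple(self.included_effects)
        for e in effects:
            if e not in valid:
                raise ConfigurationError(
                    f"effect {e!r} is not available under variant {self.variant!r}"
                )
        object.__setattr__(self, "included_effects", effects)
        if self.variant in ("eq1", "eq1_hwe"):
            if self.specified_p is None:
                raise ConfigurationError(
                    f"variant {self.variant!r} requires specified locus-2 genotype frequencies"
                )
            p = tuple(float(v) for v in self.specified_p)
            if len(p) != 3 or any(v <= 0 for v in p):
                raise ConfigurationError(
                    "specified_p must be three strictly positive frequencies"
                )
            if abs(sum(p) - 1.0) > 1e-8:
                raise ConfigurationError("specified_p must sum to 1")
            object.__setattr__(self, "specified_p", p)
        elif self.specified_p is not None:
            raise ConfigurationError(
                f"variant {self.variant!r} does not take specified genotype frequencies"
            )
        if self.variant == "eq2" and LOCUS2_MAIN in effects:
            raise ConfigurationError(
                "the locus-2 main effect is not estimable when its genotype "
                "frequencies are estimated (EQ2)"
            )

    # -- construction helpers ------------------------------------------------

    @classmethod
    def full(cls, variant: str, coding: GeneticCoding | Mapping = GeneticCoding.CODOMINANT,
             p: Sequence[float] | None = None) -> "ModelSpec":
        """Full model: all main effects plus both interactions."""
        if variant == "eq3":
            effects = SINGLE_LOCUS_EFFECTS
        elif variant == "eq2":
            effects = (MATERNAL_MAIN, CHILD_MAIN, MXM, MXO)
        else:
            effects = TWO_LOCUS_EFFECTS
        return cls(variant, effects, coding, tuple(p) if p is not None else None)

    def drop(self, effect: str) -> "ModelSpec":
        """The nested spec with one effect removed (all else identical)."""
        if effect not in self.included_effects:
            raise ConfigurationError(f"effect {effect!r} is not in the model")
        return replace(
            self, included_effects=tuple(e for e in self.included_effects if e != effect)
        )

    def coding_for(self, effect: str) -> GeneticCoding:
        if effect == LOCUS2_MAIN:
            return GeneticCoding.CODOMINANT
        if isinstance(self.coding, Mapping):
            return GeneticCoding(self.coding.get(effect, GeneticCoding.CODOMINANT))
        return GeneticCoding(self.coding)

    @property
    def n_cells(self) -> int:
        return 15 if self.variant == "eq3" else N_CELLS


def build_offsets(variant: str, p: Sequence[float] | None = None) -> np.ndarray:
    """Fixed offset vector of the log-linear predictor.

    EQ1 / EQ1_HWE: ln p_k plus ln 2 for the double-heterozygote
    configuration.  EQ2: only the ln 2 multiplicity (frequencies are
    absorbed into free lambda columns).  EQ3: 15-cell ln 2 multiplicity.
    """
    if variant not in VARIANTS:
        raise ConfigurationError(f"unknown model variant {variant!r}")
    if variant == "eq3":
        off = np.zeros(15)
        for ci, cfg in enumerate(CONFIGURATIONS):
            if cfg.mendel_multiplicity == 2:
                off[ci] = math.log(2.0)
        return off
    off = np.zeros(N_CELLS)
    if variant in ("eq1", "eq1_hwe"):
        if p is None:
            raise ConfigurationError(f"{variant} offsets require genotype frequencies")
        p = tuple(float(v) for v in p)
        if any(v <= 0 for v in p):
            raise ConfigurationError("genotype frequencies must be strictly positive for the offset")
        lnp = [math.log(v) for v in p]
    else:
        lnp = [0.0, 0.0, 0.0]
    for ci, cfg in enumerate(CONFIGURATIONS):
        for k in range(3):
            off[cell_index(ci, k)] = lnp[k] + (math.log(2.0) if cfg.mendel_multiplicity == 2 else 0.0)
    return off


def _main_effect_columns(values: np.ndarray, coding: GeneticCoding, stem: str):
    """Columns for a three-level main effect with the given coding."""
    if coding == GeneticCoding.DOMINANT:
        return [(f"{stem}_dom", (values >= 1).astype(float))]
    if coding == GeneticCoding.MULTIPLICATIVE:
        return [(f"{stem}_mult", values.astype(float))]
    return [
        (f"{stem}_1", (values == 1).astype(float)),
        (f"{stem}_2", (values == 2).astype(float)),
    ]


def _interaction_columns(u: np.ndarray, v: np.ndarray, coding: GeneticCoding, stem: str):
    if coding == GeneticCoding.DOMINANT:
        return [(f"{stem}_dom", ((u >= 1) & (v >= 1)).astype(float))]
    if coding == GeneticCoding.MULTIPLICATIVE:
        return [(f"{stem}_mult", (u * v).astype(float))]
    return [
        (f"{stem}_{a}{b}", ((u == a) & (v == b)).astype(float))
        for a in (1, 2)
        for b in (1, 2)
    ]


@dataclass
class Design:
    """Design matrix, labels, per-effect column map, and offsets."""

    X: np.ndarray
    labels: list[str]
    columns: dict[str, list[int]]
    offset: np.ndarray
    spec: ModelSpec

    def effect_columns(self, effect: str) -> list[int]:
        return self.columns.get(effect, [])


def build_design_matrix(spec: ModelSpec) -> Design:
    """Linearize the cell-table model for one spec.

    For every admissible coefficient vector,
    ``exp(X @ coef + offset)`` reproduces the tabulated expected cell
    proportions cell by cell.
    """
    n = spec.n_cells
    if spec.variant == "eq3":
        m_val = np.array([cfg.m for cfg in CONFIGURATIONS], dtype=float)
        c_val = np.array([cfg.c for cfg in CONFIGURATIONS], dtype=float)
        mt = np.array([cfg.mating_type for cfg in CONFIGURATIONS])
        k_val = None
    else:
        m_val = np.array([cfg.m for cfg in CONFIGURATIONS for _ in range(3)], dtype=float)
        c_val = np.array([cfg.c for cfg in CONFIGURATIONS for _ in range(3)], dtype=float)
        mt = np.array([cfg.mating_type for cfg in CONFIGURATIONS for _ in range(3)])
        k_val = np.array([k for _ in CONFIGURATIONS for k in range(3)], dtype=float)

    cols: list[tuple[str, np.ndarray]] = []
    columns: dict[str, list[int]] = {}

    def add(effect: str, new_cols):
        start = len(cols)
        cols.extend(new_cols)
        columns.setdefault(effect, []).extend(range(start, len(cols)))

    # nuisance stratum columns
    if spec.variant == "eq1_hwe":
        a_m = np.array([MATING_TYPE_ALLELES[m - 1] for m in mt], dtype=float)
        add("strata", [("intercept", np.ones(n)), ("logit_raf1", a_m)])
    else:
        add("strata", [(f"mu_{m}", (mt == m).astype(float)) for m in range(1, 7)])

    if spec.variant == "eq2":
        # free genotype-frequency columns lambda_k = ln(p_k / p_0)
        add("lambda", [
            ("lambda_1", (k_val == 1).astype(float)),
            ("lambda_2", (k_val == 2).astype(float)),
        ])

    for effect in spec.included_effects:
        coding = spec.coding_for(effect)
        if effect == MATERNAL_MAIN:
            add(effect, _main_effect_columns(m_val, coding, "ln_S"))
        elif effect == CHILD_MAIN:
            add(effect, _main_effect_columns(c_val, coding, "ln_R"))
        elif effect == LOCUS2_MAIN:
            add(effect, [
                ("delta_1", (k_val == 1).astype(float)),
                ("delta_2", (k_val == 2).astype(float)),
            ])
        elif effect == MXM:
            add(effect, _interaction_columns(m_val, k_val, coding, "ln_theta"))
        elif effect == MXO:
            add(effect, _interaction_columns(c_val, k_val, coding, "ln_phi"))
        elif effect == RHO:
            add(effect, _interaction_columns(m_val, c_val, coding, "ln_rho"))

    X = np.column_stack([c for _, c in cols])
    labels = [name for name, _ in cols]
    offset = build_offsets(spec.variant, spec.specified_p)
    return Design(X=X, labels=labels, columns=columns, offset=offset, spec=spec)


# ---------------------------------------------------------------------------
# Count containers
# ---------------------------------------------------------------------------


@dataclass
class CellTable:
    """Counts (possibly fractional, from EM) over the 45 or 15 cells."""

    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape not in ((N_CELLS,), (15,)):
            raise ConfigurationError("counts must cover 45 two-locus or 15 single-locus cells")
        if np.any(counts < 0):
            raise ConfigurationError("cell counts must be nonnegative")
        self.counts = counts

    @property
    def two_locus(self) -> bool:
        return self.counts.shape == (N_CELLS,)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def collapse_locus2(self) -> "CellTable":
        """Sum over the M2 strata, yielding the 15 locus-1 cells."""
        if not self.two_locus:
            return CellTable(self.counts.copy())
        return CellTable(self.counts.reshape(15, 3).sum(axis=1))


def tabulate_families(families) -> CellTable:
    """45-cell counts from fully observed families.

    Raises
    ------
    DataError
        If any family has a missing genotype (use the EM module then).
    """
    from .exceptions import DataError

    counts = np.zeros(N_CELLS)
    for fam in families:
        m, f, c, m2 = fam.m, fam.f, fam.c, fam.m2
        if MISSING in (m, f, c, m2):
            raise DataError(
                "tabulate_families requires fully observed trios; "
                "incomplete families must be analyzed with em_fit"
            )
        counts[cell_index(config_of(m, f, c), m2)] += 1
    return CellTable(counts)
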
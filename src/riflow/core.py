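"""Shared domain types: genetic architectures, fitness schemes, haplotype state.

The genome model is haploid-equivalent: the unit of state is a frequency
vector over all ``2**L`` haplotypes of an ordered set of ``L`` loci on a
linear map.  Selection acts multiplicatively on haplotypes, and random
mating with recombination is modelled by independent crossover indicators
on each adjacent inter-locus interval (no interference).

Haplotypes are encoded as integers: bit ``i`` is the allele (0/1) at locus
``i``, where allele 1 is by convention the derived / source-population
allele and allele 0 the ancestral / resident allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Locus",
    "GeneticArchitecture",
    "PairInteraction",
    "FitnessScheme",
    "HaplotypeDistribution",
    "HybridClassFitness",
    "UnknownEnvironmentError",
    "genotype_fitness",
    "recombination_distribution",
    "recombine_population",
    "recombine_cross",
    "divergent_locus",
    "neutral_locus",
]

#: hard cap on exact haplotype enumeration (2**10 = 1024 haplotypes)
MAX_LOCI = 10


class UnknownEnvironmentError(KeyError):
    """A selected locus has no selection coefficient for the requested environment."""


@dataclass(frozen=True)
class Locus:
    """One locus on the map.

    Parameters
    ----------
    id:
        Unique label.
    kind:
        ``"selected"`` or ``"neutral"``.
    s:
        Mapping environment -> selection coefficient of the locally
        disfavoured allele (fitness factor ``1 - s``; ``s`` may be negative
        for a locally favoured foreign allele, but must satisfy ``s < 1``
        is not required -- only the resulting fitness must be >= 0).
    disfavoured:
        Mapping environment -> which allele (0 or 1) is disfavoured there.
        Defaults to allele 1 in every environment listed in ``s``.
    """

    id: str
    kind: str = "neutral"
    s: Mapping[str, float] = field(default_factory=dict)
    disfavoured: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("selected", "neutral"):
            raise ValueError(f"locus kind must be 'selected' or 'neutral', got {self.kind!r}")
        if self.kind == "neutral" and self.s:
            raise ValueError(f"neutral locus {self.id!r} must not carry selection coefficients")
        for env, val in self.s.items():
            if val <= -1.0:
                raise ValueError(
                    f"locus {self.id!r}: s={val} in environment {env!r} must be > -1"
                )
        for env, a in self.disfavoured.items():
            if a not in (0, 1):
                raise ValueError(f"locus {self.id!r}: disfavoured allele must be 0 or 1")

    def s_in(self, environment: str) -> float:
        try:
            return self.s[environment]
        except KeyError:
            raise UnknownEnvironmentError(
                f"locus {self.id!r} has no selection coefficient for environment "
                f"{environment!r} (known: {sorted(self.s)})"
            ) from None

    def disfavoured_in(self, environment: str) -> int:
        return self.disfavoured.get(environment, 1)


def divergent_locus(
    id: str,
    s: float,
    environments: Sequence[str] = ("recipient", "source"),
    s_by_env: Mapping[str, float] | None = None,
) -> Locus:
    """Selected locus under divergent selection between two environments.

    Allele 1 is disfavoured (deficit ``s``) in the first environment and
    allele 0 is disfavoured in the second, so each environment favours its
    own resident allele.
    """
    e0, e1 = environments
    s0 = s if s_by_env is None else s_by_env[e0]
    s1 = s if s_by_env is None else s_by_env[e1]
    return Locus(id, "selected", s={e0: s0, e1: s1}, disfavoured={e0: 1, e1: 0})


def neutral_locus(id: str) -> Locus:
    return Locus(id, "neutral")


@dataclass(frozen=True)
class GeneticArchitecture:
    """Ordered loci on a linear map with adjacent recombination fractions.

    ``adjacent_r[i]`` is the recombination fraction between locus ``i`` and
    locus ``i + 1``; all values lie in ``[0, 0.5]``.  Compound recombination
    fractions between non-adjacent loci are obtained by convolving the
    independent crossover indicators, which keeps them <= 0.5.
    """

    loci: tuple[Locus, ...]
    adjacent_r: tuple[float, ...]

    def __init__(self, loci: Iterable[Locus], adjacent_r: Iterable[float]):
        object.__setattr__(self, "loci", tuple(loci))
        object.__setattr__(self, "adjacent_r", tuple(float(r) for r in adjacent_r))
        L = len(self.loci)
        if L < 1:
            raise ValueError("architecture needs at least one locus")
        if L > MAX_LOCI:
            raise ValueError(
                f"exact enumeration capped at {MAX_LOCI} loci ({L} requested)"
            )
        if len(self.adjacent_r) != L - 1:
            raise ValueError(
                f"expected {L - 1} adjacent recombination fractions, got {len(self.adjacent_r)}"
            )
        for r in self.adjacent_r:
            if not (0.0 <= r <= 0.5):
                raise ValueError(f"adjacent recombination fraction {r} outside [0, 0.5]")
        ids = [l.id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("locus ids must be unique")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_haplotypes(self) -> int:
        return 1 << self.n_loci

    @property
    def locus_ids(self) -> list[str]:
        return [l.id for l in self.loci]

    def index_of(self, locus_id: str) -> int:
        for i, l in enumerate(self.loci):
            if l.id == locus_id:
                return i
        raise KeyError(f"no locus {locus_id!r} in architecture")

    @property
    def selected_indices(self) -> list[int]:
        return [i for i, l in enumerate(self.loci) if l.kind == "selected"]

    @property
    def neutral_indices(self) -> list[int]:
        return [i for i, l in enumerate(self.loci) if l.kind == "neutral"]

    def compound_r(self, i: int, j: int) -> float:
        """Recombination fraction between loci i and j (no interference).

        P(odd number of crossovers) = (1 - prod(1 - 2 r_k)) / 2.
        """
        if i == j:
            return 0.0
        lo, hi = sorted((i, j))
        prod = 1.0
        for r in self.adjacent_r[lo:hi]:
            prod *= 1.0 - 2.0 * r
        return 0.5 * (1.0 - prod)

    @cached_property
    def _crossover_patterns(self) -> tuple[np.ndarray, np.ndarray]:
        """All crossover patterns as (masks, probabilities).

        A mask has bit i set when locus i is inherited from parent 1
        (parent 1 contributes locus 0 by convention; random mating restores
        the symmetry because parents are exchangeable).
        """
        L = self.n_loci
        masks = np.empty(1 << max(L - 1, 0), dtype=np.int64)
        probs = np.empty_like(masks, dtype=float)
        for bits in range(1 << (L - 1)):
            src = 0
            mask = 1
            p = 1.0
            for i, r in enumerate(self.adjacent_r):
                c = (bits >> i) & 1
                p *= r if c else (1.0 - r)
                src ^= c
                if src == 0:
                    mask |= 1 << (i + 1)
            masks[bits] = mask
            probs[bits] = p
        return masks, probs

    def marginal_allele_frequencies(self, freqs: np.ndarray) -> np.ndarray:
        """Per-locus frequency of allele 1 from a haplotype frequency array.

        ``freqs`` may be batched: shape ``(..., 2**L)``; returns ``(..., L)``.
        """
        freqs = np.asarray(freqs, dtype=float)
        haps = np.arange(self.n_haplotypes)
        carry = np.array(
            [(haps >> i) & 1 for i in range(self.n_loci)], dtype=float
        )  # (L, nH)
        return freqs @ carry.T


@dataclass(frozen=True)
class PairInteraction:
    """Joint fitness term for a pair of selected loci.

    In ``pairwise_epistasis`` mode, ``coefficient`` is the joint selection
    coefficient s12 applied (as ``1 - s12``) when the locally disfavoured
    alleles at both loci co-occur on a haplotype, replacing the two
    single-locus factors.  Additivity (s12 = s1 + s2) means no epistasis.

    In ``dmi`` mode, ``coefficient`` is the incompatibility penalty applied
    (as an extra factor ``1 - penalty``) whenever the derived alleles
    (allele 1) at both loci co-occur, regardless of environment.
    """

    locus_a: str
    locus_b: str
    coefficient: float


class FitnessScheme:
    """Haplotype fitness model over a genetic architecture.

    Modes
    -----
    multiplicative:
        fitness = product over selected loci of ``(1 - s)`` for each locally
        disfavoured allele carried.
    pairwise_epistasis:
        as multiplicative, but designated locus pairs carrying both
        disfavoured alleles contribute a joint factor ``(1 - s12)`` instead
        of the two single-locus factors.
    dmi:
        multiplicative base times an incompatibility factor ``(1 - penalty)``
        for each designated pair whose derived alleles co-occur.
    """

    MODES = ("multiplicative", "pairwise_epistasis", "dmi")

    def __init__(
        self,
        architecture: GeneticArchitecture,
        mode: str = "multiplicative",
        pairs: Sequence[PairInteraction] = (),
    ):
        if mode not in self.MODES:
            raise ValueError(f"unknown fitness mode {mode!r}; expected one of {self.MODES}")
        if mode == "multiplicative" and pairs:
            raise ValueError("multiplicative mode takes no pairwise terms")
        self.architecture = architecture
        self.mode = mode
        self.pairs = tuple(pairs)
        for p in self.pairs:
            architecture.index_of(p.locus_a)
            architecture.index_of(p.locus_b)
        self._cache: dict[str, np.ndarray] = {}

    def fitness_vector(self, environment: str) -> np.ndarray:
        """Fitness of every haplotype (length ``2**L``) in ``environment``."""
        if environment in self._cache:
            return self._cache[environment]
        arch = self.architecture
        haps = np.arange(arch.n_haplotypes)
        w = np.ones(arch.n_haplotypes)
        paired = set()
        if self.mode == "pairwise_epistasis":
            for p in self.pairs:
                paired.update((p.locus_a, p.locus_b))
        for i, locus in enumerate(arch.loci):
            if locus.kind != "selected" or locus.id in paired:
                continue
            s = locus.s_in(environment)
            bad = locus.disfavoured_in(environment)
            hit = ((haps >> i) & 1) == bad
            w = np.where(hit, w * (1.0 - s), w)
        if self.mode == "pairwise_epistasis":
            for p in self.pairs:
                ia, ib = arch.index_of(p.locus_a), arch.index_of(p.locus_b)
                la, lb = arch.loci[ia], arch.loci[ib]
                hit_a = ((haps >> ia) & 1) == la.disfavoured_in(environment)
                hit_b = ((haps >> ib) & 1) == lb.disfavoured_in(environment)
                fac = np.ones(arch.n_haplotypes)
                fac[hit_a & ~hit_b] = 1.0 - la.s_in(environment)
                fac[~hit_a & hit_b] = 1.0 - lb.s_in(environment)
                fac[hit_a & hit_b] = 1.0 - p.coefficient
                w = w * fac
        elif self.mode == "dmi":
            for p in self.pairs:
                ia, ib = arch.index_of(p.locus_a), arch.index_of(p.locus_b)
                both = (((haps >> ia) & 1) == 1) & (((haps >> ib) & 1) == 1)
                w = np.where(both, w * (1.0 - p.coefficient), w)
        if np.any(w < 0):
            raise ValueError(
                f"scheme produces negative fitness in environment {environment!r}"
            )
        self._cache[environment] = w
        return w


def genotype_fitness(scheme: FitnessScheme, haplotype: int, environment: str) -> float:
    """Fitness of a single haplotype in an environment (resident baseline 1)."""
    nH = scheme.architecture.n_haplotypes
    if not (0 <= haplotype < nH):
        raise ValueError(f"haplotype {haplotype} outside [0, {nH})")
    return float(scheme.fitness_vector(environment)[haplotype])


@dataclass
class HaplotypeDistribution:
    """Frequency vector over all haplotypes of an architecture."""

    architecture: GeneticArchitecture
    frequencies: np.ndarray

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.shape != (self.architecture.n_haplotypes,):
            raise ValueError(
                f"expected {self.architecture.n_haplotypes} frequencies, "
                f"got shape {self.frequencies.shape}"
            )
        if np.any(self.frequencies < -1e-15):
            raise ValueError("haplotype frequencies must be nonnegative")
        if abs(self.frequencies.sum() - 1.0) > 1e-12:
            raise ValueError("haplotype frequencies must sum to 1 within 1e-12")

    @classmethod
    def point_mass(cls, architecture: GeneticArchitecture, haplotype: int):
        f = np.zeros(architecture.n_haplotypes)
        f[haplotype] = 1.0
        return cls(architecture, f)

    def allele_frequency(self, locus: int | str) -> float:
        i = locus if isinstance(locus, int) else self.architecture.index_of(locus)
        haps = np.arange(self.architecture.n_haplotypes)
        return float(self.frequencies[((haps >> i) & 1) == 1].sum())


@dataclass
class HybridClassFitness:
    """Mean fitnesses W0, W1, W2, ... of migrant / F1 / backcross classes.

    ``values[k]`` is the mean fitness of class k relative to residents (= 1);
    values may exceed 1 under heterosis.  ``naive`` optionally holds the
    selection-free (pure Mendelian dilution) expectation for comparison.
    """

    values: np.ndarray
    naive: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("class fitnesses must be nonnegative")
        if self.naive is not None:
            self.naive = np.asarray(self.naive, dtype=float)


# ---------------------------------------------------------------------------
# Recombination under random mating
# ---------------------------------------------------------------------------

def _mask_marginals(fv: np.ndarray, L: int, mask: int):
    """Sum over loci outside / inside ``mask`` of an (..., 2, ..., 2) view."""
    out_axes = tuple(-(i + 1) for i in range(L) if not (mask >> i) & 1)
    in_axes = tuple(-(i + 1) for i in range(L) if (mask >> i) & 1)
    mM = fv.sum(axis=out_axes, keepdims=True) if out_axes else fv
    mC = fv.sum(axis=in_axes, keepdims=True) if in_axes else fv
    return mM, mC


def recombine_population(freqs: np.ndarray, architecture: GeneticArchitecture) -> np.ndarray:
    """Offspring haplotype distribution under random mating within a pool.

    Both parents are drawn iid from ``freqs`` (last axis enumerates the
    ``2**L`` haplotypes; leading axes are batch dimensions, e.g. demes).
    Crossovers on adjacent intervals are independent with probabilities
    ``adjacent_r`` (no interference).
    """
    freqs = np.asarray(freqs, dtype=float)
    L = architecture.n_loci
    masks, probs = architecture._crossover_patterns
    shape = freqs.shape
    fv = freqs.reshape(shape[:-1] + (2,) * L)
    out = np.zeros_like(fv)
    for mask, w in zip(masks, probs):
        mM, mC = _mask_marginals(fv, L, int(mask))
        out += w * (mM * mC)
    return out.reshape(shape)


def recombine_cross(
    f1: np.ndarray, f2: np.ndarray, architecture: GeneticArchitecture
) -> np.ndarray:
    """Offspring distribution when parent 1 ~ f1 and parent 2 ~ f2."""
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    L = architecture.n_loci
    masks, probs = architecture._crossover_patterns
    shape = np.broadcast_shapes(f1.shape, f2.shape)
    v1 = f1.reshape(f1.shape[:-1] + (2,) * L)
    v2 = f2.reshape(f2.shape[:-1] + (2,) * L)
    out = np.zeros(shape[:-1] + (2,) * L)
    for mask, w in zip(masks, probs):
        m1M, m1C = _mask_marginals(v1, L, int(mask))
        m2M, m2C = _mask_marginals(v2, L, int(mask))
        out += 0.5 * w * (m1M * m2C + m2M * m1C)
    return out.reshape(shape)


def recombination_distribution(
    architecture: GeneticArchitecture, parent1: int, parent2: int
) -> np.ndarray:
    """Exact offspring haplotype distribution for two parent haplotypes.

    Symmetric in the parents; probabilities sum to 1.
    """
    nH = architecture.n_haplotypes
    for p in (parent1, parent2):
        if not (0 <= p < nH):
            raise ValueError(f"parent haplotype {p} outside [0, {nH})")
    e1 = np.zeros(nH)
    e1[parent1] = 1.0
    e2 = np.zeros(nH)
    e2[parent2] = 1.0
    return recombine_cross(e1, e2, architecture)
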
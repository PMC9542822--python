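"""Two-deme (and small multi-deme) deterministic dynamics and RI formulas.

Reproductive isolation between two demes is defined as RI = 1 - m_e / m,
where m is the migration rate set by the model and m_e is the effective
migration rate actually experienced by a neutral marker: the per-generation
change in the recipient's marker frequency attributable to gene flow (dp),
relative to the between-deme frequency difference (Dp), m_e = dp / Dp.

The life cycle is migration -> selection -> random mating with
recombination; dp is the net change in the recipient's neutral frequency
over one full cycle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import (
    FitnessScheme,
    GeneticArchitecture,
    HaplotypeDistribution,
    HybridClassFitness,
    recombine_cross,
    recombine_population,
)

__all__ = [
    "TwoDemeConfig",
    "TwoDemeTrajectory",
    "RIEstimate",
    "simulate_two_deme",
    "simulate_demes",
    "effective_migration_rate",
    "ri_two_deme",
    "ri_from_fitness_product",
    "ri_single_linked_locus",
    "ri_two_flanking_loci",
    "expected_class_fitnesses",
    "pool_matrix_me",
    "PoolMatrixResult",
    "UndefinedEstimateError",
]

_DP_FLOOR = 1e-12


class UndefinedEstimateError(RuntimeError):
    """Raised when populations are too homogenized for m_e to be defined."""


@dataclass(frozen=True)
class TwoDemeConfig:
    """Parameters of the two-deme scenario.

    m is the fraction of the recipient deme replaced by source migrants per
    generation.  In unidirectional mode the source deme is held fixed (an
    infinite source); in bidirectional mode both demes exchange migrants at
    rate m and both are iterated.
    """

    m: float
    mode: str = "unidirectional"
    max_generations: int = 20000
    convergence_tol: float = 1e-12
    source_env: str = "source"
    recipient_env: str = "recipient"

    def __post_init__(self):
        if not (0.0 < self.m < 1.0):
            raise ValueError(f"migration rate m={self.m} must lie in (0, 1)")
        if self.mode not in ("unidirectional", "bidirectional"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")


@dataclass
class TwoDemeTrajectory:
    """Per-generation record of neutral-marker gene flow.

    For each neutral marker: p_source / p_recipient at the start of each
    generation, dp (net change in the recipient over the full cycle),
    Dp (source - recipient difference), and the instantaneous
    m_e = dp / Dp (NaN where Dp is below the numeric floor).
    """

    m: float
    markers: list[str]
    generation: np.ndarray
    p_source: dict[str, np.ndarray]
    p_recipient: dict[str, np.ndarray]
    delta_p: dict[str, np.ndarray]          # dp, per-generation change
    Delta_p: dict[str, np.ndarray]          # Dp, between-deme difference
    me_inst: dict[str, np.ndarray]
    equilibrated_generation: int | None     # selected loci converged here
    converged: bool                          # selected loci AND m_e stable
    final_state: np.ndarray = field(repr=False, default=None)

    def to_frame(self):
        import pandas as pd

        rows = []
        for mk in self.markers:
            rows.append(
                pd.DataFrame(
                    {
                        "generation": self.generation,
                        "marker": mk,
                        "p_source": self.p_source[mk],
                        "p_recipient": self.p_recipient[mk],
                        "delta_p": self.delta_p[mk],
                        "Delta_p": self.Delta_p[mk],
                        "me_inst": self.me_inst[mk],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class RIEstimate:
    """RI = 1 - m_e/m for one marker; negative under heterosis/adaptive introgression."""

    marker: str
    m_e: float
    m: float
    ri: float


def _as_freqs(init, architecture, default_hap):
    if init is None:
        f = np.zeros(architecture.n_haplotypes)
        f[default_hap] = 1.0
        return f
    if isinstance(init, HaplotypeDistribution):
        return init.frequencies.copy()
    f = np.asarray(init, dtype=float)
    if f.shape != (architecture.n_haplotypes,):
        raise ValueError("initial state has wrong length")
    return f.copy()


def simulate_demes(
    architecture: GeneticArchitecture,
    scheme: FitnessScheme,
    environments: Sequence[str],
    migration_matrix: np.ndarray,
    init: np.ndarray,
    generations: int,
    fixed_demes: Sequence[int] = (),
    callback=None,
):
    """Generic deterministic n-deme recursion (migration, selection, mating).

    ``migration_matrix[d, j]`` is the fraction of deme d (after migration)
    that originated in deme j; rows must sum to 1.  ``fixed_demes`` are reset
    to their initial state every generation (infinite sources).  ``callback``
    (state, generation) is invoked after every generation; returning True
    stops the run early.
    """
    M = np.asarray(migration_matrix, dtype=float)
    n = len(environments)
    if M.shape != (n, n):
        raise ValueError("migration matrix shape does not match deme count")
    if not np.allclose(M.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("migration matrix rows must sum to 1")
    H = np.asarray(init, dtype=float).copy()
    if H.shape != (n, architecture.n_haplotypes):
        raise ValueError("initial state has wrong shape")
    W = np.ones((n, architecture.n_haplotypes))
    for d, env in enumerate(environments):
        if d in fixed_demes:
            continue  # selection irrelevant: deme is reset each generation
        W[d] = scheme.fitness_vector(env)
    init_rows = {d: H[d].copy() for d in fixed_demes}
    for g in range(1, generations + 1):
        H = M @ H
        Hs = H * W
        norm = Hs.sum(axis=1, keepdims=True)
        if np.any(norm <= 0):
            raise RuntimeError("a deme's mean fitness dropped to zero")
        Hs /= norm
        H = recombine_population(Hs, architecture)
        for d, row in init_rows.items():
            H[d] = row
        if callback is not None and callback(H, g):
            break
    return H


def simulate_two_deme(
    architecture: GeneticArchitecture,
    scheme: FitnessScheme,
    config: TwoDemeConfig,
    init_source=None,
    init_recipient=None,
    min_generations: int = 0,
) -> TwoDemeTrajectory:
    """Deterministic two-deme run recording dp, Dp and instantaneous m_e.

    By default the source deme is fixed for allele 1 at every locus and the
    recipient for allele 0 (secondary-contact initial condition); pass
    explicit initial distributions for non-equilibrium scenarios.

    The run stops once the selected loci have equilibrated (per-generation
    change below ``convergence_tol``) and the instantaneous m_e has
    stabilised, or at ``max_generations`` (flagged, not raised).
    """
    arch = architecture
    nH = arch.n_haplotypes
    src = _as_freqs(init_source, arch, nH - 1)
    rec = _as_freqs(init_recipient, arch, 0)

    neutral = arch.neutral_indices
    if not neutral:
        raise ValueError("architecture needs at least one neutral marker")
    markers = [arch.loci[i].id for i in neutral]
    selected = arch.selected_indices

    m = config.m
    if config.mode == "unidirectional":
        M = np.array([[1.0, 0.0], [m, 1.0 - m]])
        fixed = (0,)
        envs = (config.source_env, config.recipient_env)
    else:
        M = np.array([[1.0 - m, m], [m, 1.0 - m]])
        fixed = ()
        envs = (config.source_env, config.recipient_env)

    H = np.vstack([src, rec])
    W = np.ones((2, nH))
    for d, env in enumerate(envs):
        if d in (set(fixed)):
            continue
        W[d] = scheme.fitness_vector(env)

    gens, ps, pr, dps, Dps = [], [], [], [], []
    sel_change = []
    eq_gen = None
    me_stable_since = None
    g = 0
    while g < config.max_generations:
        g += 1
        marg0 = arch.marginal_allele_frequencies(H)
        # one full life cycle
        Hn = M @ H
        Hs = Hn * W
        norm = Hs.sum(axis=1, keepdims=True)
        if np.any(norm <= 0):
            raise RuntimeError("mean fitness dropped to zero")
        Hs /= norm
        Hn = recombine_population(Hs, arch)
        for d in fixed:
            Hn[d] = H[d]
        marg1 = arch.marginal_allele_frequencies(Hn)

        gens.append(g)
        ps.append(marg0[0, neutral])
        pr.append(marg0[1, neutral])
        dps.append(marg1[1, neutral] - marg0[1, neutral])
        Dps.append(marg0[0, neutral] - marg0[1, neutral])
        if selected:
            sel_change.append(np.max(np.abs(marg1[1, selected] - marg0[1, selected])))
        else:
            sel_change.append(0.0)

        H = Hn

        if eq_gen is None and sel_change[-1] < config.convergence_tol:
            eq_gen = g
        if eq_gen is not None and g > max(eq_gen, min_generations) and len(dps) >= 2:
            me_now = _safe_ratio(dps[-1], Dps[-1])
            me_prev = _safe_ratio(dps[-2], Dps[-2])
            ok = np.all(
                np.abs(me_now - me_prev) <= 1e-10 * np.maximum(np.abs(me_now), 1e-12)
            )
            if ok:
                me_stable_since = me_stable_since or g
                if g - me_stable_since >= 10:
                    break
            else:
                me_stable_since = None

    converged = eq_gen is not None and me_stable_since is not None
    if not converged:
        warnings.warn(
            "two-deme run did not reach a stationary m_e within "
            f"{config.max_generations} generations (non-equilibrium scheme?)",
            RuntimeWarning,
            stacklevel=2,
        )

    gens_a = np.array(gens)
    ps_a = np.array(ps)
    pr_a = np.array(pr)
    dp_a = np.array(dps)
    Dp_a = np.array(Dps)
    me_a = np.where(np.abs(Dp_a) > _DP_FLOOR, dp_a / np.where(Dp_a == 0, 1, Dp_a), np.nan)

    def col(a, j):
        return a[:, j].copy()

    return TwoDemeTrajectory(
        m=m,
        markers=markers,
        generation=gens_a,
        p_source={mk: col(ps_a, j) for j, mk in enumerate(markers)},
        p_recipient={mk: col(pr_a, j) for j, mk in enumerate(markers)},
        delta_p={mk: col(dp_a, j) for j, mk in enumerate(markers)},
        Delta_p={mk: col(Dp_a, j) for j, mk in enumerate(markers)},
        me_inst={mk: col(me_a, j) for j, mk in enumerate(markers)},
        equilibrated_generation=eq_gen,
        converged=converged,
        final_state=H,
    )


def _safe_ratio(dp, Dp):
    dp = np.asarray(dp, dtype=float)
    Dp = np.asarray(Dp, dtype=float)
    return np.where(np.abs(Dp) > _DP_FLOOR, dp / np.where(Dp == 0, 1, Dp), np.nan)


def effective_migration_rate(
    trajectory: TwoDemeTrajectory,
    marker: str | None = None,
    window: tuple[int, int] | None = None,
) -> float:
    """m_e as the slope of dp against Dp through the origin.

    The window defaults to the generations after the selected loci have
    equilibrated; supply an explicit (start, stop) generation window for
    non-equilibrium scenarios.
    """
    if marker is None:
        marker = trajectory.markers[0]
    dp = trajectory.delta_p[marker]
    Dp = trajectory.Delta_p[marker]
    g = trajectory.generation
    if window is not None:
        sel = (g >= window[0]) & (g <= window[1])
    elif trajectory.equilibrated_generation is not None:
        sel = g >= trajectory.equilibrated_generation
    else:
        sel = g >= g[-1] - max(len(g) // 4, 1)
    dp, Dp = dp[sel], Dp[sel]
    denom = float(np.sum(Dp * Dp))
    if denom < _DP_FLOOR**2 or not np.any(np.abs(Dp) > _DP_FLOOR):
        raise UndefinedEstimateError(
            f"Dp for marker {marker!r} is below the numeric floor; "
            "populations are already homogenized"
        )
    return float(np.sum(dp * Dp) / denom)


def ri_two_deme(m_e: float, m: float, marker: str = "") -> RIEstimate:
    """RI = 1 - m_e/m (Eq. RI-2d). Negative when m_e exceeds m."""
    if m <= 0:
        raise ValueError(f"migration rate m={m} must be > 0")
    return RIEstimate(marker=marker, m_e=float(m_e), m=float(m), ri=1.0 - m_e / m)


def ri_from_fitness_product(
    classes: HybridClassFitness | Iterable[float],
    truncation: int | None = None,
) -> float:
    """RI from the hybrid-class fitness product.

    Full form (``truncation=None``): ``1 - W0*W1*W2*...`` over the supplied
    sequence.  For long or infinite sequences the product is truncated once
    ``|1 - Wk| < 1e-9`` for k >= 3, where the residual tail is negligible
    (fitness deficits roughly halve per backcross generation, so the tail
    product is bounded by the last factor squared).

    Truncated form (``truncation=t``): ``1 - W0*...*W_{t-1}*W_t**2``; the
    standard approximation is ``t=2``, i.e. ``1 - W0*W1*W2**2`` (gene influx
    is reduced by the same factor in the first backcross generation as in
    all subsequent ones).
    """
    if isinstance(classes, HybridClassFitness):
        values = list(classes.values)
    else:
        values = list(classes)
    if any(v < 0 for v in values):
        raise ValueError("class fitnesses must be nonnegative")
    if truncation is not None:
        if truncation < 1:
            raise ValueError("truncation must be >= 1")
        if len(values) < truncation + 1:
            raise ValueError(
                f"truncated form with t={truncation} needs at least {truncation + 1} classes"
            )
        prod = float(np.prod(values[:truncation])) * values[truncation] ** 2
        return 1.0 - prod
    prod = 1.0
    for k, w in enumerate(values):
        prod *= w
        if k >= 3 and abs(1.0 - w) < 1e-9:
            break
    return 1.0 - prod


def ri_single_linked_locus(r: float, s: float) -> float:
    """RI for a neutral locus at recombination distance r from one selected
    locus with coefficient s: RI = 1 - r/(s + r).  r = 0 gives 1."""
    if not (0.0 <= r <= 0.5):
        raise ValueError(f"r={r} outside [0, 0.5]")
    if r == 0 and s == 0:
        raise ValueError("RI undefined for r = s = 0")
    if r == 0:
        return 1.0
    return 1.0 - r / (s + r)


def ri_two_flanking_loci(r1: float, s1: float, r2: float, s2: float, s12: float) -> float:
    """RI for a neutral locus flanked by two selected loci.

    RI = 1 - [r1/(r1+s1)] [r2/(r2+s2)] [(r1+r2+s1+s2)/(r1+r2+s12)];
    the last factor equals 1 without epistasis (s12 = s1 + s2).
    """
    for r in (r1, r2):
        if not (0.0 < r <= 0.5):
            raise ValueError(f"flanking recombination fraction {r} must lie in (0, 0.5]")
    d1, d2, d3 = r1 + s1, r2 + s2, r1 + r2 + s12
    if d1 == 0 or d2 == 0 or d3 == 0:
        raise ValueError("zero denominator in two-flanking-locus formula")
    return 1.0 - (r1 / d1) * (r2 / d2) * ((r1 + r2 + s1 + s2) / d3)


def expected_class_fitnesses(
    architecture: GeneticArchitecture,
    scheme: FitnessScheme,
    environment: str = "recipient",
    n_classes: int = 30,
    migrant_haplotype: int | None = None,
) -> HybridClassFitness:
    """Mean fitnesses of migrant, F1 and successive backcross classes.

    Each class's genotype distribution is propagated through selection in
    the recipient environment and then backcrossed to the resident
    haplotype; class k's mean fitness is evaluated before selection,
    relative to residents (= 1).  Valid in the low-migration regime where
    hybrids essentially always backcross to natives.  The ``naive`` field
    holds the selection-free Mendelian expectation for comparison.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    arch = architecture
    nH = arch.n_haplotypes
    mig = nH - 1 if migrant_haplotype is None else migrant_haplotype
    w = scheme.fitness_vector(environment)
    resident = np.zeros(nH)
    resident[0] = 1.0

    def chain(with_selection: bool):
        d = np.zeros(nH)
        d[mig] = 1.0
        vals = []
        for _ in range(n_classes):
            Wk = float(d @ w)
            vals.append(Wk)
            if with_selection:
                if Wk <= 0:
                    vals.extend([0.0] * (n_classes - len(vals)))
                    break
                d = d * w / Wk
            d = recombine_cross(d, resident, arch)
        return np.array(vals)

    return HybridClassFitness(values=chain(True), naive=chain(False))


# ---------------------------------------------------------------------------
# Pool-matrix effective migration for multiple demes
# ---------------------------------------------------------------------------

@dataclass
class PoolMatrixResult:
    """Between-deme effective migration rates from the pool transition matrix.

    ``me[i, j]`` is the effective migration rate from deme i into deme j
    (diagonal NaN).  ``pools`` lists (deme, background) pairs, ``transition``
    the one-generation linear map of neutral-marker frequencies over pools,
    and ``background_frequencies[d, g]`` the equilibrium frequency of
    selected-locus background g in deme d.
    """

    me: np.ndarray
    pools: list[tuple[int, int]]
    transition: np.ndarray
    background_frequencies: np.ndarray
    irreducible: bool


def pool_matrix_me(
    architecture: GeneticArchitecture,
    scheme: FitnessScheme,
    environments: Sequence[str],
    migration_matrix: np.ndarray,
    marker: str | None = None,
    equilibrium_tol: float = 1e-13,
    max_generations: int = 200000,
) -> PoolMatrixResult:
    """Effective migration rates between demes via the pool construction.

    Individuals are split into pools (deme x selected-locus background).
    With the selected backgrounds at their migration-selection equilibrium,
    the per-generation dynamics of a neutral marker's frequency within each
    pool is exactly linear; the transition matrix over pools is built by
    propagating basis vectors through one generation of the full recursion.
    Long-run m_e between each ordered deme pair is then the stationary
    per-generation change in the target deme's marker frequency relative to
    the between-deme difference, starting from a marker localized in the
    source deme.
    """
    arch = architecture
    nH = arch.n_haplotypes
    n = len(environments)
    M = np.asarray(migration_matrix, dtype=float)
    selected = arch.selected_indices
    neutral = arch.neutral_indices
    if not neutral:
        raise ValueError("architecture needs a neutral marker")
    mi = arch.index_of(marker) if marker is not None else neutral[0]

    # 1. equilibrate the selected backgrounds (marker alleles set to 0)
    init = np.zeros((n, nH))
    for d, env in enumerate(environments):
        hap = 0
        for i in selected:
            fav = 1 - arch.loci[i].disfavoured_in(env)
            hap |= fav << i
        init[d, hap] = 1.0

    state = {"H": init, "prev": init.copy(), "eq": False}

    def cb(H, g):
        diff = np.max(np.abs(H - state["prev"]))
        state["prev"] = H.copy()
        if diff < equilibrium_tol:
            state["eq"] = True
            return True
        return False

    F = simulate_demes(arch, scheme, environments, M, init, max_generations, callback=cb)
    if not state["eq"]:
        warnings.warn(
            "selected backgrounds did not fully equilibrate; pool matrix is approximate",
            RuntimeWarning,
            stacklevel=2,
        )

    # backgrounds: haplotype restricted to selected loci
    sel_mask = sum(1 << i for i in selected)
    haps = np.arange(nH)
    bg_of_hap = haps & sel_mask
    backgrounds = sorted(set(int(b) for b in bg_of_hap))
    nb = len(backgrounds)
    bg_index = {b: k for k, b in enumerate(backgrounds)}

    Fbg = np.zeros((n, nb))
    for d in range(n):
        for h in range(nH):
            Fbg[d, bg_index[int(bg_of_hap[h])]] += F[d, h]

    floor = 1e-14
    pools = [(d, b) for d in range(n) for b in backgrounds]
    npools = len(pools)

    W = np.array([scheme.fitness_vector(env) for env in environments])

    def one_generation(H):
        Hn = M @ H
        Hs = Hn * W
        Hs /= Hs.sum(axis=1, keepdims=True)
        return recombine_population(Hs, arch)

    def build_state(q):
        # q: (n, nb) marker frequency per pool -> full haplotype state
        H = np.zeros((n, nH))
        for h in range(nH):
            b = bg_index[int(bg_of_hap[h])]
            base = F[:, (h & ~(1 << mi))] + F[:, (h | (1 << mi))]
            carry = (h >> mi) & 1
            H[:, h] = base * np.where(carry, q[:, b], 1.0 - q[:, b])
        return H

    def pool_freqs(H):
        # marker frequency within each (deme, background) pool
        q = np.zeros((n, nb))
        tot = np.zeros((n, nb))
        for h in range(nH):
            b = bg_index[int(bg_of_hap[h])]
            tot[:, b] += H[:, h]
            if (h >> mi) & 1:
                q[:, b] += H[:, h]
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(tot > floor, q / np.where(tot == 0, 1, tot), 0.0)
        return out, tot

    # 2. transition matrix by basis propagation
    L = np.zeros((npools, npools))
    for k, (d0, b0) in enumerate(pools):
        q = np.zeros((n, nb))
        q[d0, bg_index[b0]] = 1.0
        qn, _ = pool_freqs(one_generation(build_state(q)))
        L[:, k] = qn.reshape(-1)

    # reducibility diagnostic on pools that actually exist
    alive = Fbg.reshape(-1) > floor
    irreducible = _strongly_connected(L[np.ix_(alive, alive)]) if alive.sum() > 1 else True
    if not irreducible:
        warnings.warn(
            "pool transition structure is reducible/absorbing; some m_e entries "
            "may be degenerate",
            RuntimeWarning,
            stacklevel=2,
        )

    # 3. long-run pairwise m_e by aggregation onto the n slowest modes.
    # On the slow timescale the deme means follow
    #   pbar'_j = pbar_j + sum_i me[i, j] (pbar_i - pbar_j),
    # so the reduced n x n one-generation matrix is reconstructed from the
    # n leading eigenpairs of the pool transition matrix expressed in
    # deme-mean coordinates; its off-diagonal entries are the effective
    # migration rates (including multi-generation flow through
    # intermediate demes, which is how an interposed deme filters gene
    # flow between non-adjacent demes).
    wts = Fbg.reshape(-1)
    deme_of_pool = np.repeat(np.arange(n), nb)
    A = np.zeros((n, npools))
    for k in range(npools):
        A[deme_of_pool[k], k] = wts[k]
    eigvals, eigvecs = np.linalg.eig(L)
    order = np.argsort(-np.abs(eigvals))[:n]
    lam = eigvals[order]
    Y = A @ eigvecs[:, order]
    if np.max(np.abs(lam.imag)) > 1e-8 or np.linalg.cond(Y) > 1e10:
        warnings.warn(
            "pool dynamics lack a clean separation into deme-level slow modes; "
            "reduced m_e matrix is approximate",
            RuntimeWarning,
            stacklevel=2,
        )
    M_red = np.real(Y @ np.diag(lam) @ np.linalg.pinv(Y))
    me = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if i != j:
                me[i, j] = M_red[j, i]
    return PoolMatrixResult(
        me=me,
        pools=pools,
        transition=L,
        background_frequencies=Fbg,
        irreducible=irreducible,
    )


def _strongly_connected(A: np.ndarray) -> bool:
    from scipy.sparse.csgraph import connected_components

    if A.size == 0:
        return True
    ncomp, _ = connected_components((A > 1e-300).astype(int), directed=True, connection="strong")
    return ncomp == 1
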
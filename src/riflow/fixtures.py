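"""Synthetic data generators with stored ground truth.

Every generator is deterministic given its seed, and the truth parameters
are returned alongside the data so that estimator-recovery studies can be
run without any external input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .estimators import TransectData, stepped_cline_frequency

__all__ = [
    "FixtureSpec",
    "generate_transect_fixture",
    "generate_fitness_table_fixture",
    "generate_mating_table_fixture",
    "generate_trajectory_fixture",
    "generate_fixture",
]

_TARGETS = ("transect", "fitness_table", "mating_table", "trajectory")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic dataset.

    ``truth`` holds the generating parameters (e.g. center, delta_p,
    b_left/b_right for a transect; w_values for a fitness table; H and C
    for a mating table; m_e, m for a trajectory).  ``noise`` is "binomial"
    (transects only) or "none".  A seed is mandatory whenever noise is
    requested.
    """

    target: str
    truth: Mapping[str, float] = field(default_factory=dict)
    # default transect: dense spatial coverage (201 sites across 200 distance
    # units), reflecting that resolving the central gradient of a stepped
    # cline requires dense sampling around the zone
    n_sites: int = 201
    span: float = 200.0
    n_per_site: int = 100
    noise: str = "none"
    seed: int | None = None

    def __post_init__(self):
        if self.target not in _TARGETS:
            raise ValueError(f"unknown fixture target {self.target!r}")
        if self.noise not in ("none", "binomial"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.noise != "none" and self.seed is None:
            raise ValueError("a seed is mandatory when noise is requested")


def generate_transect_fixture(spec: FixtureSpec) -> tuple[TransectData, dict]:
    """Allele-frequency transect from the stepped-cline model.

    Sites are evenly spaced over ``span`` centred on the true cline center.
    Under binomial noise the counts are k ~ Binomial(n, p_model(x)); under
    noise "none" the expected counts k = n * p are returned so that k/n
    reproduces the model frequency exactly.
    """
    truth = dict(spec.truth)
    center = truth.setdefault("center", 0.0)
    delta_p = truth.setdefault("delta_p", 0.3)
    b_left = truth.setdefault("b_left", 40.0)
    b_right = truth.setdefault("b_right", b_left)
    p_left = truth.setdefault("p_left", (1.0 - delta_p) / 2.0)
    p_right = truth.setdefault("p_right", 1.0 - delta_p - p_left)
    theta_left = delta_p / (b_left * p_left)
    theta_right = delta_p / (b_right * p_right)
    truth["theta_left"], truth["theta_right"] = theta_left, theta_right

    x = center + np.linspace(-spec.span / 2, spec.span / 2, spec.n_sites)
    p = stepped_cline_frequency(x, center, p_left, theta_left, p_right, theta_right)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("truth parameters produce frequencies outside [0, 1]")
    n = np.full(spec.n_sites, spec.n_per_site, dtype=int)
    if spec.noise == "binomial":
        rng = np.random.default_rng(spec.seed)
        k = rng.binomial(n, p).astype(float)
    else:
        k = n * p  # expected counts: k/n equals the model frequency exactly
    return TransectData(x, n, k), truth


def generate_fitness_table_fixture(spec: FixtureSpec) -> tuple[pd.DataFrame, dict]:
    """Hybrid-class mean-fitness table (class index, W value)."""
    truth = dict(spec.truth)
    w = np.asarray(truth.get("w_values", [1.0, 1.0, 1.0]), dtype=float)
    if np.any(w < 0):
        raise ValueError("class fitnesses must be nonnegative")
    df = pd.DataFrame({"class": np.arange(len(w)), "value": w})
    truth["w_values"] = list(map(float, w))
    return df, truth


def generate_mating_table_fixture(spec: FixtureSpec) -> tuple[pd.DataFrame, dict]:
    """Heterospecific/conspecific mating-count table."""
    truth = dict(spec.truth)
    H = float(truth.setdefault("H", 1.0))
    C = float(truth.setdefault("C", 4.0))
    df = pd.DataFrame({"class": ["heterospecific", "conspecific"], "value": [H, C]})
    return df, truth


def generate_trajectory_fixture(spec: FixtureSpec) -> tuple[pd.DataFrame, dict]:
    """Synthetic (Dp, dp) trajectory with dp = m_e * Dp exactly."""
    truth = dict(spec.truth)
    m_e = float(truth.setdefault("m_e", 0.003))
    m = float(truth.setdefault("m", 0.01))
    n_points = int(truth.setdefault("n_points", 50))
    Dp0 = float(truth.setdefault("Dp0", 1.0))
    g = np.arange(1, n_points + 1)
    Dp = Dp0 * (1.0 - m_e) ** (g - 1)
    dp = m_e * Dp
    df = pd.DataFrame(
        {
            "generation": g,
            "marker": "neu",
            "p_source": 1.0,
            "p_recipient": 1.0 - Dp,
            "delta_p": dp,
            "Delta_p": Dp,
            "me_inst": m_e,
        }
    )
    return df, truth


def generate_fixture(spec: FixtureSpec):
    """Dispatch on the fixture target."""
    return {
        "transect": generate_transect_fixture,
        "fitness_table": generate_fitness_table_fixture,
        "mating_table": generate_mating_table_fixture,
        "trajectory": generate_trajectory_fixture,
    }[spec.target](spec)
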
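"""Model extensions: APC coupling, growth-rate switching, TCR-affinity
exponents and the multiset peptide-presentation probability.

The presentation model counts order-free combinations with repetition of
peptides across HLA slots — C(n+k-1, k) multisets — and the probability of
an all-non-alloreactive presentation is the ratio of two such counts,
evaluated in exact integer arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Sequence

import numpy as np

from allosim.expression import OrganOperator
from allosim.simulator import (
    EXP_ARG_LIMIT,
    OrganSimulation,
    SimulationConfig,
    logistic_step,
    run_organ,
)

DEFAULT_K_APC = 1e4
DEFAULT_R_APC = 1.0


@dataclass(frozen=True)
class APCState:
    """Antigen-presenting-cell population at one iteration and its
    presentation-effect value v = (1 - (n/k)^t) + 1 in (0, 2]."""

    t: int
    n_apc: float
    k_apc: float

    @property
    def v_apc(self) -> float:
        return apc_effect(self.n_apc, self.k_apc, self.t)


@dataclass(frozen=True)
class PresentationScenario:
    """n_total distinct peptides, n_allo of them alloreactive, presented
    across k_slots HLA slots (repetition allowed, order ignored)."""

    n_total: int
    n_allo: int
    k_slots: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_allo <= self.n_total):
            raise ValueError(f"need 0 <= n_allo <= n_total, got {self}")
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if self.k_slots < 1:
            raise ValueError("k_slots must be >= 1")


def apc_effect(n_apc: float, k_apc: float, t: int) -> float:
    """Presentation amplification from APC growth: (1 - (n/k)^t) + 1.

    Equals 2 in the n/k -> 0 limit (reaction onset) and 1 at n = k
    (homeostatic persistence without antigen presentation).
    """
    if k_apc <= 0:
        raise ValueError(f"k_apc must be positive, got {k_apc}")
    if not (0 <= n_apc <= k_apc):
        raise ValueError(f"n_apc must lie in [0, k_apc], got {n_apc}")
    if t < 1:
        raise ValueError(f"t must be >= 1, got {t}")
    return (1.0 - (n_apc / k_apc) ** t) + 1.0


def apc_trajectory(
    iterations: int,
    *,
    k_apc: float = DEFAULT_K_APC,
    r_apc: float = DEFAULT_R_APC,
    n0: float = 1.0,
) -> list[APCState]:
    """Logistic APC growth (same map as the T cell engine) with its own
    carrying capacity and rate; one state per iteration t = 1..iterations."""
    states: list[APCState] = []
    n = n0
    for t in range(1, iterations + 1):
        n = min(logistic_step(n, n0, k_apc, r_apc, t), k_apc)
        states.append(APCState(t=t, n_apc=n, k_apc=k_apc))
    return states


def couple_apc(
    trajectory: Sequence[float],
    apc_states: Sequence[APCState] | Sequence[float],
    cos_theta: float = 1.0,
) -> np.ndarray:
    """Elementwise product of a clone trajectory with the APC effect vector.

    The T cell and APC vectors share antigen specificity, so the angle
    between them is 0 (cos = 1). With logistic APC growth the product shows
    a crescendo-decrescendo: amplified early (v near 2), converging to the
    uncoupled steady state as v -> 1.
    """
    if len(trajectory) != len(apc_states):
        raise ValueError(
            f"length mismatch: trajectory {len(trajectory)} vs APC {len(apc_states)}"
        )
    v = np.array(
        [s.v_apc if isinstance(s, APCState) else float(s) for s in apc_states]
    )
    return np.asarray(trajectory, dtype=float) * v * cos_theta


def treg_switch(
    operator: OrganOperator,
    cfg: SimulationConfig,
    switch_iteration: int,
    new_r: float,
    *,
    keep_trajectories: bool = True,
) -> OrganSimulation:
    """Simulate with the growth rate switched mid-run.

    Iterations before ``switch_iteration`` use ``cfg.r``; from the switch
    onward ``new_r`` applies. A sign-reversed ``new_r`` (regulatory,
    anti-inflammatory milieu) collapses the population from its pre-switch
    level; a same-sign smaller ``new_r`` slows growth.
    """
    if not (1 <= switch_iteration <= cfg.iterations):
        raise ValueError(
            f"switch_iteration {switch_iteration} outside [1, {cfg.iterations}]"
        )
    sign = -1.0 if cfg.flip_r_sign else 1.0

    def schedule(t: int) -> float:
        return sign * (cfg.r if t < switch_iteration else new_r)

    return run_organ(
        operator, cfg, keep_trajectories=keep_trajectories, r_schedule=schedule
    )


def tcr_adjusted_capacity(
    pexp: float, k: float, ic50_mha: float, ic50_tcr: float
) -> float:
    """Carrying capacity with the TCR affinity as an exponent multiplier:
    (pexp*k)^((1/ic50_mha) * (1/ic50_tcr)).

    With ic50_tcr = 1 nM (the working assumption) this reduces to the base
    affinity-exponent capacity.
    """
    if not (ic50_mha > 0 and ic50_tcr > 0):
        raise ValueError("both IC50 values must be positive")
    if pexp < 0 or not (k > 0):
        raise ValueError("require pexp >= 0 and k > 0")
    if pexp == 0:
        return 0.0
    exponent = (1.0 / ic50_mha) * (1.0 / ic50_tcr)
    arg = exponent * np.log(pexp * k)
    return float(np.exp(np.clip(arg, -EXP_ARG_LIMIT, EXP_ARG_LIMIT)))


def presentation_combinations(n_peptides: int, k_slots: int) -> int:
    """Multisets of size k from n distinct peptides: C(n + k - 1, k)."""
    if n_peptides < 0 or k_slots < 0:
        raise ValueError("counts must be non-negative")
    return comb(n_peptides + k_slots - 1, k_slots)


def presentation_probability(s: PresentationScenario) -> float:
    """Probability that a uniformly chosen peptide multiset contains no
    alloreactive peptide.

    Exact rational ratio of combinations-with-repetition counts,
    C(n - n_allo + k - 1, k) / C(n + k - 1, k), returned as a float.
    Equals 0 when every peptide is alloreactive and 1 when none is.
    """
    favorable = presentation_combinations(s.n_total - s.n_allo, s.k_slots)
    total = presentation_combinations(s.n_total, s.k_slots)
    return float(Fraction(favorable, total))
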
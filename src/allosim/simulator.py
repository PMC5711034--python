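"""Iterated vector-operator dynamical system for clonal T cell growth.

Each clone responding to a peptide-HLA target grows by an iterated logistic
map whose carrying capacity is exponentiated by binding affinity
(af = 1/IC50) and multiplied by tissue expression:

    N_t = K_eff * N0 / ((K_eff - S_{t-1}) * exp(-r * t * af) + 1)

where K_eff = (Pexp * K)^af and S_{t-1} is either the clone's own previous
size (competition off) or the alpha-weighted sum of all clones' previous
sizes (Lotka-Volterra competition), with alpha(x, i) = IC50_x / IC50_i.

The sign convention is the one that makes r = +1.5 produce sigmoid growth
toward K_eff; ``flip_r_sign`` reverses it for sensitivity analysis.
Negative denominators (early competition transients) clamp the clone to 0;
it may regrow later because N0 re-enters the numerator each step. The core
is deterministic: no randomness anywhere.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

from allosim.expression import OrganOperator

logger = logging.getLogger(__name__)

EXP_ARG_LIMIT = 700.0  # |argument| cap: exp(709) overflows a double


@dataclass(frozen=True)
class SimulationConfig:
    """All model constants for one simulation run."""

    n0: float = 1.0
    k: float = 1e6
    r: float = 1.5
    iterations: int = 500
    averaging_window: tuple[int, int] = (401, 500)
    competition: bool = True
    include_self: bool = True  # test clone enters its own competition sum (alpha=1)
    flip_r_sign: bool = False  # exponent becomes exp(+r*t*af)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n0 < 1:
            raise ValueError(f"n0 must be >= 1, got {self.n0}")
        if not (self.k > self.n0):
            raise ValueError(f"k must exceed n0, got k={self.k}, n0={self.n0}")
        lo, hi = self.averaging_window
        if not (1 <= lo <= hi <= self.iterations):
            raise ValueError(
                f"averaging_window {self.averaging_window} not within [1, {self.iterations}]"
            )

    @property
    def effective_r(self) -> float:
        return -self.r if self.flip_r_sign else self.r


@dataclass
class CloneState:
    """One clone's parameters and (optionally retained) trajectory."""

    clone_id: int
    sequence: str
    hla_allele: str
    ic50_nm: float
    pexp: float
    k_eff: float
    window_mean: float = 0.0
    trajectory: Optional[np.ndarray] = None  # N_t for t = 0..iterations

    @property
    def af(self) -> float:
        return 1.0 / self.ic50_nm


class CompetitionWeights:
    """Pairwise interaction weights alpha(x, i) = IC50_x / IC50_i.

    With clones sorted by ascending IC50 the matrix has 1 on the diagonal,
    values < 1 above it and > 1 below it: clones recognizing high-affinity
    (low-IC50) targets disproportionately suppress low-affinity clones.
    """

    def __init__(self, ic50_nm: Sequence[float]):
        self._ic50 = np.asarray(ic50_nm, dtype=float)
        if np.any(self._ic50 <= 0):
            raise ValueError("all IC50 values must be positive")

    def alpha(self, x: int, i: int) -> float:
        return float(self._ic50[x] / self._ic50[i])

    def matrix(self) -> np.ndarray:
        return self._ic50[:, None] / self._ic50[None, :]

    def __len__(self) -> int:
        return len(self._ic50)


@dataclass
class OrganSimulation:
    """Per-organ result: clone states plus the window-averaged total count."""

    tissue: str
    clone_states: list[CloneState]
    organ_count: float
    n_clones_active: int


@dataclass
class DrpSimulation:
    """Whole donor-recipient-pair result across organs."""

    organ_simulations: dict[str, OrganSimulation]
    organ_counts: dict[str, float]
    total: float


def logistic_step(n_prev: float, n0: float, k: float, r: float, t: int) -> float:
    """One iteration of the base logistic map.

    N_t = k*n0 / ((k - n_prev)*exp(-r*t) + 1), clamped to [0, inf);
    overflow in the exponential is guarded.
    """
    if not (k > 0):
        raise ValueError(f"k must be positive, got {k}")
    if t < 1:
        raise ValueError(f"t must be >= 1, got {t}")
    arg = max(-EXP_ARG_LIMIT, min(EXP_ARG_LIMIT, -r * t))
    denom = (k - n_prev) * math.exp(arg) + 1.0
    if denom <= 0 or not math.isfinite(denom):
        return 0.0
    n_t = k * n0 / denom
    return max(0.0, n_t)


def clone_capacity(pexp: float, k: float, ic50_nm: float) -> float:
    """Affinity-exponent carrying capacity: (pexp*k)^(1/ic50).

    Values below 1 (weakly expressed gene, very weak binder) are allowed
    and logged.
    """
    if pexp < 0 or not (k > 0) or not (ic50_nm > 0):
        raise ValueError("require pexp >= 0, k > 0, ic50 > 0")
    if pexp == 0:
        return 0.0
    k_eff = (pexp * k) ** (1.0 / ic50_nm)
    if k_eff < 1.0:
        logger.debug("clone_capacity below 1 (pexp=%g, k=%g, ic50=%g)", pexp, k, ic50_nm)
    return k_eff


def clone_step(
    x: int,
    n_prev: Sequence[float],
    k_eff: Sequence[float],
    af: Sequence[float],
    weights: CompetitionWeights,
    cfg: SimulationConfig,
    t: int,
) -> float:
    """Scalar step for clone ``x`` given all clones' previous sizes.

    With competition on, the previous-size term is the alpha-weighted sum
    over clones (including ``x`` itself when ``cfg.include_self``); with
    competition off it reduces to clone x's own previous size. The result
    is clamped at 0 when the denominator goes non-positive.
    """
    if cfg.competition:
        s = 0.0
        for i in range(len(n_prev)):
            if i == x and not cfg.include_self:
                continue
            s += n_prev[i] * weights.alpha(x, i)
    else:
        s = n_prev[x]
    r = cfg.effective_r
    arg = max(-EXP_ARG_LIMIT, min(EXP_ARG_LIMIT, -r * t * af[x]))
    denom = (k_eff[x] - s) * math.exp(arg) + 1.0
    if denom <= 0 or not math.isfinite(denom):
        return 0.0
    return max(0.0, k_eff[x] * cfg.n0 / denom)


def _step_all(
    n_prev: np.ndarray,
    ic50: np.ndarray,
    af: np.ndarray,
    k_eff: np.ndarray,
    cfg: SimulationConfig,
    t: int,
    r_t: float,
) -> np.ndarray:
    """Vectorized step over all clones of one organ.

    Exploits alpha(x, i) = ic50_x / ic50_i to reduce the weighted sum to
    ic50_x * sum_i(N_i / ic50_i): O(n) per iteration instead of O(n^2).
    """
    with np.errstate(over="ignore", invalid="ignore"):
        if cfg.competition:
            s = ic50 * np.sum(n_prev / ic50)
            if not cfg.include_self:
                s = s - n_prev  # drop the self term (alpha(x,x) = 1)
        else:
            s = n_prev
        arg = np.clip(-r_t * t * af, -EXP_ARG_LIMIT, EXP_ARG_LIMIT)
        denom = (k_eff - s) * np.exp(arg) + 1.0
        n_t = k_eff * cfg.n0 / denom
    n_t = np.where((denom > 0) & np.isfinite(n_t), n_t, 0.0)
    return np.maximum(n_t, 0.0)


def run_organ(
    operator: OrganOperator,
    cfg: SimulationConfig,
    *,
    keep_trajectories: bool = True,
    r_schedule: Optional[Callable[[int], float]] = None,
) -> OrganSimulation:
    """Iterate every clone of one organ operator for ``cfg.iterations``.

    All clones start at N_0 = n0 (t counts globally from 1). The organ
    count is the sum over clones of the mean size across the averaging
    window. ``r_schedule`` optionally overrides r per iteration (used by
    the regulatory-switch extension). Deterministic given inputs.
    """
    n = len(operator.entries)
    if n == 0:
        logger.warning("run_organ[%s]: empty operator, organ_count = 0", operator.tissue)
        return OrganSimulation(operator.tissue, [], 0.0, 0)

    ic50 = np.array([p.ic50_nm for p, _ in operator.entries])
    pexp = np.array([x for _, x in operator.entries])
    af = 1.0 / ic50
    with np.errstate(over="ignore"):
        k_eff = np.exp(np.clip(af * np.log(pexp * cfg.k), -EXP_ARG_LIMIT, EXP_ARG_LIMIT))

    lo, hi = cfg.averaging_window
    n_curr = np.full(n, cfg.n0, dtype=float)
    window_sum = np.zeros(n)
    traj = np.empty((cfg.iterations + 1, n)) if keep_trajectories else None
    if traj is not None:
        traj[0] = n_curr

    for t in range(1, cfg.iterations + 1):
        r_t = r_schedule(t) if r_schedule is not None else cfg.effective_r
        n_curr = _step_all(n_curr, ic50, af, k_eff, cfg, t, r_t)
        if traj is not None:
            traj[t] = n_curr
        if lo <= t <= hi:
            window_sum += n_curr

    window_mean = window_sum / (hi - lo + 1)
    clone_states = [
        CloneState(
            clone_id=i,
            sequence=operator.entries[i][0].sequence,
            hla_allele=operator.entries[i][0].hla_allele,
            ic50_nm=float(ic50[i]),
            pexp=float(pexp[i]),
            k_eff=float(k_eff[i]),
            window_mean=float(window_mean[i]),
            trajectory=traj[:, i].copy() if traj is not None else None,
        )
        for i in range(n)
    ]
    return OrganSimulation(
        tissue=operator.tissue,
        clone_states=clone_states,
        organ_count=float(window_sum.sum() / (hi - lo + 1)),
        n_clones_active=int(np.sum(window_mean > 0)),
    )


def run_drp(
    operators: dict[str, OrganOperator],
    cfg: SimulationConfig,
    *,
    keep_trajectories: bool = False,
) -> DrpSimulation:
    """Simulate every organ operator and sum organ counts into the total."""
    sims = {
        tissue: run_organ(op, cfg, keep_trajectories=keep_trajectories)
        for tissue, op in operators.items()
    }
    counts = {tissue: sim.organ_count for tissue, sim in sims.items()}
    return DrpSimulation(
        organ_simulations=sims,
        organ_counts=counts,
        total=float(sum(counts.values())),
    )


def power_law_diagnostic(clone_sizes: Sequence[float]) -> tuple[float, float]:
    """Rank-frequency power-law fit of a clone-size repertoire.

    Ordinary least squares of log10(size) on log10(rank) over the positive
    sizes sorted descending. Returns (slope, r_squared). Requires at least
    10 positive sizes.
    """
    sizes = np.asarray([s for s in clone_sizes if s > 0], dtype=float)
    if len(sizes) < 10:
        raise ValueError(f"need >= 10 positive clone sizes, got {len(sizes)}")
    sizes = np.sort(sizes)[::-1]
    ranks = np.arange(1, len(sizes) + 1, dtype=float)
    log_sizes = np.log10(sizes)
    if np.allclose(log_sizes, log_sizes[0]):
        return 0.0, 0.0
    fit = stats.linregress(np.log10(ranks), log_sizes)
    return float(fit.slope), float(fit.rvalue**2)
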
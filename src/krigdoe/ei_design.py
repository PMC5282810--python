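"""Expected Improvement and MCMC-based batch experiment proposal.

New experiments are drawn with probability proportional to their Expected
Improvement using a Delayed-Rejection Adaptive-Metropolis (DRAM) chain over
the factor box: Gaussian random-walk proposals, covariance adaptation from
the chain history, and a single delayed-rejection stage with a shrunk
proposal after a first rejection. Compositions with zero EI (or outside the
box) are never accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.stats import norm

from .designs import DesignMatrix, Factor, FactorSpace
from .effects import ObservationSet
from .kriging import KrigingModel, Prediction

__all__ = [
    "EIResult",
    "MCMCConfig",
    "EIChain",
    "expected_improvement",
    "incumbent",
    "dram_sample",
    "sample_proportional",
    "select_batch",
    "uniform_space_filling",
]


@dataclass
class EIResult:
    """Expected improvement of a predictive distribution over the incumbent."""

    ei: np.ndarray | float
    z: np.ndarray | float
    f_best: float
    x: np.ndarray | None = None


def expected_improvement(pred: Prediction | tuple, f_best: float) -> EIResult:
    """Closed-form EI under a normal predictive distribution (maximization).

    For s > 0: ``EI = (mu - f_best) * Phi(z) + s * phi(z)`` with
    ``z = (mu - f_best) / s``; for s = 0 the improvement is deterministic,
    ``EI = max(mu - f_best, 0)``.
    """
    if isinstance(pred, Prediction):
        mu, s = np.asarray(pred.mean, float), np.asarray(pred.sd, float)
    else:
        mu, s = np.asarray(pred[0], float), np.asarray(pred[1], float)
    if np.any(s < 0):
        raise ValueError("predictive standard deviation must be >= 0")
    scalar = mu.ndim == 0
    mu, s = np.atleast_1d(mu), np.atleast_1d(s)
    imp = mu - f_best
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(s > 0, imp / np.where(s > 0, s, 1.0), np.where(imp > 0, np.inf, -np.inf))
    ei = np.where(s > 0, imp * norm.cdf(z) + s * norm.pdf(z), np.maximum(imp, 0.0))
    ei = np.maximum(ei, 0.0)  # guard tiny negative round-off
    if scalar:
        return EIResult(float(ei[0]), float(z[0]), float(f_best))
    return EIResult(ei, z, float(f_best))


def incumbent(model: KrigingModel, obs: ObservationSet) -> float:
    """Noise-robust incumbent: max Kriging mean over the observed inputs."""
    if len(obs) == 0:
        raise ValueError("incumbent requires at least one observation")
    X = obs.inputs(model.factor_names)
    X = np.unique(np.round(X, 12), axis=0)
    return float(np.max(model.predict(X).mean))


@dataclass
class MCMCConfig:
    """DRAM sampler settings (chain length and burn-in follow the campaign
    defaults of 10,000 draws with the first 1,000 discarded)."""

    chain_length: int = 10_000
    burn_in: int = 1_000
    scale_fraction: float = 0.1      # initial proposal SD as fraction of box range
    adapt_start: int = 200
    adapt_interval: int = 1
    dr_shrink: float = 0.2           # delayed-rejection proposal shrink factor
    seed: int = 0
    cov_reg: float = 1e-10

    def __post_init__(self):
        if not 0 <= self.burn_in < self.chain_length:
            raise ValueError("need 0 <= burn_in < chain_length")
        if self.scale_fraction <= 0 or self.dr_shrink <= 0:
            raise ValueError("scales must be positive")


@dataclass
class EIChain:
    """Post-burn-in MCMC states with their target values."""

    states: np.ndarray            # (n, d) natural units
    values: np.ndarray            # target (EI) value per state
    acceptance_rate: float
    lower: np.ndarray
    upper: np.ndarray
    factor_names: tuple[str, ...]
    config: MCMCConfig

    def __len__(self) -> int:
        return len(self.states)


def _log_mvn(dx: np.ndarray, L: np.ndarray) -> float:
    """log N(dx; 0, L L') up to the shared normalization constant."""
    z = linalg.solve_triangular(L, dx, lower=True)
    return -0.5 * float(z @ z) - float(np.sum(np.log(np.diag(L))))


def sample_proportional(fn, lower, upper, cfg: MCMCConfig, x0=None,
                        factor_names=None) -> EIChain:
    """DRAM chain targeting a density proportional to ``fn`` on a box.

    ``fn`` maps a composition (1-D array) to a non-negative target value;
    proposals falling outside the box or onto ``fn(x) = 0`` are always
    rejected. Fully reproducible from ``cfg.seed``.
    """
    lower = np.asarray(lower, dtype=float).ravel()
    upper = np.asarray(upper, dtype=float).ravel()
    d = len(lower)
    rng = np.random.default_rng(cfg.seed)

    def log_target(x):
        if np.any(x < lower) or np.any(x > upper):
            return -np.inf
        v = float(fn(x))
        return np.log(v) if v > 0 else -np.inf

    if x0 is None:
        x0 = (lower + upper) / 2.0
    x = np.asarray(x0, dtype=float).copy()
    lt_x = log_target(x)
    if not np.isfinite(lt_x):
        raise ValueError("initial state has zero target density")

    scales = cfg.scale_fraction * (upper - lower)
    L = np.diag(scales)
    sd = 2.38 ** 2 / d
    mean = np.zeros(d)
    M2 = np.zeros((d, d))
    count = 0

    states = np.empty((cfg.chain_length, d))
    values = np.empty(cfg.chain_length)
    accepted = 0

    for it in range(cfg.chain_length):
        z = rng.standard_normal(d)
        y1 = x + L @ z
        lt_y1 = log_target(y1)
        log_a1 = min(0.0, lt_y1 - lt_x)
        if np.log(rng.uniform()) < log_a1:
            x, lt_x = y1, lt_y1
            accepted += 1
        elif log_a1 < 0.0:
            # delayed rejection: shrunk second-stage proposal
            y2 = x + cfg.dr_shrink * (L @ rng.standard_normal(d))
            lt_y2 = log_target(y2)
            if np.isfinite(lt_y2):
                log_a1_rev = min(0.0, lt_y1 - lt_y2)
                num = lt_y2 + _log_mvn(y1 - y2, L) + _log1m_exp(log_a1_rev)
                den = lt_x + _log_mvn(y1 - x, L) + _log1m_exp(log_a1)
                if np.log(rng.uniform()) < num - den:
                    x, lt_x = y2, lt_y2
                    accepted += 1
        states[it] = x
        values[it] = np.exp(lt_x)

        # running covariance adaptation
        count += 1
        delta = x - mean
        mean = mean + delta / count
        M2 = M2 + np.outer(delta, x - mean)
        if count > cfg.adapt_start and (it % cfg.adapt_interval == 0) and count > d + 1:
            cov = sd * M2 / (count - 1) + cfg.cov_reg * np.eye(d)
            try:
                L = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                pass  # keep previous proposal

    names = tuple(factor_names) if factor_names is not None else tuple(f"x{i}" for i in range(d))
    return EIChain(states[cfg.burn_in:], values[cfg.burn_in:],
                   accepted / cfg.chain_length, lower, upper, names, cfg)


def _log1m_exp(log_a: float) -> float:
    """log(1 - exp(log_a)) for log_a <= 0."""
    if log_a >= 0.0:
        return -np.inf
    return float(np.log1p(-np.exp(log_a)))


def dram_sample(model: KrigingModel, f_best: float, space: FactorSpace | tuple,
                cfg: MCMCConfig | None = None, coarse_resolution: int = 5) -> EIChain:
    """Sample compositions with probability proportional to EI(x).

    The EI landscape is first probed on a coarse grid; a flat-zero landscape
    aborts with advice to maximize the predictive mean directly. The chain is
    started at the best coarse-grid state.
    """
    cfg = cfg or MCMCConfig()
    if isinstance(space, FactorSpace):
        lower, upper, names = space.lower, space.upper, tuple(space.names)
    else:
        lower, upper = np.asarray(space[0], float), np.asarray(space[1], float)
        names = tuple(model.factor_names)
    d = len(lower)

    def ei_fn(x):
        pred = model.predict(np.atleast_2d(x))
        return float(expected_improvement((pred.mean, pred.sd), f_best).ei[0])

    # coarse grid scan for a viable starting state
    if coarse_resolution ** d <= 20000:
        grids = [np.linspace(lower[i], upper[i], coarse_resolution) for i in range(d)]
        mesh = np.meshgrid(*grids, indexing="ij")
        Q = np.column_stack([m.ravel() for m in mesh])
    else:
        rng = np.random.default_rng(cfg.seed)
        Q = rng.uniform(lower, upper, size=(4096, d))
    pred = model.predict(Q)
    ei = expected_improvement((pred.mean, pred.sd), f_best).ei
    scale = max(abs(f_best), float(np.max(pred.sd)), 1e-30)
    if float(np.max(ei)) <= 1e-12 * scale:
        raise ValueError(
            "EI is (numerically) zero everywhere on the box; the surrogate sees no "
            "room for improvement -- maximize the predictive mean directly instead"
        )
    x0 = Q[int(np.argmax(ei))]
    chain = sample_proportional(ei_fn, lower, upper, cfg, x0=x0, factor_names=names)
    if not 0.05 < chain.acceptance_rate < 0.8:
        warnings.warn(f"DRAM acceptance rate {chain.acceptance_rate:.3f} outside (0.05, 0.8)",
                      RuntimeWarning, stacklevel=2)
    return chain


def select_batch(chain: EIChain, n_batch: int, min_separation: float = 0.0,
                 round_id: int = 4) -> DesignMatrix:
    """Distill a batch of distinct proposals from a chain.

    Farthest-point subsampling in coded coordinates, seeded at the
    maximum-EI state; pairwise separation >= ``min_separation`` is enforced
    where feasible (a warning is emitted otherwise).
    """
    states, values = chain.states, chain.values
    keep = values > 0
    states, values = states[keep], values[keep]
    if len(states) == 0:
        raise ValueError("chain contains no states with positive EI")
    uniq, idx = np.unique(np.round(states, 12), axis=0, return_index=True)
    states, values = states[np.sort(idx)], values[np.sort(idx)]
    if n_batch > len(states):
        raise ValueError(f"requested {n_batch} proposals but chain holds only "
                         f"{len(states)} distinct positive-EI states")

    span = chain.upper - chain.lower
    coded = 2.0 * (states - chain.lower) / span - 1.0
    chosen = [int(np.argmax(values))]
    mind = np.linalg.norm(coded - coded[chosen[0]], axis=1)
    for _ in range(n_batch - 1):
        nxt = int(np.argmax(mind))
        if mind[nxt] <= 0:
            raise ValueError("chain collapsed onto fewer distinct states than requested")
        if mind[nxt] < min_separation:
            warnings.warn(f"minimum separation {min_separation} not attainable; "
                          f"closest pair at {mind[nxt]:.4g}", RuntimeWarning, stacklevel=2)
        chosen.append(nxt)
        mind = np.minimum(mind, np.linalg.norm(coded - coded[nxt], axis=1))

    space = FactorSpace([Factor(n, float(lo), float(hi)) for n, lo, hi
                         in zip(chain.factor_names, chain.lower, chain.upper)],
                        require_reference_inside=False)
    return DesignMatrix.from_natural(space, states[chosen], "ei_proposed", round_id,
                                     meta={"generator": "ei_batch", "n_batch": n_batch})


def uniform_space_filling(space: FactorSpace, n: int, seed: int = 0,
                          round_id: int = 4, start_index: int = 1) -> DesignMatrix:
    """Seeded uniform draws over the factor box (exploration filler runs)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    natural = rng.uniform(space.lower, space.upper, size=(n, space.k))
    return DesignMatrix.from_natural(space, natural, "random_uniform", round_id,
                                     meta={"generator": "uniform_space_filling", "seed": seed},
                                     start_index=start_index)
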
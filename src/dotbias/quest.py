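"""Bayesian adaptive probe placement (QUEST) for 2AFC numerosity trials.

The engine maintains a discretized posterior over the point of subjective
equality (PSE) of the current block.  The likelihood of a response is a
cumulative Gaussian in linear numerosity centred on each candidate PSE
(criterion level 0.5 — "PSE mode" with guess rate 0), with a small lapse
floor.  After every trial the posterior mean, perturbed by Gaussian jitter
of 0.5 dots, becomes the next probe numerosity, which concentrates probes
around the PSE and roughly balances "probe more" and "probe fewer"
responses over a block.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import ndtr, logsumexp

__all__ = [
    "QuestState",
    "QuestConfig",
    "PerturbationConfig",
    "init_quest",
    "quest_update",
    "next_probe",
    "posterior_mean",
    "posterior_sd",
]

#: Phi^-1(0.75): converts a Gaussian SD into a JND and back.
PROBIT_75 = 0.6744897501960817


@dataclass(frozen=True)
class PerturbationConfig:
    """Jitter applied to the running PSE estimate before it is used as the
    next probe.  ``sd`` is in dots (0.5 by default, at every numerosity);
    ``sd_fraction``, if set, overrides it with ``sd_fraction * reference``
    for blocks where a fixed 0.5-dot jitter would span almost nothing."""

    sd: float = 0.5
    min_probe: int = 2
    sd_fraction: float | None = None

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.min_probe < 1:
            raise ValueError("min_probe must be >= 1")

    def effective_sd(self, reference_n: float | None = None) -> float:
        if self.sd_fraction is not None and reference_n is not None:
            return self.sd_fraction * reference_n
        return self.sd


@dataclass(frozen=True)
class QuestConfig:
    """Hyperparameters for per-block engine initialisation.

    The prior over the PSE is a Gaussian centred on the reference
    numerosity with SD ``prior_sd_fraction * reference``.  The assumed
    psychometric spread is ``assumed_weber * reference`` (the same
    coefficient-of-variation convention used by the synthetic observers).
    """

    prior_sd_fraction: float = 0.4
    assumed_weber: float = 0.25
    lapse: float = 0.02
    n_grid: int = 301
    grid_span_sd: float = 4.0
    grid_min: float = 1.0

    def sigma_for(self, reference_n: float) -> float:
        return self.assumed_weber * reference_n

    def init_for(self, reference_n: float) -> "QuestState":
        prior_sd = self.prior_sd_fraction * reference_n
        return init_quest(
            prior_mean=reference_n,
            prior_sd=prior_sd,
            sigma=self.sigma_for(reference_n),
            lapse=self.lapse,
            n_grid=self.n_grid,
            grid_span_sd=self.grid_span_sd,
            grid_min=self.grid_min,
        )


@dataclass(frozen=True)
class QuestState:
    """Discretized posterior over the PSE."""

    grid: np.ndarray
    log_posterior: np.ndarray
    sigma: float                 # assumed psychometric SD (linear dots)
    lapse: float = 0.02
    response_count: int = 0

    def __post_init__(self):
        if len(self.grid) <= 1:
            raise ValueError("degenerate grid (<= 1 point)")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if not 0 <= self.lapse < 0.5:
            raise ValueError("lapse must lie in [0, 0.5)")

    @property
    def posterior(self) -> np.ndarray:
        return np.exp(self.log_posterior)

    def to_json(self) -> str:
        return json.dumps({
            "grid": self.grid.tolist(),
            "log_posterior": self.log_posterior.tolist(),
            "sigma": self.sigma,
            "lapse": self.lapse,
            "response_count": self.response_count,
        })

    @classmethod
    def from_json(cls, text: str) -> "QuestState":
        d = json.loads(text)
        return cls(grid=np.asarray(d["grid"], float),
                   log_posterior=np.asarray(d["log_posterior"], float),
                   sigma=d["sigma"], lapse=d["lapse"],
                   response_count=d["response_count"])


def init_quest(prior_mean: float, prior_sd: float, sigma: float,
               lapse: float = 0.02, n_grid: int = 301,
               grid_span_sd: float = 4.0, grid_min: float = 1.0,
               grid: np.ndarray | None = None) -> QuestState:
    """Initialise the posterior to a discretized Gaussian prior.

    The grid spans ``prior_mean +/- grid_span_sd * prior_sd`` (clipped
    below at ``grid_min``) unless an explicit grid is given.
    """
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if grid is None:
        lo = max(grid_min, prior_mean - grid_span_sd * prior_sd)
        hi = prior_mean + grid_span_sd * prior_sd
        grid = np.linspace(lo, hi, n_grid)
    else:
        grid = np.asarray(grid, float)
    logp = -0.5 * ((grid - prior_mean) / prior_sd) ** 2
    logp -= logsumexp(logp)
    return QuestState(grid=grid, log_posterior=logp, sigma=sigma, lapse=lapse)


def _response_prob(state: QuestState, probe: float) -> np.ndarray:
    """P(chose probe | PSE = grid point) under the assumed psychometric
    function with a symmetric lapse floor."""
    p = ndtr((probe - state.grid) / state.sigma)
    return state.lapse + (1.0 - 2.0 * state.lapse) * p


def quest_update(state: QuestState, probe: float, chose_probe: bool) -> QuestState:
    """Bayes update of the posterior after one response.

    Probes outside the grid range are clamped (with a warning) so the
    likelihood stays well defined.
    """
    lo, hi = state.grid[0], state.grid[-1]
    if probe < lo or probe > hi:
        warnings.warn(
            f"probe {probe} outside grid [{lo:.2f}, {hi:.2f}]; clamped",
            RuntimeWarning, stacklevel=2)
        probe = float(np.clip(probe, lo, hi))
    p = _response_prob(state, probe)
    logp = state.log_posterior + (np.log(p) if chose_probe else np.log1p(-p))
    logp = logp - logsumexp(logp)
    return replace(state, log_posterior=logp,
                   response_count=state.response_count + 1)


def posterior_mean(state: QuestState) -> float:
    w = state.posterior
    return float(np.sum(w * state.grid))


def posterior_sd(state: QuestState) -> float:
    w = state.posterior
    m = np.sum(w * state.grid)
    return float(np.sqrt(np.sum(w * (state.grid - m) ** 2)))


def _perturbed_estimate(state: QuestState, pcfg: PerturbationConfig,
                        rng: np.random.Generator,
                        reference_n: float | None = None) -> float:
    """PSE estimate plus Gaussian jitter, before rounding."""
    return posterior_mean(state) + rng.normal(0.0, pcfg.effective_sd(reference_n))

def next_probe(state: QuestState, pcfg: PerturbationConfig,
               rng: np.random.Generator,
               reference_n: float | None = None) -> int:
    """Integer probe numerosity for the next trial: the perturbed posterior
    mean, rounded, clamped at ``min_probe``."""
    x = _perturbed_estimate(state, pcfg, rng, reference_n)
    return int(max(pcfg.min_probe, round(x)))
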
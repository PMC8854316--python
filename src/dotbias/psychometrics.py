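"""Psychometric-function fitting for 2AFC numerosity trials.

The proportion of "probe more numerous" responses as a function of probe
numerosity is fit with a cumulative Gaussian by maximum likelihood.  The
fitted median is the point of subjective equality (PSE); the numerosity
difference between the 50% and 75% points is the just-noticeable
difference (JND = 0.6745 sigma); JND divided by the perceived numerosity
(the PSE) is the Weber fraction; and the percent bias is
100 * (PSE - reference) / reference, negative for underestimation.

Reaction-time trimming (responses beyond 2 SD from a subject's mean RT)
is applied before fitting, per subject across that subject's session.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr
from scipy.stats import norm

from .quest import PROBIT_75

__all__ = [
    "PsychometricFit",
    "CumulativeGaussianAFC",
    "EstimationError",
    "trim_rt",
    "fit_psychometric",
    "bias_percent",
    "aggregate_curve",
]


class EstimationError(RuntimeError):
    """Raised when the data cannot constrain a psychometric fit."""


@dataclass(frozen=True)
class PsychometricFit:
    """Fitted PSE and spread plus the derived precision indices."""

    pse: float
    sigma: float
    jnd: float
    wf: float
    bias_pct: float
    n_trials_used: int
    converged: bool

    def as_row(self) -> dict:
        return dict(pse=self.pse, sigma=self.sigma, jnd=self.jnd, wf=self.wf,
                    bias_pct=self.bias_pct, n_trials_used=self.n_trials_used,
                    converged=self.converged)


def bias_percent(pse: float, reference_n: float) -> float:
    """Percent difference of the PSE from the reference; negative values
    mean the reference was underestimated."""
    if reference_n <= 0:
        raise ValueError("reference_n must be positive")
    return 100.0 * (pse - reference_n) / reference_n


def trim_rt(trials: pd.DataFrame, rt_col: str = "rt_s",
            subject_col: str = "subject_id") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop trials whose RT falls outside mean +/- 2 SD, per subject.

    The mean and (ddof=1) SD are computed once over each subject's whole
    session — a single pass, no re-iteration after removal.  A subject
    with zero RT spread keeps all trials.  Returns ``(kept, removed)``.
    """
    if len(trials) < 3:
        raise EstimationError("need at least 3 trials to trim RTs")
    keep = np.ones(len(trials), bool)
    rt = trials[rt_col].to_numpy(float)
    for _, idx in trials.groupby(subject_col, sort=False).indices.items():
        r = rt[idx]
        sd = r.std(ddof=1) if len(r) > 1 else 0.0
        if sd == 0.0:
            continue
        m = r.mean()
        keep[idx] = (r >= m - 2 * sd) & (r <= m + 2 * sd)
    return trials.loc[keep], trials.loc[~keep]


def _aggregate(probe: np.ndarray, chose: np.ndarray):
    """Collapse trials to (level, n_chose, n_total) triples."""
    levels, inv = np.unique(probe, return_inverse=True)
    n = np.bincount(inv, minlength=len(levels)).astype(float)
    k = np.bincount(inv, weights=chose.astype(float), minlength=len(levels))
    return levels.astype(float), k, n


class CumulativeGaussianAFC:
    """Maximum-likelihood cumulative-Gaussian psychometric model.

    A scikit-learn-style estimator: ``fit(X, y)`` with probe numerosities
    ``X`` (1d or column vector) and boolean "chose probe" responses ``y``
    sets the fitted attributes ``pse_``, ``sigma_``, ``converged_`` and
    ``n_trials_``.  The response model is

        P(chose probe | x) = lapse/2 + (1 - lapse) * Phi((x - pse) / sigma)

    with ``lapse`` fixed (0 by default).  Optimisation is bounded
    quasi-Newton on (pse, log sigma) with analytic gradients and
    ``n_starts`` deterministic starts to guard against local minima.
    """

    def __init__(self, lapse: float = 0.0, n_starts: int = 3,
                 tol: float = 1e-8, sigma_min_frac: float = 1e-3):
        self.lapse = lapse
        self.n_starts = n_starts
        self.tol = tol
        self.sigma_min_frac = sigma_min_frac

    # minimal get/set_params so the class composes with sklearn tooling
    def get_params(self, deep: bool = True) -> dict:
        return dict(lapse=self.lapse, n_starts=self.n_starts, tol=self.tol,
                    sigma_min_frac=self.sigma_min_frac)

    def set_params(self, **params) -> "CumulativeGaussianAFC":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _nll_grad(self, theta, levels, k, n):
        pse, log_sigma = theta
        sigma = np.exp(log_sigma)
        z = (levels - pse) / sigma
        F = ndtr(z)
        lam = self.lapse
        psi = lam / 2.0 + (1.0 - lam) * F
        psi = np.clip(psi, 1e-12, 1 - 1e-12)
        nll = -np.sum(k * np.log(psi) + (n - k) * np.log1p(-psi))
        # gradient
        w = -(k / psi - (n - k) / (1 - psi)) * (1.0 - lam)
        phi = norm.pdf(z)
        d_pse = np.sum(w * (-phi / sigma))
        d_logs = np.sum(w * (-z * phi))
        return nll, np.array([d_pse, d_logs])

    def fit(self, X, y) -> "CumulativeGaussianAFC":
        probe = np.asarray(X, float).reshape(-1)
        chose = np.asarray(y, bool).reshape(-1)
        if probe.shape != chose.shape:
            raise ValueError("X and y lengths differ")
        levels, k, n = _aggregate(probe, chose)
        if len(levels) < 2:
            raise EstimationError("need >= 2 distinct probe levels")
        if k.sum() == 0 or k.sum() == n.sum():
            raise EstimationError("all responses identical; PSE unidentified")

        span = levels[-1] - levels[0]
        scale = max(span, levels.mean())
        sigma_min = self.sigma_min_frac * scale
        bounds = [(levels[0] - 2 * span, levels[-1] + 2 * span),
                  (np.log(sigma_min), np.log(10 * scale))]

        # crude start from the empirical response proportions
        p_hat = (k + 0.5) / (n + 1.0)
        order = np.argsort(p_hat, kind="stable")  # xp must increase for interp
        pse0 = float(np.interp(0.5, p_hat[order], levels[order]))
        q75 = float(np.interp(0.75, p_hat[order], levels[order]))
        sigma0 = np.clip((q75 - pse0) / PROBIT_75, 2 * sigma_min, 5 * scale)
        starts = [(pse0, sigma0),
                  (pse0 - 0.2 * span, 2 * sigma0),
                  (pse0 + 0.2 * span, max(0.5 * sigma0, 2 * sigma_min))]

        best = None
        for s_pse, s_sig in starts[: self.n_starts]:
            x0 = np.array([np.clip(s_pse, *bounds[0]),
                           np.clip(np.log(s_sig), *bounds[1])])
            res = optimize.minimize(
                self._nll_grad, x0, args=(levels, k, n), jac=True,
                method="L-BFGS-B", bounds=bounds,
                options={"ftol": self.tol, "gtol": 1e-10})
            if best is None or res.fun < best.fun:
                best = res
        self.pse_ = float(best.x[0])
        self.sigma_ = float(np.exp(best.x[1]))
        self.nll_ = float(best.fun)
        self.converged_ = bool(best.success)
        self.n_trials_ = int(n.sum())
        return self

    def predict_proba(self, X) -> np.ndarray:
        x = np.asarray(X, float).reshape(-1)
        p1 = self.lapse / 2.0 + (1 - self.lapse) * ndtr((x - self.pse_) / self.sigma_)
        return np.column_stack([1 - p1, p1])


def _fit_from_arrays(probe, chose, reference_n, lapse, n_starts) -> PsychometricFit:
    est = CumulativeGaussianAFC(lapse=lapse, n_starts=n_starts).fit(probe, chose)
    jnd = PROBIT_75 * est.sigma_
    return PsychometricFit(
        pse=est.pse_, sigma=est.sigma_, jnd=jnd,
        wf=jnd / est.pse_,
        bias_pct=bias_percent(est.pse_, reference_n),
        n_trials_used=est.n_trials_, converged=est.converged_)


def fit_psychometric(trials, reference_n: float, lapse: float = 0.0,
                     n_starts: int = 3) -> PsychometricFit:
    """Fit one condition's trials; ``trials`` is a trial-log DataFrame
    (columns ``probe_n`` and ``chose_probe``) or a ``(probe, chose)`` pair
    of arrays."""
    if isinstance(trials, pd.DataFrame):
        probe = trials["probe_n"].to_numpy(float)
        chose = trials["chose_probe"].to_numpy(bool)
    else:
        probe, chose = trials
    return _fit_from_arrays(probe, chose, reference_n, lapse, n_starts)


def aggregate_curve(trials: pd.DataFrame, reference_n: float,
                    lapse: float = 0.0) -> tuple[PsychometricFit, pd.DataFrame]:
    """Pool trials (possibly from many subjects), fit, and return the fit
    together with a (probe, proportion-chose-probe, count) table."""
    probe = trials["probe_n"].to_numpy(float)
    chose = trials["chose_probe"].to_numpy(bool)
    fit = _fit_from_arrays(probe, chose, reference_n, lapse, 3)
    levels, k, n = _aggregate(probe, chose)
    table = pd.DataFrame({"probe_n": levels, "prop_chose_probe": k / n,
                          "n_trials": n.astype(int)})
    return fit, table
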
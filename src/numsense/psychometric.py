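"""Cumulative-Gaussian psychometric fitting on log numerosity.

The probability of a "many" response is modeled as

    p(many | N) = Phi((log10 N - mu) / sigma)

where ``mu`` is the log10 point of subjective equality (PSE) and ``sigma``
the Gaussian spread on the log10 axis.  From the fitted parameters three
standard indices are derived:

* PSE  = 10**mu, the numerosity judged "many" half the time (accuracy/bias);
* JND  = z75 * sigma in log10 units, the 50%->75% distance, with
  z75 = Phi^-1(0.75) = 0.67449;
* Weber fraction Wf = 10**JND - 1 = N75/N50 - 1, the normalized
  discrimination threshold (precision).

Fitting is maximum likelihood on the raw Bernoulli trials (not least squares
on binned proportions), with bounded multi-start optimization.  The module
follows the statsmodels idiom: build a :class:`PsychometricModel` from trial
data, call :meth:`~PsychometricModel.fit`, and read estimates, standard
errors and a ``summary()`` table off the returned
:class:`PsychometricResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from .design import Z75
from .exceptions import DegenerateFitError, InsufficientDataError

__all__ = [
    "FitOptions",
    "PsychometricModel",
    "PsychometricResults",
    "fit_psychometric",
    "fit_group_aggregate",
    "derive_indices",
]

_PCLIP = 1e-12


@dataclass(frozen=True)
class FitOptions:
    """Bounds and restart policy for the bounded ML optimization."""

    sigma_bounds: tuple[float, float] = (1e-3, 1.0)
    mu_bounds: tuple[float, float] = (math.log10(4.0), math.log10(64.0))
    restarts: int = 5
    restart_seed: int = 0

    def __post_init__(self):
        for lo, hi in (self.sigma_bounds, self.mu_bounds):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError("bounds must be finite and ordered")


def derive_indices(mu_log: float, sigma_log: float) -> tuple[float, float, float]:
    """(pse, jnd_log, wf) from the fitted log-Gaussian parameters.

    pse = 10**mu, jnd = z75*sigma (log10 units), wf = 10**jnd - 1.
    """
    if sigma_log < 0:
        raise ValueError("sigma_log must be >= 0")
    pse = 10.0**mu_log
    jnd_log = Z75 * sigma_log
    wf = 10.0**jnd_log - 1.0
    return pse, jnd_log, wf


def _extract_xy(trials) -> tuple[np.ndarray, np.ndarray]:
    """Pull (numerosity, response) arrays from trial records or a DataFrame,
    dropping anchor trials."""
    if isinstance(trials, pd.DataFrame):
        t = trials
        mask = ~t["is_anchor"].astype(bool) if "is_anchor" in t else np.ones(len(t), bool)
        n = t.loc[mask, "numerosity"].to_numpy(float)
        resp = t.loc[mask, "response_many"]
        y = resp.to_numpy()
    else:
        n, y = [], []
        for tr in trials:
            if getattr(tr, "is_anchor", False):
                continue
            n.append(tr.numerosity)
            y.append(tr.response_many)
        n, y = np.asarray(n, float), np.asarray(y, object)
    keep = np.array([v is not None and v == v for v in y])
    return n[keep], np.asarray(y[keep], float)


class PsychometricModel:
    """Bernoulli cumulative-Gaussian model of "many" responses.

    Parameters
    ----------
    numerosity, response_many : array-like
        One entry per scored trial; responses are 0/1 ("few"/"many").
    """

    def __init__(self, numerosity: Sequence[float], response_many: Sequence[float]):
        n = np.asarray(numerosity, float)
        y = np.asarray(response_many, float)
        if n.shape != y.shape or n.ndim != 1:
            raise ValueError("numerosity and response_many must be 1-d and aligned")
        if np.any(n <= 0):
            raise ValueError("numerosities must be positive")
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ValueError("responses must be binary")
        if len(np.unique(n)) < 2:
            raise InsufficientDataError("need responses at >= 2 distinct numerosities")
        if y.min() == y.max():
            raise DegenerateFitError(
                "all responses identical ('many' or 'few' only): no finite MLE"
            )
        self.logn = np.log10(n)
        self.y = y
        # bin to unique levels: likelihood only depends on per-level counts
        self._lv, inv = np.unique(self.logn, return_inverse=True)
        self._k = np.bincount(inv, weights=y)
        self._m = np.bincount(inv).astype(float)

    @classmethod
    def from_trials(cls, trials) -> "PsychometricModel":
        """Build from TrialRecord sequences or a trials DataFrame
        (anchor trials and missing responses are dropped)."""
        n, y = _extract_xy(trials)
        return cls(n, y)

    @property
    def nobs(self) -> int:
        return int(self._m.sum())

    def loglike(self, params: Sequence[float]) -> float:
        """Bernoulli log-likelihood at (mu_log, sigma_log)."""
        mu, sigma = params
        p = norm.cdf((self._lv - mu) / max(sigma, 1e-12))
        p = np.clip(p, _PCLIP, 1 - _PCLIP)
        return float(self._k @ np.log(p) + (self._m - self._k) @ np.log1p(-p))

    def _starts(self, options: FitOptions) -> np.ndarray:
        # deterministic coverage of the box plus seeded jitter
        mu_lo, mu_hi = options.mu_bounds
        s_lo, s_hi = options.sigma_bounds
        phat = np.clip(self._k / self._m, 0.05, 0.95)
        # crude initial mu: level where the observed proportion crosses 1/2
        mu0 = float(np.interp(0.5, phat, self._lv)) if np.any(np.diff(phat) > 0) else float(
            np.mean(self._lv)
        )
        base = [
            (mu0, 0.1),
            (np.mean(self._lv), 0.05),
            (np.mean(self._lv), 0.3),
        ]
        rng = np.random.default_rng(options.restart_seed)
        while len(base) < options.restarts:
            base.append(
                (
                    rng.uniform(mu_lo, mu_hi),
                    float(np.exp(rng.uniform(np.log(max(s_lo, 1e-3)), np.log(s_hi)))),
                )
            )
        out = np.array(base[: options.restarts])
        out[:, 0] = np.clip(out[:, 0], mu_lo, mu_hi)
        out[:, 1] = np.clip(out[:, 1], s_lo, s_hi)
        return out

    def fit(self, options: FitOptions = FitOptions()) -> "PsychometricResults":
        """Bounded multi-start maximum likelihood.

        Ties between restarts are broken by higher log-likelihood, then by
        smaller sigma.  ``converged`` is False when every start failed or the
        winning estimate sits on a parameter bound.
        """
        bounds = [options.mu_bounds, options.sigma_bounds]
        best = None
        for x0 in self._starts(options):
            res = minimize(
                lambda p: -self.loglike(p),
                x0,
                method="L-BFGS-B",
                bounds=bounds,
            )
            cand = (-res.fun, -res.x[1], res)
            if best is None or cand[:2] > best[:2]:
                best = cand
        ll, _, res = best
        mu, sigma = float(res.x[0]), float(res.x[1])
        tol = 1e-8
        at_bound = (
            min(abs(mu - options.mu_bounds[0]), abs(mu - options.mu_bounds[1])) < tol
            or min(abs(sigma - options.sigma_bounds[0]), abs(sigma - options.sigma_bounds[1]))
            < tol
        )
        return PsychometricResults(
            model=self,
            mu_log=mu,
            sigma_log=sigma,
            loglik=float(ll),
            converged=bool(res.success and not at_bound),
            options=options,
        )


class PsychometricResults:
    """Fitted psychometric function with derived indices.

    Attributes
    ----------
    mu_log, sigma_log : float
        ML estimates on the log10-numerosity axis.
    pse, jnd_log, wf : float
        Derived point of subjective equality (dots), just-noticeable
        difference (log10 units) and Weber fraction.
    bse : ndarray
        Asymptotic standard errors of (mu_log, sigma_log) from the observed
        information; NaN when the Hessian is singular (e.g. on a bound).
    """

    def __init__(self, model, mu_log, sigma_log, loglik, converged, options):
        self.model = model
        self.mu_log = mu_log
        self.sigma_log = sigma_log
        self.loglik = loglik
        self.converged = converged
        self.options = options
        self.pse, self.jnd_log, self.wf = derive_indices(mu_log, sigma_log)
        self.n_trials = model.nobs
        self.params = np.array([mu_log, sigma_log])
        self.bse = self._bse()

    def _bse(self) -> np.ndarray:
        h = 1e-4
        f = self.model.loglike
        p = self.params
        H = np.empty((2, 2))
        for i in range(2):
            for j in range(2):
                ei, ej = np.eye(2)[i] * h, np.eye(2)[j] * h
                H[i, j] = (
                    f(p + ei + ej) - f(p + ei - ej) - f(p - ei + ej) + f(p - ei - ej)
                ) / (4 * h * h)
        try:
            cov = np.linalg.inv(-H)
            d = np.diag(cov)
            return np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
        except np.linalg.LinAlgError:
            return np.array([np.nan, np.nan])

    def predict(self, numerosity) -> np.ndarray:
        """p(many) at the given numerosities."""
        n = np.asarray(numerosity, float)
        return norm.cdf((np.log10(n) - self.mu_log) / max(self.sigma_log, 1e-12))

    def summary(self) -> str:
        lines = [
            "Psychometric fit (cumulative Gaussian on log10 numerosity)",
            "=" * 58,
            f"{'n trials':<22}{self.n_trials:>12d}",
            f"{'log-likelihood':<22}{self.loglik:>12.3f}",
            f"{'converged':<22}{str(self.converged):>12}",
            "-" * 58,
            f"{'mu (log10 PSE)':<22}{self.mu_log:>12.4f}   se {self.bse[0]:.4f}",
            f"{'sigma (log10)':<22}{self.sigma_log:>12.4f}   se {self.bse[1]:.4f}",
            "-" * 58,
            f"{'PSE (dots)':<22}{self.pse:>12.3f}",
            f"{'JND (log10 units)':<22}{self.jnd_log:>12.4f}",
            f"{'Weber fraction':<22}{self.wf:>12.4f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "mu_log": self.mu_log,
            "sigma_log": self.sigma_log,
            "pse": self.pse,
            "jnd_log": self.jnd_log,
            "wf": self.wf,
            "n_trials": self.n_trials,
            "loglik": self.loglik,
            "converged": self.converged,
        }


def fit_psychometric(trials, options: FitOptions = FitOptions()) -> PsychometricResults:
    """Fit one observer's scored trials (anchors excluded automatically)."""
    return PsychometricModel.from_trials(trials).fit(options)


def fit_group_aggregate(
    participants: Iterable, group: str, options: FitOptions = FitOptions()
) -> PsychometricResults:
    """Pool all scored trials of a group's participants and fit once."""
    pooled = []
    found = False
    for p in participants:
        if p.group != group:
            continue
        if p.trials:
            found = True
            pooled.extend(p.trials)
    if not found:
        raise InsufficientDataError(f"no participant with trials in group {group!r}")
    return fit_psychometric(pooled, options)
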
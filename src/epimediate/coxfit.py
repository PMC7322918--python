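"""Cox proportional-hazards fitting by Newton-Raphson with Efron tie handling.

The EWAS and GWAS stages fit the same survival outcome against thousands of
single-column perturbations of a design matrix.  :class:`CoxPartial`
pre-computes the risk-set / tie structure once so each fit costs only the
Newton iterations, which keeps genome-scale scans and replicate-level
calibration studies cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["CoxFit", "CoxPartial", "cox_fit"]


@dataclass
class CoxFit:
    """Result of one partial-likelihood fit.

    ``beta``/``se`` are per-covariate log hazard ratios and Wald standard
    errors; ``p`` are two-sided normal P-values.
    """

    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    n: int
    n_events: int

    @property
    def p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.beta / self.se))


class CoxPartial:
    """Partial-likelihood machinery for a fixed (time, event) outcome.

    Parameters
    ----------
    time : array of follow-up times (days), > 0.
    event : array of 0/1 death indicators.
    """

    def __init__(self, time, event):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event)
        if time.ndim != 1 or time.shape != event.shape:
            raise ValueError("time and event must be 1-d arrays of equal length")
        if np.any(time <= 0):
            raise ValueError("survival times must be positive")
        ev = event.astype(bool)
        if not ev.any():
            raise ValueError("no events: Cox partial likelihood is degenerate")
        self.order = np.argsort(time, kind="stable")
        t = time[self.order]
        self.event_sorted = ev[self.order]
        self.n = t.size
        self.n_events = int(ev.sum())
        # group rows by distinct time; the risk set at a group's time is the
        # suffix starting at the group's first row
        _, starts = np.unique(t, return_index=True)
        bounds = np.append(starts, self.n)
        self.groups = []
        for g in range(len(starts)):
            lo, hi = bounds[g], bounds[g + 1]
            ev_idx = np.arange(lo, hi)[self.event_sorted[lo:hi]]
            if ev_idx.size:
                self.groups.append((lo, ev_idx))

    def _derivatives(self, X, beta):
        """Log-likelihood, gradient and observed information at ``beta``."""
        n, p = X.shape
        eta = X @ beta
        eta = eta - eta.max()  # shifts loglik by a constant only
        w = np.exp(eta)
        wx = w[:, None] * X
        wxx = wx[:, :, None] * X[:, None, :]
        # suffix sums: risk-set aggregates for every possible entry row
        s0 = np.cumsum(w[::-1])[::-1]
        s1 = np.cumsum(wx[::-1], axis=0)[::-1]
        s2 = np.cumsum(wxx[::-1], axis=0)[::-1]
        ll = 0.0
        grad = np.zeros(p)
        info = np.zeros((p, p))
        for lo, ev_idx in self.groups:
            d = ev_idx.size
            ll += eta[ev_idx].sum()
            grad += X[ev_idx].sum(axis=0)
            w_t = w[ev_idx].sum()
            s1_t = wx[ev_idx].sum(axis=0)
            s2_t = wxx[ev_idx].sum(axis=0)
            # Efron: the d tied events each see the risk set minus an
            # increasing fraction of the tied group's own mass
            frac = np.arange(d) / d
            for f in frac:
                phi = s0[lo] - f * w_t
                u1 = (s1[lo] - f * s1_t) / phi
                ll -= np.log(phi)
                grad -= u1
                info += (s2[lo] - f * s2_t) / phi - np.outer(u1, u1)
        return ll, grad, info

    def fit(self, X, max_iter=40, tol=1e-9) -> CoxFit:
        """Maximise the partial likelihood for design ``X`` (n x p)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != self.n:
            raise ValueError("design row count does not match outcome length")
        Xs = X[self.order]
        p = Xs.shape[1]
        beta = np.zeros(p)
        ll, grad, info = self._derivatives(Xs, beta)
        converged = False
        for _ in range(max_iter):
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError:
                break
            # step-halving keeps the ascent monotone
            for _ in range(30):
                cand = beta + step
                ll_new, grad_new, info_new = self._derivatives(Xs, cand)
                if ll_new >= ll - 1e-12:
                    break
                step = step / 2.0
            else:
                break
            delta = np.max(np.abs(cand - beta))
            beta, ll, grad, info = cand, ll_new, grad_new, info_new
            if delta < tol:
                converged = True
                break
        try:
            cov = np.linalg.inv(info)
            se = np.sqrt(np.diag(cov))
            if not np.all(np.isfinite(se)):
                converged = False
        except np.linalg.LinAlgError:
            cov = np.full((p, p), np.nan)
            se = np.full(p, np.nan)
            converged = False
        return CoxFit(beta=beta, se=se, cov=cov, loglik=ll, converged=converged,
                      n=self.n, n_events=self.n_events)

    def score_test(self, X) -> tuple[float, float]:
        """Score (Rao) chi-square test of beta = 0 and its P-value.

        With a single binary covariate and no ties this is the log-rank test.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        Xs = X[self.order]
        _, grad, info = self._derivatives(Xs, np.zeros(Xs.shape[1]))
        stat = float(grad @ np.linalg.solve(info, grad))
        pval = float(stats.chi2.sf(stat, df=Xs.shape[1]))
        return stat, pval


def cox_fit(X, time, event, **kwargs) -> CoxFit:
    """One-shot Cox fit; see :class:`CoxPartial` for the reusable form."""
    return CoxPartial(time, event).fit(X, **kwargs)
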
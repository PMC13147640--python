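"""Three-component Gaussian mixture on ROH lengths and class boundaries.

ROH length distributions in livestock are multi-modal: short runs trace
ancient haplotype sharing and LD, long runs recent consanguinity.  A
univariate unequal-variance Gaussian mixture fitted to segment lengths
(kb) yields data-driven cut points between the short, medium and long
classes: each boundary is the point where the posterior-most-probable
component switches between two adjacent components, i.e. the root of
the weighted-density equality between them.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp


@dataclass(frozen=True)
class MixtureModel:
    """Fitted mixture, components sorted by increasing mean (kb)."""

    weights: tuple[float, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    boundaries: tuple[float, ...]
    loglik: float
    n_iter: int
    converged: bool

    def classify(self, lengths_kb: np.ndarray) -> np.ndarray:
        """Class index per length using the fitted boundaries."""
        return np.searchsorted(np.asarray(self.boundaries), np.asarray(lengths_kb),
                               side="right")


def _log_density(x: np.ndarray, w, mu, sd) -> np.ndarray:
    """(n, K) component log densities including mixture weights."""
    x = x[:, None]
    return (
        np.log(w)[None, :]
        - 0.5 * math.log(2 * math.pi)
        - np.log(sd)[None, :]
        - 0.5 * ((x - mu[None, :]) / sd[None, :]) ** 2
    )


def _em(x: np.ndarray, w, mu, sd, tol: float, max_iter: int):
    """Plain EM for a univariate K-component Gaussian mixture.

    The observed-data log-likelihood is checked to be non-decreasing at
    every iteration (up to round-off) — a property of EM that doubles as
    an internal correctness assertion.
    """
    n = x.size
    sd_floor = max(1e-8, 1e-6 * float(np.std(x)))
    prev_ll = -np.inf
    ll = prev_ll
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        logd = _log_density(x, w, mu, sd)
        lse = logsumexp(logd, axis=1)
        ll = float(lse.sum())
        if ll < prev_ll - 1e-8 * max(1.0, abs(ll)):
            raise AssertionError(
                f"EM log-likelihood decreased ({prev_ll} -> {ll})"
            )
        resp = np.exp(logd - lse[:, None])
        # responsibilities sum to one by construction; guard round-off
        np.testing.assert_allclose(resp.sum(axis=1), 1.0, atol=1e-9)
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.sqrt(np.maximum(var, sd_floor ** 2))
        if abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
            converged = True
            break
        prev_ll = ll
    return w, mu, sd, ll, it, converged


def fit_length_mixture(
    lengths_kb,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_init: int = 10,
    n_components: int = 3,
    log_scale: bool = False,
) -> MixtureModel:
    """Fit the length mixture and derive class boundaries.

    Parameters
    ----------
    lengths_kb
        Segment lengths in kb; at least 30 values required.
    seed
        Seeds the random restarts; the first initialisation is the
        deterministic quantile start (25/50/75% quantile means).
    log_scale
        Fit on log10 lengths instead of raw kb (robustness option);
        boundaries are mapped back to kb.
    """
    x = np.asarray(lengths_kb, dtype=float)
    if x.size < 30:
        raise ValueError(f"need >= 30 lengths to fit, got {x.size}")
    if np.any(x <= 0):
        raise ValueError("lengths must be positive")
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: all lengths identical")
    if log_scale:
        x = np.log10(x)

    rng = np.random.default_rng(seed)
    K = n_components
    span_sd = float(np.std(x))
    inits = []
    qs = np.quantile(x, np.linspace(0.25, 0.75, K))
    inits.append((np.full(K, 1.0 / K), qs, np.full(K, span_sd)))
    for _ in range(max(0, n_init - 1)):
        mu0 = np.sort(rng.choice(x, size=K, replace=False))
        inits.append((np.full(K, 1.0 / K), mu0.astype(float), np.full(K, span_sd)))

    best = None
    for w0, mu0, sd0 in inits:
        try:
            fit = _em(x, w0.copy(), mu0.copy(), sd0.copy(), tol, max_iter)
        except AssertionError:
            raise
        if best is None or fit[3] > best[3]:
            best = fit
    w, mu, sd, ll, it, converged = best
    if not converged:
        warnings.warn("EM did not converge; returning best state", RuntimeWarning)

    order = np.argsort(mu)
    w, mu, sd = w[order], mu[order], sd[order]
    bounds = component_boundaries(w, mu, sd)
    if log_scale:
        mu_out = tuple(float(10 ** m) for m in mu)
        sd_out = tuple(float(s) for s in sd)  # sds remain on log10 scale
        bounds = tuple(float(10 ** b) for b in bounds)
    else:
        mu_out = tuple(float(m) for m in mu)
        sd_out = tuple(float(s) for s in sd)
        bounds = tuple(float(b) for b in bounds)
    return MixtureModel(
        weights=tuple(float(v) for v in w),
        means=mu_out, sds=sd_out, boundaries=bounds,
        loglik=float(ll), n_iter=int(it), converged=bool(converged),
    )


def component_boundaries(weights, means, sds) -> tuple[float, ...]:
    """Posterior switch points between adjacent sorted components.

    For each adjacent pair, solves ``w1 N(x; m1, s1) = w2 N(x; m2, s2)``
    (a quadratic in x) and keeps the root strictly between the two
    means; if no root lies there, falls back to a fine-grid scan for the
    point where the weighted-density argmax switches.
    """
    w = np.asarray(weights, float)
    mu = np.asarray(means, float)
    sd = np.asarray(sds, float)
    out = []
    for k in range(mu.size - 1):
        w1, m1, s1 = w[k], mu[k], sd[k]
        w2, m2, s2 = w[k + 1], mu[k + 1], sd[k + 1]
        # log w1 - log s1 - (x-m1)^2/(2 s1^2) = log w2 - log s2 - (x-m2)^2/(2 s2^2)
        a = 1.0 / (2 * s2 ** 2) - 1.0 / (2 * s1 ** 2)
        b = m1 / s1 ** 2 - m2 / s2 ** 2
        c = (m2 ** 2 / (2 * s2 ** 2) - m1 ** 2 / (2 * s1 ** 2)
             + math.log(w1) - math.log(w2) - math.log(s1) + math.log(s2))
        root = None
        if abs(a) < 1e-15:
            if abs(b) > 0:
                r = -c / b
                if m1 < r < m2:
                    root = r
        else:
            disc = b * b - 4 * a * c
            if disc >= 0:
                sq = math.sqrt(disc)
                for r in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)):
                    if m1 < r < m2:
                        root = r
                        break
        if root is None:
            grid = np.linspace(m1, m2, 20001)
            ld = _log_density(grid, np.array([w1, w2]), np.array([m1, m2]),
                              np.array([s1, s2]))
            upper = np.flatnonzero(ld[:, 1] >= ld[:, 0])
            root = float(grid[upper[0]]) if upper.size else float(0.5 * (m1 + m2))
        out.append(float(root))
    if any(b2 <= b1 for b1, b2 in zip(out, out[1:])):
        raise ValueError("derived boundaries are not increasing")
    return tuple(out)


def classify_segments(segments, boundaries_kb):
    """Attach short/medium/long labels by length.

    Half-open rule: short if ``length_kb < b1``; medium if
    ``b1 <= length_kb < b2``; long otherwise — a length equal to a
    boundary goes to the upper class.
    """
    from dataclasses import replace

    b1, b2 = boundaries_kb
    if not b1 < b2:
        raise ValueError("boundaries must be increasing")
    labels = ("short", "medium", "long")
    out = []
    for s in segments:
        idx = 0 if s.length_kb < b1 else (1 if s.length_kb < b2 else 2)
        out.append(replace(s, class_label=labels[idx]))
    return out
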
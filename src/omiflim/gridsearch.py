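"""Brute-force grid evaluation of the biexponential Poisson likelihood.

An exhaustive cross-check for the gradient-based MLE fitter: the lifetime
and photon-fraction axes are scanned on a dense grid, and at every grid
point the total amplitude and constant background are profiled out by
maximizing the Poisson likelihood in those two parameters alone
(multiplicative Richardson-Lucy-type updates, which are monotone for this
model, followed by extra refinement of the leading candidates).  The
returned maximum is a lower bound on the global maximum likelihood that the
optimizer must meet or beat.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

from .model import BIN_WIDTH_PS, DecayModel


def _profile_amp_background(
    shapes: np.ndarray, counts: np.ndarray, n_iter: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Profile (A, C) per shape by multiplicative updates; returns logliks.

    ``shapes``: (n_points, n_bins) unit-sum decay shapes.  Model per point:
    mu = A * shape + C.  Updates A <- A * sum(y*p/mu) and
    C <- C * mean(y/mu) each monotonically increase the Poisson likelihood.
    """
    n_pts, n_bins = shapes.shape
    total = counts.sum()
    tail = max(1, n_bins // 20)
    c0 = max(float(counts[-tail:].mean()), 1e-3)
    a = np.full(n_pts, max(total - n_bins * c0, 1.0))
    c = np.full(n_pts, c0)
    for _ in range(n_iter):
        mu = a[:, None] * shapes + c[:, None]
        ratio = counts / np.maximum(mu, 1e-300)
        a *= (ratio * shapes).sum(axis=1)
        c *= ratio.mean(axis=1)
    mu = np.maximum(a[:, None] * shapes + c[:, None], 1e-300)
    ll = (counts * np.log(mu)).sum(axis=1) - mu.sum(axis=1)
    return ll, a, c


def grid_profile_loglik(
    counts: np.ndarray,
    irf: np.ndarray,
    tau1_grid: np.ndarray,
    tau2_grid: np.ndarray,
    alpha_grid: np.ndarray,
    bin_width: float = BIN_WIDTH_PS,
    n_iter: int = 40,
    n_polish: int = 100,
    polish_iter: int = 400,
) -> dict:
    """Best Poisson log-likelihood over a (tau1, tau2, alpha1) grid.

    Returns the maximizing grid point, its profiled amplitude/background,
    and the full log-likelihood (including the log y! terms, so the value
    is directly comparable with :attr:`FitResult.loglik`).
    """
    counts = np.asarray(counts, dtype=float)
    model = DecayModel(irf, bin_width)
    p1 = np.stack([model.component(t) for t in tau1_grid])
    p2 = np.stack([model.component(t) for t in tau2_grid])
    n1, n2 = len(tau1_grid), len(tau2_grid)

    best = []
    for alpha in alpha_grid:
        shapes = (alpha * p1)[:, None, :] + ((1 - alpha) * p2)[None, :, :]
        shapes = shapes.reshape(n1 * n2, -1)
        ll, a, c = _profile_amp_background(shapes, counts, n_iter)
        order = np.argsort(ll)[::-1][: max(1, n_polish // len(alpha_grid) + 5)]
        for idx in order:
            i, j = divmod(int(idx), n2)
            best.append((ll[idx], alpha, i, j, a[idx], c[idx]))

    best.sort(reverse=True)
    finalists = best[:n_polish]
    lgamma = gammaln(counts + 1.0).sum()
    top = None
    for _, alpha, i, j, _, _ in finalists:
        shape = (alpha * p1[i] + (1 - alpha) * p2[j])[None, :]
        ll, a, c = _profile_amp_background(shape, counts, polish_iter)
        full = float(ll[0] - lgamma)
        if top is None or full > top["loglik"]:
            top = {
                "loglik": full,
                "tau1": float(tau1_grid[i]),
                "tau2": float(tau2_grid[j]),
                "alpha1": float(alpha),
                "amplitude": float(a[0]),
                "background": float(c[0]),
            }
    return top


def default_grid() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The reference scan: tau1 100-1000 by 25 ps, tau2 1200-4000 by 50 ps,
    alpha1 0-1 by 0.02."""
    return (
        np.arange(100.0, 1000.0 + 1e-9, 25.0),
        np.arange(1200.0, 4000.0 + 1e-9, 50.0),
        np.arange(0.0, 1.0 + 1e-9, 0.02),
    )
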
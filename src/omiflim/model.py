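"""Shared biexponential TCSPC forward model.

The observable at each pixel is a photon-arrival-time histogram over one
laser repetition period.  The underlying emission is a two-component
exponential decay

    I(t) = alpha1 * exp(-t / tau1) + alpha2 * exp(-t / tau2) + C

convolved with the instrument response function (IRF).  Because the long
component (tau2 ~ 2.5 ns) is not negligible against the 12.5 ns repetition
period of an 80 MHz source, the convolution is treated as circular over the
period: photons emitted late in one period wrap into the early bins of the
next.  The periodic sum of an exponential differs from a single period only
by a constant factor, so after unit-sum normalization the per-period bin
shape is unchanged and the wrap-around enters solely through the circular
convolution with the IRF.
"""

from __future__ import annotations

import numpy as np

#: Default TCSPC time axis: 256 bins over one 80 MHz repetition period.
N_BINS = 256
PERIOD_PS = 12_500.0
BIN_WIDTH_PS = PERIOD_PS / N_BINS  # 48.828125 ps


def bin_centers(n_bins: int = N_BINS, bin_width: float = BIN_WIDTH_PS) -> np.ndarray:
    """Arrival-time bin centers in picoseconds."""
    return (np.arange(n_bins) + 0.5) * bin_width


def exp_shape(tau: float, n_bins: int = N_BINS, bin_width: float = BIN_WIDTH_PS) -> np.ndarray:
    """Unit-sum single-exponential bin shape for lifetime ``tau`` (ps)."""
    if tau <= 0:
        raise ValueError(f"lifetime must be positive, got {tau}")
    u = np.exp(-bin_centers(n_bins, bin_width) / tau)
    return u / u.sum()


def exp_shape_dtau(tau: float, n_bins: int = N_BINS, bin_width: float = BIN_WIDTH_PS) -> np.ndarray:
    """Derivative of :func:`exp_shape` with respect to ``tau``.

    For E = u / sum(u) with u = exp(-t/tau), dE/dtau = E * (w - <w>_E)
    where w = t / tau**2 and <w>_E is the E-weighted mean of w.
    """
    e = exp_shape(tau, n_bins, bin_width)
    w = bin_centers(n_bins, bin_width) / tau**2
    return e * (w - float(e @ w))


def circular_convolve(irf: np.ndarray, signal: np.ndarray) -> np.ndarray:
    """Circular convolution of ``signal`` with ``irf`` over the period."""
    n = len(signal)
    if len(irf) != n:
        raise ValueError("IRF and signal must share the time axis")
    return np.fft.irfft(np.fft.rfft(irf) * np.fft.rfft(signal), n)


class DecayModel:
    """Biexponential + constant model on a fixed time axis with a fixed IRF.

    Caches the IRF spectrum so that repeated evaluations (per-pixel fitting)
    only pay for the exponential shapes.  Expected counts per bin are

        mu = IRF (*) [a1 * E(tau1) + a2 * E(tau2)] + C

    with (*) the circular convolution over the repetition period, E the
    unit-sum exponential shape and a1, a2 expected photon counts per
    component.  Since the IRF is unit-sum, sum(mu) = a1 + a2 + n_bins * C.
    """

    def __init__(self, irf: np.ndarray, bin_width: float = BIN_WIDTH_PS):
        irf = np.asarray(irf, dtype=float)
        if irf.ndim != 1 or len(irf) < 16:
            raise ValueError("IRF must be a 1-D histogram of at least 16 bins")
        if np.any(irf < 0):
            raise ValueError("IRF must be nonnegative")
        s = irf.sum()
        if s <= 0:
            raise ValueError("IRF must have positive mass")
        self.irf = irf / s
        self.n_bins = len(irf)
        self.bin_width = float(bin_width)
        self._irf_fft = np.fft.rfft(self.irf)
        self._t = bin_centers(self.n_bins, self.bin_width)

    def convolve(self, shape: np.ndarray) -> np.ndarray:
        return np.fft.irfft(self._irf_fft * np.fft.rfft(shape), self.n_bins)

    def component(self, tau: float) -> np.ndarray:
        """IRF-convolved unit-sum exponential for lifetime ``tau``."""
        return self.convolve(exp_shape(tau, self.n_bins, self.bin_width))

    def component_dtau(self, tau: float) -> np.ndarray:
        return self.convolve(exp_shape_dtau(tau, self.n_bins, self.bin_width))

    def expected(self, tau1: float, tau2: float, a1: float, a2: float, c: float) -> np.ndarray:
        """Expected counts per bin."""
        return a1 * self.component(tau1) + a2 * self.component(tau2) + c

    def nll_and_grad(
        self, theta: np.ndarray, counts: np.ndarray
    ) -> tuple[float, np.ndarray]:
        """Poisson negative log-likelihood (up to y! terms) and its gradient.

        ``theta`` = (tau1, tau2, a1, a2, c).  The two component shapes and
        their tau-derivatives are convolved with the IRF in one batched FFT.
        """
        tau1, tau2, a1, a2, c = theta
        t = self._t
        stack = np.empty((4, self.n_bins))
        for i, tau in enumerate((tau1, tau2)):
            u = np.exp(-t / tau)
            e = u / u.sum()
            w = t / tau**2
            stack[2 * i] = e
            stack[2 * i + 1] = e * (w - float(e @ w))
        conv = np.fft.irfft(self._irf_fft * np.fft.rfft(stack, axis=1), self.n_bins, axis=1)
        p1, d1, p2, d2 = conv
        mu = np.maximum(a1 * p1 + a2 * p2 + c, 1e-12)
        nll = float(mu.sum() - counts @ np.log(mu))
        r = 1.0 - counts / mu  # d nll / d mu
        grad = np.array(
            [a1 * (r @ d1), a2 * (r @ d2), r @ p1, r @ p2, r.sum()]
        )
        return nll, grad

    def loglik(self, theta: np.ndarray, counts: np.ndarray) -> float:
        """Full Poisson log-likelihood including the log(y!) terms."""
        from scipy.special import gammaln

        tau1, tau2, a1, a2, c = theta
        mu = np.maximum(self.expected(tau1, tau2, a1, a2, c), 1e-12)
        return float(counts @ np.log(mu) - mu.sum() - gammaln(counts + 1.0).sum())
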
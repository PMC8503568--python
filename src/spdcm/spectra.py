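"""Cross-spectral density features.

Each subject's ROI time series is summarized by complex cross-spectral
density (CSD) matrices on a fixed frequency grid — the data feature the
spectral DCM is fitted to.  The primary route is parametric: fit a
multivariate autoregressive (MAR) model and evaluate its spectrum, which is
smooth and low-variance.  A Welch segment-averaged estimator is provided as
an independent, non-parametric oracle for tests and diagnostics.

Convention: all spectra are two-sided densities per Hz, i.e. the spectrum of
a unit-variance white series sampled every ``tr`` seconds is flat at ``tr``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .cohort import RoiTimeSeries


class SpectraError(ValueError):
    pass


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing positive frequencies in Hz."""

    freqs: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", f)
        if f.ndim != 1 or f.size == 0:
            raise SpectraError("frequency grid must be a non-empty 1-D array")
        if f[0] <= 0 or np.any(np.diff(f) <= 0):
            raise SpectraError("frequencies must be strictly increasing and > 0")

    def __len__(self) -> int:
        return self.freqs.size


def default_grid(
    tr: float,
    n_freqs: int = 32,
    fmin: float = 0.02,
    fmax: float = 0.25,
    n_volumes: int | None = None,
    min_cycles: float = 8.0,
) -> FrequencyGrid:
    """Linearly spaced grid in the resting-state BOLD band.

    The lower edge (default 0.02 Hz) keeps the grid away from the steep,
    poorly resolved low-frequency end of the power-law band, where
    autoregressive spectral features are most biased; the band is further
    truncated to what the data resolve (at least ``min_cycles`` cycles per
    record) and to Nyquist.
    """
    nyquist = 0.5 / tr
    hi = min(fmax, nyquist)
    lo = fmin
    if n_volumes is not None:
        lo = max(lo, min_cycles / (n_volumes * tr))
    if not lo < hi:
        raise SpectraError(f"empty frequency band [{lo}, {hi}]")
    return FrequencyGrid(np.linspace(lo, hi, n_freqs))


@dataclass(frozen=True)
class CrossSpectra:
    """Complex R x R Hermitian CSD matrix at each grid frequency."""

    grid: FrequencyGrid
    csd: np.ndarray  # (F, R, R) complex

    def __post_init__(self):
        s = np.asarray(self.csd, dtype=complex)
        object.__setattr__(self, "csd", s)
        if s.ndim != 3 or s.shape[0] != len(self.grid) or s.shape[1] != s.shape[2]:
            raise SpectraError("csd must have shape (F, R, R)")
        asym = np.max(np.abs(s - s.conj().transpose(0, 2, 1)))
        if asym > 1e-10 * max(1.0, float(np.max(np.abs(s)))):
            raise SpectraError(f"CSD not Hermitian (max asymmetry {asym:.3g})")
        diag = np.diagonal(s, axis1=1, axis2=2)
        if np.min(diag.real) < -1e-10 * max(1.0, float(np.max(np.abs(diag)))):
            raise SpectraError("CSD diagonal must be non-negative")

    @property
    def n_regions(self) -> int:
        return self.csd.shape[1]

    def to_dict(self) -> dict:
        return {
            "freqs": self.grid.freqs.tolist(),
            "real": self.csd.real.tolist(),
            "imag": self.csd.imag.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CrossSpectra":
        return cls(
            FrequencyGrid(np.asarray(d["freqs"])),
            np.asarray(d["real"]) + 1j * np.asarray(d["imag"]),
        )


@dataclass(frozen=True)
class MarModel:
    """Multivariate autoregression x_t = sum_k C_k x_{t-k} + e_t."""

    coeff: np.ndarray  # (p, R, R)
    noise_cov: np.ndarray  # (R, R)

    def __post_init__(self):
        c = np.asarray(self.coeff, dtype=float)
        q = np.asarray(self.noise_cov, dtype=float)
        object.__setattr__(self, "coeff", c)
        object.__setattr__(self, "noise_cov", q)
        if c.ndim != 3 or c.shape[1] != c.shape[2]:
            raise SpectraError("coeff must have shape (p, R, R)")
        if q.shape != (c.shape[1], c.shape[1]):
            raise SpectraError("noise_cov shape mismatch")
        if np.max(np.abs(q - q.T)) > 1e-10:
            raise SpectraError("noise_cov must be symmetric")
        if np.min(np.linalg.eigvalsh(q)) <= 0:
            raise SpectraError("noise_cov must be positive definite")

    @property
    def order(self) -> int:
        return self.coeff.shape[0]

    @property
    def n_regions(self) -> int:
        return self.coeff.shape[1]

    def spectral_radius(self) -> float:
        p, r = self.order, self.n_regions
        comp = np.zeros((p * r, p * r))
        comp[:r, :] = np.concatenate(self.coeff, axis=1)
        if p > 1:
            comp[r:, : r * (p - 1)] = np.eye(r * (p - 1))
        return float(np.max(np.abs(np.linalg.eigvals(comp))))


def fit_mar(ts: RoiTimeSeries, order: int = 8, ridge: float = 1e-3) -> MarModel:
    """Least-squares (ridge-regularized) MAR fit with a stability check."""
    if order < 1:
        raise SpectraError("MAR order must be a positive integer")
    x = ts.data
    t_len, r = x.shape
    if t_len <= r * order + 10:
        raise SpectraError(
            f"series too short for MAR order {order} (T={t_len}, R={r})"
        )
    n = t_len - order
    design = np.concatenate(
        [x[order - k - 1 : t_len - k - 1] for k in range(order)], axis=1
    )  # (n, R*p): columns are lags 1..p stacked
    target = x[order:]
    gram = design.T @ design + ridge * np.eye(r * order)
    try:
        beta = np.linalg.solve(gram, design.T @ target)  # (R*p, R)
    except np.linalg.LinAlgError as exc:
        raise SpectraError(f"rank-deficient MAR regressors: {exc}") from exc
    coeff = np.stack(
        [beta[k * r : (k + 1) * r].T for k in range(order)], axis=0
    )  # coeff[k] maps x_{t-k-1} -> x_t
    resid = target - design @ beta
    dof = max(n - r * order, 1)
    noise_cov = resid.T @ resid / dof
    # symmetrize and floor eigenvalues against numerically singular residuals
    noise_cov = 0.5 * (noise_cov + noise_cov.T)
    w, v = np.linalg.eigh(noise_cov)
    noise_cov = (v * np.maximum(w, 1e-12)) @ v.T
    model = MarModel(coeff, noise_cov)
    rho = model.spectral_radius()
    if rho >= 1.0:
        raise SpectraError(
            f"fitted MAR unstable (spectral radius {rho:.3f}); try a lower order"
        )
    return model


def mar_to_csd(mar: MarModel, grid: FrequencyGrid, tr: float) -> CrossSpectra:
    """Spectrum of a MAR model: S(f) = tr * A(f)^-1 Sigma A(f)^-*.

    A(f) = I - sum_k C_k exp(-i 2 pi f (k+1) tr).  Hermitian by construction.
    """
    r = mar.n_regions
    freqs = grid.freqs
    lags = np.arange(1, mar.order + 1)
    phase = np.exp(-2j * np.pi * freqs[:, None] * lags[None, :] * tr)  # (F, p)
    a = np.eye(r)[None, :, :] - np.einsum("fp,prc->frc", phase, mar.coeff)
    try:
        ainv = np.linalg.inv(a)
    except np.linalg.LinAlgError:
        dets = np.abs(np.linalg.det(a))
        f_bad = freqs[int(np.argmin(dets))]
        raise SpectraError(f"MAR transfer singular at f = {f_bad:.4g} Hz")
    s = tr * np.einsum("frc,cd,fed->fre", ainv, mar.noise_cov, ainv.conj())
    s = 0.5 * (s + s.conj().transpose(0, 2, 1))
    return CrossSpectra(grid, s)


def csd_welch(
    ts: RoiTimeSeries, grid: FrequencyGrid, nperseg: int | None = None
) -> CrossSpectra:
    """Segment-averaged (Hann-tapered) cross-periodogram on the grid.

    Non-parametric oracle for tests and diagnostics; linear interpolation of
    real and imaginary parts onto the requested grid.
    """
    x = ts.data
    t_len, r = x.shape
    if nperseg is None:
        nperseg = min(256, t_len // 4)
    if t_len < 4 * nperseg:
        raise SpectraError("need T >= 4 x segment length for Welch averaging")
    fs = 1.0 / ts.tr
    # two-sided density so that white noise -> tr at every frequency;
    # broadcasting computes every pair (i, j) at once, shape (R, R, Fn).
    f_native, pxy = signal.csd(
        x.T[:, None, :],
        x.T[None, :, :],
        fs=fs,
        nperseg=nperseg,
        detrend="constant",
        scaling="density",
        return_onesided=False,
        axis=-1,
    )
    # scipy returns conj(X_i) * X_j; our convention is E[X_i conj(X_j)]
    sxx = pxy.conj()
    order = np.argsort(f_native)
    f_sorted = f_native[order]
    sxx = sxx[:, :, order]
    pos = f_sorted > 0
    f_pos, s_pos = f_sorted[pos], sxx[:, :, pos]
    if f_sorted[0] < 0 and f_pos[-1] < 0.5 * fs:
        # extend to Nyquist using S(-f_N) = S(f_N)* for real signals
        f_pos = np.append(f_pos, -f_sorted[0])
        s_pos = np.concatenate([s_pos, sxx[:, :, :1].conj()], axis=2)
    if grid.freqs[0] < f_pos[0] - 1e-12 or grid.freqs[-1] > f_pos[-1] + 1e-12:
        raise SpectraError(
            f"grid [{grid.freqs[0]:.4g}, {grid.freqs[-1]:.4g}] outside resolvable "
            f"band [{f_pos[0]:.4g}, {f_pos[-1]:.4g}]"
        )
    out = np.empty((len(grid), r, r), dtype=complex)
    for i in range(r):
        for j in range(r):
            out[:, i, j] = np.interp(grid.freqs, f_pos, s_pos[i, j].real) + 1j * np.interp(
                grid.freqs, f_pos, s_pos[i, j].imag
            )
    out = 0.5 * (out + out.conj().transpose(0, 2, 1))
    # clip tiny negative diagonal leakage from interpolation
    idx = np.arange(r)
    diag = out[:, idx, idx].real
    out[:, idx, idx] = np.maximum(diag, 0.0)
    return CrossSpectra(grid, out)
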
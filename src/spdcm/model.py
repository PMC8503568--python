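"""Generative spectral-DCM model for a hub-and-spoke network.

The network couples one subcortical hub to each sensory cortical node in
both directions (bottom-up and top-down); cortico-cortical connections are
not modelled (direct connections between primary sensory cortices are
anatomically implausible), and every node carries an inhibitory
self-connection.  For R regions this gives 2(R-1) directed couplings plus R
self-connections — 13 free coupling parameters in the canonical 5-node
model.

Neural dynamics are linear, dx/dt = A x + v, with v a power-law neuronal
fluctuation process.  The predicted BOLD cross-spectrum is

    S(f) = H(w) T(w) G_v(w) T(w)* H(w)* + G_e(w) I,   w = 2 pi f

with neuronal transfer T(w) = (i w I - A)^-1, a per-region linearized
hemodynamic transfer H, and power-law neuronal / observation noise spectra
G_v, G_e = alpha * w^-beta.

Parameter conventions:
  * off-diagonal couplings are in Hz, prior mean 0;
  * the self-connection is log-scaled: A[i, i] = -0.5 * exp(s_i), so a
    positive self parameter means stronger self-inhibition (more functional
    segregation);
  * hemodynamic decay/transit and noise amplitudes are log-scaled around
    fixed defaults; noise exponents beta are constrained to [0, 2] via a
    scaled logistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .spectra import CrossSpectra, FrequencyGrid


class ModelError(ValueError):
    pass


class StabilityError(ModelError):
    """Assembled A matrix has an eigenvalue with non-negative real part."""


@dataclass(frozen=True)
class ConnectivityMask:
    """Allowed directed couplings; entry (i, j) permits influence j -> i."""

    allowed: np.ndarray  # (R, R) bool, False on the diagonal
    self_allowed: np.ndarray  # (R,) bool
    region_labels: tuple[str, ...]

    def __post_init__(self):
        a = np.asarray(self.allowed, dtype=bool)
        s = np.asarray(self.self_allowed, dtype=bool)
        object.__setattr__(self, "allowed", a)
        object.__setattr__(self, "self_allowed", s)
        object.__setattr__(self, "region_labels", tuple(self.region_labels))
        if a.ndim != 2 or a.shape[0] != a.shape[1] or a.shape[0] != s.size:
            raise ModelError("mask shape mismatch")
        if np.any(np.diag(a)):
            raise ModelError("diagonal entries belong to the self set")

    @property
    def n_regions(self) -> int:
        return self.allowed.shape[0]

    @property
    def n_coupling(self) -> int:
        return int(self.allowed.sum() + self.self_allowed.sum())

    def coupling_names(self) -> list[str]:
        """Names of the free coupling parameters, in packing order."""
        names = [
            f"{self.region_labels[j]}->{self.region_labels[i]}"
            for i, j in self.offdiag_indices()
        ]
        names += [
            f"self_{self.region_labels[i]}"
            for i in range(self.n_regions)
            if self.self_allowed[i]
        ]
        return names

    def offdiag_indices(self) -> list[tuple[int, int]]:
        return [tuple(ij) for ij in np.argwhere(self.allowed)]


def build_connectivity_mask(
    region_labels, subcortical_index: int = 0
) -> ConnectivityMask:
    """Hub-and-spoke mask: hub <-> every spoke, all self-connections."""
    labels = tuple(region_labels)
    r = len(labels)
    if r < 2:
        raise ModelError("need at least 2 regions")
    if not 0 <= subcortical_index < r:
        raise ModelError("subcortical_index out of range")
    allowed = np.zeros((r, r), dtype=bool)
    for i in range(r):
        if i != subcortical_index:
            allowed[i, subcortical_index] = True  # bottom-up: hub -> cortex
            allowed[subcortical_index, i] = True  # top-down: cortex -> hub
    return ConnectivityMask(allowed, np.ones(r, dtype=bool), labels)


@dataclass(frozen=True)
class ParamLayout:
    """Packing of the free-parameter vector for a given mask.

    Order: couplings (off-diagonal in mask order), self_log (per region),
    neural noise (log-amplitude, exponent-raw), observation noise
    (log-amplitude, exponent-raw), hemodynamics (decay_log, transit_log per
    region).
    """

    mask: ConnectivityMask

    @property
    def n_offdiag(self) -> int:
        return int(self.mask.allowed.sum())

    @property
    def n_regions(self) -> int:
        return self.mask.n_regions

    @property
    def n_params(self) -> int:
        r = self.n_regions
        return self.n_offdiag + r + 4 + 2 * r

    @property
    def slices(self) -> dict[str, slice]:
        r, no = self.n_regions, self.n_offdiag
        return {
            "a": slice(0, no),
            "self_log": slice(no, no + r),
            "neural": slice(no + r, no + r + 2),
            "obs": slice(no + r + 2, no + r + 4),
            "hemo": slice(no + r + 4, no + r + 4 + 2 * r),
        }

    @property
    def coupling_slice(self) -> slice:
        """Couplings taken to the second level: off-diagonals + self."""
        return slice(0, self.n_offdiag + self.n_regions)

    def param_names(self) -> list[str]:
        names = list(self.mask.coupling_names())
        names += ["neural_log_amp", "neural_exp_raw", "obs_log_amp", "obs_exp_raw"]
        for lab in self.mask.region_labels:
            names += [f"hemo_decay_{lab}", f"hemo_transit_{lab}"]
        return names

    def pack(self, **parts: np.ndarray) -> np.ndarray:
        theta = np.zeros(self.n_params)
        for key, sl in self.slices.items():
            if key in parts:
                theta[sl] = np.asarray(parts[key], dtype=float)
        return theta

    def unpack(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ModelError(
                f"parameter vector has length {theta.size}, expected {self.n_params}"
            )
        return {key: theta[sl].copy() for key, sl in self.slices.items()}


@dataclass(frozen=True)
class DcmPriors:
    """Diagonal Gaussian priors over the packed parameter vector."""

    mean: np.ndarray
    var: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.mean, dtype=float)
        v = np.asarray(self.var, dtype=float)
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "var", v)
        if m.shape != v.shape or m.ndim != 1:
            raise ModelError("prior mean/var shape mismatch")
        if np.any(v <= 0):
            raise ModelError("prior variances must be positive")


def default_priors(layout: ParamLayout) -> DcmPriors:
    """Weakly informative priors keeping A near -0.5 I a priori.

    Couplings N(0, 1/16 Hz^2); self logs N(0, 1/64); hemodynamic logs
    N(0, 1/256).  Noise spectra: the power-law exponents are tight around
    beta = 1 (raw N(0, 1/64)); the log-amplitudes get room to move
    (variance 1/4), with the observation-noise amplitude centred well below
    the neuronal level (mean -4) — clean BOLD carries far less measurement
    noise than signal, and a mean-zero amplitude prior would force the model
    to predict a spurious white noise floor.  Validated by parameter
    recovery.
    """
    var = layout.pack(
        a=np.full(layout.n_offdiag, 1.0 / 16.0),
        self_log=np.full(layout.n_regions, 1.0 / 64.0),
        neural=[1.0 / 4.0, 1.0 / 64.0],
        obs=[1.0 / 4.0, 1.0 / 64.0],
        hemo=np.full(2 * layout.n_regions, 1.0 / 256.0),
    )
    mean = layout.pack(obs=[-4.0, 0.0])
    return DcmPriors(mean=mean, var=var)


@dataclass(frozen=True)
class DcmPosterior:
    """Gaussian posterior over the packed parameters plus fit diagnostics."""

    mean: np.ndarray
    cov: np.ndarray
    free_energy: float
    explained_variance: float
    converged: bool
    layout: ParamLayout
    f_history: tuple[float, ...] = ()  # free energy at each accepted step

    def coupling_mean(self) -> np.ndarray:
        return self.mean[self.layout.coupling_slice]

    def coupling_cov(self) -> np.ndarray:
        sl = self.layout.coupling_slice
        return self.cov[sl, sl]

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "cov": self.cov.tolist(),
            "free_energy": float(self.free_energy),
            "explained_variance": float(self.explained_variance),
            "converged": bool(self.converged),
            "param_names": self.layout.param_names(),
        }


def assemble_A(theta: np.ndarray, layout: ParamLayout) -> np.ndarray:
    """Coupling matrix in Hz: masked off-diagonals, diag = -0.5 exp(s)."""
    parts = layout.unpack(theta)
    r = layout.n_regions
    a = np.zeros((r, r))
    for val, (i, j) in zip(parts["a"], layout.mask.offdiag_indices()):
        a[i, j] = val
    diag = -0.5 * np.ones(r)
    diag[layout.mask.self_allowed] = -0.5 * np.exp(
        parts["self_log"][layout.mask.self_allowed]
    )
    np.fill_diagonal(a, diag)
    return a


def _powerlaw(omega: np.ndarray, log_amp: float, exp_raw: float) -> np.ndarray:
    beta = 2.0 * expit(exp_raw)  # constrained to [0, 2]
    return np.exp(log_amp) * omega ** (-beta)


def hemo_transfer(omega: np.ndarray, decay_log: float, transit_log: float) -> np.ndarray:
    """Two-pole low-pass surrogate for the hemodynamic (balloon) kernel.

    h(w) = kappa / ((i w + kappa)(i w + gamma)) with kappa = 0.64 e^decay,
    gamma = 0.32 e^transit; unit-free 2-parameter-per-region filter capturing
    the BOLD low-pass characteristic.
    """
    kappa = 0.64 * np.exp(decay_log)
    gamma = 0.32 * np.exp(transit_log)
    return kappa / ((1j * omega + kappa) * (1j * omega + gamma))


def predict_csd(
    theta: np.ndarray,
    layout: ParamLayout,
    grid: FrequencyGrid,
    unit_hemo: bool = False,
    include_obs: bool = True,
) -> CrossSpectra:
    """Model-predicted cross-spectral density on the grid.

    ``unit_hemo`` replaces the hemodynamic transfer by 1 (diagnostics and
    closed-form tests).  Raises :class:`StabilityError` for unstable A.
    """
    parts = layout.unpack(theta)
    a = assemble_A(theta, layout)
    eig = np.linalg.eigvals(a)
    if np.max(eig.real) >= -1e-12:
        raise StabilityError(
            f"A unstable: max real eigenvalue {np.max(eig.real):.4g}"
        )
    r = layout.n_regions
    omega = 2.0 * np.pi * grid.freqs
    m = 1j * omega[:, None, None] * np.eye(r)[None] - a[None]
    t = np.linalg.inv(m)  # (F, R, R)
    if unit_hemo:
        h = np.ones((len(grid), r), dtype=complex)
    else:
        hemo = parts["hemo"].reshape(r, 2)
        h = np.stack(
            [hemo_transfer(omega, hemo[i, 0], hemo[i, 1]) for i in range(r)], axis=1
        )
    ht = h[:, :, None] * t  # diag(h) @ T
    g_v = _powerlaw(omega, parts["neural"][0], parts["neural"][1])
    s = g_v[:, None, None] * np.einsum("frc,fec->fre", ht, ht.conj())
    if include_obs:
        g_e = _powerlaw(omega, parts["obs"][0], parts["obs"][1])
        s = s + g_e[:, None, None] * np.eye(r)[None]
    s = 0.5 * (s + s.conj().transpose(0, 2, 1))
    return CrossSpectra(grid, s)


def predict_csd_vectors(
    thetas: np.ndarray, layout: ParamLayout, grid: FrequencyGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Batched prediction of stacked CSD data vectors for B parameter sets.

    Returns ``(vectors, stable)``: vectors has shape (B, L) in the
    :func:`csd_to_vector` stacking order; rows whose A matrix is unstable
    are NaN and flagged False in ``stable``.  This is the fast path for
    finite-difference Jacobians in the inversion.
    """
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    b, _ = thetas.shape
    r = layout.n_regions
    sl = layout.slices
    # assemble A for every candidate
    a = np.zeros((b, r, r))
    for col, (i, j) in enumerate(layout.mask.offdiag_indices()):
        a[:, i, j] = thetas[:, sl["a"].start + col]
    diag = -0.5 * np.ones((b, r))
    sel = layout.mask.self_allowed
    diag[:, sel] = -0.5 * np.exp(thetas[:, sl["self_log"]][:, sel])
    a[:, np.arange(r), np.arange(r)] = diag
    stable = np.max(np.linalg.eigvals(a).real, axis=1) < -1e-12

    omega = 2.0 * np.pi * grid.freqs  # (F,)
    f = omega.size
    m = 1j * omega[None, :, None, None] * np.eye(r) - a[:, None, :, :]
    t = np.full((b, f, r, r), np.nan, dtype=complex)
    if stable.any():
        t[stable] = np.linalg.inv(m[stable])
    hemo = thetas[:, sl["hemo"]].reshape(b, r, 2)
    kappa = 0.64 * np.exp(hemo[:, :, 0])  # (B, R)
    gamma = 0.32 * np.exp(hemo[:, :, 1])
    h = kappa[:, None, :] / (
        (1j * omega[None, :, None] + kappa[:, None, :])
        * (1j * omega[None, :, None] + gamma[:, None, :])
    )  # (B, F, R)
    ht = h[:, :, :, None] * t
    neural = thetas[:, sl["neural"]]
    g_v = np.exp(neural[:, :1]) * omega[None, :] ** (
        -2.0 * expit(neural[:, 1:2])
    )  # (B, F)
    s = g_v[:, :, None, None] * np.einsum("bfrc,bfec->bfre", ht, ht.conj())
    obs = thetas[:, sl["obs"]]
    g_e = np.exp(obs[:, :1]) * omega[None, :] ** (-2.0 * expit(obs[:, 1:2]))
    s = s + g_e[:, :, None, None] * np.eye(r)
    s = 0.5 * (s + s.conj().transpose(0, 1, 3, 2))

    chunks = []
    for i in range(r):
        for j in range(i, r):
            chunks.append(s[:, :, i, j].real)
            if j > i:
                chunks.append(s[:, :, i, j].imag)
    return np.concatenate(chunks, axis=1), stable


def csd_to_vector(csd: CrossSpectra) -> tuple[np.ndarray, np.ndarray]:
    """Stack a CSD into a real vector with per-element mode labels.

    Real parts of all upper-triangular entries (including the diagonal) plus
    imaginary parts of the strict upper triangle, across frequencies.  The
    mode label indexes the region pair, shared between real and imaginary
    parts — one residual-precision hyperparameter per pair.
    """
    f, r = csd.csd.shape[0], csd.n_regions
    chunks, modes = [], []
    mode = 0
    for i in range(r):
        for j in range(i, r):
            chunks.append(csd.csd[:, i, j].real)
            modes.append(np.full(f, mode))
            if j > i:
                chunks.append(csd.csd[:, i, j].imag)
                modes.append(np.full(f, mode))
            mode += 1
    return np.concatenate(chunks), np.concatenate(modes).astype(int)


def explained_variance(data: CrossSpectra, fitted: CrossSpectra) -> float:
    """1 - SS(residual)/SS(data) over the stacked real/imaginary CSD."""
    if data.csd.shape != fitted.csd.shape:
        raise ModelError("data and fitted CSD shapes differ")
    if not np.allclose(data.grid.freqs, fitted.grid.freqs):
        raise ModelError("data and fitted grids differ")
    y, _ = csd_to_vector(data)
    g, _ = csd_to_vector(fitted)
    ss_data = float(np.sum(y**2))
    if ss_data <= 0:
        raise ModelError("data sum of squares is zero")
    return 1.0 - float(np.sum((y - g) ** 2)) / ss_data
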
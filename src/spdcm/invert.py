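"""Variational-Laplace inversion of the spectral DCM.

The posterior over the packed parameter vector is approximated by a
Gaussian whose mode is found by damped Gauss-Newton (Levenberg-Marquardt)
ascent on the free energy

    F = log-likelihood accuracy - KL(posterior || prior)

with residual-precision hyperparameters (one log-precision per region-pair
data mode) estimated jointly by Newton steps in the same loop.  Steps are
accepted only when F does not decrease, so the free-energy sequence over
accepted iterations is non-decreasing by construction.

Non-convergence never excludes a subject; the best-so-far posterior is
returned flagged as not converged.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np

from .model import (
    DcmPosterior,
    DcmPriors,
    ParamLayout,
    StabilityError,
    csd_to_vector,
    predict_csd,
)
from .spectra import CrossSpectra


@dataclass(frozen=True)
class InversionSettings:
    max_iter: int = 128
    f_tol: float = 1e-2  # convergence: |dF| < f_tol for tol_streak accepted steps
    tol_streak: int = 3
    damping0: float = 1.0 / 32.0
    fd_step: float = 1e-4  # central finite-difference step per parameter
    max_rejects: int = 8
    lambda_prior_var: float = 1.0
    lambda_clip: float = 12.0


class InversionWarning(UserWarning):
    pass


def _jacobian(theta, layout, grid, step):
    """Prediction and central finite-difference Jacobian, batched.

    Perturbations that destabilize A fall back to a one-sided difference;
    an unstable center raises :class:`StabilityError`.
    """
    from .model import predict_csd_vectors

    n = theta.size
    batch = np.concatenate(
        [theta[None], theta[None] + step * np.eye(n), theta[None] - step * np.eye(n)]
    )
    vecs, stable = predict_csd_vectors(batch, layout, grid)
    if not stable[0]:
        raise StabilityError("A unstable at the current parameter estimate")
    g0 = vecs[0]
    cols = np.empty((g0.size, n))
    for k in range(n):
        up, lo = 1 + k, 1 + n + k
        if stable[up] and stable[lo]:
            cols[:, k] = (vecs[up] - vecs[lo]) / (2 * step)
        elif stable[up]:
            cols[:, k] = (vecs[up] - g0) / step
        elif stable[lo]:
            cols[:, k] = (g0 - vecs[lo]) / step
        else:
            cols[:, k] = 0.0
    return g0, cols


def _free_energy(e, pi_elem, theta, pm, p0, lam, lam_var, sigma_q_logdet):
    """Laplace free energy up to parameter-independent constants."""
    n = e.size
    accuracy = -0.5 * float(e @ (pi_elem * e)) + 0.5 * float(np.sum(np.log(pi_elem)))
    accuracy -= 0.5 * n * np.log(2 * np.pi)
    d = theta - pm
    complexity = -0.5 * float(d @ (p0 * d)) + 0.5 * float(np.sum(np.log(p0)))
    hyper = -0.5 * float(np.sum(lam**2)) / lam_var
    return accuracy + complexity + hyper + 0.5 * sigma_q_logdet + 0.5 * theta.size


def _scale_to_prior(data: CrossSpectra, layout: ParamLayout, priors: DcmPriors):
    """Rescale the data CSD so its overall level matches the prior-mean
    prediction; amplitudes are log-parameterized, so this only centers them
    on their priors (explained variance is scale-invariant)."""
    pred = predict_csd(priors.mean, layout, data.grid)
    num = float(np.mean(np.abs(np.diagonal(data.csd, axis1=1, axis2=2).real)))
    den = float(np.mean(np.abs(np.diagonal(pred.csd, axis1=1, axis2=2).real)))
    if num <= 0:
        return data
    return dataclasses.replace(data, csd=data.csd * (den / num))


def fit_subject(
    ts,
    layout: ParamLayout,
    priors: DcmPriors | None = None,
    settings: InversionSettings = InversionSettings(),
    mar_order: int = 8,
    grid=None,
) -> DcmPosterior:
    """Whole first-level pipeline for one subject: condition the series
    (linear detrend, common-scale normalization), fit the MAR spectral
    features on the default grid, and invert the spectral DCM."""
    from .cohort import standardize_series
    from .spectra import default_grid, fit_mar, mar_to_csd

    ts = standardize_series(ts, scale="global")
    if grid is None:
        grid = default_grid(ts.tr, n_volumes=ts.n_volumes)
    csd = mar_to_csd(fit_mar(ts, order=mar_order), grid, ts.tr)
    return invert_subject(csd, layout, priors, settings)


def invert_subject(
    data: CrossSpectra,
    layout: ParamLayout,
    priors: DcmPriors | None = None,
    settings: InversionSettings = InversionSettings(),
) -> DcmPosterior:
    """Fit the spectral DCM to one subject's cross spectra."""
    from .model import default_priors, explained_variance  # cycle-free late import

    if priors is None:
        priors = default_priors(layout)
    if priors.mean.size != layout.n_params:
        raise ValueError("priors layout does not match mask")
    if data.n_regions != layout.n_regions:
        raise ValueError("data R does not match mask")
    data = _scale_to_prior(data, layout, priors)
    grid = data.grid
    y, modes = csd_to_vector(data)
    n_modes = int(modes.max()) + 1

    theta = priors.mean.copy()
    p0 = 1.0 / priors.var
    lam = np.zeros(n_modes)
    nu = settings.damping0

    def elem_precision(lam):
        return np.exp(lam)[modes]

    g, jac = _jacobian(theta, layout, grid, settings.fd_step)
    e = y - g

    def curvature(jac, lam):
        pi = elem_precision(lam)
        return jac.T @ (pi[:, None] * jac) + np.diag(p0)

    def posterior_logdet(h):
        sign, logdet = np.linalg.slogdet(h)
        return -logdet  # log det of Sigma_q = H^-1

    h = curvature(jac, lam)
    f_cur = _free_energy(
        e, elem_precision(lam), theta, priors.mean, p0, lam,
        settings.lambda_prior_var, posterior_logdet(h),
    )

    streak = 0
    converged = False
    best = (f_cur, theta.copy(), h.copy())
    f_history = [f_cur]
    for _ in range(settings.max_iter):
        # ---- hyperparameter (log-precision) Newton updates, guarded by F
        sigma_q = np.linalg.inv(h)
        jt_j_diag = np.einsum("ij,jk,ik->i", jac, sigma_q, jac)
        lam_new = lam.copy()
        for m in range(n_modes):
            sel = modes == m
            sse = float(np.sum(e[sel] ** 2) + np.sum(jt_j_diag[sel]))
            n_m = int(np.sum(sel))
            lm = lam_new[m]
            for _ in range(4):
                grad = -0.5 * np.exp(lm) * sse + 0.5 * n_m - lm / settings.lambda_prior_var
                hess = -0.5 * np.exp(lm) * sse - 1.0 / settings.lambda_prior_var
                stp = np.clip(-grad / hess, -2.0, 2.0)
                lm = float(np.clip(lm + stp, -settings.lambda_clip, settings.lambda_clip))
            lam_new[m] = lm
        h_new = curvature(jac, lam_new)
        f_new = _free_energy(
            e, elem_precision(lam_new), theta, priors.mean, p0, lam_new,
            settings.lambda_prior_var, posterior_logdet(h_new),
        )
        if f_new >= f_cur - 1e-9:
            lam, h, f_cur = lam_new, h_new, f_new

        # ---- Gauss-Newton parameter step with Levenberg-Marquardt damping
        pi = elem_precision(lam)
        grad = jac.T @ (pi * e) - p0 * (theta - priors.mean)
        accepted = False
        for _ in range(settings.max_rejects):
            h_damped = h + nu * np.diag(np.diag(h))
            try:
                step = np.linalg.solve(h_damped, grad)
            except np.linalg.LinAlgError:
                nu *= 2
                continue
            theta_try = theta + step
            try:
                g_try, jac_try = _jacobian(theta_try, layout, grid, settings.fd_step)
            except StabilityError:
                nu *= 2
                continue
            e_try = y - g_try
            h_try = curvature(jac_try, lam)
            f_try = _free_energy(
                e_try, pi, theta_try, priors.mean, p0, lam,
                settings.lambda_prior_var, posterior_logdet(h_try),
            )
            if f_try >= f_cur - 1e-9:
                df = f_try - f_cur
                theta, g, jac, e, h, f_cur = theta_try, g_try, jac_try, e_try, h_try, f_try
                nu = max(nu / 2, 1e-8)
                accepted = True
                streak = streak + 1 if abs(df) < settings.f_tol else 0
                break
            nu *= 2
        f_history.append(f_cur)
        if f_cur > best[0]:
            best = (f_cur, theta.copy(), h.copy())
        if accepted and streak >= settings.tol_streak:
            converged = True
            break
        if not accepted:
            streak += 1  # no improving step found at any damping: stationary
            if streak >= settings.tol_streak:
                converged = True
                break

    if not converged:
        warnings.warn(
            "inversion did not converge; returning best-so-far posterior",
            InversionWarning,
        )
        f_cur, theta, h = best

    cov = np.linalg.inv(h)
    cov = 0.5 * (cov + cov.T)
    fitted = predict_csd(theta, layout, grid)
    ev = explained_variance(data, fitted)
    return DcmPosterior(
        mean=theta,
        cov=cov,
        free_energy=float(f_cur),
        explained_variance=float(ev),
        converged=converged,
        layout=layout,
        f_history=tuple(f_history),
    )
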
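"""Hierarchical (parametric empirical Bayes) group inference.

Subjects' first-level Gaussian posteriors over coupling parameters are
treated as noisy observations of subject-specific effects generated by a
Bayesian general linear model over covariates (mean, age, group, age-by-
group interaction, framewise displacement, optional site dummies):

    theta_i = (x_i^T kron I_K) beta + eps_i,   eps_i ~ N(0, exp(-lambda) I)

The between-subject log-precision lambda is estimated by maximizing the
(exact, conjugate-Gaussian) model evidence; the first-level posterior
covariances enter the likelihood, so first-level uncertainty propagates to
the group level.  Nested effect structures are scored by Bayesian model
reduction and combined by Bayesian model averaging; an effect is called
significant when its 90% credible interval excludes zero, equivalently when
its posterior probability exceeds 0.90.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .cohort import ParticipantRecord

Z90 = 1.6449  # 95th percentile of the standard normal: 90% two-sided CI


class DesignError(ValueError):
    pass


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

GROUP_CODE = {"ASD": +0.5, "TD": -0.5}


def _zscore(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    if sd < 1e-12:
        raise DesignError(f"column {name!r} has zero variance")
    return (x - x.mean()) / sd


@dataclass(frozen=True)
class PebDesign:
    matrix: np.ndarray  # (N, P)
    column_labels: tuple[str, ...]
    site_mode: str = "none"

    def __post_init__(self):
        x = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", x)
        object.__setattr__(self, "column_labels", tuple(self.column_labels))
        if x.ndim != 2 or x.shape[1] != len(self.column_labels):
            raise DesignError("matrix/labels mismatch")
        if self.column_labels[0] != "mean" or not np.allclose(x[:, 0], 1.0):
            raise DesignError("first column must be the all-ones mean")
        rank = np.linalg.matrix_rank(x)
        if rank < x.shape[1]:
            # name the collinear columns via QR pivoting
            _, r = np.linalg.qr(x)
            bad = [
                self.column_labels[j]
                for j in range(x.shape[1])
                if abs(r[j, j]) < 1e-8 * max(1.0, abs(r[0, 0]))
            ]
            raise DesignError(f"design is rank deficient; collinear columns: {bad}")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.matrix.shape[1]


def _site_dummies(
    sites: list[str], against: np.ndarray | None
) -> tuple[np.ndarray, list[str]]:
    """S-1 centered dummy columns (reference = most populous site); when
    ``against`` is given, each dummy is Gram-Schmidt orthogonalized against
    those columns and then against previously processed dummies."""
    counts = pd.Series(sites).value_counts()
    if len(counts) < 2:
        raise DesignError("site dummies require at least 2 sites")
    reference = counts.index[0]
    labels = [s for s in counts.index if s != reference]
    cols = []
    basis = None
    if against is not None:
        q, _ = np.linalg.qr(against)  # orthonormal span of the age columns
        basis = [q[:, j] for j in range(q.shape[1])]
    for s in labels:
        col = np.asarray([1.0 if x == s else 0.0 for x in sites])
        col = col - col.mean()
        if basis is not None:
            for b in basis:
                col = col - float(col @ b) * b
            nrm = np.linalg.norm(col)
            if nrm > 1e-10:
                basis.append(col / nrm)
        cols.append(col)
    return np.stack(cols, axis=1), [f"site_{s}" for s in labels]


def build_design(
    records: list[ParticipantRecord],
    site_mode: str = "none",
) -> PebDesign:
    """Main between-subject design: [mean, age, group, age x group, FD, sites].

    Age and FD are z-scored; group is coded ASD = +0.5, TD = -0.5 (so the
    interaction reads as the group difference in age slope); the interaction
    is the elementwise product of the coded columns, mean-centered.  Site
    handling: ``none``, ``dummies`` (S-1 centered dummies, reference = most
    populous site), or ``orthogonalized`` (dummies successively
    orthogonalized against the age-bearing columns, then each other).
    """
    if len(records) < 2:
        raise DesignError("need at least 2 subjects")
    if site_mode not in ("none", "dummies", "orthogonalized"):
        raise DesignError(f"unknown site_mode {site_mode!r}")
    age = _zscore([r.age for r in records], "age")
    group = np.asarray([GROUP_CODE[r.group] for r in records])
    group = group - group.mean()
    inter = age * np.asarray([GROUP_CODE[r.group] for r in records])
    inter = inter - inter.mean()
    fd = _zscore([r.mean_fd for r in records], "FD")
    cols = [np.ones(len(records)), age, group, inter, fd]
    labels = ["mean", "age", "group", "age_x_group", "FD"]
    if site_mode != "none":
        against = (
            np.stack([age, inter], axis=1) if site_mode == "orthogonalized" else None
        )
        dummies, dlabels = _site_dummies([r.site for r in records], against)
        cols.append(dummies)
        labels += dlabels
        matrix = np.column_stack(cols)
    else:
        matrix = np.stack(cols, axis=1)
    return PebDesign(matrix, labels, site_mode=site_mode)


def build_within_group_age_design(
    records: list[ParticipantRecord],
    site_mode: str = "none",
) -> PebDesign:
    """Within-group age design: [mean, group, age_TD, age_ASD, FD, sites].

    age_g is the group-wise-centered age (scaled by the pooled SD of the
    group-centered ages) masked to group g, so the two columns sum to the
    overall group-wise-centered age column.
    """
    groups = {r.group for r in records}
    if groups != {"ASD", "TD"}:
        raise DesignError("both groups must be present")
    age = np.asarray([r.age for r in records], dtype=float)
    gvec = np.asarray([r.group for r in records])
    centered = age.copy()
    for g in ("ASD", "TD"):
        centered[gvec == g] -= age[gvec == g].mean()
    sd = centered.std(ddof=0)
    if sd < 1e-12:
        raise DesignError("age has zero within-group variance")
    centered /= sd
    group = np.asarray([GROUP_CODE[r.group] for r in records])
    group = group - group.mean()
    age_td = np.where(gvec == "TD", centered, 0.0)
    age_asd = np.where(gvec == "ASD", centered, 0.0)
    fd = _zscore([r.mean_fd for r in records], "FD")
    cols = [np.ones(len(records)), group, age_td, age_asd, fd]
    labels = ["mean", "group", "age_TD", "age_ASD", "FD"]
    if site_mode != "none":
        against = (
            np.stack([age_td, age_asd], axis=1)
            if site_mode == "orthogonalized"
            else None
        )
        dummies, dlabels = _site_dummies([r.site for r in records], against)
        cols.append(dummies)
        labels += dlabels
        matrix = np.column_stack(cols)
    else:
        matrix = np.stack(cols, axis=1)
    return PebDesign(matrix, labels, site_mode=site_mode)


# ---------------------------------------------------------------------------
# PEB fit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Peb2ndLevelPriors:
    beta_var: float = 1.0 / 16.0  # N(0, 1/16) per second-level effect
    lambda_prior_var: float = 1.0  # N(0, 1) on the between-subject log-precision


@dataclass
class PebResult:
    """Posterior over second-level effects beta (K connections x P covariates).

    ``beta_cov`` is the full covariance over vec(beta) with index p*K + k.
    """

    beta_mean: np.ndarray  # (K, P)
    beta_cov: np.ndarray  # (KP, KP)
    prior_mean: np.ndarray  # (KP,)
    prior_var: np.ndarray  # (KP,)
    lambda_between: float
    free_energy: float
    design: PebDesign
    connection_names: list[str]

    @property
    def n_connections(self) -> int:
        return self.beta_mean.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.beta_mean.shape[1]

    def vec_index(self, k: int, p: int) -> int:
        return p * self.n_connections + k


def _gather_first_level(posteriors, subset):
    means, covs = [], []
    for idx, post in enumerate(posteriors):
        if hasattr(post, "coupling_mean"):
            m = post.coupling_mean()
            c = post.coupling_cov()
        else:  # (mean, cov) pair, e.g. synthetic first-level posteriors
            m, c = post
            m, c = np.asarray(m, float), np.asarray(c, float)
        if subset is not None:
            m = m[subset]
            c = c[np.ix_(subset, subset)]
        if np.min(np.linalg.eigvalsh(0.5 * (c + c.T))) <= 0:
            raise ValueError(f"non-PD first-level covariance for subject index {idx}")
        means.append(m)
        covs.append(0.5 * (c + c.T))
    return np.stack(means), np.stack(covs)


def fit_peb(
    posteriors,
    design: PebDesign,
    subset: list[int] | None = None,
    priors2: Peb2ndLevelPriors = Peb2ndLevelPriors(),
    connection_names: list[str] | None = None,
    lambda_mode: str = "single",
) -> PebResult:
    """Empirical-Bayes fit of the second-level GLM over subjects.

    ``posteriors`` are first-level :class:`DcmPosterior` objects (their
    coupling sub-posterior is used) or plain ``(mean, cov)`` pairs.
    ``lambda_mode="single"`` uses one between-subject log-precision shared
    by all connections; ``"per_connection"`` gives each connection its own
    component (coordinate-wise evidence ascent), which matters when the
    between-subject spread differs strongly across connections.
    """
    means, covs = _gather_first_level(posteriors, subset)
    n, k = means.shape
    if design.n_subjects != n:
        raise ValueError(
            f"design has {design.n_subjects} rows but {n} posteriors given"
        )
    if lambda_mode not in ("single", "per_connection"):
        raise ValueError(f"unknown lambda_mode {lambda_mode!r}")
    x = design.matrix
    p = x.shape[1]
    kp = k * p
    s0_inv = np.full(kp, 1.0 / priors2.beta_var)

    def evidence(lam_vec: np.ndarray):
        sb = np.diag(np.exp(-lam_vec))
        prec = np.diag(s0_inv).astype(float)
        b = np.zeros(kp)
        quad = 0.0
        logdet_v = 0.0
        for i in range(n):
            v_i = covs[i] + sb
            w = np.linalg.inv(v_i)
            logdet_v += float(np.linalg.slogdet(v_i)[1])
            prec += np.kron(np.outer(x[i], x[i]), w)
            wm = w @ means[i]
            b += np.kron(x[i], wm)
            quad += float(means[i] @ wm)
        cf = np.linalg.cholesky(0.5 * (prec + prec.T))
        beta_hat = np.linalg.solve(prec, b)
        logdet_prec = 2.0 * float(np.sum(np.log(np.diag(cf))))
        logdet_s0 = -float(np.sum(np.log(s0_inv)))
        log_ev = (
            -0.5 * (quad - float(b @ beta_hat))
            - 0.5 * logdet_v
            - 0.5 * logdet_s0
            - 0.5 * logdet_prec
            - 0.5 * n * k * np.log(2 * np.pi)
        )
        f = log_ev - 0.5 * float(lam_vec @ lam_vec) / priors2.lambda_prior_var
        return f, beta_hat, prec

    res = minimize_scalar(
        lambda lam: -evidence(np.full(k, lam))[0],
        bounds=(-8.0, 12.0), method="bounded", options={"xatol": 1e-3},
    )
    lam_vec = np.full(k, float(res.x))
    if lambda_mode == "per_connection":
        for _ in range(3):  # coordinate-wise evidence ascent sweeps
            for j in range(k):
                def neg(lj, j=j):
                    trial = lam_vec.copy()
                    trial[j] = lj
                    return -evidence(trial)[0]
                r = minimize_scalar(neg, bounds=(-8.0, 12.0), method="bounded",
                                    options={"xatol": 1e-2})
                lam_vec[j] = float(r.x)
    lam = float(np.mean(lam_vec))
    f, beta_hat, prec = evidence(lam_vec)
    beta_cov = np.linalg.inv(prec)
    beta_cov = 0.5 * (beta_cov + beta_cov.T)
    if connection_names is None:
        connection_names = [f"theta_{i}" for i in range(k)]
    return PebResult(
        beta_mean=beta_hat.reshape(p, k).T,
        beta_cov=beta_cov,
        prior_mean=np.zeros(kp),
        prior_var=np.full(kp, priors2.beta_var),
        lambda_between=lam,
        free_energy=float(f),
        design=design,
        connection_names=list(connection_names),
    )


# ---------------------------------------------------------------------------
# Bayesian model reduction
# ---------------------------------------------------------------------------


def bayesian_model_reduction(
    prior_mean: np.ndarray,
    prior_cov: np.ndarray,
    post_mean: np.ndarray,
    post_cov: np.ndarray,
    red_prior_mean: np.ndarray,
    red_prior_cov: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Posterior and evidence change of a model with a reduced (nested) prior.

    Uses the closed-form Gaussian identity: the likelihood implied by the
    full prior/posterior pair is combined with the reduced prior.  Covariance
    arguments may be 1-D (diagonal) or 2-D.  Returns (reduced posterior mean,
    reduced posterior covariance, delta log-evidence); a non-positive-definite
    reduced precision yields delta log-evidence of -inf.
    """

    def as_cov(c, dim):
        c = np.asarray(c, dtype=float)
        return np.diag(c) if c.ndim == 1 else c

    m0 = np.asarray(prior_mean, float)
    dim = m0.size
    c0 = as_cov(prior_cov, dim)
    m = np.asarray(post_mean, float)
    c = as_cov(post_cov, dim)
    m0r = np.asarray(red_prior_mean, float)
    c0r = as_cov(red_prior_cov, dim)

    p0 = np.linalg.inv(c0)
    pp = np.linalg.inv(c)
    p0r = np.linalg.inv(c0r)
    h = pp @ m - p0 @ m0  # likelihood natural mean
    pr = pp - p0 + p0r
    try:
        np.linalg.cholesky(0.5 * (pr + pr.T))
    except np.linalg.LinAlgError:
        return m, c, -np.inf
    mr = np.linalg.solve(pr, h + p0r @ m0r)
    cr = np.linalg.inv(pr)
    cr = 0.5 * (cr + cr.T)

    def logdet(a):
        return float(np.linalg.slogdet(a)[1])

    df = 0.5 * (logdet(p0r) - logdet(pr) - logdet(p0) + logdet(pp)) + 0.5 * (
        float(mr @ pr @ mr)
        - float(m0r @ p0r @ m0r)
        - float(m @ pp @ m)
        + float(m0 @ p0 @ m0)
    )
    return mr, cr, float(df)


# ---------------------------------------------------------------------------
# Bayesian model averaging over nested effect structures
# ---------------------------------------------------------------------------

OFF_PRIOR_VAR = 1e-8  # "switched off" = reduced prior variance on the entry


@dataclass
class BmaResult:
    """Model-averaged second-level effects and the decision-rule outputs.

    ``posterior_prob`` is the probability that the sign of the effect is
    determined by the moment-matched BMA posterior, 2*Phi(|m|/sd) - 1, which
    makes ``posterior_prob > 0.90``, ``significant`` and "the 90% credible
    interval (mean +/- 1.6449 sd) excludes zero" exactly equivalent.  The
    model-space retention probability from BMR is reported alongside.
    """

    effect_mean: np.ndarray  # (K, P)
    effect_sd: np.ndarray
    posterior_prob: np.ndarray
    retention_prob: np.ndarray
    ci90_low: np.ndarray
    ci90_high: np.ndarray
    significant: np.ndarray  # bool
    connection_names: list[str]
    covariate_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, cn in enumerate(self.connection_names):
            for p, pn in enumerate(self.covariate_names):
                rows.append(
                    {
                        "connection": cn,
                        "covariate": pn,
                        "effect": self.effect_mean[k, p],
                        "sd": self.effect_sd[k, p],
                        "posterior_prob": self.posterior_prob[k, p],
                        "retention_prob": self.retention_prob[k, p],
                        "ci_low": self.ci90_low[k, p],
                        "ci_high": self.ci90_high[k, p],
                        "significant": bool(self.significant[k, p]),
                        "label": decision_rule(
                            self.effect_mean[k, p],
                            max(self.effect_sd[k, p], 1e-12),
                            self.posterior_prob[k, p],
                        ),
                    }
                )
        return pd.DataFrame(rows)


def _reduced_prior(peb: PebResult, off: np.ndarray):
    var = peb.prior_var.copy()
    var[off] = OFF_PRIOR_VAR
    return peb.prior_mean, var


def _score(peb: PebResult, off_mask: np.ndarray):
    m0, v0 = peb.prior_mean, peb.prior_var
    m0r, v0r = _reduced_prior(peb, off_mask)
    k = peb.n_connections
    vec_mean = peb.beta_mean.T.reshape(-1)
    return bayesian_model_reduction(
        m0, v0, vec_mean, peb.beta_cov, m0r, v0r
    )


def bma_search(
    peb: PebResult,
    search: str = "greedy",
    max_models: int = 2**16,
    searchable: list[int] | None = None,
) -> BmaResult:
    """Search nested effect structures and average them by evidence.

    Candidate models switch off subsets of vec(beta) entries (reduced prior
    variance ~0).  ``greedy`` iteratively prunes the entry whose removal most
    increases evidence, then averages over the 2^min(8, n) neighborhood of
    the entries with the weakest evidence contribution; ``exhaustive``
    enumerates all subsets (<= ``max_models``).  Averaging weights are the
    softmax of log evidences; moment-matched mixture mean/sd feed the
    decision rule.
    """
    kp = peb.beta_cov.shape[0]
    effects = np.arange(kp) if searchable is None else np.asarray(searchable, int)
    ne = effects.size

    def model_eval(off_bool):
        mr, cr, df = _score(peb, off_bool)
        return mr, cr, df

    models: list[tuple[np.ndarray, np.ndarray, np.ndarray, float]] = []
    if search == "exhaustive":
        if 2**ne > max_models:
            raise ValueError(
                f"exhaustive search over {ne} effects exceeds the {max_models} cap"
            )
        for bits in product([False, True], repeat=ne):
            off = np.zeros(kp, dtype=bool)
            off[effects[np.asarray(bits)]] = True
            mr, cr, df = model_eval(off)
            models.append((off, mr, cr, df))
    elif search == "greedy":
        off = np.zeros(kp, dtype=bool)
        improved = True
        while improved:
            improved = False
            base_mr, base_cr, base_df = model_eval(off)
            best_gain, best_j = 0.0, -1
            for j in effects:
                if off[j]:
                    continue
                trial = off.copy()
                trial[j] = True
                _, _, df = model_eval(trial)
                if df - base_df > best_gain + 1e-10:
                    best_gain, best_j = df - base_df, j
            if best_j >= 0:
                off[best_j] = True
                improved = True
        # neighborhood: the <=8 searchable effects whose single toggle moves
        # the evidence least (the least decided entries)
        base_mr, base_cr, base_df = model_eval(off)
        sensitivities = []
        for j in effects:
            trial = off.copy()
            trial[j] = ~trial[j]
            _, _, df = model_eval(trial)
            sensitivities.append((abs(df - base_df), j))
        sensitivities.sort()
        neigh = [j for _, j in sensitivities[: min(8, ne)]]
        for bits in product([False, True], repeat=len(neigh)):
            trial = off.copy()
            for b, j in zip(bits, neigh):
                trial[j] = b
            mr, cr, df = model_eval(trial)
            models.append((trial, mr, cr, df))
    else:
        raise ValueError(f"unknown search mode {search!r}")

    log_ev = np.asarray([m[3] for m in models])
    finite = np.isfinite(log_ev)
    log_ev = np.where(finite, log_ev, -np.inf)
    w = np.exp(log_ev - np.max(log_ev[finite]))
    w /= w.sum()

    mean = np.zeros(kp)
    second = np.zeros(kp)
    retain = np.zeros(kp)
    for wi, (off, mr, cr, _) in zip(w, models):
        if wi == 0:
            continue
        mean += wi * mr
        second += wi * (np.diag(cr) + mr**2)
        retain += wi * (~off)
    var = np.maximum(second - mean**2, 0.0)
    sd = np.sqrt(var)

    k, p = peb.n_connections, peb.n_covariates
    mean_kp = mean.reshape(p, k).T
    sd_kp = sd.reshape(p, k).T
    retain_kp = retain.reshape(p, k).T
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(mean_kp) / np.where(sd_kp > 0, sd_kp, np.inf)
    pprob = 2.0 * norm.cdf(z) - 1.0
    ci_low = mean_kp - Z90 * sd_kp
    ci_high = mean_kp + Z90 * sd_kp
    significant = pprob > 0.90
    return BmaResult(
        effect_mean=mean_kp,
        effect_sd=sd_kp,
        posterior_prob=pprob,
        retention_prob=retain_kp,
        ci90_low=ci_low,
        ci90_high=ci_high,
        significant=significant,
        connection_names=peb.connection_names,
        covariate_names=list(peb.design.column_labels),
    )


def decision_rule(effect_mean: float, effect_sd: float, posterior_prob: float) -> str:
    """significant iff P > 0.90; trend iff 0.80 < P <= 0.90; else null."""
    if effect_sd <= 0:
        raise ValueError("effect_sd must be positive")
    if not 0.0 <= posterior_prob <= 1.0:
        raise ValueError("posterior_prob must be in [0, 1]")
    if posterior_prob > 0.90:
        return "significant"
    if posterior_prob > 0.80:
        return "trend"
    return "null"
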
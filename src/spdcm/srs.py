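"""Symptom-severity association stage.

Relates per-subject connection strengths (first-level posterior means) to
total SRS score: a Gaussian linear mixed model with a site random intercept
(fixed effects: intercept, SRS, age, SRS x age, FD), Benjamini-Hochberg FDR
over the tested connections, the +/-1 SD SRS stratification used for
presentation, and a PEB variant with an SRS x age design that honors
first-level uncertainty.

The mixed model is fitted by restricted maximum likelihood, profiled over
the single variance ratio rho = sigma_site^2 / sigma_e^2 (1-D bounded
optimization); fixed effects are tested by Wald statistics on
between-within denominator degrees of freedom, df = N - p - (n_sites - 1).
Subjects with missing SRS are excluded from this stage only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import t as t_dist

from .cohort import ParticipantRecord
from .peb import PebDesign, Peb2ndLevelPriors, _site_dummies, _zscore, bma_search, fit_peb


class SrsError(ValueError):
    pass


@dataclass
class LmmResult:
    """Fixed effects and variance components of one random-intercept fit."""

    terms: pd.DataFrame  # term, estimate, se, t, df, p
    sigma2_site: float
    sigma2_resid: float
    n_subjects: int
    n_sites: int

    def p_value(self, term: str) -> float:
        row = self.terms.loc[self.terms["term"] == term]
        if row.empty:
            raise KeyError(term)
        return float(row["p"].iloc[0])


def _site_matrices(site_labels):
    sites = pd.Series(site_labels).astype(str)
    groups = {s: np.flatnonzero((sites == s).to_numpy()) for s in sites.unique()}
    return groups


def fit_lmm_random_intercept(
    y: np.ndarray,
    x: np.ndarray,
    term_names: list[str],
    site_labels,
    force_zero_site_variance: bool = False,
) -> LmmResult:
    """REML fit of y = X b + u_site + e with a single random intercept."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    if y.shape != (n,):
        raise SrsError("y/X shape mismatch")
    if np.linalg.matrix_rank(x) < p:
        raise SrsError("singular fixed-effect design")
    groups = _site_matrices(site_labels)
    n_sites = len(groups)
    if n_sites < 2 and not force_zero_site_variance:
        raise SrsError("need at least 2 sites for a site random intercept")

    def gls(rho):
        """Weighted normal equations for V = I + rho * J (blockwise)."""
        xtvx = np.zeros((p, p))
        xtvy = np.zeros(p)
        ytvy = 0.0
        logdet_v = 0.0
        for idx in groups.values():
            ns = idx.size
            shrink = rho / (1.0 + rho * ns)
            xs, ys = x[idx], y[idx]
            xm, ym = xs.sum(axis=0), ys.sum()
            xtvx += xs.T @ xs - shrink * np.outer(xm, xm)
            xtvy += xs.T @ ys - shrink * xm * ym
            ytvy += ys @ ys - shrink * ym * ym
            logdet_v += np.log1p(rho * ns)
        return xtvx, xtvy, ytvy, logdet_v

    def neg_reml(log_rho):
        rho = np.exp(log_rho)
        xtvx, xtvy, ytvy, logdet_v = gls(rho)
        beta = np.linalg.solve(xtvx, xtvy)
        rss = ytvy - xtvy @ beta
        sigma2 = max(rss / (n - p), 1e-300)
        sign, logdet_xx = np.linalg.slogdet(xtvx)
        return 0.5 * ((n - p) * np.log(sigma2) + logdet_v + logdet_xx)

    if force_zero_site_variance:
        rho = 0.0
    else:
        res = minimize_scalar(
            neg_reml, bounds=(-12.0, 12.0), method="bounded", options={"xatol": 1e-6}
        )
        rho = float(np.exp(res.x))
        if neg_reml(-30.0) <= res.fun:  # boundary: no site variance supported
            rho = 0.0

    xtvx, xtvy, ytvy, _ = gls(rho)
    beta = np.linalg.solve(xtvx, xtvy)
    rss = ytvy - xtvy @ beta
    sigma2 = rss / (n - p)
    cov_beta = sigma2 * np.linalg.inv(xtvx)
    se = np.sqrt(np.diag(cov_beta))
    df = n - p - (n_sites - 1)
    if df < 1:
        raise SrsError("non-positive residual degrees of freedom")
    tval = beta / se
    pval = 2.0 * t_dist.sf(np.abs(tval), df)
    terms = pd.DataFrame(
        {"term": term_names, "estimate": beta, "se": se, "t": tval, "df": df, "p": pval}
    )
    return LmmResult(
        terms=terms,
        sigma2_site=float(rho * sigma2),
        sigma2_resid=float(sigma2),
        n_subjects=n,
        n_sites=n_sites,
    )


def srs_design(records: list[ParticipantRecord]):
    """Fixed-effect design [1, SRS, age, SRS x age, FD] on SRS-complete rows."""
    kept = [r for r in records if r.srs_total is not None]
    if len(kept) < 5:
        raise SrsError("too few SRS-complete subjects")
    srs = _zscore([r.srs_total for r in kept], "SRS")
    age = _zscore([r.age for r in kept], "age")
    fd = _zscore([r.mean_fd for r in kept], "FD")
    inter = srs * age
    inter = inter - inter.mean()
    x = np.column_stack([np.ones(len(kept)), srs, age, inter, fd])
    names = ["intercept", "SRS", "age", "SRS_x_age", "FD"]
    return kept, x, names


def fit_lmm_for_connections(
    strengths: pd.DataFrame,
    records: list[ParticipantRecord],
    tested_term: str = "SRS_x_age",
) -> pd.DataFrame:
    """Per-connection LMM table with BH-FDR over ``tested_term``.

    ``strengths`` is indexed by subject_id with one column per connection.
    """
    kept, x, names = srs_design(records)
    ids = [r.subject_id for r in kept]
    missing = [i for i in ids if i not in strengths.index]
    if missing:
        raise SrsError(f"missing connection strengths for subjects: {missing[:5]}")
    sites = [r.site for r in kept]
    rows = []
    for conn in strengths.columns:
        y = strengths.loc[ids, conn].to_numpy(dtype=float)
        fit = fit_lmm_random_intercept(y, x, names, sites)
        for _, trow in fit.terms.iterrows():
            rows.append({"connection": conn, **trow.to_dict(),
                         "sigma2_site": fit.sigma2_site})
    table = pd.DataFrame(rows)
    sel = table["term"] == tested_term
    table.loc[sel, "q"] = bh_fdr(table.loc[sel, "p"].to_numpy())
    return table


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise SrsError("empty p-value list")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise SrsError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def stratify_srs(records: list[ParticipantRecord]) -> dict[str, str]:
    """Stratify SRS-complete subjects at mean +/- 1 SD (boundaries -> mid).

    Presentation aid only, never used for inference.
    """
    kept = [r for r in records if r.srs_total is not None]
    if len(kept) < 3:
        raise SrsError("need at least 3 subjects with SRS")
    vals = np.asarray([r.srs_total for r in kept], dtype=float)
    sd = vals.std(ddof=1)
    if sd < 1e-12:
        raise SrsError("zero SRS variance")
    mean = vals.mean()
    out = {}
    for r, v in zip(kept, vals):
        if v < mean - sd:
            out[r.subject_id] = "low"
        elif v > mean + sd:
            out[r.subject_id] = "high"
        else:
            out[r.subject_id] = "mid"
    return out


def peb_srs_interaction(
    posteriors,
    records: list[ParticipantRecord],
    site_mode: str = "dummies",
    connection_names: list[str] | None = None,
    priors2: Peb2ndLevelPriors = Peb2ndLevelPriors(),
    search: str = "greedy",
):
    """PEB over the SRS-complete subsample with design
    [mean, SRS, age, SRS x age, FD, site dummies]; returns (PebResult,
    BmaResult).  ``posteriors`` must align with ``records``; subjects
    lacking SRS are dropped from both."""
    pairs = [
        (p, r) for p, r in zip(posteriors, records) if r.srs_total is not None
    ]
    if not pairs:
        raise SrsError("no SRS-complete subjects")
    posts, kept = zip(*pairs)
    srs = _zscore([r.srs_total for r in kept], "SRS")
    age = _zscore([r.age for r in kept], "age")
    fd = _zscore([r.mean_fd for r in kept], "FD")
    inter = srs * age
    inter = inter - inter.mean()
    cols = [np.ones(len(kept)), srs, age, inter, fd]
    labels = ["mean", "SRS", "age", "SRS_x_age", "FD"]
    if site_mode != "none":
        against = (
            np.stack([age, inter], axis=1) if site_mode == "orthogonalized" else None
        )
        dummies, dlabels = _site_dummies([r.site for r in kept], against)
        cols.append(dummies)
        labels += dlabels
        matrix = np.column_stack(cols)
    else:
        matrix = np.stack(cols, axis=1)
    design = PebDesign(matrix, labels, site_mode=site_mode)
    peb = fit_peb(list(posts), design, priors2=priors2, connection_names=connection_names)
    return peb, bma_search(peb, search=search)
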
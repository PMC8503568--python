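"""Synthetic multi-site cohorts with known ground truth.

Generates two-group (ASD/TD), multi-site cohorts with the demographics of
the developmental population this pipeline targets: ASD ages 17.6 (7.6)
years in [7, 50], TD 16.9 (6.6) in [6.5, 39.4], eight sites, group-separated
SRS scores (ASD 89.4 (32.4), TD 22.2 (18.1)), and mean-FD motion nuisance.
Per-subject coupling parameters are built from a baseline plus configurable
covariate effects (the default truth encodes the qualitative pattern of an
age-dependent rise in self-inhibition and fall in bottom-up coupling that is
attenuated in the ASD group), and BOLD series are sampled from the same
linear stochastic model the spectral DCM assumes, so every pipeline stage
has a recoverable truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CANONICAL_REGIONS, ParticipantRecord, RoiTimeSeries
from .model import (
    ConnectivityMask,
    ParamLayout,
    assemble_A,
    build_connectivity_mask,
    hemo_transfer,
)


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class GroupAges:
    mean: float
    sd: float
    lo: float
    hi: float


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    ``effect_table`` maps (connection name, covariate name) to a coefficient
    in Hz per SD of the covariate (per group unit for 'group'); covariates
    are {mean, age, group, age_x_group, SRS, SRS_x_age}.  ``site_age_shift``
    (years, one per site) induces age-site confounding when non-zero.
    """

    n_per_group: tuple[int, int] = (166, 193)  # (ASD, TD)
    n_sites: int = 8
    tr: float = 2.0
    n_volumes: int = 200
    region_labels: tuple[str, ...] = CANONICAL_REGIONS
    ages_asd: GroupAges = GroupAges(17.6, 7.6, 7.0, 50.0)
    ages_td: GroupAges = GroupAges(16.9, 6.6, 6.5, 39.4)
    site_age_shift: tuple[float, ...] | None = None
    effect_table: dict = field(default_factory=dict)
    baseline_bottom_up: float = 0.15
    baseline_top_down: float = 0.10
    baseline_self_log: float = 0.0
    subject_sd: float = 0.05  # Hz, residual between-subject coupling spread
    neural_log_amp: float = 0.0
    neural_exp_raw: float = 0.0  # beta = 1 power-law neuronal fluctuations
    obs_exp_raw: float = 0.0
    obs_noise_rel: float = 0.15  # observation-noise SD relative to signal SD
    fd_noise_coupling: float = 0.5  # obs amplitude multiplier 1 + c * FD
    fd_mean: float = 0.12
    fd_sd: float = 0.06
    srs_asd: tuple[float, float] = (89.4, 32.4)
    srs_td: tuple[float, float] = (22.2, 18.1)
    srs_missing_frac: float = 0.39  # fraction without an SRS score
    hemo_subject_sd: float = 0.05
    dt_factor: int = 16
    burn_in_s: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_per_group) < 1 or self.n_sites < 1 or self.n_volumes < 1:
            raise SynthError("counts must be positive")
        if self.site_age_shift is not None and len(self.site_age_shift) != self.n_sites:
            raise SynthError("site_age_shift length must equal n_sites")

    def mask(self) -> ConnectivityMask:
        return build_connectivity_mask(self.region_labels, 0)

    def layout(self) -> ParamLayout:
        return ParamLayout(self.mask())


COVARIATES = ("mean", "age", "group", "age_x_group", "SRS", "SRS_x_age")


def default_effect_table(region_labels=CANONICAL_REGIONS) -> dict:
    """Default ground truth: TD age slope +0.10/SD on every self-connection
    and -0.08 Hz/SD on every bottom-up coupling, with ASD slopes at 25% of
    TD's — encoded via the age and age-by-group terms under ASD = +0.5 /
    TD = -0.5 coding."""
    td_self, td_bu = 0.10, -0.08
    asd_frac = 0.25
    table: dict = {}
    hub = region_labels[0]
    for lab in region_labels:
        mean_slope = 0.5 * (td_self + asd_frac * td_self)
        inter = asd_frac * td_self - td_self  # ASD minus TD slope
        table[(f"self_{lab}", "age")] = mean_slope
        table[(f"self_{lab}", "age_x_group")] = inter
        if lab != hub:
            mean_slope = 0.5 * (td_bu + asd_frac * td_bu)
            inter = asd_frac * td_bu - td_bu
            table[(f"{hub}->{lab}", "age")] = mean_slope
            table[(f"{hub}->{lab}", "age_x_group")] = inter
    return table


@dataclass
class SyntheticTruth:
    """Ground truth for recovery tests: per-subject coupling vectors, the
    covariate values used to build them, and the effect table."""

    coupling: pd.DataFrame  # subjects x coupling names
    theta_full: np.ndarray  # (N, n_params) incl. noise/hemo parameters
    covariates: pd.DataFrame  # subjects x covariate names (coded values)
    effect_table: dict
    region_labels: tuple[str, ...]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "coupling": self.coupling.reset_index().to_dict(orient="list"),
            "theta_full": self.theta_full.tolist(),
            "covariates": self.covariates.reset_index().to_dict(orient="list"),
            "effect_table": {f"{k[0]}|{k[1]}": v for k, v in self.effect_table.items()},
            "region_labels": list(self.region_labels),
        }
        Path(path).write_text(json.dumps(payload))


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    todo = np.arange(size)
    for _ in range(1000):
        draw = rng.normal(mean, sd, size=todo.size)
        ok = (draw >= lo) & (draw <= hi)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
        if todo.size == 0:
            return out
    out[todo] = np.clip(rng.normal(mean, sd, size=todo.size), lo, hi)
    return out


def sample_cohort(spec: CohortSpec) -> tuple[list[ParticipantRecord], SyntheticTruth]:
    """Draw participants and their ground-truth coupling parameters."""
    rng = np.random.default_rng(spec.seed)
    mask = spec.mask()
    layout = spec.layout()
    names = mask.coupling_names()
    n_asd, n_td = spec.n_per_group
    n = n_asd + n_td
    groups = np.array(["ASD"] * n_asd + ["TD"] * n_td)
    sites = rng.integers(0, spec.n_sites, size=n)
    shift = np.zeros(spec.n_sites)
    if spec.site_age_shift is not None:
        shift = np.asarray(spec.site_age_shift, dtype=float)

    age = np.empty(n)
    for g, pars in (("ASD", spec.ages_asd), ("TD", spec.ages_td)):
        sel = groups == g
        age[sel] = _truncated_normal(
            rng, pars.mean, pars.sd, pars.lo, pars.hi, int(sel.sum())
        )
    age = np.clip(age + shift[sites], 5.0, 60.0)
    fd = np.clip(rng.normal(spec.fd_mean, spec.fd_sd, size=n), 0.01, None)
    srs = np.empty(n)
    for g, (m, s) in (("ASD", spec.srs_asd), ("TD", spec.srs_td)):
        sel = groups == g
        srs[sel] = np.clip(rng.normal(m, s, size=int(sel.sum())), 0.0, None)
    srs_missing = rng.random(n) < spec.srs_missing_frac

    # coded covariates (age in SD units, group +/-0.5, products centered only
    # through their factors — the truth is built directly from these values)
    age_z = (age - age.mean()) / age.std(ddof=0)
    gcode = np.where(groups == "ASD", 0.5, -0.5)
    srs_z = (srs - srs.mean()) / srs.std(ddof=0)
    cov = pd.DataFrame(
        {
            "mean": np.ones(n),
            "age": age_z,
            "group": gcode,
            "age_x_group": age_z * gcode,
            "SRS": srs_z,
            "SRS_x_age": srs_z * age_z,
        }
    )

    for conn, covname in spec.effect_table:
        if conn not in names:
            raise SynthError(f"effect table names unknown connection {conn!r}")
        if covname not in COVARIATES:
            raise SynthError(f"effect table names unknown covariate {covname!r}")

    baseline = np.zeros(len(names))
    hub = spec.region_labels[0]
    for idx, nm in enumerate(names):
        if nm.startswith("self_"):
            baseline[idx] = spec.baseline_self_log
        elif nm.startswith(f"{hub}->"):
            baseline[idx] = spec.baseline_bottom_up
        else:
            baseline[idx] = spec.baseline_top_down

    effects = np.zeros((len(names), len(COVARIATES)))
    for (conn, covname), coef in spec.effect_table.items():
        effects[names.index(conn), COVARIATES.index(covname)] = coef
    covmat = cov[list(COVARIATES)].to_numpy()

    records: list[ParticipantRecord] = []
    coupling = np.empty((n, len(names)))
    theta_full = np.empty((n, layout.n_params))
    n_off = layout.n_offdiag
    r = layout.n_regions
    for i in range(n):
        mean_i = baseline + effects @ covmat[i]
        for attempt in range(100):
            vec = mean_i + rng.normal(0.0, spec.subject_sd, size=len(names))
            theta = layout.pack(
                a=vec[:n_off],
                self_log=vec[n_off:],
                neural=[spec.neural_log_amp, spec.neural_exp_raw],
                obs=[0.0, spec.obs_exp_raw],  # amplitude set at simulation time
                hemo=rng.normal(0.0, spec.hemo_subject_sd, size=2 * r),
            )
            a = assemble_A(theta, layout)
            if np.max(np.linalg.eigvals(a).real) < -1e-6:
                break
        else:
            raise SynthError(
                "could not draw a stable coupling matrix in 100 tries; "
                "reduce effect sizes or subject_sd"
            )
        coupling[i] = vec
        theta_full[i] = theta
        records.append(
            ParticipantRecord(
                subject_id=f"sub-{i:04d}",
                group=str(groups[i]),
                age=float(age[i]),
                mean_fd=float(fd[i]),
                site=f"site{sites[i]:02d}",
                srs_total=None if srs_missing[i] else float(srs[i]),
                excluded_by_motion=bool(fd[i] > 0.34),
            )
        )

    ids = [rec.subject_id for rec in records]
    truth = SyntheticTruth(
        coupling=pd.DataFrame(coupling, index=ids, columns=names),
        theta_full=theta_full,
        covariates=pd.DataFrame(covmat, index=ids, columns=list(COVARIATES)),
        effect_table=dict(spec.effect_table),
        region_labels=spec.region_labels,
    )
    return records, truth


def _powerlaw_noise(rng, n, dt, log_amp, exp_raw, n_ch):
    """Real series whose two-sided spectral density is amp * omega^-beta."""
    from scipy.special import expit

    beta = 2.0 * expit(exp_raw)
    amp = np.exp(log_amp)
    w = rng.standard_normal((n, n_ch))
    wf = np.fft.rfft(w, axis=0)
    f = np.fft.rfftfreq(n, d=dt)
    gain = np.zeros_like(f)
    gain[1:] = np.sqrt(amp * (2.0 * np.pi * f[1:]) ** (-beta) / dt)
    return np.fft.irfft(wf * gain[:, None], n=n, axis=0)


def simulate_bold_from_params(
    theta: np.ndarray,
    layout: ParamLayout,
    tr: float,
    n_volumes: int,
    rng: np.random.Generator,
    dt_factor: int = 16,
    burn_in_s: float = 60.0,
) -> RoiTimeSeries:
    """Sample BOLD from the generative model: Euler-Maruyama integration of
    dx/dt = A x + v (v power-law neuronal noise), hemodynamic filtering,
    downsampling to the repetition time, and power-law observation noise."""
    parts = layout.unpack(theta)
    a = assemble_A(theta, layout)
    if np.max(np.linalg.eigvals(a).real) >= 0:
        raise SynthError("unstable A passed to the simulator")
    r = layout.n_regions
    dt = tr / dt_factor
    n_burn = int(np.ceil(burn_in_s / tr))
    n_total = (n_volumes + n_burn) * dt_factor

    v = _powerlaw_noise(
        rng, n_total, dt, parts["neural"][0], parts["neural"][1], r
    )
    # Euler recurrence x_{t+1} = (I + dt A) x_t + dt v_t, solved per
    # eigenmode with an IIR filter for speed
    try:
        eigval, q = np.linalg.eig(a)
        u = np.linalg.solve(q, v.T)  # (R, n)
        from scipy.signal import lfilter

        y = np.empty_like(u)
        for m in range(r):
            y[m] = lfilter([0.0, dt], [1.0, -(1.0 + dt * eigval[m])], u[m])
        x = (q @ y).T.real
    except np.linalg.LinAlgError:
        x = np.zeros((n_total, r))
        m_step = np.eye(r) + dt * a
        xi = np.zeros(r)
        for t in range(1, n_total):
            xi = m_step @ xi + dt * v[t - 1]
            x[t] = xi

    # hemodynamic filtering in the frequency domain
    hemo = parts["hemo"].reshape(r, 2)
    xf = np.fft.rfft(x, axis=0)
    f = np.fft.rfftfreq(n_total, d=dt)
    omega = 2.0 * np.pi * f
    bold = np.empty_like(x)
    for i in range(r):
        h = hemo_transfer(omega, hemo[i, 0], hemo[i, 1])
        h[0] = h[0].real  # DC gain is real
        bold[:, i] = np.fft.irfft(xf[:, i] * h, n=n_total, axis=0)

    bold = bold[n_burn * dt_factor :: dt_factor][:n_volumes]
    noise = _powerlaw_noise(
        rng, n_volumes, tr, parts["obs"][0], parts["obs"][1], r
    )
    return RoiTimeSeries(bold + noise, tr=tr, region_labels=layout.mask.region_labels)


def _signal_variance(theta, layout, tr, n_volumes):
    """Band-integrated model signal variance per region (no obs noise)."""
    from .model import predict_csd
    from .spectra import FrequencyGrid

    f_lo = 1.0 / (n_volumes * tr)
    f_hi = 0.5 / tr
    grid = FrequencyGrid(np.linspace(f_lo, f_hi, 128))
    s = predict_csd(theta, layout, grid, include_obs=False)
    diag = np.diagonal(s.csd, axis1=1, axis2=2).real
    return 2.0 * np.trapezoid(diag, grid.freqs, axis=0)  # two-sided


def obs_log_amp_for(theta, layout, tr, n_volumes, rel_sd, exp_raw):
    """Observation-noise log-amplitude giving the requested noise-to-signal
    SD ratio over the resolvable band."""
    from scipy.special import expit

    sig_var = float(np.mean(_signal_variance(theta, layout, tr, n_volumes)))
    beta = 2.0 * expit(exp_raw)
    f_lo, f_hi = 1.0 / (n_volumes * tr), 0.5 / tr
    f = np.linspace(f_lo, f_hi, 256)
    unit = 2.0 * np.trapezoid((2.0 * np.pi * f) ** (-beta), f)
    target = (rel_sd**2) * sig_var
    return float(np.log(target / unit))


def simulate_subject_bold(
    spec: CohortSpec,
    theta: np.ndarray,
    mean_fd: float,
    rng: np.random.Generator,
) -> RoiTimeSeries:
    """Cohort-level wrapper: sets the observation-noise amplitude from the
    relative noise level, inflated by motion (1 + c * FD)."""
    layout = spec.layout()
    theta = np.asarray(theta, float).copy()
    rel = spec.obs_noise_rel * (1.0 + spec.fd_noise_coupling * mean_fd)
    sl = layout.slices["obs"]
    theta[sl.start] = obs_log_amp_for(
        theta, layout, spec.tr, spec.n_volumes, rel, spec.obs_exp_raw
    )
    return simulate_bold_from_params(
        theta, layout, spec.tr, spec.n_volumes, rng,
        dt_factor=spec.dt_factor, burn_in_s=spec.burn_in_s,
    )


def make_confounded_sites(spec: CohortSpec, severity: float) -> CohortSpec:
    """Scale per-site mean-age offsets so that sites differ in mean age.

    severity 0 leaves sites exchangeable; severity 1 spreads site mean ages
    over roughly +/-6 years, enough for a one-way ANOVA of age on site to be
    decisive at the study's sample size.
    """
    if spec.n_sites < 2:
        raise SynthError("need at least 2 sites")
    base = np.linspace(-6.0, 6.0, spec.n_sites)
    return dataclasses.replace(spec, site_age_shift=tuple(severity * base))


def sample_posterior_cohort(
    spec: CohortSpec,
    first_level_sd: float = 0.05,
) -> tuple[list[ParticipantRecord], SyntheticTruth, list[tuple[np.ndarray, np.ndarray]]]:
    """Synthetic first-level posteriors for group-stage testing.

    Instead of simulating BOLD and inverting, each subject's coupling
    posterior is drawn directly as N(theta_true, first_level_sd^2 I) — a
    synthetic stand-in for the inversion stage that isolates the hierarchical
    machinery.  Returns (records, truth, posteriors) with posteriors as
    (mean, cov) pairs aligned with records.
    """
    records, truth = sample_cohort(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x9E37]))
    k = truth.coupling.shape[1]
    posts = []
    for i in range(len(records)):
        mean = truth.coupling.iloc[i].to_numpy() + rng.normal(0, first_level_sd, k)
        posts.append((mean, first_level_sd**2 * np.eye(k)))
    return records, truth, posts


def write_cohort(
    spec: CohortSpec,
    out_dir: str | Path,
    simulate_series: bool = True,
) -> tuple[list[ParticipantRecord], SyntheticTruth]:
    """Emit the on-disk layout the cohort reader consumes: participants.csv,
    series/<id>.tsv, truth.json and manifest.yaml."""
    from .cohort import write_timeseries
    import yaml

    out = Path(out_dir)
    (out / "series").mkdir(parents=True, exist_ok=True)
    records, truth = sample_cohort(spec)
    rows = []
    for rec in records:
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "age": rec.age,
                "mean_fd": rec.mean_fd,
                "site": rec.site,
                "srs_total": "" if rec.srs_total is None else rec.srs_total,
            }
        )
    pd.DataFrame(rows).to_csv(out / "participants.csv", index=False)
    truth.to_json(out / "truth.json")
    if simulate_series:
        ss = np.random.SeedSequence([spec.seed, 0x5B0])
        child = ss.spawn(len(records))
        for i, rec in enumerate(records):
            rng = np.random.default_rng(child[i])
            ts = simulate_subject_bold(spec, truth.theta_full[i], rec.mean_fd, rng)
            write_timeseries(ts, out / "series" / f"{rec.subject_id}.tsv")
    manifest = {
        "participants": "participants.csv",
        "series_dir": "series",
        "tr": spec.tr,
        "region_labels": list(spec.region_labels),
        "seed": spec.seed,
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    return records, truth
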
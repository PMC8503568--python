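"""Participant metadata and ROI time-series I/O.

The effective-connectivity model operates on a fixed five-node network: one
subcortical node (basal ganglia + thalamus) and four primary sensory cortical
nodes (ventral somatosensory, dorsal somatosensory, auditory, visual).  All
downstream code assumes the canonical region order defined here, with the
subcortical node first.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

#: Canonical region order.  Index 0 is the only subcortical node.
CANONICAL_REGIONS: tuple[str, ...] = ("SubC", "vS1", "dS1", "A1", "V1")

#: Mean-FD motion-exclusion threshold in mm (strict >).
DEFAULT_FD_EXCLUSION_MM: float = 0.34

#: Plausible age range in years for validation.
DEFAULT_AGE_RANGE: tuple[float, float] = (5.0, 60.0)

GROUPS = ("ASD", "TD")


class CohortError(ValueError):
    """Raised on schema or validation failures in cohort inputs."""


@dataclass(frozen=True)
class ParticipantRecord:
    """One row of the participant table.

    ``srs_total`` may be missing (None); such subjects are excluded only from
    the symptom-association stage.  ``excluded_by_motion`` is a flag, never a
    silent drop — downstream stages decide what to do with flagged subjects.
    """

    subject_id: str
    group: str
    age: float
    mean_fd: float
    site: str
    srs_total: float | None = None
    excluded_by_motion: bool = False

    def __post_init__(self):
        if self.group not in GROUPS:
            raise CohortError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not np.isfinite(self.age) or self.age <= 0:
            raise CohortError(f"age must be a positive real, got {self.age!r}")
        if not np.isfinite(self.mean_fd) or self.mean_fd < 0:
            raise CohortError(f"mean_fd must be non-negative, got {self.mean_fd!r}")
        if not self.site:
            raise CohortError("site label must be non-empty")
        if self.srs_total is not None and (
            not np.isfinite(self.srs_total) or self.srs_total < 0
        ):
            raise CohortError(f"srs_total must be non-negative, got {self.srs_total!r}")


@dataclass(frozen=True)
class RoiTimeSeries:
    """T x R BOLD matrix with repetition time and ordered region labels."""

    data: np.ndarray
    tr: float
    region_labels: tuple[str, ...]

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "region_labels", tuple(self.region_labels))
        if data.ndim != 2:
            raise CohortError("time series must be a 2-D (T x R) matrix")
        if data.shape[1] != len(self.region_labels):
            raise CohortError("number of columns must match region labels")
        if len(set(self.region_labels)) != len(self.region_labels):
            raise CohortError("region labels must be unique")
        if self.tr <= 0:
            raise CohortError("tr must be positive")
        if not np.all(np.isfinite(data)):
            t, r = map(int, np.argwhere(~np.isfinite(data))[0])
            raise CohortError(
                f"non-finite value at (row {t}, region {self.region_labels[r]})"
            )

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass
class CohortManifest:
    """Pointers tying the participant table to per-subject series files."""

    records: list[ParticipantRecord]
    series_paths: dict[str, Path]
    tr: float

    def __post_init__(self):
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise CohortError("subject ids must be unique")
        missing = [i for i in ids if i not in self.series_paths]
        if missing:
            raise CohortError(f"records without a series path: {missing}")


_REQUIRED_COLUMNS = ("subject_id", "group", "age", "mean_fd", "site")


def read_participants(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    fd_exclusion_mm: float = DEFAULT_FD_EXCLUSION_MM,
    age_range: tuple[float, float] = DEFAULT_AGE_RANGE,
) -> list[ParticipantRecord]:
    """Read and validate the participant table (CSV or TSV).

    ``schema`` maps required column names to the names actually used in the
    file.  Subjects with mean FD strictly above ``fd_exclusion_mm`` are
    flagged ``excluded_by_motion``; missing ``srs_total`` is preserved as
    None.  Row-level failures are collected and reported together with their
    row numbers.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    colmap = dict(schema) if schema else {}
    for want in _REQUIRED_COLUMNS:
        have = colmap.get(want, want)
        if have not in df.columns:
            raise CohortError(f"missing required column {have!r} (for {want!r})")
    srs_col = colmap.get("srs_total", "srs_total")

    records: list[ParticipantRecord] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        try:
            age = float(row[colmap.get("age", "age")])
            fd = float(row[colmap.get("mean_fd", "mean_fd")])
            if not age_range[0] <= age <= age_range[1]:
                raise CohortError(
                    f"age {age} outside plausible range {age_range}"
                )
            srs = None
            if srs_col in df.columns and pd.notna(row[srs_col]):
                srs = float(row[srs_col])
            records.append(
                ParticipantRecord(
                    subject_id=str(row[colmap.get("subject_id", "subject_id")]),
                    group=str(row[colmap.get("group", "group")]),
                    age=age,
                    mean_fd=fd,
                    site=str(row[colmap.get("site", "site")]),
                    srs_total=srs,
                    excluded_by_motion=bool(fd > fd_exclusion_mm),
                )
            )
        except (CohortError, TypeError, ValueError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise CohortError("invalid participant rows:\n" + "\n".join(errors))
    return records


def read_timeseries(
    path: str | Path,
    tr: float,
    expected_labels: Sequence[str] = CANONICAL_REGIONS,
    min_volumes: int = 64,
) -> RoiTimeSeries:
    """Read a per-subject TSV (header = region labels, one row per volume).

    Columns are reordered to ``expected_labels``; a label set mismatch is an
    error, as are non-finite entries (reported with coordinates) and series
    shorter than ``min_volumes``.
    """
    df = pd.read_csv(path, sep="\t")
    have, want = set(df.columns), set(expected_labels)
    if have != want:
        raise CohortError(
            f"{path}: region labels {sorted(have)} do not match expected {sorted(want)}"
        )
    df = df[list(expected_labels)]
    if len(df) < min_volumes:
        raise CohortError(f"{path}: series too short (T={len(df)} < {min_volumes})")
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        t, r = map(int, np.argwhere(~np.isfinite(values))[0])
        raise CohortError(
            f"{path}: non-finite value at (row {t}, region {list(expected_labels)[r]})"
        )
    return RoiTimeSeries(values, tr=tr, region_labels=tuple(expected_labels))


def write_timeseries(ts: RoiTimeSeries, path: str | Path) -> None:
    """Write a time series as TSV with full float precision (round-trips)."""
    df = pd.DataFrame(ts.data, columns=list(ts.region_labels))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def standardize_series(
    ts: RoiTimeSeries, detrend_order: int = 1, scale: str = "per_region"
) -> RoiTimeSeries:
    """Remove a polynomial trend per region and rescale.

    ``detrend_order`` 0 removes the mean, 1 a linear trend, 2 a quadratic.
    ``scale="per_region"`` gives every region unit variance;
    ``scale="global"`` divides all regions by one common factor (the root
    mean variance), preserving the relative amplitudes between regions —
    the conditioning the spectral model fit uses, since the generative
    model carries no per-region gain parameter.  Idempotent up to numerical
    tolerance.  A zero-variance region is an error (its label is named).
    """
    if detrend_order not in (0, 1, 2):
        raise CohortError("detrend_order must be in {0, 1, 2}")
    if scale not in ("per_region", "global"):
        raise CohortError("scale must be 'per_region' or 'global'")
    x = ts.data.copy()
    t = np.arange(x.shape[0], dtype=float)
    basis = np.vander(t / max(t[-1], 1.0), detrend_order + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(basis, x, rcond=None)
    x = x - basis @ coef
    sd = x.std(axis=0, ddof=0)
    for j, s in enumerate(sd):
        if s < 1e-14:
            raise CohortError(
                f"zero-variance region after detrending: {ts.region_labels[j]}"
            )
    x = x / sd if scale == "per_region" else x / np.sqrt(np.mean(sd**2))
    return dataclasses.replace(ts, data=x)


def read_manifest(path: str | Path) -> CohortManifest:
    """Read a YAML/JSON manifest: participant table path, series dir, TR."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    base = path.parent
    records = read_participants(
        base / cfg["participants"],
        fd_exclusion_mm=float(cfg.get("fd_exclusion_mm", DEFAULT_FD_EXCLUSION_MM)),
    )
    series_dir = base / cfg["series_dir"]
    series_paths = {
        r.subject_id: series_dir / f"{r.subject_id}.tsv" for r in records
    }
    for sid, p in series_paths.items():
        if not p.exists():
            raise CohortError(f"missing series file for subject {sid}: {p}")
    return CohortManifest(records=records, series_paths=series_paths, tr=float(cfg["tr"]))
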
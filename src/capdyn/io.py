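"""Session and cohort I/O, z-scoring, and motion QC.

A *session* is one subject at one timepoint: ``n_runs`` resting-state runs
concatenated into a single frames x ROIs matrix, with run boundaries recorded
so that no dwell or transition is ever computed across an acquisition break.

File formats (all plain TSV, UTF-8, '.' decimal):

* session matrix — one file per run; header row = parcel ids, one row per frame
* cohort manifest — one row per (subject, timepoint, run) with group,
  covariates, motion and mood columns
* parcel table — see :mod:`capdyn.atlas`
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import validate_parcel_table

__all__ = [
    "RoiTimeSeries",
    "FormatError",
    "read_session_matrix",
    "write_session_matrix",
    "zscore_session",
    "read_manifest",
    "write_manifest",
    "load_session",
    "load_cohort",
    "qc_mean_fd",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = [
    "subject_id",
    "group",
    "timepoint",
    "run_index",
    "path",
    "age",
    "sex",
    "mean_fd",
    "hdrs",
    "rrs_brooding",
    "rrs_reflection",
    "rrs_reappraisal",
]

FLOAT_FMT = "%.10g"


class FormatError(ValueError):
    """Raised for malformed session / manifest files."""


@dataclass
class RoiTimeSeries:
    """One session's parcellated BOLD time series.

    ``data`` stacks the session's runs; ``run_boundaries`` holds the starting
    frame index of each run (first entry 0). ``fd_mm`` is the per-frame
    framewise displacement; the first frame of each run is 0 by convention
    (FD is a frame-to-frame difference measure).
    """

    subject_id: str
    group: str
    timepoint: str
    data: np.ndarray
    tr_seconds: float = 0.8
    fd_mm: np.ndarray | None = None
    run_boundaries: np.ndarray = field(default_factory=lambda: np.array([0]))
    zscored: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError("data must be a frames x ROIs matrix with >= 2 frames")
        if np.isnan(self.data).any():
            raise ValueError("data contains missing values")
        if self.fd_mm is None:
            self.fd_mm = np.zeros(self.data.shape[0])
        self.fd_mm = np.asarray(self.fd_mm, dtype=float)
        if self.fd_mm.shape != (self.data.shape[0],):
            raise ValueError("fd_mm length must equal number of frames")
        self.run_boundaries = np.asarray(self.run_boundaries, dtype=int)
        if self.run_boundaries[0] != 0 or np.any(np.diff(self.run_boundaries) <= 0):
            raise ValueError("run_boundaries must be sorted and start at 0")
        if self.run_boundaries[-1] >= self.data.shape[0]:
            raise ValueError("run boundary beyond data length")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    @property
    def n_runs(self) -> int:
        return len(self.run_boundaries)

    def run_slices(self) -> list[slice]:
        edges = list(self.run_boundaries) + [self.n_frames]
        return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


def write_session_matrix(path, data: np.ndarray, parcel_ids) -> None:
    """Write one run's frames x ROIs matrix as TSV (header = parcel ids)."""
    df = pd.DataFrame(np.asarray(data, dtype=float), columns=list(parcel_ids))
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_session_matrix(path, parcel_table: pd.DataFrame | None = None) -> np.ndarray:
    """Read one run's matrix, validating shape and numeric content.

    Roundtrips through :func:`write_session_matrix` to better than 1e-12
    relative error. Non-numeric cells and parcel-count mismatches raise
    :class:`FormatError` naming the offending cell / count.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.ParserError as e:  # ragged rows
        raise FormatError(f"{path}: malformed TSV ({e})") from None
    num = df.apply(pd.to_numeric, errors="coerce")
    if num.isna().any().any():
        r, c = np.argwhere(num.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric cell at frame {r}, column {df.columns[c]!r} "
            f"(value {df.iat[r, c]!r})"
        )
    if parcel_table is not None:
        validate_parcel_table(parcel_table)
        want = [str(p) for p in parcel_table["parcel_id"]]
        got = [str(c) for c in df.columns]
        if got != want:
            raise FormatError(
                f"{path}: header has {len(got)} parcel ids, parcel table has "
                f"{len(want)} (or order differs)"
            )
    return num.to_numpy(dtype=float)


def zscore_session(
    ts: RoiTimeSeries,
    per_run: bool = True,
    zero_variance: str = "error",
) -> RoiTimeSeries:
    """Standardize each ROI time series (sample sd, denominator n-1).

    Default is per run within the session, which removes run-level offsets
    before frames are pooled; ``per_run=False`` standardizes across the
    concatenated session instead. Idempotent to numerical precision.

    ``zero_variance`` policy for constant ROI columns: ``"error"`` (default)
    or ``"zeros"`` (emit zeros with a warning).
    """
    if ts.zscored:
        raise ValueError("session already z-scored")
    if zero_variance not in ("error", "zeros"):
        raise ValueError("zero_variance must be 'error' or 'zeros'")
    out = ts.data.copy()
    segments = ts.run_slices() if per_run else [slice(0, ts.n_frames)]
    for sl in segments:
        block = out[sl]
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        bad = np.where(sd == 0)[0]
        if bad.size:
            if zero_variance == "error":
                raise ValueError(f"zero-variance ROI column(s) at index {bad.tolist()}")
            warnings.warn(f"zero-variance ROI column(s) {bad.tolist()} set to 0")
            sd = sd.copy()
            sd[bad] = 1.0
        out[sl] = (block - mu) / sd
        if bad.size:
            out[sl][:, bad] = 0.0
    return replace(ts, data=out, zscored=True)


# ---------------------------------------------------------------------------
# manifests


def write_manifest(path, manifest: pd.DataFrame) -> None:
    _validate_manifest(manifest)
    manifest.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return _validate_manifest(df)


def _validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest missing columns: {missing}")
    key = df[["subject_id", "timepoint", "run_index"]]
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0].tolist()
        raise FormatError(f"duplicate (subject, timepoint, run) in manifest: {dup}")
    return df


def load_session(
    rows: pd.DataFrame,
    parcel_table: pd.DataFrame | None = None,
    root=None,
) -> RoiTimeSeries:
    """Assemble one session's RoiTimeSeries from its manifest rows (one per
    run), concatenating runs in run_index order."""
    rows = rows.sort_values("run_index")
    sub = rows["subject_id"].iloc[0]
    mats, boundaries, pos = [], [], 0
    for _, r in rows.iterrows():
        p = r["path"] if root is None else f"{root}/{r['path']}"
        m = read_session_matrix(p, parcel_table)
        boundaries.append(pos)
        pos += m.shape[0]
        mats.append(m)
    return RoiTimeSeries(
        subject_id=str(sub),
        group=str(rows["group"].iloc[0]),
        timepoint=str(rows["timepoint"].iloc[0]),
        data=np.vstack(mats),
        run_boundaries=np.array(boundaries),
    )


def load_cohort(
    manifest: pd.DataFrame,
    parcel_table: pd.DataFrame | None = None,
    root=None,
) -> list[RoiTimeSeries]:
    """Load every session referenced by the manifest, in manifest order."""
    _validate_manifest(manifest)
    sessions = []
    for (_, _), rows in manifest.groupby(["subject_id", "timepoint"], sort=False):
        sessions.append(load_session(rows, parcel_table, root))
    return sessions


def qc_mean_fd(
    manifest: pd.DataFrame, threshold_mm: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Motion QC on session-level mean framewise displacement.

    A session with mean FD >= ``threshold_mm`` is excluded (strict
    "less than" retention rule, so exactly 0.5 mm is excluded), and exclusion
    propagates to the whole subject. Returns (retained, excluded) manifests.
    """
    _validate_manifest(manifest)
    if manifest["mean_fd"].isna().any():
        bad = manifest.loc[manifest["mean_fd"].isna(), "subject_id"].tolist()
        raise ValueError(f"missing mean_fd for subjects {bad}")
    bad_subjects = set(manifest.loc[manifest["mean_fd"] >= threshold_mm, "subject_id"])
    mask = manifest["subject_id"].isin(bad_subjects)
    return manifest[~mask].copy(), manifest[mask].copy()
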
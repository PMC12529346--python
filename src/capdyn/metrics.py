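"""State-dynamics metrics for per-session CAP state sequences.

Given a per-frame state sequence (states numbered 1..K) the metrics are:

* fraction of time (FT, fractional occupancy): share of frames in each state;
* mean dwell time (MDT): average length, in TRs, of uninterrupted runs of a
  state, never spanning an acquisition (run) boundary;
* transition probability (TP): estimated on the *collapsed* sequence
  (consecutive duplicates removed within each run, which controls for the
  autocorrelation induced by state persistence). In the default mode the
  denominator counts occurrences of the source state that have a successor
  within the same run, so each defined row is a probability distribution
  (the Markov reading); a "literal" mode divides by all occurrences of the
  source state instead.

Unvisited states give FT 0 but *missing* (NaN) MDT; TP rows with no outgoing
transition are missing. The TP diagonal is structurally 0 after collapsing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import RoiTimeSeries

__all__ = [
    "StateSequence",
    "CapMetricSet",
    "fraction_time",
    "mean_dwell_time",
    "collapse_runs",
    "transition_probability",
    "per_state_fd",
    "session_metrics",
    "metrics_table",
    "static_fc",
]


@dataclass
class StateSequence:
    """Per-frame integer state labels (1..K) for one session, with run
    boundaries so no dwell or transition crosses an acquisition break."""

    subject_id: str
    timepoint: str
    labels: np.ndarray
    run_boundaries: np.ndarray = field(default_factory=lambda: np.array([0]))
    group: str | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size == 0:
            raise ValueError("empty state sequence")
        self.run_boundaries = np.asarray(self.run_boundaries, dtype=int)
        if self.run_boundaries[0] != 0 or np.any(np.diff(self.run_boundaries) <= 0):
            raise ValueError("run_boundaries must be sorted and start at 0")
        if self.run_boundaries[-1] >= self.labels.size:
            raise ValueError("run boundary beyond sequence length")

    def __len__(self) -> int:
        return self.labels.size

    def run_slices(self) -> list[slice]:
        edges = list(self.run_boundaries) + [self.labels.size]
        return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


@dataclass
class CapMetricSet:
    """Per-session metric bundle. ``mdt_tr`` is in TR units; ``tp`` rows of
    unvisited / terminal-only states are NaN."""

    ft: np.ndarray
    mdt_tr: np.ndarray
    tp: np.ndarray
    state_counts: np.ndarray
    per_state_fd_mm: np.ndarray | None = None


def _check_labels(labels: np.ndarray, K: int) -> None:
    if labels.min() < 1 or labels.max() > K:
        bad = labels[(labels < 1) | (labels > K)][0]
        raise ValueError(f"state label {bad} outside 1..{K}")


def fraction_time(seq: StateSequence, K: int) -> np.ndarray:
    """Proportion of the session's frames spent in each state."""
    _check_labels(seq.labels, K)
    counts = np.bincount(seq.labels, minlength=K + 1)[1:]
    return counts / seq.labels.size


def _runs(seq: StateSequence) -> list[tuple[int, int]]:
    """(state, length) for each maximal run, never crossing a run boundary."""
    out = []
    for sl in seq.run_slices():
        x = seq.labels[sl]
        change = np.flatnonzero(np.diff(x)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [x.size]])
        out.extend((int(x[s]), int(e - s)) for s, e in zip(starts, ends))
    return out


def mean_dwell_time(seq: StateSequence, K: int) -> np.ndarray:
    """Mean maximal-run length (in TRs) per state; NaN for unvisited states."""
    _check_labels(seq.labels, K)
    total = np.zeros(K)
    n = np.zeros(K)
    for state, length in _runs(seq):
        total[state - 1] += length
        n[state - 1] += 1
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, total / np.maximum(n, 1), np.nan)


def collapse_runs(seq: StateSequence) -> StateSequence:
    """Remove consecutive duplicate states within each run (idempotent)."""
    parts, boundaries, pos = [], [], 0
    for sl in seq.run_slices():
        x = seq.labels[sl]
        keep = np.concatenate([[True], np.diff(x) != 0])
        boundaries.append(pos)
        part = x[keep]
        pos += part.size
        parts.append(part)
    return StateSequence(
        subject_id=seq.subject_id,
        timepoint=seq.timepoint,
        labels=np.concatenate(parts),
        run_boundaries=np.array(boundaries),
        group=seq.group,
    )


def transition_probability(
    seq: StateSequence, K: int, literal: bool = False, collapsed: bool = False
) -> np.ndarray:
    """K x K transition probability matrix on the collapsed sequence.

    ``literal=True`` divides by all occurrences of the source state (the
    plain "transitions over occurrences" reading; rows then sum to < 1 when
    the state ends a run), otherwise by occurrences with a successor, so
    every defined row sums to 1. Transitions are never counted across run
    boundaries. Pass ``collapsed=True`` if ``seq`` is already collapsed.
    """
    _check_labels(seq.labels, K)
    c = seq if collapsed else collapse_runs(seq)
    counts = np.zeros((K, K))
    occ_with_next = np.zeros(K)
    occ_total = np.bincount(c.labels, minlength=K + 1)[1:].astype(float)
    for sl in c.run_slices():
        x = c.labels[sl]
        if x.size >= 2:
            np.add.at(counts, (x[:-1] - 1, x[1:] - 1), 1.0)
            np.add.at(occ_with_next, x[:-1] - 1, 1.0)
    denom = occ_total if literal else occ_with_next
    tp = np.full((K, K), np.nan)
    defined = denom > 0
    tp[defined] = counts[defined] / denom[defined, None]
    return tp


def per_state_fd(seq: StateSequence, ts: RoiTimeSeries, K: int) -> np.ndarray:
    """Mean framewise displacement over the frames assigned to each state."""
    _check_labels(seq.labels, K)
    if ts.fd_mm.shape != seq.labels.shape:
        raise ValueError("FD trace and label sequence lengths differ")
    out = np.full(K, np.nan)
    for s in range(1, K + 1):
        mask = seq.labels == s
        if mask.any():
            out[s - 1] = ts.fd_mm[mask].mean()
    return out


def session_metrics(
    seq: StateSequence,
    K: int,
    ts: RoiTimeSeries | None = None,
    literal_tp: bool = False,
) -> CapMetricSet:
    """Compute the full per-session metric bundle."""
    return CapMetricSet(
        ft=fraction_time(seq, K),
        mdt_tr=mean_dwell_time(seq, K),
        tp=transition_probability(seq, K, literal=literal_tp),
        state_counts=np.bincount(seq.labels, minlength=K + 1)[1:],
        per_state_fd_mm=None if ts is None else per_state_fd(seq, ts, K),
    )


def metrics_table(
    items: list[tuple[StateSequence, CapMetricSet]], K: int
) -> pd.DataFrame:
    """Long-format table of all per-session metrics.

    Columns: subject_id, group, timepoint, metric in {FT, MDT, TP, FD_state},
    state_from, state_to (empty unless TP), value.
    """
    rows = []
    for seq, m in items:
        meta = (seq.subject_id, seq.group, seq.timepoint)
        for s in range(K):
            rows.append((*meta, "FT", s + 1, None, m.ft[s]))
            rows.append((*meta, "MDT", s + 1, None, m.mdt_tr[s]))
            if m.per_state_fd_mm is not None:
                rows.append((*meta, "FD_state", s + 1, None, m.per_state_fd_mm[s]))
        for a in range(K):
            for b in range(K):
                if a != b:
                    rows.append((*meta, "TP", a + 1, b + 1, m.tp[a, b]))
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "group",
            "timepoint",
            "metric",
            "state_from",
            "state_to",
            "value",
        ],
    )


def static_fc(ts: RoiTimeSeries) -> np.ndarray:
    """Static functional connectivity: full pairwise Pearson correlation of
    ROI time series (symmetric, unit diagonal). Zero-variance ROIs give NaN
    rows/columns with a warning."""
    if ts.n_frames < 3:
        raise ValueError("need >= 3 frames for static FC")
    sd = ts.data.std(axis=0)
    bad = np.where(sd == 0)[0]
    if bad.size:
        warnings.warn(f"zero-variance ROI(s) {bad.tolist()}: NaN in FC matrix")
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.corrcoef(ts.data.T)
    fc[bad, :] = np.nan
    fc[:, bad] = np.nan
    np.fill_diagonal(fc, np.where(sd == 0, np.nan, 1.0))
    return fc
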
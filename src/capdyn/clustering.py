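"""Frame-wise k-means under correlation distance: the co-activation pattern
(CAP) extraction stage.

All z-scored frames from all subjects and sessions are pooled and clustered
with Lloyd-style k-means where the distance between a frame ``x`` and a
centroid ``c`` is ``1 - corr(x, c)``. Frames are row-standardized internally
(zero mean, unit norm over ROIs), which makes correlation distance a monotone
function of Euclidean distance, so the usual mean-update iteration converges
with a non-increasing objective (spherical k-means). The accepted solution is
the best of ``n_replicates`` random restarts.

The number of states is chosen by scanning k and locating the elbow of the
cluster validity index (CVI) curve — the ratio of mean within-cluster to mean
between-cluster correlation distance — with a two-segment piecewise-linear
least-squares fit. Per-cluster silhouette scores are available as the
alternative criterion.

Organised statsmodels-style: :class:`CoactivationPatterns` is the model
object, ``fit()`` returns a :class:`CapResults` carrying centroids, labels
and diagnostics; the module-level functions (``kmeans_caps``, ``scan_k``,
``select_k_elbow``, ...) are thin functional entry points over the same code.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .atlas import network_indicators
from .io import RoiTimeSeries
from .metrics import StateSequence

logger = logging.getLogger(__name__)

__all__ = [
    "FramePool",
    "concat_frames",
    "CoactivationPatterns",
    "CapResults",
    "KSelectionCurve",
    "kmeans_caps",
    "scan_k",
    "select_k_elbow",
    "cluster_validity_index",
    "silhouette_by_cluster",
    "label_caps_by_network",
    "centroid_similarity_matrix",
    "frame_centroid_similarity",
    "match_clusters",
    "assign_states",
]

INDEX_MAP_COLUMNS = ["subject_id", "group", "timepoint", "run_index", "frame_index"]


class ZeroVarianceFrameError(ValueError):
    pass


def _standardize_rows(X: np.ndarray, what: str = "frame") -> np.ndarray:
    """Center each row and scale to unit sd (population); correlation between
    two standardized rows is then their dot product / n_cols."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    Xc = X - mu
    sd = Xc.std(axis=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        raise ZeroVarianceFrameError(
            f"zero-variance {what}(s) at row index {bad.tolist()}: "
            "correlation distance undefined"
        )
    return Xc / sd


@dataclass
class FramePool:
    """All pooled frames (already z-scored per ROI) plus an index map that
    records, for every pooled row, which (subject, timepoint, run, frame) it
    came from — invertible back to per-session label vectors."""

    frames: np.ndarray
    index_map: pd.DataFrame

    def __post_init__(self):
        if len(self.index_map) != self.frames.shape[0]:
            raise ValueError("index_map length must equal frame count")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_rois(self) -> int:
        return self.frames.shape[1]

    def split_labels(self, labels: np.ndarray, K: int | None = None) -> list[StateSequence]:
        """Invert the pooling: per-session StateSequence objects, in pool
        order, with run boundaries restored."""
        labels = np.asarray(labels)
        out = []
        im = self.index_map.reset_index(drop=True)
        for (sub, tp), grp in im.groupby(["subject_id", "timepoint"], sort=False):
            rows = grp.index.to_numpy()
            runs = grp["run_index"].to_numpy()
            boundaries = np.flatnonzero(np.concatenate([[True], np.diff(runs) != 0]))
            out.append(
                StateSequence(
                    subject_id=str(sub),
                    timepoint=str(tp),
                    labels=labels[rows],
                    run_boundaries=boundaries,
                    group=str(grp["group"].iloc[0]),
                )
            )
        return out


def concat_frames(sessions: list[RoiTimeSeries]) -> FramePool:
    """Stack all sessions' frames (in the given order) into one pool."""
    if not sessions:
        raise ValueError("no sessions to pool")
    n_rois = sessions[0].n_rois
    mats, rows = [], []
    for ts in sessions:
        if ts.n_rois != n_rois:
            raise ValueError(
                f"mixed parcel counts in pool: {ts.n_rois} vs {n_rois} "
                f"(subject {ts.subject_id})"
            )
        if not ts.zscored:
            raise ValueError(f"session {ts.subject_id}/{ts.timepoint} not z-scored")
        mats.append(ts.data)
        for run_idx, sl in enumerate(ts.run_slices()):
            for f in range(sl.stop - sl.start):
                rows.append((ts.subject_id, ts.group, ts.timepoint, run_idx, f))
    return FramePool(
        frames=np.vstack(mats),
        index_map=pd.DataFrame(rows, columns=INDEX_MAP_COLUMNS),
    )


# ---------------------------------------------------------------------------
# k-means under correlation distance


def _plusplus_init(Xs: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding under correlation distance: subsequent
    centroids are drawn with probability proportional to the squared distance
    to the nearest chosen one, so duplicated frames never seed two clusters."""
    n, m = Xs.shape
    C = np.empty((k, m))
    C[0] = Xs[rng.integers(n)]
    d = 1.0 - Xs @ C[0] / m
    for j in range(1, k):
        w = np.clip(d, 0.0, None) ** 2
        total = w.sum()
        if total <= 0:  # fewer distinct frames than k: fall back to uniform
            idx = rng.integers(n)
        else:
            idx = np.searchsorted(np.cumsum(w / total), rng.random())
        C[j] = Xs[idx]
        d = np.minimum(d, 1.0 - Xs @ C[j] / m)
    return C


def _lloyd(Xs: np.ndarray, k: int, max_iter: int, rng: np.random.Generator):
    """One k-means replicate on row-standardized frames. Returns
    (labels 0-based, centroids, objective)."""
    n, m = Xs.shape
    C = _plusplus_init(Xs, k, rng)
    prev_labels = None
    prev_obj = np.inf
    check_monotone = True
    for _ in range(max_iter):
        Cs = _standardize_rows(C, "centroid")
        D = 1.0 - Xs @ Cs.T / m
        labels = D.argmin(axis=1)
        obj = D[np.arange(n), labels].sum()
        if check_monotone and obj > prev_obj + 1e-6 * max(1.0, abs(prev_obj)):
            raise AssertionError("k-means objective increased")  # pragma: no cover
        check_monotone = True
        # re-seed empty clusters from the farthest frame
        counts = np.bincount(labels, minlength=k)
        empty = np.flatnonzero(counts == 0)
        if empty.size:
            logger.info("re-seeding %d empty cluster(s)", empty.size)
            far = np.argsort(-D[np.arange(n), labels])
            for j, f in zip(empty, far):
                C[j] = Xs[f]
            check_monotone = False
            prev_obj = obj
            continue
        if prev_labels is not None and np.array_equal(labels, prev_labels):
            break
        for j in range(k):
            C[j] = Xs[labels == j].mean(axis=0)
        prev_labels, prev_obj = labels, obj
    return labels, C, float(obj)


@dataclass
class KSelectionCurve:
    """CVI (and optionally silhouette) as a function of k, plus the
    two-segment elbow fit once :func:`select_k_elbow` has run."""

    k_values: list[int]
    cvi_scores: list[float]
    silhouette_scores: list[float] | None = None
    chosen_k: int | None = None
    elbow_fit: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        d = {"k": self.k_values, "cvi": self.cvi_scores}
        if self.silhouette_scores is not None:
            d["silhouette"] = self.silhouette_scores
        return pd.DataFrame(d)


@dataclass
class CapResults:
    """Fitted CAP solution.

    ``centroids`` are arithmetic means of the (row-standardized) member
    frames; ``labels`` are 1..k per pooled frame. ``state_order`` maps
    reporting state ids to raw cluster ids when the states have been
    re-ordered by network labeling.
    """

    k: int
    centroids: np.ndarray
    labels: np.ndarray
    objective: float
    replicate_scores: list[float]
    seed: int
    pool: FramePool | None = None
    selection_curve: KSelectionCurve | None = None
    distance: str = "correlation"
    state_names: list[str] | None = None

    # -- diagnostics -------------------------------------------------------
    def recompute_objective(self) -> float:
        Xs = _standardize_rows(self.pool.frames)
        Cs = _standardize_rows(self.centroids, "centroid")
        D = 1.0 - Xs @ Cs.T / Xs.shape[1]
        return float(D[np.arange(len(self.labels)), self.labels - 1].sum())

    def cvi(self) -> float:
        return cluster_validity_index(self.pool, self)

    def state_sequences(self) -> list[StateSequence]:
        return self.pool.split_labels(self.labels, self.k)

    def label_networks(self, parcel_table: pd.DataFrame) -> pd.DataFrame:
        return label_caps_by_network(self, parcel_table)

    def reorder_by_network(
        self, parcel_table: pd.DataFrame, network_order: list[str]
    ) -> "CapResults":
        """Re-number states so that reporting order follows ``network_order``
        (e.g. Vis, SomMot, Default, Limbic, SalVentAttn, Cont — mirroring the
        VN/DAN, SMN, DMN, vDMN, SN, CEN convention). Unmatched networks keep
        their relative raw order at the end."""
        lab = self.label_networks(parcel_table)
        best = lab["best_network"].tolist()
        order = []
        for net in network_order:
            order.extend([i for i, b in enumerate(best) if b == net and i not in order])
        order.extend([i for i in range(self.k) if i not in order])
        perm = np.array(order)  # new state s comes from raw cluster perm[s]
        inv = np.empty(self.k, dtype=int)
        inv[perm] = np.arange(self.k)
        return CapResults(
            k=self.k,
            centroids=self.centroids[perm],
            labels=inv[self.labels - 1] + 1,
            objective=self.objective,
            replicate_scores=self.replicate_scores,
            seed=self.seed,
            pool=self.pool,
            selection_curve=self.selection_curve,
            state_names=[best[i] for i in perm],
        )

    def summary(self) -> str:
        lines = [
            "Co-activation pattern solution",
            "==============================",
            f"k states:        {self.k}",
            f"frames:          {len(self.labels)}",
            f"distance:        {self.distance}",
            f"objective:       {self.objective:.4f}",
            f"replicates:      {len(self.replicate_scores)}"
            f" (best {min(self.replicate_scores):.4f})",
            f"seed:            {self.seed}",
        ]
        if self.pool is not None:
            lines.append(f"CVI:             {self.cvi():.4f}")
        if self.selection_curve is not None and self.selection_curve.chosen_k:
            lines.append(f"elbow-chosen k:  {self.selection_curve.chosen_k}")
        counts = np.bincount(self.labels, minlength=self.k + 1)[1:]
        for s in range(self.k):
            name = self.state_names[s] if self.state_names else ""
            lines.append(f"  state {s + 1}: {counts[s]} frames  {name}")
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------
    def save(self, outdir, parcel_ids=None) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        cols = list(parcel_ids) if parcel_ids is not None else list(range(self.centroids.shape[1]))
        pd.DataFrame(self.centroids, columns=cols).to_csv(
            outdir / "centroids.tsv", sep="\t", index=False, float_format="%.10g"
        )
        lab = self.pool.index_map.copy() if self.pool is not None else pd.DataFrame()
        lab["state"] = self.labels
        lab.to_csv(outdir / "labels.tsv", sep="\t", index=False)
        meta = {
            "k": self.k,
            "seed": self.seed,
            "objective": self.objective,
            "replicate_scores": self.replicate_scores,
            "distance": self.distance,
            "state_names": self.state_names,
        }
        (outdir / "model.json").write_text(json.dumps(meta, indent=2))


class CoactivationPatterns:
    """Model object for CAP extraction.

    Parameters
    ----------
    pool : FramePool
        Pooled z-scored frames from all subjects and sessions.
    k : int, optional
        Number of states. If omitted, ``fit`` scans ``k_range`` and picks the
        CVI elbow.
    k_range : (int, int)
        Inclusive scan range when ``k`` is not fixed (desk-scale default
        2..15; the full-study protocol scans 2..50).
    n_replicates, max_iter : int
        Random restarts and Lloyd iteration cap per fit.
    scan_replicates : int
        Restarts used per k during the scan (cheaper than the final fit).
    """

    def __init__(
        self,
        pool: FramePool,
        k: int | None = None,
        k_range: tuple[int, int] = (2, 15),
        n_replicates: int = 100,
        max_iter: int = 1000,
        scan_replicates: int = 10,
    ):
        self.pool = pool
        self.k = k
        self.k_range = k_range
        self.n_replicates = n_replicates
        self.max_iter = max_iter
        self.scan_replicates = scan_replicates

    def fit(self, seed: int = 0) -> CapResults:
        curve = None
        k = self.k
        if k is None:
            curve = scan_k(
                self.pool,
                k_min=self.k_range[0],
                k_max=self.k_range[1],
                n_replicates=self.scan_replicates,
                max_iter=self.max_iter,
                seed=seed,
            )
            k = select_k_elbow(curve)
        res = kmeans_caps(
            self.pool, k, n_replicates=self.n_replicates, max_iter=self.max_iter, seed=seed
        )
        res.selection_curve = curve
        return res


def kmeans_caps(
    pool: FramePool,
    k: int,
    n_replicates: int = 100,
    max_iter: int = 1000,
    seed: int = 0,
) -> CapResults:
    """Correlation-distance k-means with random restarts; the accepted
    solution is the replicate with the lowest total within-cluster distance.
    Deterministic given ``seed`` (per-replicate seeds derive from it)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if pool.n_frames <= k:
        raise ValueError("need more frames than clusters")
    Xs = _standardize_rows(pool.frames)
    best = None
    scores = []
    for rep in range(n_replicates):
        rng = np.random.default_rng([seed, k, rep])
        labels, C, obj = _lloyd(Xs, k, max_iter, rng)
        scores.append(obj)
        if best is None or obj < best[2]:
            best = (labels, C, obj)
    labels, C, obj = best
    assert np.bincount(labels, minlength=k).min() > 0, "empty cluster accepted"
    return CapResults(
        k=k,
        centroids=C,
        labels=labels + 1,
        objective=obj,
        replicate_scores=scores,
        seed=seed,
        pool=pool,
    )


def cluster_validity_index(pool: FramePool, model: CapResults) -> float:
    """Ratio of mean frame-to-own-centroid distance to mean frame-to-other-
    centroid distance (lower is better)."""
    if model.k < 2:
        raise ValueError("CVI needs k >= 2 (no between-cluster term)")
    Xs = _standardize_rows(pool.frames)
    Cs = _standardize_rows(model.centroids, "centroid")
    D = 1.0 - Xs @ Cs.T / Xs.shape[1]
    idx = np.arange(pool.n_frames)
    own = D[idx, model.labels - 1]
    mask = np.ones_like(D, dtype=bool)
    mask[idx, model.labels - 1] = False
    between = D[mask]
    cvi = own.mean() / between.mean()
    # near-duplicate centroids shrink the between term and inflate the CVI
    cc = np.corrcoef(model.centroids)
    iu = np.triu_indices(model.k, 1)
    if np.any(cc[iu] > 0.999):
        warnings.warn("near-duplicate centroids: CVI between-term degenerate")
    return float(cvi)


def scan_k(
    pool: FramePool,
    k_min: int = 2,
    k_max: int = 15,
    n_replicates: int = 10,
    max_iter: int = 1000,
    seed: int = 0,
    silhouette: bool = False,
) -> KSelectionCurve:
    """Fit k-means for every k in [k_min, k_max] and record the CVI per k.
    Per-k seeds derive deterministically from ``seed``."""
    if k_max >= pool.n_frames:
        raise ValueError("k_max must be below the frame count")
    ks, cvis, sils = [], [], []
    for k in range(k_min, k_max + 1):
        try:
            res = kmeans_caps(pool, k, n_replicates=n_replicates, max_iter=max_iter, seed=seed)
        except Exception as e:
            raise RuntimeError(f"clustering failed at k={k}: {e}") from e
        ks.append(k)
        cvis.append(cluster_validity_index(pool, res))
        if silhouette:
            sils.append(float(np.mean(list(silhouette_by_cluster(pool, res).values()))))
    return KSelectionCurve(ks, cvis, sils if silhouette else None)


def select_k_elbow(curve: KSelectionCurve) -> int:
    """Elbow of the score-vs-k curve by exhaustive two-segment piecewise-
    linear least squares: every interior k is tried as the breakpoint (shared
    by both segments) and the breakpoint minimizing total residual sum of
    squares wins; ties break toward smaller k. If the best two-segment fit
    improves on a single line by < 1% RSS the elbow is ambiguous: the
    smallest k is returned with a warning, flagged in ``elbow_fit``."""
    x = np.asarray(curve.k_values, dtype=float)
    y = np.asarray(curve.cvi_scores, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 k values for elbow fitting")

    def rss(xs, ys):
        A = np.vstack([xs, np.ones_like(xs)]).T
        _, res, *_ = np.linalg.lstsq(A, ys, rcond=None)
        if res.size:
            return float(res[0])
        fit = A @ np.linalg.lstsq(A, ys, rcond=None)[0]
        return float(((ys - fit) ** 2).sum())

    single = rss(x, y)
    best_b, best_rss = None, np.inf
    for b in range(1, x.size - 1):
        total = rss(x[: b + 1], y[: b + 1]) + rss(x[b:], y[b:])
        if total < best_rss - 1e-12:
            best_rss, best_b = total, b
    scale = float(((y - y.mean()) ** 2).sum())
    flat = single <= 1e-10 * max(scale, 1e-30)  # exactly (or numerically) linear
    improvement = (single - best_rss) / single if single > 0 else 0.0
    ambiguous = flat or improvement < 0.01
    if ambiguous:
        warnings.warn("ambiguous elbow: two-segment fit barely beats a single line")
        chosen = int(x[0])
    else:
        chosen = int(x[best_b])
    curve.chosen_k = chosen
    curve.elbow_fit = {
        "breakpoint_k": int(x[best_b]),
        "rss_two_segment": best_rss,
        "rss_single_line": single,
        "ambiguous": bool(ambiguous),
    }
    return chosen


def silhouette_by_cluster(pool: FramePool, model: CapResults) -> dict[int, float]:
    """Per-cluster mean silhouette under correlation distance. Singleton
    clusters contribute silhouette 0 for their member (sklearn convention).
    Builds the full pairwise distance matrix — desk-scale pools only."""
    from sklearn.metrics import silhouette_samples

    if model.k < 2:
        raise ValueError("silhouette needs k >= 2")
    Xs = _standardize_rows(pool.frames)
    D = 1.0 - Xs @ Xs.T / Xs.shape[1]
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    s = silhouette_samples(D, model.labels, metric="precomputed")
    return {int(c): float(s[model.labels == c].mean()) for c in range(1, model.k + 1)}


def label_caps_by_network(model_or_centroids, parcel_table: pd.DataFrame) -> pd.DataFrame:
    """Correlate each centroid with each network's binary parcel-membership
    indicator; the best-matching network names the state. Returns a states x
    networks table of correlations plus a ``best_network`` column."""
    C = model_or_centroids.centroids if hasattr(model_or_centroids, "centroids") else model_or_centroids
    C = np.asarray(C, dtype=float)
    ind = network_indicators(parcel_table)
    if ind.shape[0] != C.shape[1]:
        raise ValueError("parcel table does not cover the model's ROI space")
    Cs = _standardize_rows(C, "centroid")
    Is = _standardize_rows(ind.to_numpy().T, "network indicator")
    R = Cs @ Is.T / C.shape[1]
    out = pd.DataFrame(R, columns=list(ind.columns))
    out.index = [f"state_{i + 1}" for i in range(C.shape[0])]
    out["best_network"] = out[list(ind.columns)].idxmax(axis=1)
    return out


def centroid_similarity_matrix(model: CapResults) -> np.ndarray:
    """Pearson correlations between centroid activation patterns (symmetric,
    unit diagonal)."""
    cc = np.corrcoef(model.centroids)
    np.fill_diagonal(cc, 1.0)
    return cc


def frame_centroid_similarity(pool: FramePool, model: CapResults) -> pd.DataFrame:
    """Correlation between each frame and its assigned centroid, aggregated
    per (subject, timepoint, state) for the group-representativeness ANOVA."""
    Xs = _standardize_rows(pool.frames)
    Cs = _standardize_rows(model.centroids, "centroid")
    R = Xs @ Cs.T / Xs.shape[1]
    r_own = R[np.arange(pool.n_frames), model.labels - 1]
    df = pool.index_map[["subject_id", "group", "timepoint"]].copy()
    df["state"] = model.labels
    df["r"] = r_own
    return (
        df.groupby(["subject_id", "group", "timepoint", "state"], sort=False)["r"]
        .mean()
        .reset_index()
    )


def match_clusters(centroids_a: np.ndarray, centroids_b: np.ndarray):
    """Optimal one-to-one matching between two centroid sets, maximizing the
    total pairwise correlation (Hungarian assignment). Returns
    (rows_of_a, matched_cols_of_b, matched correlations)."""
    A = np.asarray(centroids_a, dtype=float)
    B = np.asarray(centroids_b, dtype=float)
    if A.shape[1] != B.shape[1]:
        raise ValueError("centroid sets live in different ROI spaces")
    As = _standardize_rows(A, "centroid")
    Bs = _standardize_rows(B, "centroid")
    R = As @ Bs.T / A.shape[1]
    ra, cb = linear_sum_assignment(-R)
    return ra, cb, R[ra, cb]


def assign_states(ts: RoiTimeSeries, model: CapResults) -> StateSequence:
    """Per-frame state labels for one session.

    If the session is part of the model's pool (matched on subject and
    timepoint), labels come from the clustering itself; otherwise each frame
    goes to the nearest centroid under correlation distance (ties to the
    lowest state id).
    """
    if ts.n_rois != model.centroids.shape[1]:
        raise ValueError("session ROI space does not match the model")
    if model.pool is not None:
        im = model.pool.index_map
        mask = (im["subject_id"] == ts.subject_id) & (im["timepoint"] == ts.timepoint)
        if mask.sum() == ts.n_frames:
            return StateSequence(
                subject_id=ts.subject_id,
                timepoint=ts.timepoint,
                labels=model.labels[mask.to_numpy()],
                run_boundaries=ts.run_boundaries.copy(),
                group=ts.group,
            )
    Xs = _standardize_rows(ts.data)
    Cs = _standardize_rows(model.centroids, "centroid")
    D = 1.0 - Xs @ Cs.T / ts.n_rois
    labels = D.argmin(axis=1) + 1  # argmin takes the lowest index on ties
    return StateSequence(
        subject_id=ts.subject_id,
        timepoint=ts.timepoint,
        labels=labels,
        run_boundaries=ts.run_boundaries.copy(),
        group=ts.group,
    )
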
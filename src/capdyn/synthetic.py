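"""Synthetic multi-subject cohort with known CAP states and Markov dynamics.

The generator emulates the structure of a two-group longitudinal
resting-state study: a depressed (TRD) group scanned at baseline and after
treatment, a control (HC) group scanned at baseline with a longitudinal
subsample, 454 parcellated ROIs at TR = 0.8 s, two runs per session, six
planted spatial states with Markov switching, treatment effects expressed
through the transition structure (salience / executive / visual states), and
a planted correlation between the change in salience-state occupancy and the
percent change in reflective rumination.

Because every state sequence and pattern is returned as ground truth, the
whole downstream pipeline (clustering, metrics, statistics) is testable
without any restricted data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .atlas import parcel_table_for_size, validate_parcel_table
from .io import MANIFEST_COLUMNS, RoiTimeSeries
from .metrics import StateSequence, fraction_time

__all__ = [
    "PatternSet",
    "MarkovParams",
    "CohortSpec",
    "GroundTruth",
    "make_state_patterns",
    "simulate_markov_sequence",
    "simulate_session",
    "simulate_cohort",
    "stationary_distribution",
    "default_group_markov",
    "write_cohort",
    "DEFAULT_STATE_NAMES",
    "DEFAULT_STATE_NETWORKS",
]

#: Reporting order of the six planted states and the network each one loads on.
DEFAULT_STATE_NAMES = ["VN/DAN", "SMN", "DMN", "vDMN", "SN", "CEN"]
DEFAULT_STATE_NETWORKS = ["Vis", "SomMot", "Default", "Limbic", "SalVentAttn", "Cont"]
#: Secondary (weaker) network loadings, e.g. the visual state also carries
#: dorsal-attention weight.
_SECONDARY = {"VN/DAN": {"DorsAttn": 0.5}}

SN_STATE = 5  # 1-based id of the salience state in the default inventory
CEN_STATE = 6
VN_STATE = 1


@dataclass
class PatternSet:
    """Planted spatial states: signed activation weights per ROI, on a
    z-score scale (zero mean, unit variance across ROIs)."""

    patterns: np.ndarray
    state_names: list[str]
    networks: list[str]

    def __post_init__(self):
        self.patterns = np.asarray(self.patterns, dtype=float)
        mu = self.patterns.mean(axis=1)
        sd = self.patterns.std(axis=1)
        if np.abs(mu).max() > 1e-8 or np.abs(sd - 1).max() > 1e-8:
            raise ValueError("patterns must be standardized across ROIs")
        if self.n_states > 1:
            cc = np.corrcoef(self.patterns)
            iu = np.triu_indices(self.n_states, 1)
            if np.abs(cc[iu]).max() >= 0.8:
                raise ValueError("planted patterns too similar (|r| >= 0.8)")

    @property
    def n_states(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_rois(self) -> int:
        return self.patterns.shape[1]


@dataclass
class MarkovParams:
    """Row-stochastic switching dynamics; the self-transition mass governs
    dwell length."""

    initial_probs: np.ndarray
    transition_matrix: np.ndarray

    def __post_init__(self):
        self.initial_probs = np.asarray(self.initial_probs, dtype=float)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        P = self.transition_matrix
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("transition_matrix must be square")
        if self.initial_probs.shape != (P.shape[0],):
            raise ValueError("initial_probs length must match transition_matrix")
        if (P < 0).any() or (self.initial_probs < 0).any():
            raise ValueError("negative probabilities")
        if np.abs(P.sum(axis=1) - 1).max() > 1e-12:
            raise ValueError("transition_matrix rows must sum to 1")
        if abs(self.initial_probs.sum() - 1) > 1e-12:
            raise ValueError("initial_probs must sum to 1")

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]


def stationary_distribution(markov: MarkovParams) -> np.ndarray:
    """Stationary distribution of the chain: the left eigenvector of the
    transition matrix at eigenvalue 1, normalized to a simplex. This is the
    expected fraction of time per state in long sequences. Raises for
    reducible chains (e.g. the identity matrix)."""
    P = markov.transition_matrix
    n, _ = connected_components(csr_matrix(P > 0), connection="strong")
    if n > 1:
        raise ValueError(f"chain is reducible ({n} communicating classes); no unique stationary distribution")
    K = P.shape[0]
    A = P.T - np.eye(K)
    A[-1, :] = 1.0
    b = np.zeros(K)
    b[-1] = 1.0
    pi = np.linalg.solve(A, b)
    pi = np.clip(pi, 0, None)
    return pi / pi.sum()


def default_group_markov() -> dict[str, MarkovParams]:
    """Planted group dynamics for the six-state inventory.

    HC is a symmetric chain (self-transition 0.6, uniform switching). The
    depressed baseline chain routes extra mass into the salience state and
    away from the executive state (higher FT(SN), lower FT(CEN)) and skews
    the salience state's exits toward the visual state and away from the
    executive state (higher TP(SN->VN), lower TP(SN->CEN)). The
    post-treatment chain is a 25/75 mixture of the baseline and HC chains,
    i.e. dynamics mostly normalized toward controls.
    """
    K = 6
    sn, cen, vn = SN_STATE - 1, CEN_STATE - 1, VN_STATE - 1
    hc = np.full((K, K), 0.08)
    np.fill_diagonal(hc, 0.60)

    trd = np.full((K, K), 0.08)
    np.fill_diagonal(trd, 0.60)
    for i in range(K):
        if i in (sn, cen):
            continue
        trd[i, sn] = 0.11
        trd[i, cen] = 0.05
    trd[sn] = 0.06
    trd[sn, sn] = 0.66
    trd[sn, vn] = 0.13
    trd[sn, cen] = 0.03
    trd[cen] = 0.085
    trd[cen, cen] = 0.55
    trd[cen, sn] = 0.11

    post = 0.25 * trd + 0.75 * hc
    out = {}
    for name, P in (("HC", hc), ("TRD_baseline", trd), ("TRD_post", post)):
        P = P / P.sum(axis=1, keepdims=True)
        mp = MarkovParams(initial_probs=np.full(K, 1 / K), transition_matrix=P)
        out[name] = MarkovParams(stationary_distribution(mp), P)
    return out


@dataclass
class CohortSpec:
    """Stated world of the synthetic study. Sample sizes, TR, run structure
    and the mood-coupling strength mirror the study being emulated; noise
    level, motion statistics and effect routing are desk-scale choices
    documented in the methods note."""

    n_trd: int = 58
    n_hc: int = 56
    n_hc_longitudinal: int = 18
    n_rois: int = 454
    n_runs: int = 2
    frames_per_run: int = 250
    tr_seconds: float = 0.8
    noise_sigma: float = 1.0
    group_markov: dict[str, MarkovParams] | None = None
    mood_coupling_r: float = -0.402
    fd_mean: float = 0.15
    fd_sd: float = 0.17
    subject_jitter_sd: float = 0.15
    ar1_phi: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_trd, self.n_hc, self.n_rois, self.n_runs) <= 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.n_hc_longitudinal <= self.n_hc:
            raise ValueError("n_hc_longitudinal must be within 0..n_hc")
        if self.frames_per_run < 2:
            raise ValueError("frames_per_run must be >= 2")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if abs(self.mood_coupling_r) > 1:
            raise ValueError("|mood_coupling_r| must be <= 1")
        if self.group_markov is None:
            self.group_markov = default_group_markov()


@dataclass
class GroundTruth:
    """Everything the generator knows: planted patterns, true per-session
    state sequences, per-subject chains, and the planted mood couplings."""

    patterns: PatternSet
    parcel_table: pd.DataFrame
    sequences: dict = field(default_factory=dict)
    markov: dict = field(default_factory=dict)
    mood: pd.DataFrame | None = None


def make_state_patterns(
    n_states: int,
    parcel_table: pd.DataFrame,
    seed: int = 0,
    texture_sd: float = 0.05,
) -> PatternSet:
    """Block-structured spatial states: each pattern loads 1.0 on one
    network's parcels (plus any secondary loadings), near-zero elsewhere,
    with a small random texture, standardized across ROIs. Network labeling
    of the resulting states recovers the generating network."""
    validate_parcel_table(parcel_table)
    networks = list(dict.fromkeys(parcel_table["network"]))
    if n_states > len(networks):
        raise ValueError(
            f"n_states={n_states} exceeds the {len(networks)} distinct networks available"
        )
    rng = np.random.default_rng(seed)
    names, prim = [], []
    used = set()
    for i in range(n_states):
        if i < len(DEFAULT_STATE_NETWORKS) and DEFAULT_STATE_NETWORKS[i] in networks:
            names.append(DEFAULT_STATE_NAMES[i])
            prim.append(DEFAULT_STATE_NETWORKS[i])
        else:
            net = next(n for n in networks if n not in used and n not in prim)
            names.append(f"state_{net}")
            prim.append(net)
        used.add(prim[-1])

    net_col = parcel_table["network"].to_numpy()
    n_rois = len(parcel_table)
    P = np.zeros((n_states, n_rois))
    for i, (name, net) in enumerate(zip(names, prim)):
        P[i, net_col == net] = 1.0
        for sec, w in _SECONDARY.get(name, {}).items():
            if sec in networks and sec != net:
                P[i, net_col == sec] = w
        P[i] += rng.normal(0, texture_sd, n_rois)
        P[i] = (P[i] - P[i].mean()) / P[i].std()
    return PatternSet(patterns=P, state_names=names, networks=prim)


def simulate_markov_sequence(
    markov: MarkovParams, n_frames: int, rng: np.random.Generator
) -> np.ndarray:
    """One run's chain, started fresh from the initial distribution.
    Returns 1-based labels."""
    cum = np.cumsum(markov.transition_matrix, axis=1)
    x = np.empty(n_frames, dtype=int)
    x[0] = np.searchsorted(np.cumsum(markov.initial_probs), rng.random())
    u = rng.random(n_frames - 1)
    for t in range(1, n_frames):
        x[t] = np.searchsorted(cum[x[t - 1]], u[t - 1])
    return x + 1


def _fd_trace(n_frames: int, fd_mean: float, fd_sd: float, rng) -> np.ndarray:
    fd = np.abs(rng.normal(fd_mean, fd_sd, n_frames))
    fd[0] = 0.0  # FD is a difference measure; first frame undefined
    return fd


def simulate_session(
    patterns: PatternSet,
    markov: MarkovParams,
    frames_per_run: int,
    n_runs: int = 2,
    noise_sigma: float = 1.0,
    seed=0,
    subject_id: str = "sub",
    group: str = "HC",
    timepoint: str = "baseline",
    tr_seconds: float = 0.8,
    fd_mean: float = 0.15,
    fd_sd: float = 0.17,
    ar1_phi: float = 0.0,
) -> tuple[RoiTimeSeries, StateSequence]:
    """Simulate one session: each run is a fresh Markov chain over the
    planted states, and each frame is the active state's pattern plus
    Gaussian ROI noise (optionally AR(1) in time via ``ar1_phi``). An FD
    trace of folded-normal draws is attached, independent of the states."""
    if patterns.n_states != markov.n_states:
        raise ValueError("pattern count and Markov order differ")
    if frames_per_run < 2:
        raise ValueError("frames_per_run must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    T = frames_per_run * n_runs
    labels = np.concatenate(
        [simulate_markov_sequence(markov, frames_per_run, rng) for _ in range(n_runs)]
    )
    data = patterns.patterns[labels - 1].copy()
    if noise_sigma > 0:
        eps = rng.normal(0, 1.0, data.shape)
        if ar1_phi:
            for t in range(1, T):
                eps[t] = ar1_phi * eps[t - 1] + np.sqrt(1 - ar1_phi**2) * eps[t]
        data += noise_sigma * eps
    boundaries = np.arange(n_runs) * frames_per_run
    fd = np.concatenate(
        [_fd_trace(frames_per_run, fd_mean, fd_sd, rng) for _ in range(n_runs)]
    )
    ts = RoiTimeSeries(
        subject_id=subject_id,
        group=group,
        timepoint=timepoint,
        data=data,
        tr_seconds=tr_seconds,
        fd_mm=fd,
        run_boundaries=boundaries,
    )
    seq = StateSequence(
        subject_id=subject_id,
        timepoint=timepoint,
        labels=labels,
        run_boundaries=boundaries.copy(),
        group=group,
    )
    return ts, seq


def _jitter_matrix(P: np.ndarray, sd: float, rng) -> np.ndarray:
    """Per-subject heterogeneity: multiplicative log-normal jitter on the
    rows, renormalized. The same jitter field is reused across a subject's
    timepoints so the treatment effect is a within-subject shift."""
    if sd == 0:
        return P.copy()
    E = np.exp(rng.normal(0, sd, P.shape))
    Q = P * E
    return Q / Q.sum(axis=1, keepdims=True)


def simulate_cohort(spec: CohortSpec):
    """Simulate the full cohort.

    Returns ``(manifest, sessions, truth)``: a manifest DataFrame with one
    row per (subject, timepoint, run) including covariates, motion and mood
    scores; the list of RoiTimeSeries sessions (not yet z-scored); and the
    :class:`GroundTruth`.

    TRD subjects get baseline + post sessions with the treatment effect
    expressed in the transition structure; all HC get baseline and the first
    ``n_hc_longitudinal`` of them a second session with unchanged dynamics.
    The percent change in reflective rumination is generated from each TRD
    subject's *realized* change in salience-state occupancy so that their
    correlation equals ``mood_coupling_r`` in expectation.
    """
    rng = np.random.default_rng(spec.seed)
    parcel_table = parcel_table_for_size(spec.n_rois)
    patterns = make_state_patterns(6, parcel_table, seed=int(rng.integers(2**31)))
    gm = spec.group_markov
    truth = GroundTruth(patterns=patterns, parcel_table=parcel_table)
    sessions: list[RoiTimeSeries] = []
    rows = []

    def _run_session(sub, group, tp, markov, age, sex, moods):
        ts, seq = simulate_session(
            patterns,
            markov,
            spec.frames_per_run,
            spec.n_runs,
            spec.noise_sigma,
            seed=rng,
            subject_id=sub,
            group=group,
            timepoint=tp,
            tr_seconds=spec.tr_seconds,
            fd_mean=spec.fd_mean,
            fd_sd=spec.fd_sd,
            ar1_phi=spec.ar1_phi,
        )
        sessions.append(ts)
        truth.sequences[(sub, tp)] = seq
        truth.markov[(sub, tp)] = markov
        for r, sl in enumerate(ts.run_slices()):
            rows.append(
                dict(
                    subject_id=sub,
                    group=group,
                    timepoint=tp,
                    run_index=r,
                    path=f"sessions/{sub}_{tp}_run{r}.tsv",
                    age=age,
                    sex=sex,
                    mean_fd=float(ts.fd_mm[sl].mean()),
                    **moods,
                )
            )
        return seq

    # --- TRD subjects: baseline + post ------------------------------------
    trd_delta_ft_sn = np.empty(spec.n_trd)
    trd_subjects = [f"TRD{i + 1:03d}" for i in range(spec.n_trd)]
    trd_moods_cache = []
    for i, sub in enumerate(trd_subjects):
        age = float(np.clip(rng.normal(40.7, 11.3), 18, 75))
        sex = "F" if rng.random() < 0.4828 else "M"
        # jitter field drawn once per subject, shared across timepoints
        E_seed = rng.integers(2**31)
        P_base = _jitter_matrix(
            gm["TRD_baseline"].transition_matrix,
            spec.subject_jitter_sd,
            np.random.default_rng(E_seed),
        )
        P_post = _jitter_matrix(
            gm["TRD_post"].transition_matrix,
            spec.subject_jitter_sd,
            np.random.default_rng(E_seed),
        )
        mk_base = MarkovParams(stationary_distribution(MarkovParams(np.full(6, 1 / 6), P_base)), P_base)
        mk_post = MarkovParams(stationary_distribution(MarkovParams(np.full(6, 1 / 6), P_post)), P_post)
        # mood scores filled in after realized occupancies are known
        moods = dict(hdrs=np.nan, rrs_brooding=np.nan, rrs_reflection=np.nan, rrs_reappraisal=np.nan)
        seq_b = _run_session(sub, "TRD", "baseline", mk_base, age, sex, moods)
        seq_p = _run_session(sub, "TRD", "post", mk_post, age, sex, moods)
        K = patterns.n_states
        trd_delta_ft_sn[i] = (
            fraction_time(seq_p, K)[SN_STATE - 1] - fraction_time(seq_b, K)[SN_STATE - 1]
        )
        trd_moods_cache.append((sub, age, sex))

    # --- planted mood couplings -------------------------------------------
    r = spec.mood_coupling_r
    zx = (trd_delta_ft_sn - trd_delta_ft_sn.mean()) / trd_delta_ft_sn.std()
    eps = rng.normal(0, 1, spec.n_trd)
    pct_reflection = np.clip(-0.236 + 0.30 * (r * zx + np.sqrt(1 - r**2) * eps), None, 0.8)
    refl_base = np.clip(rng.normal(11.21, 3.8, spec.n_trd), 1, None)
    refl_post = refl_base / (1 - pct_reflection)
    hdrs_base = np.clip(rng.normal(19.0, 4.76, spec.n_trd), 10, None)
    hdrs_post = np.clip(rng.normal(8.4, 4.6, spec.n_trd), 0, None)
    brood_base = np.clip(rng.normal(13.4, 3.71, spec.n_trd), 1, None)
    brood_post = np.clip(rng.normal(9.5, 3.13, spec.n_trd), 1, None)
    reapp_base = np.clip(rng.normal(13.9, 4.24, spec.n_trd), 1, None)
    reapp_post = np.clip(reapp_base + rng.normal(-0.57, 3.0, spec.n_trd), 1, None)
    mood_by_key = {}
    for i, sub in enumerate(trd_subjects):
        mood_by_key[(sub, "baseline")] = dict(
            hdrs=hdrs_base[i],
            rrs_brooding=brood_base[i],
            rrs_reflection=refl_base[i],
            rrs_reappraisal=reapp_base[i],
        )
        mood_by_key[(sub, "post")] = dict(
            hdrs=hdrs_post[i],
            rrs_brooding=brood_post[i],
            rrs_reflection=refl_post[i],
            rrs_reappraisal=reapp_post[i],
        )
    truth.mood = pd.DataFrame(
        dict(
            subject_id=trd_subjects,
            delta_ft_sn=trd_delta_ft_sn,
            pct_change_reflection=pct_reflection,
        )
    )

    # --- HC subjects -------------------------------------------------------
    for i in range(spec.n_hc):
        sub = f"HC{i + 1:03d}"
        age = float(np.clip(rng.normal(32.61, 12.0), 18, 75))
        sex = "F" if rng.random() < 0.5636 else "M"
        P = _jitter_matrix(gm["HC"].transition_matrix, spec.subject_jitter_sd, rng)
        mk = MarkovParams(stationary_distribution(MarkovParams(np.full(6, 1 / 6), P)), P)
        moods = dict(
            hdrs=float(np.clip(rng.normal(2.0, 1.5), 0, None)),
            rrs_brooding=float(np.clip(rng.normal(8.5, 2.5), 1, None)),
            rrs_reflection=float(np.clip(rng.normal(9.0, 3.0), 1, None)),
            rrs_reappraisal=float(np.clip(rng.normal(13.5, 4.0), 1, None)),
        )
        _run_session(sub, "HC", "baseline", mk, age, sex, moods)
        if i < spec.n_hc_longitudinal:
            # second session with unchanged parameters (no planted change)
            _run_session(sub, "HC", "post", mk, age, sex, moods)

    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    # back-fill the TRD mood columns now that couplings are known
    for i, row in manifest.iterrows():
        key = (row["subject_id"], row["timepoint"])
        if key in mood_by_key:
            for k, v in mood_by_key[key].items():
                manifest.at[i, k] = v
    return manifest, sessions, truth


def write_cohort(outdir, manifest, sessions, truth) -> None:
    """Write the cohort in the formats the I/O layer reads: per-run session
    TSVs, the manifest, the parcel table, and ground truth (true patterns as
    TSV, sequences as JSON integer arrays)."""
    import json
    from pathlib import Path

    from .atlas import write_parcel_table
    from .io import write_manifest, write_session_matrix

    outdir = Path(outdir)
    (outdir / "sessions").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    parcel_ids = truth.parcel_table["parcel_id"].tolist()
    for ts in sessions:
        for r, sl in enumerate(ts.run_slices()):
            write_session_matrix(
                outdir / "sessions" / f"{ts.subject_id}_{ts.timepoint}_run{r}.tsv",
                ts.data[sl],
                parcel_ids,
            )
    write_manifest(outdir / "manifest.tsv", manifest)
    write_parcel_table(outdir / "parcels.tsv", truth.parcel_table)
    pd.DataFrame(truth.patterns.patterns, columns=parcel_ids).to_csv(
        outdir / "truth" / "true_patterns.tsv", sep="\t", index=False, float_format="%.10g"
    )
    seqs = {
        f"{sub}|{tp}": dict(
            labels=seq.labels.tolist(), run_boundaries=seq.run_boundaries.tolist()
        )
        for (sub, tp), seq in truth.sequences.items()
    }
    (outdir / "truth" / "ground_truth.json").write_text(
        json.dumps(
            dict(
                state_names=truth.patterns.state_names,
                networks=truth.patterns.networks,
                sequences=seqs,
            )
        )
    )
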
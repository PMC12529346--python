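"""Group and longitudinal statistics for CAP metrics.

The battery mirrors a longitudinal two-group design: paired t-tests for
within-subject treatment change, Pearson correlations between metric changes
and percent change in mood scores, covariate-adjusted (age, sex)
cross-sectional comparisons, and Bonferroni families — one across the K
states tested and one across the selected state transitions. Reported
p-values are always unadjusted; family-wise thresholds only set the
significance flags.

Demographic-table helpers (Welch t from summary statistics, 2x2 Pearson
chi-square without continuity correction, one-way ANOVA) live here too.

:class:`CapDynamicsAnalysis` bundles the battery statsmodels-style: build it
from the long metrics table plus the manifest, ``fit()`` returns a results
object with the test table and a ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "FamilySpec",
    "percent_change",
    "paired_change_test",
    "correlate_change_with_mood",
    "adjusted_group_comparison",
    "bonferroni_family",
    "tp_test_family",
    "welch_t_summary",
    "chi2_2x2",
    "oneway_anova",
    "CapDynamicsAnalysis",
    "CapDynamicsResults",
]


@dataclass
class TestResult:
    """One hypothesis test. ``significant`` is set against the family-wise
    threshold once the result joins a family; ``p`` stays unadjusted."""

    name: str
    statistic: float
    df: float
    p: float
    n: int
    family: str | None = None
    alpha_adjusted: float | None = None
    significant: bool | None = None

    @property
    def direction(self) -> int:
        return int(np.sign(self.statistic))

    def as_dict(self) -> dict:
        return dict(
            name=self.name,
            statistic=self.statistic,
            df=self.df,
            p=self.p,
            n=self.n,
            family=self.family,
            alpha_adjusted=self.alpha_adjusted,
            significant=self.significant,
        )


@dataclass
class FamilySpec:
    """A Bonferroni family: m tests at family-wise alpha, each flagged at
    alpha/m."""

    name: str
    m: int
    alpha: float = 0.05

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("family must contain at least one test")

    @property
    def threshold(self) -> float:
        return self.alpha / self.m


def bonferroni_family(
    results: list[TestResult], name: str, m: int | None = None, alpha: float = 0.05
) -> FamilySpec:
    """Flag each result against the family threshold alpha/m (m defaults to
    the number of results). P-values remain unadjusted."""
    spec = FamilySpec(name=name, m=m if m is not None else len(results), alpha=alpha)
    for r in results:
        r.family = name
        r.alpha_adjusted = spec.threshold
        r.significant = bool(r.p < spec.threshold)
    return spec


def tp_test_family(significant_states: set[int], K: int) -> list[tuple[int, int]]:
    """Transition tests implied by the state-selection rule: for every state
    with a significant occupancy/dwell effect, test the transitions *into* it
    from every other state. Two selected states among six give the 10-test
    family (0.05/10)."""
    bad = [s for s in significant_states if not 1 <= s <= K]
    if bad:
        raise ValueError(f"states {bad} outside 1..{K}")
    return [(a, s) for s in sorted(significant_states) for a in range(1, K + 1) if a != s]


def percent_change(baseline, post):
    """Percent change on the post-score scale: (post - baseline) / post.
    A post score of 0 gives a missing value with a warning."""
    baseline = np.asarray(baseline, dtype=float)
    post = np.asarray(post, dtype=float)
    zero = post == 0
    if np.any(zero):
        warnings.warn("post score of 0: percent change undefined, set to NaN")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (post - baseline) / post
    out = np.where(zero, np.nan, out)
    return float(out) if out.ndim == 0 else out


def _complete(*cols):
    mask = np.ones(len(cols[0]), dtype=bool)
    for c in cols:
        mask &= ~np.isnan(np.asarray(c, dtype=float))
    return [np.asarray(c, dtype=float)[mask] for c in cols]


def paired_change_test(baseline, post, name: str = "paired") -> TestResult:
    """Classical paired t-test on post - baseline differences (two-sided,
    df = n_pairs - 1); pairs with missing values dropped pairwise."""
    b, p = _complete(baseline, post)
    n = len(b)
    if n < 2:
        raise ValueError("need at least 2 complete pairs")
    d = p - b
    if d.std(ddof=1) == 0:
        raise ValueError("zero variance of paired differences")
    t, pv = sps.ttest_rel(p, b)
    return TestResult(name=name, statistic=float(t), df=n - 1, p=float(pv), n=n)


def correlate_change_with_mood(delta_metric, pct_change_mood, name: str = "r") -> TestResult:
    """Pearson correlation between a metric change and a mood percent change
    (two-sided t with df = n - 2)."""
    x, y = _complete(delta_metric, pct_change_mood)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in correlation input")
    r, pv = sps.pearsonr(x, y)
    return TestResult(name=name, statistic=float(r), df=n - 2, p=float(pv), n=n)


def adjusted_group_comparison(
    metric, group, age, sex, name: str = "group", residualize: bool = False
) -> TestResult:
    """Cross-sectional group comparison controlling for age and sex.

    Default is the ANCOVA-style reading: OLS of the metric on intercept +
    group indicator + age + sex, reporting the t of the group coefficient
    (df = n - 4). ``residualize=True`` instead removes age/sex by OLS and
    runs a two-sample t on the residuals (df = n - 2).
    """
    import statsmodels.api as sm

    metric = np.asarray(metric, dtype=float)
    group = np.asarray(group)
    age = np.asarray(age, dtype=float)
    sexn = np.asarray([1.0 if s in ("F", 1, True) else 0.0 for s in sex])
    mask = ~np.isnan(metric) & ~np.isnan(age)
    metric, group, age, sexn = metric[mask], group[mask], age[mask], sexn[mask]
    levels = pd.unique(group)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(levels)}")
    g = (group == levels[1]).astype(float)
    if min(g.sum(), (1 - g).sum()) < 3:
        raise ValueError("each group needs >= 3 observations")
    n = len(metric)
    if residualize:
        Z = sm.add_constant(np.column_stack([age, sexn]))
        resid = metric - Z @ np.linalg.lstsq(Z, metric, rcond=None)[0]
        t, pv = sps.ttest_ind(resid[g == 1], resid[g == 0])
        return TestResult(name=name, statistic=float(t), df=n - 2, p=float(pv), n=n)
    X = sm.add_constant(np.column_stack([g, age, sexn]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear covariates in adjusted comparison")
    fit = sm.OLS(metric, X).fit()
    return TestResult(
        name=name, statistic=float(fit.tvalues[1]), df=n - 4, p=float(fit.pvalues[1]), n=n
    )


def welch_t_summary(mean1, sd1, n1, mean2, sd2, n2, name: str = "welch") -> TestResult:
    """Welch two-sample t from summary statistics (Welch-Satterthwaite df,
    two-sided p). Reproduces demographic-table comparisons printed from
    group means and SDs."""
    if min(n1, n2) < 2 or min(sd1, sd2) <= 0:
        raise ValueError("need n >= 2 and sd > 0 per group")
    t, pv = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=False)
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return TestResult(name=name, statistic=float(t), df=float(df), p=float(pv), n=n1 + n2)


def chi2_2x2(a: int, b: int, c: int, d: int, name: str = "chi2") -> TestResult:
    """Pearson chi-square on a 2x2 count table without continuity
    correction: N(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), df = 1."""
    counts = np.array([a, b, c, d], dtype=float)
    if (counts < 0).any() or counts.sum() < 1:
        raise ValueError("counts must be non-negative with N >= 1")
    margins = [a + b, c + d, a + c, b + d]
    if 0 in margins:
        raise ValueError("zero marginal total: chi-square undefined")
    N = counts.sum()
    stat = N * (a * d - b * c) ** 2 / np.prod(np.array(margins, dtype=float))
    pv = sps.chi2.sf(stat, df=1)
    return TestResult(name=name, statistic=float(stat), df=1, p=float(pv), n=int(N))


def oneway_anova(groups: list[np.ndarray], name: str = "anova") -> TestResult:
    """Classical one-way ANOVA across >= 2 groups (each with >= 2 values)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[~np.isnan(g)] for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    F, pv = sps.f_oneway(*groups)
    N = sum(len(g) for g in groups)
    dfb, dfw = len(groups) - 1, N - len(groups)
    return TestResult(name=name, statistic=float(F), df=dfb, p=float(pv), n=N)


# ---------------------------------------------------------------------------
# study-level battery


def _key(a, b=None) -> str:
    return f"{int(a)}" if b is None or pd.isna(b) else f"{int(a)}->{int(b)}"


def _pivot(metrics: pd.DataFrame, metric: str) -> pd.DataFrame:
    sub = metrics[metrics["metric"] == metric].copy()
    sub["key"] = [_key(a, b) for a, b in zip(sub["state_from"], sub["state_to"])]
    return sub.pivot_table(
        index=["subject_id", "group", "timepoint"],
        columns="key",
        values="value",
        dropna=False,
    ).reset_index()


class CapDynamicsAnalysis:
    """Statistical model over the per-session CAP metrics of a two-group
    longitudinal cohort.

    Parameters
    ----------
    metrics : DataFrame
        Long table from :func:`capdyn.metrics.metrics_table`.
    manifest : DataFrame
        Cohort manifest (one row per run) carrying group, age, sex and mood
        scores.
    K : int
        Number of states.
    alpha : float
        Family-wise error level (default 0.05).
    """

    MOODS = ["hdrs", "rrs_brooding", "rrs_reflection", "rrs_reappraisal"]

    def __init__(self, metrics: pd.DataFrame, manifest: pd.DataFrame, K: int, alpha: float = 0.05):
        self.metrics = metrics
        self.K = K
        self.alpha = alpha
        keep = ["subject_id", "group", "timepoint", "age", "sex"] + self.MOODS
        self.subjects = manifest[keep].drop_duplicates(["subject_id", "timepoint"]).reset_index(drop=True)

    # -- helpers -----------------------------------------------------------
    def _paired_frames(self, metric: str, group: str = "TRD"):
        wide = _pivot(self.metrics, metric)
        base = wide[(wide["group"] == group) & (wide["timepoint"] == "baseline")]
        post = wide[(wide["group"] == group) & (wide["timepoint"] == "post")]
        merged = base.merge(post, on="subject_id", suffixes=("_b", "_p"))
        return merged

    def fit(self) -> "CapDynamicsResults":
        K, alpha = self.K, self.alpha
        tests: list[TestResult] = []
        families: list[FamilySpec] = []

        # 1. mood improvements in the treated group (unadjusted alpha)
        moods = self.subjects[self.subjects["group"] == "TRD"]
        mb = moods[moods["timepoint"] == "baseline"].set_index("subject_id")
        mp = moods[moods["timepoint"] == "post"].set_index("subject_id")
        common = mb.index.intersection(mp.index)
        improved = []
        for mood in self.MOODS:
            res = paired_change_test(
                mb.loc[common, mood], mp.loc[common, mood], name=f"mood_change:{mood}"
            )
            res.alpha_adjusted = alpha
            res.significant = bool(res.p < alpha)
            tests.append(res)
            if res.significant:
                improved.append(mood)

        # 2-3. longitudinal FT / MDT per state, Bonferroni across the K states
        sig_states: set[int] = set()
        for metric in ("FT", "MDT"):
            merged = self._paired_frames(metric)
            fam = []
            for s in range(1, K + 1):
                try:
                    res = paired_change_test(
                        merged[f"{s}_b"], merged[f"{s}_p"], name=f"{metric}_change:state{s}"
                    )
                except ValueError:
                    continue
                fam.append(res)
                tests.append(res)
            families.append(bonferroni_family(fam, f"{metric}_longitudinal", m=K, alpha=alpha))
            sig_states |= {
                int(r.name.rsplit("state", 1)[1]) for r in fam if r.significant
            }

        # 4. TP tests for transitions into the selected states
        tp_pairs = tp_test_family(sig_states, K)
        tp_results = []
        if tp_pairs:
            merged = self._paired_frames("TP")
            for a, b in tp_pairs:
                try:
                    res = paired_change_test(
                        merged[f"{a}->{b}_b"], merged[f"{a}->{b}_p"], name=f"TP_change:{a}->{b}"
                    )
                except (ValueError, KeyError):
                    continue
                tp_results.append(res)
                tests.append(res)
            families.append(
                bonferroni_family(tp_results, "TP_longitudinal", m=len(tp_pairs), alpha=alpha)
            )

        # 5. brain-behavior: change in FT per state vs percent change of each
        #    significantly improved mood (family across the K states)
        ft = self._paired_frames("FT")
        for mood in improved:
            pct = percent_change(
                mb.loc[common, mood].to_numpy(), mp.loc[common, mood].to_numpy()
            )
            pct_by_sub = pd.Series(pct, index=common)
            fam = []
            for s in range(1, K + 1):
                delta = ft[f"{s}_p"] - ft[f"{s}_b"]
                y = pct_by_sub.reindex(ft["subject_id"]).to_numpy()
                try:
                    res = correlate_change_with_mood(
                        delta.to_numpy(), y, name=f"corr_dFT_state{s}:{mood}"
                    )
                except ValueError:
                    continue
                fam.append(res)
                tests.append(res)
            families.append(bonferroni_family(fam, f"corr_{mood}", m=K, alpha=alpha))

        # 6. cross-sectional adjusted comparisons for metrics with
        #    significant longitudinal effects (TRD baseline vs HC, TRD post vs HC)
        cross_targets = [("FT", _key(s)) for s in sorted(sig_states)] + [
            ("TP", _key(a, b)) for a, b in tp_pairs
            if any(r.significant for r in tp_results if r.name == f"TP_change:{a}->{b}")
        ]
        cov = self.subjects.set_index(["subject_id", "timepoint"])
        for metric, key in cross_targets:
            wide = _pivot(self.metrics, metric)
            for tp_label in ("baseline", "post"):
                sel = wide[
                    ((wide["group"] == "TRD") & (wide["timepoint"] == tp_label))
                    | ((wide["group"] == "HC") & (wide["timepoint"] == "baseline"))
                ]
                meta = cov.reindex(list(zip(sel["subject_id"], sel["timepoint"])))
                try:
                    res = adjusted_group_comparison(
                        sel[key].to_numpy(),
                        sel["group"].to_numpy(),
                        meta["age"].to_numpy(),
                        meta["sex"].to_numpy(),
                        name=f"crosssec_{metric}_{key}:TRD_{tp_label}_vs_HC",
                    )
                except ValueError:
                    continue
                res.alpha_adjusted = alpha
                res.significant = bool(res.p < alpha)
                tests.append(res)

        # 7. HC longitudinal stability (no planted change expected)
        hc = self._paired_frames("FT", group="HC")
        if len(hc) >= 3:
            fam = []
            for s in range(1, K + 1):
                try:
                    res = paired_change_test(
                        hc[f"{s}_b"], hc[f"{s}_p"], name=f"HC_stability_FT:state{s}"
                    )
                except ValueError:
                    continue
                fam.append(res)
                tests.append(res)
            families.append(bonferroni_family(fam, "HC_stability", m=K, alpha=alpha))

        # 8. per-state motion ANOVA across (HC, TRD baseline, TRD post)
        fd = self.metrics[self.metrics["metric"] == "FD_state"]
        if len(fd):
            for s in range(1, K + 1):
                sub = fd[fd["state_from"] == s]
                groups = [
                    sub[(sub["group"] == "HC") & (sub["timepoint"] == "baseline")]["value"],
                    sub[(sub["group"] == "TRD") & (sub["timepoint"] == "baseline")]["value"],
                    sub[(sub["group"] == "TRD") & (sub["timepoint"] == "post")]["value"],
                ]
                try:
                    res = oneway_anova(groups, name=f"FD_anova:state{s}")
                except ValueError:
                    continue
                res.alpha_adjusted = alpha
                res.significant = bool(res.p < alpha)
                tests.append(res)

        return CapDynamicsResults(
            tests=tests, families=families, significant_states=sorted(sig_states), K=K
        )


@dataclass
class CapDynamicsResults:
    tests: list[TestResult]
    families: list[FamilySpec]
    significant_states: list[int]
    K: int
    frame_similarity_anova: list[TestResult] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.as_dict() for t in self.tests])

    def family_summary(self) -> dict:
        return {
            f.name: dict(m=f.m, alpha=f.alpha, threshold=f.threshold) for f in self.families
        }

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "CAP dynamics statistical battery",
            "================================",
            f"states: {self.K}; states with longitudinal FT/MDT effects: "
            f"{self.significant_states}",
            "",
        ]
        for f in self.families:
            lines.append(f"family {f.name}: m={f.m}, threshold={f.threshold:.4g}")
        lines.append("")
        with pd.option_context("display.width", 120, "display.max_rows", 500):
            lines.append(
                df[["name", "statistic", "df", "p", "family", "alpha_adjusted", "significant"]]
                .round({"statistic": 3, "df": 1})
                .to_string(index=False)
            )
        return "\n".join(lines)
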
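"""Normality-gated group-comparison decision tree.

The workflow mirrors common practice in tissue viability and particle
tracking studies: every group is first screened with the D'Agostino–Pearson
omnibus K² normality test. If any group rejects normality (p < 0.05) the
comparison is rank-based — Kruskal–Wallis with Dunn's post hoc. Otherwise
equality of standard deviations is assessed with the Brown–Forsythe
(median-centered) variance test: if rejected, the Brown–Forsythe and Welch
ANOVA with Dunnett's T3 post hoc; if not, ordinary one-way ANOVA with
Tukey's multiple comparisons.

All test statistics are computed from their published formulas here;
:mod:`scipy.stats` supplies only the reference distributions (χ², F, t,
normal, studentized range).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

BRANCHES = ("anova_tukey", "welch_brown_forsythe_dunnettT3", "kruskal_dunn")

#: minimum group size for the K² omnibus; smaller groups force the rank branch
MIN_N_NORMALITY = 8


@dataclass
class GroupedSamples:
    """Numeric observations keyed by group label."""

    groups: dict[str, np.ndarray]
    alpha_sig: float = 0.05

    def __post_init__(self) -> None:
        self.groups = {k: np.asarray(v, dtype=np.float64) for k, v in self.groups.items()}
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        for k, v in self.groups.items():
            if v.ndim != 1 or len(v) < 3:
                raise ValueError(f"group {k!r} needs >= 3 one-dimensional observations")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"group {k!r} contains non-finite values")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, group_col: str = "group",
                   value_col: str = "value", alpha_sig: float = 0.05) -> "GroupedSamples":
        groups = {str(g): sub[value_col].to_numpy() for g, sub in df.groupby(group_col)}
        return cls(groups, alpha_sig)

    @property
    def labels(self) -> list[str]:
        return list(self.groups.keys())


@dataclass
class TestPlan:
    """Recorded branch decision plus every intermediate p-value."""

    branch: str
    normality_p: dict[str, float]
    variance_homogeneity_p: Optional[float]
    alpha_sig: float = 0.05
    notes: list[str] = field(default_factory=list)


@dataclass
class ComparisonResult:
    branch: str
    omnibus_stat: float
    omnibus_p: float
    pairwise: pd.DataFrame  # group1, group2, statistic, p_raw, p_adj, significant
    alpha_sig: float = 0.05
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "branch": self.branch,
            "omnibus_stat": self.omnibus_stat,
            "omnibus_p": self.omnibus_p,
            "alpha_sig": self.alpha_sig,
            "pairwise": self.pairwise.to_dict(orient="records"),
            **self.extra,
        }


# ---------------------------------------------------------------------------
# Test statistics from their published formulas
# ---------------------------------------------------------------------------


def dagostino_k2(x: np.ndarray) -> tuple[float, float]:
    """D'Agostino–Pearson omnibus K² normality test.

    Combines D'Agostino's skewness Z and the Anscombe–Glynn kurtosis Z as
    K² = Z₁² + Z₂² ~ χ²(2) under normality. Requires n ≥ 8.
    """
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    if n < 8:
        raise ValueError(f"K2 omnibus requires n >= 8, got {n}")
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    m3 = np.mean((x - m) ** 3)
    m4 = np.mean((x - m) ** 4)
    # skewness transform (D'Agostino 1970)
    b1 = m3 / m2**1.5
    y = b1 * math.sqrt((n + 1) * (n + 3) / (6.0 * (n - 2)))
    beta2 = 3.0 * (n**2 + 27 * n - 70) * (n + 1) * (n + 3) / (
        (n - 2) * (n + 5) * (n + 7) * (n + 9)
    )
    w2 = -1.0 + math.sqrt(2.0 * (beta2 - 1.0))
    delta = 1.0 / math.sqrt(0.5 * math.log(w2))
    a = math.sqrt(2.0 / (w2 - 1.0))
    z1 = delta * math.log(y / a + math.sqrt((y / a) ** 2 + 1.0))
    # kurtosis transform (Anscombe & Glynn 1983)
    b2 = m4 / m2**2
    eb2 = 3.0 * (n - 1) / (n + 1)
    vb2 = 24.0 * n * (n - 2) * (n - 3) / ((n + 1) ** 2 * (n + 3) * (n + 5))
    xk = (b2 - eb2) / math.sqrt(vb2)
    sqrt_b1_b2 = (
        6.0 * (n**2 - 5 * n + 2) / ((n + 7) * (n + 9))
        * math.sqrt(6.0 * (n + 3) * (n + 5) / (n * (n - 2) * (n - 3)))
    )
    a_k = 6.0 + 8.0 / sqrt_b1_b2 * (
        2.0 / sqrt_b1_b2 + math.sqrt(1.0 + 4.0 / sqrt_b1_b2**2)
    )
    num = 1.0 - 2.0 / a_k
    den = 1.0 + xk * math.sqrt(2.0 / (a_k - 4.0))
    z2 = ((1.0 - 2.0 / (9.0 * a_k)) - np.cbrt(num / den)) / math.sqrt(2.0 / (9.0 * a_k))
    k2 = z1 * z1 + z2 * z2
    return float(k2), float(sps.chi2.sf(k2, 2))


def brown_forsythe_variance_test(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Brown–Forsythe test of equal variances (ANOVA on |x − group median|)."""
    z = [np.abs(np.asarray(g) - np.median(g)) for g in groups]
    return oneway_anova(z)


def oneway_anova(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Ordinary one-way ANOVA F test."""
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    N = int(ns.sum())
    means = np.array([g.mean() for g in groups])
    grand = float(np.concatenate(groups).mean())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((g - g.mean()) ** 2) for g in groups))
    df1, df2 = k - 1, N - k
    if ss_within == 0.0:
        # all groups internally constant: F is infinite unless means also tie
        return (0.0, 1.0) if ss_between == 0.0 else (float("inf"), 0.0)
    f = (ss_between / df1) / (ss_within / df2)
    return float(f), float(sps.f.sf(f, df1, df2))


def welch_anova(groups: Sequence[np.ndarray]) -> tuple[float, float, float]:
    """Welch's heteroscedastic one-way ANOVA (returns F*, df2, p)."""
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    k = len(groups)
    ns = np.array([len(g) for g in groups], dtype=float)
    vars_ = np.array([g.var(ddof=1) for g in groups])
    if np.any(vars_ == 0):
        vars_ = np.maximum(vars_, 1e-300)
    w = ns / vars_
    W = w.sum()
    means = np.array([g.mean() for g in groups])
    mstar = float(np.sum(w * means) / W)
    A = float(np.sum(w * (means - mstar) ** 2) / (k - 1))
    lam = float(np.sum((1.0 - w / W) ** 2 / (ns - 1.0)))
    B = 1.0 + 2.0 * (k - 2) / (k**2 - 1.0) * lam
    f = A / B
    df2 = (k**2 - 1.0) / (3.0 * lam) if lam > 0 else float("inf")
    return float(f), float(df2), float(sps.f.sf(f, k - 1, df2))


def brown_forsythe_anova(groups: Sequence[np.ndarray]) -> tuple[float, float, float]:
    """Brown–Forsythe heteroscedastic ANOVA on means (returns F*, df2, p)."""
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    k = len(groups)
    ns = np.array([len(g) for g in groups], dtype=float)
    N = ns.sum()
    means = np.array([g.mean() for g in groups])
    vars_ = np.array([g.var(ddof=1) for g in groups])
    grand = float(np.concatenate(groups).mean())
    num = float(np.sum(ns * (means - grand) ** 2))
    den_terms = (1.0 - ns / N) * vars_
    den = float(den_terms.sum())
    if den == 0.0:
        return (0.0, float("inf"), 1.0) if num == 0.0 else (float("inf"), 1.0, 0.0)
    f = num / den
    c = den_terms / den
    df2 = 1.0 / float(np.sum(c**2 / (ns - 1.0)))
    return float(f), float(df2), float(sps.f.sf(f, k - 1, df2))


def kruskal_wallis(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Kruskal–Wallis H with the standard tie correction, p from χ²(k−1)."""
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    k = len(groups)
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)  # midranks for ties
    idx = 0
    rank_sums = []
    for g in groups:
        rank_sums.append(ranks[idx: idx + len(g)].sum())
        idx += len(g)
    h = 12.0 / (N * (N + 1)) * sum(
        rs**2 / len(g) for rs, g in zip(rank_sums, groups)
    ) - 3.0 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_term / (N**3 - N)
    if correction == 0.0:
        return 0.0, 1.0  # every observation tied
    h /= correction
    return float(h), float(sps.chi2.sf(h, k - 1))


# ---------------------------------------------------------------------------
# Post-hoc procedures
# ---------------------------------------------------------------------------


def _pairs(labels: list[str], comparisons: str, reference: Optional[str]) -> list[tuple[str, str]]:
    if comparisons == "all_pairs":
        return list(itertools.combinations(labels, 2))
    if comparisons == "vs_reference":
        ref = reference if reference is not None else labels[0]
        if ref not in labels:
            raise ValueError(f"reference group {ref!r} not among {labels}")
        return [(ref, lab) for lab in labels if lab != ref]
    raise ValueError(f"comparisons must be 'all_pairs' or 'vs_reference', got {comparisons!r}")


def tukey_pairs(samples: GroupedSamples, pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Tukey–Kramer HSD: q = |Δmean| / sqrt(MSE/2·(1/n₁+1/n₂)), p from the
    studentized range with k groups and N−k error df. The studentized-range
    p is already family-adjusted; the raw column holds the pooled-t p."""
    groups = samples.groups
    k = len(groups)
    N = sum(len(v) for v in groups.values())
    mse = sum(np.sum((v - v.mean()) ** 2) for v in groups.values()) / (N - k)
    rows = []
    for g1, g2 in pairs:
        a, b = groups[g1], groups[g2]
        diff = a.mean() - b.mean()
        se_q = math.sqrt(mse / 2.0 * (1.0 / len(a) + 1.0 / len(b))) if mse > 0 else 0.0
        if se_q == 0.0:
            q = 0.0 if diff == 0.0 else float("inf")
        else:
            q = abs(diff) / se_q
        p_adj = float(sps.studentized_range.sf(q, k, N - k)) if np.isfinite(q) else 0.0
        t = q / math.sqrt(2.0)
        p_raw = float(2.0 * sps.t.sf(t, N - k)) if np.isfinite(t) else 0.0
        rows.append((g1, g2, q, p_raw, min(p_adj, 1.0)))
    return _pair_frame(rows, samples.alpha_sig)


def dunnett_t3_pairs(samples: GroupedSamples, pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Dunnett's T3-style pairwise comparisons for unequal variances:
    Welch t statistics with Welch–Satterthwaite df and a Šidák family
    adjustment over the requested comparisons."""
    groups = samples.groups
    m = len(pairs)
    rows = []
    for g1, g2 in pairs:
        a, b = groups[g1], groups[g2]
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        se = math.sqrt(va + vb)
        diff = a.mean() - b.mean()
        if se == 0.0:
            t = 0.0 if diff == 0.0 else float("inf")
            df = float(len(a) + len(b) - 2)
        else:
            t = abs(diff) / se
            df = (va + vb) ** 2 / (
                va**2 / (len(a) - 1) + vb**2 / (len(b) - 1)
            )
        p_raw = float(2.0 * sps.t.sf(t, df)) if np.isfinite(t) else 0.0
        p_adj = 1.0 - (1.0 - p_raw) ** m
        rows.append((g1, g2, t, p_raw, min(p_adj, 1.0)))
    return _pair_frame(rows, samples.alpha_sig)


def dunn_pairs(samples: GroupedSamples, pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Dunn's rank-based multiple comparisons with tie correction and a
    Bonferroni family adjustment over the requested comparisons."""
    groups = samples.groups
    labels = samples.labels
    pooled = np.concatenate([groups[g] for g in labels])
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    idx = 0
    for g in labels:
        n = len(groups[g])
        mean_ranks[g] = float(ranks[idx: idx + n].mean())
        sizes[g] = n
        idx += n
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_factor = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    m = len(pairs)
    rows = []
    for g1, g2 in pairs:
        se = math.sqrt(var_factor * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        diff = mean_ranks[g1] - mean_ranks[g2]
        if se == 0.0:
            z = 0.0 if diff == 0.0 else float("inf")
        else:
            z = abs(diff) / se
        p_raw = float(2.0 * sps.norm.sf(z)) if np.isfinite(z) else 0.0
        p_adj = min(1.0, m * p_raw)
        rows.append((g1, g2, z, p_raw, p_adj))
    return _pair_frame(rows, samples.alpha_sig)


def _pair_frame(rows: list[tuple], alpha_sig: float) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["group1", "group2", "statistic", "p_raw", "p_adj"])
    df["significant"] = df["p_adj"] < alpha_sig
    return df


# ---------------------------------------------------------------------------
# The decision tree
# ---------------------------------------------------------------------------


def select_test_branch(samples: GroupedSamples) -> TestPlan:
    """Choose the comparison branch from normality and variance screens.

    Branching (all thresholds at ``alpha_sig``): any group non-normal by the
    K² omnibus → ``kruskal_dunn``; else unequal SDs by the Brown–Forsythe
    variance test → ``welch_brown_forsythe_dunnettT3``; else ``anova_tukey``.
    Groups too small for the K² omnibus (n < 8) force the rank-based branch
    with a note, since normality cannot be assessed.
    """
    notes: list[str] = []
    if any(len(v) < MIN_N_NORMALITY for v in samples.groups.values()):
        small = [k for k, v in samples.groups.items() if len(v) < MIN_N_NORMALITY]
        notes.append(
            f"groups {small} have n < {MIN_N_NORMALITY}; normality not assessable, "
            "falling back to the rank-based branch"
        )
        return TestPlan(
            branch="kruskal_dunn",
            normality_p={k: float("nan") for k in samples.groups},
            variance_homogeneity_p=None,
            alpha_sig=samples.alpha_sig,
            notes=notes,
        )
    normality_p = {k: dagostino_k2(v)[1] for k, v in samples.groups.items()}
    if any(p < samples.alpha_sig for p in normality_p.values()):
        return TestPlan("kruskal_dunn", normality_p, None, samples.alpha_sig, notes)
    _, var_p = brown_forsythe_variance_test(list(samples.groups.values()))
    if var_p < samples.alpha_sig:
        branch = "welch_brown_forsythe_dunnettT3"
    else:
        branch = "anova_tukey"
    return TestPlan(branch, normality_p, var_p, samples.alpha_sig, notes)


def run_comparison(
    samples: GroupedSamples,
    plan: Optional[TestPlan] = None,
    comparisons: str = "all_pairs",
    reference: Optional[str] = None,
) -> ComparisonResult:
    """Omnibus test plus the branch's named post-hoc procedure.

    ``comparisons`` is ``all_pairs`` or ``vs_reference`` (reference defaults
    to the first group). Deterministic given the data.
    """
    if plan is None:
        plan = select_test_branch(samples)
    if plan.branch not in BRANCHES:
        raise ValueError(f"unknown branch {plan.branch!r}")
    group_arrays = list(samples.groups.values())
    pairs = _pairs(samples.labels, comparisons, reference)
    extra: dict = {"comparisons": comparisons}
    if plan.branch == "anova_tukey":
        stat, p = oneway_anova(group_arrays)
        pairwise = tukey_pairs(samples, pairs)
    elif plan.branch == "welch_brown_forsythe_dunnettT3":
        stat, df2, p = welch_anova(group_arrays)
        bf_stat, bf_df2, bf_p = brown_forsythe_anova(group_arrays)
        extra.update({"welch_df2": df2, "brown_forsythe_F": bf_stat,
                      "brown_forsythe_p": bf_p})
        pairwise = dunnett_t3_pairs(samples, pairs)
    else:
        stat, p = kruskal_wallis(group_arrays)
        pairwise = dunn_pairs(samples, pairs)
    return ComparisonResult(
        branch=plan.branch,
        omnibus_stat=stat,
        omnibus_p=p,
        pairwise=pairwise,
        alpha_sig=samples.alpha_sig,
        extra=extra,
    )
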
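"""Gated statistical comparison of treatment groups.

The gate mirrors common practice for small formulation studies: Shapiro–Wilk
normality per group and Levene's variance-homogeneity test decide the route —

* all groups normal, homoscedastic  → one-way ANOVA (+ Dunnett vs a control,
  else Games–Howell all-pairs),
* all groups normal, heteroscedastic → Welch ANOVA + Games–Howell,
* any group non-normal               → Kruskal–Wallis + Dunn (Holm-adjusted).

Two-sample comparisons gate between Student's t-test and Mann–Whitney.
Significance is annotated with the conventional star codes
(* p<0.05, ** p<0.01, *** p<0.001).

Dunn's rank-based post hoc test (with tie correction) is implemented here
directly; Welch ANOVA and Games–Howell come from pingouin, Dunnett from
scipy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ROUTES = ("anova_dunnett", "welch_games_howell", "kruskal_dunn", "t_test", "mann_whitney")


def star_code(p: float, alpha: float = 0.05) -> str:
    """Conventional significance stars: * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < alpha:
        return "*"
    return "n.s."


@dataclass
class ComparisonResult:
    """Outcome of a gated group comparison.

    ``posthoc`` is a DataFrame with columns (group_a, group_b, p,
    significant, star_code); use :meth:`pair_p` for order-free lookup.
    """

    metric: str
    route: str
    gate_pvalues: dict
    omnibus_p: float
    posthoc: pd.DataFrame
    alpha: float = 0.05
    notes: list[str] = field(default_factory=list)

    def pair_p(self, a: str, b: str) -> float:
        ph = self.posthoc
        row = ph[((ph.group_a == a) & (ph.group_b == b)) | ((ph.group_a == b) & (ph.group_b == a))]
        if row.empty:
            raise KeyError(f"no post hoc comparison for pair ({a}, {b})")
        return float(row.iloc[0]["p"])

    def to_frame(self) -> pd.DataFrame:
        return self.posthoc.assign(metric=self.metric, route=self.route, omnibus_p=self.omnibus_p)


def _validate_groups(groups: Sequence[Sequence[float]], labels: Sequence[str], min_n: int = 3):
    if len(groups) != len(labels):
        raise ValueError("groups and labels length mismatch")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    for lab, arr in zip(labels, arrays):
        if arr.size < min_n:
            raise ValueError(f"insufficient replicates in group {lab!r}: n={arr.size} < {min_n}")
    return arrays


def _shapiro_p(x: np.ndarray) -> float:
    # a zero-variance sample is maximally non-normal for gating purposes
    if np.ptp(x) == 0:
        return 0.0
    return float(stats.shapiro(x).pvalue)


def choose_route(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    labels: Optional[Sequence[str]] = None,
) -> str:
    """Select the multi-group route from the Shapiro/Levene gate.

    All groups must pass Shapiro–Wilk (conservative 'all' reading) for a
    parametric route; Levene (mean-centred) then separates classic from
    Welch ANOVA.  Any non-normal group sends the data down Kruskal–Wallis.
    """
    labels = labels if labels is not None else [f"g{i}" for i in range(len(groups))]
    arrays = _validate_groups(groups, labels)
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    shapiro_ps = [_shapiro_p(a) for a in arrays]
    all_normal = all(p >= alpha for p in shapiro_ps)
    if not all_normal:
        return "kruskal_dunn"
    levene_p = float(stats.levene(*arrays, center="mean").pvalue)
    return "anova_dunnett" if levene_p >= alpha else "welch_games_howell"


def gated_omnibus(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    labels: Optional[Sequence[str]] = None,
) -> tuple[str, float]:
    """Route selection plus the matching omnibus p-value, without post hocs.

    Useful for calibration studies where only the omnibus decision matters.
    """
    labels = labels if labels is not None else [f"g{i}" for i in range(len(groups))]
    arrays = _validate_groups(groups, labels)
    route = choose_route(groups, alpha=alpha, labels=labels)
    if route == "anova_dunnett":
        return route, float(stats.f_oneway(*arrays).pvalue)
    if route == "kruskal_dunn":
        return route, float(stats.kruskal(*arrays).pvalue)
    import pingouin as pg

    df = pd.DataFrame(
        {
            "value": np.concatenate(arrays),
            "group": np.concatenate([[lab] * a.size for lab, a in zip(labels, arrays)]),
        }
    )
    wa = pg.welch_anova(data=df, dv="value", between="group")
    pcol = "p_unc" if "p_unc" in wa.columns else "p-unc"
    return route, float(wa[pcol].iloc[0])


def _gate(arrays, labels, alpha):
    shapiro_ps = {lab: _shapiro_p(a) for lab, a in zip(labels, arrays)}
    try:
        levene_p = float(stats.levene(*arrays, center="mean").pvalue)
    except ValueError:  # degenerate input
        levene_p = float("nan")
    return {"shapiro": shapiro_ps, "levene": levene_p}


def _posthoc_frame(rows: list[tuple[str, str, float]], alpha: float) -> pd.DataFrame:
    recs = [
        {
            "group_a": a,
            "group_b": b,
            "p": float(min(max(p, 0.0), 1.0)),
            "significant": bool(p < alpha),
            "star_code": star_code(p, alpha),
        }
        for a, b, p in rows
    ]
    return pd.DataFrame(recs, columns=["group_a", "group_b", "p", "significant", "star_code"])


def dunn_posthoc(
    groups: Sequence[np.ndarray],
    labels: Sequence[str],
    adjust: str = "holm",
) -> list[tuple[str, str, float]]:
    """Dunn's all-pairs rank comparison with tie correction.

    z_ij = (R̄_i − R̄_j) / sqrt[(N(N+1)/12 − T) (1/n_i + 1/n_j)] with the tie
    term T = Σ(t³ − t) / (12(N − 1)); two-sided normal p-values, Holm-adjusted
    by default.
    """
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start: start + g.size].mean())
        sizes.append(g.size)
        start += g.size

    raw = []
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        raw.append((labels[i], labels[j], 2.0 * stats.norm.sf(abs(z))))
    if adjust == "holm":
        ps = np.array([p for _, _, p in raw])
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * ps[idx])
            adj[idx] = min(1.0, running)
        raw = [(a, b, adj[k]) for k, (a, b, _) in enumerate(raw)]
    return raw


def _games_howell(arrays, labels) -> list[tuple[str, str, float]]:
    import pingouin as pg

    df = pd.DataFrame(
        {
            "value": np.concatenate(arrays),
            "group": np.concatenate([[lab] * a.size for lab, a in zip(labels, arrays)]),
        }
    )
    gh = pg.pairwise_gameshowell(data=df, dv="value", between="group")
    return [(str(r["A"]), str(r["B"]), float(r["pval"])) for _, r in gh.iterrows()]


def compare_groups(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str],
    alpha: float = 0.05,
    control: Optional[str] = None,
    metric: str = "",
) -> ComparisonResult:
    """Gated omnibus + route-matched post hoc comparison of ≥2 groups.

    When ``control`` names a group and the classic ANOVA route is selected,
    Dunnett's many-to-one test compares every treatment against it;
    otherwise the post hoc is all-pairs (Games–Howell on the parametric
    routes, Holm-adjusted Dunn on the rank route).
    """
    arrays = _validate_groups(groups, labels)
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if control is not None and control not in labels:
        raise ValueError(f"control group {control!r} not among labels {list(labels)}")

    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        # all values identical: every test is vacuous, report the null outcome
        rows = [(a, b, 1.0) for a, b in combinations(labels, 2)]
        return ComparisonResult(
            metric=metric,
            route="anova_dunnett",
            gate_pvalues={"shapiro": {lab: float("nan") for lab in labels}, "levene": float("nan")},
            omnibus_p=1.0,
            posthoc=_posthoc_frame(rows, alpha),
            alpha=alpha,
            notes=["no variance: all values identical; tests are vacuous"],
        )

    gate = _gate(arrays, labels, alpha)
    route, omnibus_p = gated_omnibus(groups, alpha=alpha, labels=labels)

    if route == "anova_dunnett":
        if control is not None:
            ctrl_idx = list(labels).index(control)
            treat = [a for i, a in enumerate(arrays) if i != ctrl_idx]
            t_labels = [lab for i, lab in enumerate(labels) if i != ctrl_idx]
            dn = stats.dunnett(*treat, control=arrays[ctrl_idx])
            rows = [(lab, control, float(p)) for lab, p in zip(t_labels, dn.pvalue)]
        else:
            rows = _games_howell(arrays, labels)
    elif route == "welch_games_howell":
        rows = _games_howell(arrays, labels)
    else:  # kruskal_dunn
        rows = dunn_posthoc(arrays, labels)

    return ComparisonResult(
        metric=metric,
        route=route,
        gate_pvalues=gate,
        omnibus_p=omnibus_p,
        posthoc=_posthoc_frame(rows, alpha),
        alpha=alpha,
    )


def compare_two(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = 0.05,
    labels: tuple[str, str] = ("a", "b"),
    metric: str = "",
) -> ComparisonResult:
    """Two-sample comparison: Student's t-test if both samples pass
    Shapiro–Wilk, Mann–Whitney otherwise (two-sided)."""
    arrays = _validate_groups([a, b], list(labels))
    xa, xb = arrays
    if np.ptp(np.concatenate(arrays)) == 0:
        return ComparisonResult(
            metric=metric,
            route="t_test",
            gate_pvalues={"shapiro": {labels[0]: float("nan"), labels[1]: float("nan")}},
            omnibus_p=1.0,
            posthoc=_posthoc_frame([(labels[0], labels[1], 1.0)], alpha),
            alpha=alpha,
            notes=["no variance: all values identical; tests are vacuous"],
        )
    sp = {labels[0]: _shapiro_p(xa), labels[1]: _shapiro_p(xb)}
    if all(p >= alpha for p in sp.values()):
        route = "t_test"
        p = float(stats.ttest_ind(xa, xb, equal_var=True).pvalue)
    else:
        route = "mann_whitney"
        p = float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
    return ComparisonResult(
        metric=metric,
        route=route,
        gate_pvalues={"shapiro": sp},
        omnibus_p=p,
        posthoc=_posthoc_frame([(labels[0], labels[1], p)], alpha),
        alpha=alpha,
    )
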
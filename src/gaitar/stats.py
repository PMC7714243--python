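"""Group-level comparison of gait metrics across walking conditions.

One-way ANOVA with Tukey HSD post-hoc tests on per-participant condition
means of (a) mean peak vGRF and (b) the AR centroid-distance statistic, with
compact letter displays summarising which conditions differ. Participants'
values in different conditions are treated as independent observations — the
classical one-way layout — which ignores the repeated-measures structure; the
report flags this limitation.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

METRICS = ("mean_peak_vgrf_bw", "ar_distance")


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    df_between: int
    df_within: int
    group_means: np.ndarray
    group_sds: np.ndarray
    group_ns: np.ndarray
    ms_within: float


def _validate_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in gs):
        raise ValueError("every group needs at least 2 observations")
    return gs


def one_way_anova(groups) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA from sums of squares.

    F = MS_between / MS_within with df (k−1, N−k); the p-value comes from the
    F distribution. Zero pooled within-group variance is degenerate and
    raises.
    """
    gs = _validate_groups(groups)
    k = len(gs)
    ns = np.array([g.size for g in gs])
    N = int(ns.sum())
    means = np.array([g.mean() for g in gs])
    grand = np.concatenate(gs).mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(gs, means)))
    df_b, df_w = k - 1, N - k
    if ss_within <= 0.0:
        raise ValueError("zero within-group variance: ANOVA undefined")
    ms_w = ss_within / df_w
    f = (ss_between / df_b) / ms_w
    p = float(_sps.f.sf(f, df_b, df_w))
    return AnovaResult(f=f, p=p, df_between=df_b, df_within=df_w,
                       group_means=means,
                       group_sds=np.array([g.std(ddof=1) for g in gs]),
                       group_ns=ns, ms_within=ms_w)


@dataclass(frozen=True)
class PairwiseComparison:
    i: int
    j: int
    mean_difference: float
    q: float
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class TukeyResult:
    anova: AnovaResult
    alpha: float
    pairs: tuple[PairwiseComparison, ...]
    q_critical: float
    letters: tuple[str, ...] = field(default=())

    def pair(self, i: int, j: int) -> PairwiseComparison:
        a, b = min(i, j), max(i, j)
        for p in self.pairs:
            if (p.i, p.j) == (a, b):
                return p
        raise KeyError((i, j))


def studentized_range_critical(alpha: float, k: int, df: int) -> float:
    """Upper-α quantile q(α; k, df) of the studentized range distribution."""
    return float(_sps.studentized_range.ppf(1.0 - alpha, k, df))


def tukey_hsd(groups, alpha: float = 0.05) -> TukeyResult:
    """Tukey HSD pairwise comparisons after a one-way layout.

    q_ij = |mean_i − mean_j| / sqrt(MS_within (1/n_i + 1/n_j) / 2) (the
    Tukey–Kramer form for unequal n); adjusted p-values come from the
    studentized range distribution with (k, df_within). Results are symmetric
    in pair order and completed with a compact letter display.
    """
    anova = one_way_anova(groups)
    k = anova.group_means.size
    qcrit = studentized_range_critical(alpha, k, anova.df_within)
    pairs = []
    for i, j in itertools.combinations(range(k), 2):
        diff = float(anova.group_means[i] - anova.group_means[j])
        se = np.sqrt(anova.ms_within / 2.0
                     * (1.0 / anova.group_ns[i] + 1.0 / anova.group_ns[j]))
        q = abs(diff) / se
        p_adj = float(_sps.studentized_range.sf(q, k, anova.df_within))
        pairs.append(PairwiseComparison(i=i, j=j, mean_difference=diff, q=q,
                                        p_adjusted=min(1.0, p_adj),
                                        significant=p_adj < alpha))
    result = TukeyResult(anova=anova, alpha=alpha, pairs=tuple(pairs), q_critical=qcrit)
    return TukeyResult(anova=anova, alpha=alpha, pairs=tuple(pairs),
                       q_critical=qcrit, letters=tuple(letter_display(result)))


def letter_display(tukey: TukeyResult) -> list[str]:
    """Compact letter display: groups sharing a letter are not significantly
    different.

    Letters are assigned to the maximal cliques of the graph whose edges are
    the non-significant pairs, ordered by descending group mean, so every
    non-significant pair shares at least one letter and no significant pair
    shares any.
    """
    import networkx as nx

    k = tukey.anova.group_means.size
    g = nx.Graph()
    g.add_nodes_from(range(k))
    for p in tukey.pairs:
        if not p.significant:
            g.add_edge(p.i, p.j)
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(g)]
    # deterministic order: cliques containing larger means come first
    cliques.sort(key=lambda c: (-max(tukey.anova.group_means[list(c)]), c))
    letters = [""] * k
    for letter, clique in zip(string.ascii_uppercase, cliques):
        for i in clique:
            letters[i] += letter
    return ["".join(sorted(s)) for s in letters]


DEFAULT_FAMILIES = {
    "symmetric": ["sym_0.75", "sym_1.00", "sym_1.50"],
    "symmetric_vs_asymmetric": ["sym_1.00", "asym_0.25", "asym_0.50"],
}


@dataclass(frozen=True)
class FamilyComparison:
    limb: str
    metric: str
    family: str
    conditions: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    ns: np.ndarray
    anova_p: float
    anova_f: float
    letters: tuple[str, ...]
    tukey: TukeyResult


@dataclass(frozen=True)
class ConditionComparison:
    """All family comparisons plus tabular views of the study metrics."""

    families: tuple[FamilyComparison, ...]
    note: str = ("participants treated as independent observations per condition "
                 "(one-way layout); repeated-measures correlation is ignored")

    def table(self) -> pd.DataFrame:
        """Display table: one row per limb × metric × family, mean (sd) cells
        with letter superscripts, to one decimal place."""
        rows = []
        for fc in self.families:
            row = {"limb": fc.limb, "metric": fc.metric, "family": fc.family}
            for cond, m, s, letters in zip(fc.conditions, fc.means, fc.sds, fc.letters):
                row[cond] = f"{m:.1f} ({s:.1f}) {letters}"
            row["p_value"] = f"{fc.anova_p:.3f}" if fc.anova_p >= 0.001 else "<0.001"
            rows.append(row)
        return pd.DataFrame(rows)

    def find(self, limb: str, metric: str, family: str) -> FamilyComparison:
        for fc in self.families:
            if (fc.limb, fc.metric, fc.family) == (limb, metric, family):
                return fc
        raise KeyError((limb, metric, family))

    def records(self) -> list[dict]:
        out = []
        for fc in self.families:
            out.append({
                "limb": fc.limb, "metric": fc.metric, "family": fc.family,
                "conditions": list(fc.conditions),
                "means": [float(x) for x in fc.means],
                "sds": [float(x) for x in fc.sds],
                "n": [int(x) for x in fc.ns],
                "anova_F": fc.anova_f, "anova_p": fc.anova_p,
                "letters": list(fc.letters),
                "pairs": [{"i": p.i, "j": p.j, "diff": p.mean_difference,
                           "q": p.q, "p_adjusted": p.p_adjusted,
                           "significant": p.significant} for p in fc.tukey.pairs],
                "note": self.note,
            })
        return out


def compare_conditions(metrics: pd.DataFrame,
                       families: dict[str, list[str]] | None = None,
                       alpha: float = 0.05) -> ConditionComparison:
    """Per-limb ANOVA + Tukey comparisons of condition means for each metric.

    ``metrics`` must be long-form with columns ``participant, limb, condition,
    metric, value`` and one value per participant × limb × condition × metric.
    ``families`` maps a family name to the ordered condition labels compared
    within it (default: the three symmetric speeds, and symmetric 1.0 m/s
    versus the two asymmetric conditions).
    """
    required = {"participant", "limb", "condition", "metric", "value"}
    if not required.issubset(metrics.columns):
        raise ValueError(f"metrics table must have columns {sorted(required)}")
    dup = metrics.duplicated(subset=["participant", "limb", "condition", "metric"])
    if dup.any():
        raise ValueError("metrics table has duplicate participant/limb/condition/metric cells")
    families = families or DEFAULT_FAMILIES

    missing = []
    results = []
    for limb in sorted(metrics["limb"].unique()):
        for metric in sorted(metrics["metric"].unique()):
            sub = metrics[(metrics["limb"] == limb) & (metrics["metric"] == metric)]
            for fam_name, conds in families.items():
                groups = []
                for cond in conds:
                    vals = sub.loc[sub["condition"] == cond, "value"].to_numpy()
                    if vals.size < 2:
                        missing.append((limb, metric, fam_name, cond))
                    groups.append(vals)
                if missing:
                    continue
                tk = tukey_hsd(groups, alpha=alpha)
                results.append(FamilyComparison(
                    limb=limb, metric=metric, family=fam_name,
                    conditions=tuple(conds),
                    means=tk.anova.group_means, sds=tk.anova.group_sds,
                    ns=tk.anova.group_ns,
                    anova_p=tk.anova.p, anova_f=tk.anova.f,
                    letters=tk.letters, tukey=tk))
    if missing:
        raise ValueError(f"missing/short metric cells: {missing}")
    return ConditionComparison(families=tuple(results))
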
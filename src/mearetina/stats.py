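"""Group statistics: the normality-gated parametric/nonparametric tree.

For any upstream metric, groups are compared with the standard decision
tree: Shapiro–Wilk normality per group; if every group passes at α the
parametric branch runs (Student's t-test for two groups, one-way ANOVA
with Tukey's post-hoc for more), otherwise the nonparametric branch
(Mann–Whitney U, or Kruskal–Wallis with Dunn's post-hoc,
Bonferroni-adjusted). Significance codes follow the usual convention
(* p<0.05, ** p<0.01, *** p<0.001).

Groups (channels or cells) are treated as independent observations; any
nesting of channels within retinas is deliberately not modelled here —
reported n is the number of channels/cells per group.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class ComparisonResult:
    """Outcome of one group comparison."""

    metric_name: str
    groups: dict[str, int]                  # label → n
    group_means: dict[str, float]
    group_sems: dict[str, float]
    normality_p: dict[str, float]
    branch: str                             # parametric | nonparametric
    omnibus_test: str
    omnibus_stat: float
    omnibus_p: float
    posthoc: dict[str, float] = field(default_factory=dict)
    significance: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def significance_code(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _dunn_posthoc(samples: Sequence[np.ndarray],
                  labels: Sequence[str]) -> dict[str, float]:
    """Dunn's rank-based z-test for all pairs, Bonferroni-adjusted."""
    pooled = np.concatenate(samples)
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    # tie correction: sum(t^3 - t) over tied groups
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts ** 3 - counts).sum())
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    mean_ranks, sizes = [], []
    start = 0
    for s in samples:
        mean_ranks.append(ranks[start:start + s.size].mean())
        sizes.append(s.size)
        start += s.size
    m = len(samples) * (len(samples) - 1) // 2
    out = {}
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            z = ((mean_ranks[i] - mean_ranks[j])
                 / np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j])))
            p = 2.0 * sps.norm.sf(abs(z))
            out[f"{labels[i]} vs {labels[j]}"] = float(min(1.0, p * m))
    return out


def _tukey_posthoc(samples: Sequence[np.ndarray],
                   labels: Sequence[str]) -> dict[str, float]:
    res = sps.tukey_hsd(*samples)
    out = {}
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            out[f"{labels[i]} vs {labels[j]}"] = float(res.pvalue[i, j])
    return out


def compare_groups(values_by_group: Mapping[str, np.ndarray],
                   metric_name: str = "", alpha: float = 0.05,
                   welch: bool = False,
                   posthoc_alpha: float = 0.05) -> ComparisonResult:
    """Run the full decision tree on one metric.

    The branch is parametric iff every group passes Shapiro–Wilk at
    ``alpha``; constant-valued groups make normality undefined and route
    nonparametric with a warning. Post-hoc tests run only when the omnibus
    p-value is below ``posthoc_alpha``. ``welch`` enables the
    unequal-variance t-test (off by default: the classic tree uses
    Student's t).
    """
    labels = list(values_by_group)
    samples = [np.asarray(values_by_group[g], dtype=float) for g in labels]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    for g, s in zip(labels, samples):
        if s.size < 3:
            raise ValueError(f"group '{g}' has n={s.size} < 3")

    warns: list[str] = []
    normality_p: dict[str, float] = {}
    all_normal = True
    for g, s in zip(labels, samples):
        if np.ptp(s) == 0:
            normality_p[g] = np.nan
            all_normal = False
            warns.append(f"group '{g}' is constant; normality undefined, "
                         "routed nonparametric")
        else:
            normality_p[g] = float(sps.shapiro(s).pvalue)
            all_normal &= normality_p[g] >= alpha

    branch = "parametric" if all_normal else "nonparametric"
    posthoc: dict[str, float] = {}
    if len(samples) == 2:
        if branch == "parametric":
            test = "welch-t" if welch else "student-t"
            r = sps.ttest_ind(samples[0], samples[1], equal_var=not welch)
        else:
            test = "mann-whitney"
            r = sps.mannwhitneyu(samples[0], samples[1],
                                 alternative="two-sided")
        stat, p = float(r.statistic), float(r.pvalue)
    else:
        if branch == "parametric":
            test = "one-way-anova"
            r = sps.f_oneway(*samples)
            stat, p = float(r.statistic), float(r.pvalue)
            if p < posthoc_alpha:
                posthoc = _tukey_posthoc(samples, labels)
        else:
            test = "kruskal-wallis"
            try:
                r = sps.kruskal(*samples)
                stat, p = float(r.statistic), float(r.pvalue)
            except ValueError:        # all values identical across groups
                stat, p = 0.0, 1.0
                warns.append("all values identical; Kruskal–Wallis "
                             "undefined, p set to 1")
            if p < posthoc_alpha:
                posthoc = _dunn_posthoc(samples, labels)

    return ComparisonResult(
        metric_name=metric_name,
        groups={g: int(s.size) for g, s in zip(labels, samples)},
        group_means={g: float(s.mean()) for g, s in zip(labels, samples)},
        group_sems={g: float(s.std(ddof=1) / np.sqrt(s.size))
                    for g, s in zip(labels, samples)},
        normality_p=normality_p,
        branch=branch, omnibus_test=test,
        omnibus_stat=stat, omnibus_p=p,
        posthoc=posthoc,
        significance={pair: significance_code(q)
                      for pair, q in posthoc.items()},
        warnings=warns,
    )


def summarize_report(results: Sequence[ComparisonResult],
                     metadata: Mapping[str, object] | None = None,
                     ) -> tuple[dict, str]:
    """Machine-readable (JSON-able dict) and Markdown twin of all comparisons.

    Ordering is deterministic (input order for comparisons, insertion
    order within each). The n definition (channels, cells, mice) should be
    passed in ``metadata`` by the caller — n is always reported per group,
    never pooled.
    """
    meta = dict(metadata or {})
    doc: dict = {"metadata": meta, "comparisons": []}
    lines = ["# Group comparison report", ""]
    for k, v in meta.items():
        lines.append(f"- {k}: {v}")
    if meta:
        lines.append("")
    for res in results:
        entry = {
            "metric": res.metric_name,
            "groups": [
                {"label": g, "n": res.groups[g],
                 "mean": res.group_means[g], "sem": res.group_sems[g]}
                for g in res.groups],
            "normality_p": res.normality_p,
            "branch": res.branch,
            "omnibus": {"test": res.omnibus_test, "stat": res.omnibus_stat,
                        "p": res.omnibus_p,
                        "code": significance_code(res.omnibus_p)},
            "posthoc": [
                {"pair": pair, "p_adj": p,
                 "code": res.significance[pair]}
                for pair, p in res.posthoc.items()],
            "warnings": res.warnings,
        }
        doc["comparisons"].append(entry)
        lines.append(f"## {res.metric_name}")
        lines.append("")
        for g in res.groups:
            lines.append(f"- {g}: {res.group_means[g]:.3g} ± "
                         f"{res.group_sems[g]:.3g} (n={res.groups[g]})")
        lines.append(f"- branch: {res.branch}; {res.omnibus_test} "
                     f"stat={res.omnibus_stat:.4g}, "
                     f"p={res.omnibus_p:.3g} "
                     f"[{significance_code(res.omnibus_p)}]")
        for pair, p in res.posthoc.items():
            lines.append(f"- post-hoc {pair}: p={p:.3g} "
                         f"[{res.significance[pair]}]")
        for w in res.warnings:
            lines.append(f"- warning: {w}")
        lines.append("")
    return doc, "\n".join(lines)
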
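"""Group comparisons: Kruskal-Wallis + Dunn and one-way ANOVA + Tukey.

The nonparametric route (Kruskal-Wallis omnibus with Dunn's z-tests on mean
ranks, multiplicity-adjusted) is the default for skewed behavioral measures
such as anticipation indices and rhythm power; the parametric route (one-way
ANOVA with Tukey's HSD) fits approximately normal measures such as per-brain
mean fluorescence.  ``select_test`` offers an advisory normality screen, but
the pipeline applies whichever test its configuration names.

Dunn's test here uses the tie-corrected pooled rank variance

``sigma_ij^2 = [N(N+1)/12 - sum_g (t_g^3 - t_g) / (12 (N-1))] (1/n_i + 1/n_j)``

and adjusts the two-sided normal p-values over all pairs by Bonferroni
(default) or Holm.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class GroupComparison:
    method: str  # "kruskal_dunn" | "anova_tukey"
    groups: dict[str, np.ndarray]
    omnibus_stat: float
    omnibus_p: float
    pairwise: dict[tuple[str, str], float]  # adjusted p per pair
    pairwise_unadjusted: dict[tuple[str, str], float]


def _clean_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out = {}
    for label, vals in groups.items():
        a = np.asarray(vals, dtype=float)
        a = a[np.isfinite(a)]
        if a.size < 2:
            raise ValueError(f"group {label!r} needs at least 2 finite observations")
        out[label] = a
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    return out


def _adjust(pvals: dict[tuple[str, str], float], method: str) -> dict[tuple[str, str], float]:
    pairs = list(pvals)
    p = np.array([pvals[k] for k in pairs])
    m = p.size
    if method == "bonferroni":
        adj = np.minimum(1.0, p * m)
    elif method == "holm":
        order = np.argsort(p)
        adj = np.empty_like(p)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, min(1.0, (m - rank) * p[idx]))
            adj[idx] = running
    else:
        raise ValueError(f"unknown adjustment {method!r}")
    return {k: float(v) for k, v in zip(pairs, adj)}


def kruskal_dunn(
    groups: Mapping[str, Sequence[float]], adjust: str = "bonferroni"
) -> GroupComparison:
    """Kruskal-Wallis omnibus with Dunn's multiplicity-adjusted post-hoc."""
    g = _clean_groups(groups)
    labels = list(g)
    samples = [g[k] for k in labels]
    if np.ptp(np.concatenate(samples)) == 0:
        h, omnibus_p = 0.0, 1.0
    else:
        h, omnibus_p = sps.kruskal(*samples)
    pooled = np.concatenate(samples)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for label, a in zip(labels, samples):
        mean_ranks[label] = ranks[start : start + a.size].mean()
        start += a.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    raw: dict[tuple[str, str], float] = {}
    for a, b in combinations(labels, 2):
        se = np.sqrt(base_var * (1.0 / g[a].size + 1.0 / g[b].size))
        if se == 0:
            raw[(a, b)] = 1.0
            continue
        z = (mean_ranks[a] - mean_ranks[b]) / se
        raw[(a, b)] = float(2 * sps.norm.sf(abs(z)))
    return GroupComparison(
        method="kruskal_dunn",
        groups=g,
        omnibus_stat=float(h),
        omnibus_p=float(omnibus_p),
        pairwise=_adjust(raw, adjust),
        pairwise_unadjusted=raw,
    )


def anova_tukey(groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """One-way ANOVA omnibus with Tukey HSD pairwise comparisons."""
    g = _clean_groups(groups)
    labels = list(g)
    samples = [g[k] for k in labels]
    if np.ptp(np.concatenate(samples)) == 0:
        f, p = 0.0, 1.0
        pairwise = {pair: 1.0 for pair in combinations(labels, 2)}
        return GroupComparison("anova_tukey", g, f, p, pairwise, dict(pairwise))
    f, p = sps.f_oneway(*samples)
    hsd = sps.tukey_hsd(*samples)
    pairwise = {}
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            pairwise[(a, labels[j])] = float(hsd.pvalue[i, j])
    # Tukey p-values are already familywise-adjusted
    return GroupComparison(
        method="anova_tukey",
        groups=g,
        omnibus_stat=float(f),
        omnibus_p=float(p),
        pairwise=pairwise,
        pairwise_unadjusted=dict(pairwise),
    )


def select_test(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> str:
    """Advisory normality screen: 'parametric' or 'nonparametric'.

    Shapiro-Wilk on each group; any rejection (or a group too small to test)
    recommends the nonparametric route.  A configured per-figure choice always
    overrides this advice in the pipeline.
    """
    g = _clean_groups(groups)
    for a in g.values():
        if a.size < 3 or np.ptp(a) == 0:
            return "nonparametric"
        if sps.shapiro(a).pvalue < alpha:
            return "nonparametric"
    return "parametric"


def comparison_to_frame(comp: GroupComparison):
    import pandas as pd

    rows = [
        {
            "comparison": "omnibus",
            "method": comp.method,
            "stat": comp.omnibus_stat,
            "p": comp.omnibus_p,
        }
    ]
    for (a, b), padj in comp.pairwise.items():
        rows.append(
            {
                "comparison": f"{a} vs {b}",
                "method": comp.method,
                "stat": np.nan,
                "p": padj,
            }
        )
    return pd.DataFrame(rows)
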
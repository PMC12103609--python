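"""Community-level summaries: densities, group assignment, medians, tests.

Sites are partitioned into three community types by hierarchical clustering
of their morph composition (Bray-Curtis distance on per-site morph
proportions, average linkage, tree cut at three clusters): orange-dominant
``O``, pink-dominant ``P`` and mixed ``M``. Per-group medians and a
rank-sum comparison of nearest-neighbour distances quantify how each
morph's spacing changes with community context.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import mannwhitneyu

from .geometry import Window


def density(count: int, window: Optional[Window] = None) -> float:
    """Individuals per square metre in the observation window."""
    if count < 0:
        raise ValueError("count must be non-negative")
    window = window or Window()
    return count / window.area_m2


@dataclass(frozen=True)
class GroupAssignment:
    """Site -> community-type labels with the clustering linkage record."""

    labels: dict
    linkage: np.ndarray
    mean_orange_proportion: dict

    def __getitem__(self, site_id: str) -> str:
        return self.labels[site_id]

    def sizes(self) -> dict:
        out = {"O": 0, "P": 0, "M": 0}
        for g in self.labels.values():
            out[g] += 1
        return out


def assign_groups(compositions: Mapping[str, tuple]) -> GroupAssignment:
    """Cluster sites into O / P / M community types by morph composition.

    ``compositions`` maps site_id -> (orange count, pink count). Sites are
    represented by their morph *proportion* vectors (no pseudo-counts),
    clustered with average linkage on Bray-Curtis distances and cut at
    three groups; clusters are labelled by mean orange proportion
    (highest -> O, lowest -> P, middle -> M).
    """
    site_ids = sorted(compositions)
    if len(site_ids) < 3:
        raise ValueError("group assignment needs at least 3 sites")
    props = []
    for sid in site_ids:
        o, p = compositions[sid]
        total = o + p
        if total <= 0:
            raise ValueError(f"site {sid!r} has no individuals")
        props.append((o / total, p / total))
    props = np.asarray(props)
    dist = pdist(props, metric="braycurtis")
    link = linkage(dist, method="average")
    clusters = fcluster(link, t=3, criterion="maxclust")

    mean_orange = {
        c: float(props[clusters == c, 0].mean()) for c in np.unique(clusters)
    }
    order = sorted(mean_orange, key=mean_orange.get, reverse=True)
    name_by_cluster = {}
    if len(order) >= 1:
        name_by_cluster[order[0]] = "O"
    if len(order) >= 2:
        name_by_cluster[order[-1]] = "P"
    for c in order[1:-1]:
        name_by_cluster[c] = "M"
    labels = {sid: name_by_cluster[c] for sid, c in zip(site_ids, clusters)}
    return GroupAssignment(
        labels=labels,
        linkage=link,
        mean_orange_proportion={name_by_cluster[c]: v for c, v in mean_orange.items()},
    )


def group_medians(
    summaries: Sequence[Mapping], group: str, morph: str, fieldname: str
) -> float:
    """Median of a per-site field over one group and morph.

    ``summaries`` are per-site/morph records (dicts or DataFrame rows) with
    at least ``group``, ``morph`` and the named field. Even-count medians
    are midpoints.
    """
    if isinstance(summaries, pd.DataFrame):
        summaries = summaries.to_dict("records")
    values = [
        float(s[fieldname])
        for s in summaries
        if s.get("group") == group and s.get("morph") == morph and pd.notna(s.get(fieldname))
    ]
    if not values:
        raise ValueError(f"no values for group={group!r}, morph={morph!r}, field={fieldname!r}")
    return float(np.median(values))


def compare_nn_between_groups(values_a: Sequence[float], values_b: Sequence[float]):
    """Two-sided Wilcoxon rank-sum comparison of two groups of site medians.

    Uses the exact rank-sum null distribution when the combined sample size
    is at most 25 and there are no ties, and the tie-corrected normal
    approximation otherwise. Returns ``(statistic, p)``; with fewer than 2
    sites in either group the p-value is not estimable (returned as NaN).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if len(a) < 2 or len(b) < 2:
        import warnings

        warnings.warn("a group has fewer than 2 sites; p not estimable", stacklevel=2)
        return math.nan, math.nan
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 25 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def percent_change(before: float, after: float) -> int:
    """Relative change in percent, rounded to the nearest integer."""
    if before <= 0:
        raise ValueError("baseline value must be positive")
    return int(round(100.0 * (after - before) / before))
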
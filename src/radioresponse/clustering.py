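"""Radiosensitivity cohort assignment by hierarchical clustering of SF3.5.

Cell lines are clustered on their surviving fraction at 3.5 Gy (a univariate
feature, so no standardisation) with Euclidean distance and average (UPGMA)
linkage, and the tree is cut into k = 4 groups.  Labels follow the
sensitive-to-resistant convention: S, MS, MR, R, ordered by ascending
cluster-mean SF3.5 (a higher surviving fraction means more resistant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .datasets import PanelEntry

__all__ = ["SensitivityGrouping", "cluster_sf35", "resistant_vs_rest", "GROUP_ORDER"]

GROUP_ORDER = ("S", "MS", "MR", "R")


@dataclass(frozen=True)
class SensitivityGrouping:
    """Partition of the panel into ordered radiosensitivity cohorts."""

    assignments: dict[str, str]  # cell line -> label
    group_means: dict[str, float]  # label -> mean SF3.5
    linkage_record: np.ndarray  # scipy condensed linkage matrix

    def members(self, label: str) -> list[str]:
        return [line for line, lab in self.assignments.items() if lab == label]


def _labels_for_k(k: int) -> tuple[str, ...]:
    if k == 4:
        return GROUP_ORDER
    return tuple(f"G{i + 1}" for i in range(k))


def cluster_sf35(entries: list[PanelEntry], k: int = 4) -> SensitivityGrouping:
    """UPGMA clustering of the panel on SF3.5, cut to exactly k cohorts.

    Labels are assigned by ascending cluster-mean SF3.5; for k = 4 they are
    S < MS < MR < R, otherwise G1..Gk.
    """
    if len(entries) < k:
        raise ValueError(f"need at least k={k} entries, got {len(entries)}")
    names = [e.cell_line for e in entries]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate cell-line names: {dupes}")
    values = np.array([e.sf35 for e in entries], dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("SF3.5 values must be finite")

    # cluster in sorted order so the partition is invariant to row order
    order = np.lexsort((names_arr := np.array(names), values))
    sorted_vals = values[order]
    z = linkage(sorted_vals.reshape(-1, 1), method="average", metric="euclidean")
    raw = fcluster(z, t=k, criterion="maxclust")

    means = {cid: float(sorted_vals[raw == cid].mean()) for cid in np.unique(raw)}
    labels = _labels_for_k(k)
    relabel = {cid: labels[rank] for rank, cid in enumerate(sorted(means, key=means.get))}
    assignments = {
        str(names_arr[order][i]): relabel[raw[i]] for i in range(len(entries))
    }
    # restore the caller's row order in the mapping
    assignments = {name: assignments[name] for name in names}
    group_means = {relabel[cid]: means[cid] for cid in means}
    return SensitivityGrouping(
        assignments=assignments, group_means=group_means, linkage_record=z
    )


def resistant_vs_rest(grouping: SensitivityGrouping) -> dict[str, str]:
    """Collapse the 4-way grouping to resistant (R) vs. other."""
    if "R" not in grouping.group_means:
        raise ValueError("grouping has no R cohort")
    return {
        line: ("resistant" if lab == "R" else "other")
        for line, lab in grouping.assignments.items()
    }
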
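"""Hub identification and between-group hub taxonomy.

A region is a hub when its degree centrality (by default the group-mean
degree-centrality AUC over the sparsity sweep) is at least one standard
deviation above the average over all regions.  Comparing the hub sets of two
groups partitions them into:

* **lost** — hubs of the control group only (degraded in patients),
* **preserved** — hubs of both groups,
* **reconfigured** — hubs of the patient group only (newly prominent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = ["HubConfig", "HubReport", "identify_hubs", "classify_hub_changes",
           "group_hub_report"]


@dataclass(frozen=True)
class HubConfig:
    """Hub definition: metric, SD threshold, and cross-subject summary.

    ``metric='degree_centrality_auc'`` thresholds the per-node AUC of degree
    centrality; ``threshold_sd`` is the number of standard deviations above
    the across-node mean (population-SD, n denominator) a node must reach.
    """

    metric: str = "degree_centrality_auc"
    threshold_sd: float = 1.0
    group_summary: str = "mean"

    def __post_init__(self) -> None:
        if self.threshold_sd < 0:
            raise ValueError("threshold_sd must be >= 0")
        if self.group_summary != "mean":
            raise ValueError("only group_summary='mean' is supported")


@dataclass(frozen=True)
class HubReport:
    """Per-group hub sets and their lost/preserved/reconfigured partition."""

    hubs_control: frozenset[str]
    hubs_patient: frozenset[str]
    lost: frozenset[str]
    preserved: frozenset[str]
    reconfigured: frozenset[str]

    def to_dict(self) -> dict[str, list[str]]:
        return {
            "hubs_control": sorted(self.hubs_control),
            "hubs_patient": sorted(self.hubs_patient),
            "lost": sorted(self.lost),
            "preserved": sorted(self.preserved),
            "reconfigured": sorted(self.reconfigured),
        }


def identify_hubs(
    nodal_values: Mapping[str, float] | Sequence[float] | np.ndarray,
    config: HubConfig | None = None,
    node_labels: Sequence[str] | None = None,
) -> frozenset[str]:
    """Nodes whose value is >= mean + threshold_sd * SD across all nodes.

    The SD uses the population (n) denominator.  Ties exactly at the cutoff
    count as hubs.  If every node has the identical value (SD = 0) there are
    no hubs by intent of the definition: an empty set is returned with a
    warning.
    """
    config = config or HubConfig()
    if isinstance(nodal_values, Mapping):
        labels = tuple(nodal_values.keys())
        vals = np.array([nodal_values[k] for k in labels], dtype=float)
    else:
        vals = np.asarray(nodal_values, dtype=float)
        labels = (
            tuple(node_labels)
            if node_labels is not None
            else tuple(str(i) for i in range(len(vals)))
        )
    if len(vals) < 2:
        raise ValueError("hub identification needs at least 2 nodes")
    sd = float(vals.std())  # population denominator
    if sd == 0.0:
        warnings.warn("all nodal values identical; no hubs", UserWarning, stacklevel=2)
        return frozenset()
    cutoff = float(vals.mean()) + config.threshold_sd * sd
    return frozenset(lab for lab, v in zip(labels, vals) if v >= cutoff)


def classify_hub_changes(
    hubs_control: frozenset[str] | set[str],
    hubs_patient: frozenset[str] | set[str],
    universe: Sequence[str] | None = None,
) -> HubReport:
    """Partition two hub sets into lost / preserved / reconfigured.

    When ``universe`` is given, both sets must be drawn from it.
    """
    hc, hp = frozenset(hubs_control), frozenset(hubs_patient)
    if universe is not None:
        uni = frozenset(universe)
        stray = (hc | hp) - uni
        if stray:
            raise ValueError(f"hub labels outside the node universe: {sorted(stray)}")
    return HubReport(
        hubs_control=hc,
        hubs_patient=hp,
        lost=hc - hp,
        preserved=hc & hp,
        reconfigured=hp - hc,
    )


def group_hub_report(
    control_values: np.ndarray,
    patient_values: np.ndarray,
    node_labels: Sequence[str],
    config: HubConfig | None = None,
) -> HubReport:
    """Hub taxonomy from per-subject nodal values of two groups.

    ``*_values`` are (n_subjects, n_nodes) arrays of the hub metric (e.g.
    degree-centrality AUC); each group's values are averaged across subjects
    and thresholded independently.
    """
    config = config or HubConfig()
    hc = identify_hubs(np.asarray(control_values).mean(axis=0), config, node_labels)
    hp = identify_hubs(np.asarray(patient_values).mean(axis=0), config, node_labels)
    return classify_hub_changes(hc, hp, universe=node_labels)
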
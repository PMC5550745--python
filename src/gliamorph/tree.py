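"""Threshold decision tree assigning any measured cell to a morphotype.

The tree mirrors the published two-stage scheme: a first node on the
convex hull span ratio (CHSR) isolates the elongated reactive morphotype
(Cluster 4; the published cut is CHSR > 1.93), a second node on cell
circularity (CC) separates Cluster 2 from the remainder, and a third node
on convex hull area (CHA) splits Clusters 1 and 3.  Each cluster is then
subdivided into two Types (x.1 / x.2) by a cut on its sub-typing
descriptor — maximum span across the hull for Clusters 1 and 3, convex
hull circularity for Clusters 2 and 4 by default.

Only the first threshold has a published value; every threshold here can
be *fitted* from labeled data as the 1-D cut minimizing misclassification
between the node's class groups (ties resolved to the midpoint between
the class-conditional extremes), with provenance recorded per node.  All
comparisons are strictly-greater, so a cell sitting exactly on a
threshold goes to the lower branch.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PAPER_CHSR_THRESHOLD",
    "ThresholdNode",
    "MorphotypeTree",
    "MorphotypeLabel",
    "fit_threshold",
    "fit_thresholds",
    "classify",
    "classify_table",
    "distribution_report",
]

#: published first-node cut: CHSR above this means the reactive morphotype
PAPER_CHSR_THRESHOLD = 1.93

DEFAULT_NODE_DESCRIPTORS = {
    "node1": "convex_hull_span_ratio",
    "node2": "cell_circularity",
    "node3": "convex_hull_area_um2",
}
DEFAULT_SUBTYPE_DESCRIPTORS = {
    1: "max_span_across_hull_um",
    3: "max_span_across_hull_um",
    2: "convex_hull_circularity",
    4: "convex_hull_circularity",
}


class TreeError(ValueError):
    pass


@dataclass(frozen=True)
class ThresholdNode:
    """One binary rule: value > threshold sends the cell to ``high``."""

    descriptor: str
    threshold: float
    high: int  # cluster (or branch tag) on the strictly-greater side
    low: int
    provenance: str = "fitted"  # or "paper"
    separable: bool = True
    training_error: float = 0.0

    def route(self, value: float) -> int:
        return self.high if value > self.threshold else self.low


@dataclass(frozen=True)
class MorphotypeLabel:
    cluster: int
    subtype: int  # 1 or 2

    @property
    def type_name(self) -> str:
        return f"{self.cluster}.{self.subtype}"


@dataclass(frozen=True)
class MorphotypeTree:
    """node1 (CHSR) -> Cluster 4 | node2 (CC) -> Cluster 2 | node3 (CHA)
    -> Clusters 1/3; then per-cluster sub-type cuts."""

    node1: ThresholdNode
    node2: ThresholdNode
    node3: ThresholdNode
    subtype_cuts: dict[int, ThresholdNode]
    training_agreement: float | None = None

    def to_json(self) -> str:
        payload = {
            "node1": asdict(self.node1),
            "node2": asdict(self.node2),
            "node3": asdict(self.node3),
            "subtype_cuts": {str(k): asdict(v) for k, v in self.subtype_cuts.items()},
            "training_agreement": self.training_agreement,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MorphotypeTree":
        d = json.loads(text)
        return cls(
            node1=ThresholdNode(**d["node1"]),
            node2=ThresholdNode(**d["node2"]),
            node3=ThresholdNode(**d["node3"]),
            subtype_cuts={int(k): ThresholdNode(**v) for k, v in d["subtype_cuts"].items()},
            training_agreement=d.get("training_agreement"),
        )


def fit_threshold(values: np.ndarray, is_high: np.ndarray) -> tuple[float, bool, float]:
    """1-D cut minimizing misclassification of high-group vs low-group.

    Candidates are midpoints between consecutive distinct sorted values;
    among equal-error candidates the middle of the best run is taken, so a
    perfectly separable node gets the midpoint between the two
    class-conditional extremes.  Returns (threshold, separable flag,
    training error rate); the node is flagged non-separable when the best
    cut still misclassifies more than half of either class.
    """
    values = np.asarray(values, float)
    is_high = np.asarray(is_high, bool)
    if is_high.all() or (~is_high).all():
        raise TreeError("both class groups must be non-empty to fit a threshold")
    uniq = np.unique(values)
    if len(uniq) == 1:
        return float(uniq[0]), False, float(min(is_high.mean(), 1 - is_high.mean()))
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    # error(c) = #high with v <= c  +  #low with v > c
    errors = np.array(
        [np.sum(is_high & (values <= c)) + np.sum(~is_high & (values > c)) for c in cands]
    )
    best = errors.min()
    idx = np.flatnonzero(errors == best)
    # middle of the best-candidate run; for a clean gap this is its center
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    longest = max(runs, key=len)
    if len(longest) % 2 == 1:
        thr = float(cands[longest[len(longest) // 2]])
    else:
        thr = float((cands[longest[0]] + cands[longest[-1]]) / 2.0)
    err_high = np.sum(is_high & (values <= thr)) / is_high.sum()
    err_low = np.sum(~is_high & (values > thr)) / (~is_high).sum()
    separable = max(err_high, err_low) <= 0.5
    if not separable:
        warnings.warn("threshold fitted on a node whose groups largely overlap")
    return thr, bool(separable), float(best / len(values))


def _node(values, is_high, descriptor, high, low) -> ThresholdNode:
    thr, separable, err = fit_threshold(np.asarray(values, float), is_high)
    return ThresholdNode(
        descriptor=descriptor, threshold=thr, high=high, low=low,
        provenance="fitted", separable=separable, training_error=err,
    )


def fit_thresholds(
    features: pd.DataFrame,
    cluster_labels,
    subtype_descriptors: dict[int, str] | None = None,
    node_descriptors: dict[str, str] | None = None,
    chsr_threshold: float | None = None,
) -> MorphotypeTree:
    """Fit all tree thresholds from a labeled feature table (raw scale).

    ``cluster_labels`` are the size-ordered HCA clusters 1-4.  Node
    orientation (which side is the "greater" side) is taken from the class
    means at each node, since only the first threshold's direction is
    published.  Pass ``chsr_threshold`` (e.g. the published 1.93) to pin
    node 1 instead of fitting it.  Sub-type cuts default to the cohort
    mean of the sub-typing descriptor.
    """
    labels = np.asarray(cluster_labels)
    present = np.unique(labels)
    if len(present) < 2:
        raise TreeError("need at least two clusters to fit a decision tree")
    node_desc = {**DEFAULT_NODE_DESCRIPTORS, **(node_descriptors or {})}
    sub_desc = {**DEFAULT_SUBTYPE_DESCRIPTORS, **(subtype_descriptors or {})}

    d1 = node_desc["node1"]
    is4 = labels == 4
    if chsr_threshold is not None:
        node1 = ThresholdNode(
            descriptor=d1, threshold=float(chsr_threshold), high=4, low=0,
            provenance="paper",
        )
    elif is4.any():
        node1 = _node(features[d1], is4, d1, high=4, low=0)
    else:
        node1 = ThresholdNode(descriptor=d1, threshold=np.inf, high=4, low=0,
                              provenance="fitted", separable=False)

    rest = ~is4
    d2 = node_desc["node2"]
    is2 = labels[rest] == 2
    v2 = features.loc[rest, d2].to_numpy()
    if is2.any() and (~is2).any():
        # orient by class means: cluster 2 on its own side of the cut
        if v2[is2].mean() >= v2[~is2].mean():
            node2 = _node(v2, is2, d2, high=2, low=0)
        else:
            node2 = _node(v2, ~is2, d2, high=0, low=2)
    else:
        raise TreeError("cluster 2 or the 1/3 group is absent; cannot fit node 2")

    d3 = node_desc["node3"]
    in13 = rest & np.isin(labels, (1, 3))
    v3 = features.loc[in13, d3].to_numpy()
    is1 = labels[in13] == 1
    if is1.any() and (~is1).any():
        if v3[is1].mean() >= v3[~is1].mean():
            node3 = _node(v3, is1, d3, high=1, low=3)
        else:
            node3 = _node(v3, ~is1, d3, high=3, low=1)
    else:
        raise TreeError("clusters 1 and 3 must both be present to fit node 3")

    subtype_cuts = {}
    for cl in (1, 2, 3, 4):
        desc = sub_desc[cl]
        cut = float(features[desc].mean())  # cohort z = 0 on the raw scale
        subtype_cuts[cl] = ThresholdNode(
            descriptor=desc, threshold=cut, high=2, low=1, provenance="fitted"
        )

    tree = MorphotypeTree(node1=node1, node2=node2, node3=node3, subtype_cuts=subtype_cuts)
    predicted = np.array([classify(row, tree).cluster for _, row in features.iterrows()])
    agreement = float((predicted == labels).mean())
    return MorphotypeTree(
        node1=node1, node2=node2, node3=node3,
        subtype_cuts=subtype_cuts, training_agreement=agreement,
    )


def _value(vector, name: str) -> float:
    if hasattr(vector, "to_dict") and not isinstance(vector, (pd.Series, dict)):
        vector = vector.to_dict()
    try:
        return float(vector[name])
    except (KeyError, IndexError):
        raise TreeError(f"vector is missing descriptor {name!r}") from None


def classify(vector, tree: MorphotypeTree) -> MorphotypeLabel:
    """Route one cell (MorphometricVector, dict or Series) through the tree."""
    if tree.node1.route(_value(vector, tree.node1.descriptor)) == 4:
        cluster = 4
    else:
        c2 = tree.node2.route(_value(vector, tree.node2.descriptor))
        cluster = 2 if c2 == 2 else tree.node3.route(_value(vector, tree.node3.descriptor))
    sub = tree.subtype_cuts[cluster]
    subtype = sub.route(_value(vector, sub.descriptor))
    return MorphotypeLabel(cluster=cluster, subtype=subtype)


def classify_table(features: pd.DataFrame, tree: MorphotypeTree) -> pd.DataFrame:
    """Classify every row; returns cluster and type columns indexed like the input."""
    out = [classify(row, tree) for _, row in features.iterrows()]
    return pd.DataFrame(
        {
            "cluster": [o.cluster for o in out],
            "type": [o.type_name for o in out],
        },
        index=features.index,
    )


def distribution_report(
    labels: pd.DataFrame,
    metadata: pd.DataFrame,
    by: tuple[str, ...] = ("region", "treatment", "time_h"),
    level: str = "cluster",
) -> pd.DataFrame:
    """Percentage of cells per morphotype within each metadata stratum.

    Returns one row per (stratum x morphotype) with a ``percent`` column;
    percentages sum to 100 within each stratum.  Empty strata simply do
    not appear.
    """
    if not labels.index.equals(metadata.index):
        metadata = metadata.loc[labels.index]
    df = pd.concat([labels, metadata[list(by)]], axis=1)
    counts = df.groupby(list(by) + [level], observed=True).size().rename("n").reset_index()
    totals = counts.groupby(list(by), observed=True)["n"].transform("sum")
    counts["percent"] = 100.0 * counts["n"] / totals
    return counts
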
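"""Edge taxonomy on the group-average network.

Hubs are nodes whose weighted degree or betweenness exceeds mean + 1 sample
standard deviation over all nodes (either criterion suffices).  Edges of the
group-average support are partitioned three ways: by hub status of their
endpoints (rich-club / feeder / local), by functional-module membership
(within / between), and by mean streamline length against the support-wide
average (short / long, ties short).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Connectome, RegionTable
from .metrics import betweenness_centrality, degree_strength

HUB_CLASSES = ("rich-club", "feeder", "local")
MODULE_CLASSES = ("within", "between")
LENGTH_CLASSES = ("short", "long")


@dataclass
class EdgeClassification:
    """Labels for every edge of the group-average support."""

    edges: np.ndarray          # E x 2 region indices (i < j)
    hubs: np.ndarray           # boolean, length R
    hub_class: np.ndarray      # E, in HUB_CLASSES
    module_class: np.ndarray   # E, in MODULE_CLASSES
    length_class: np.ndarray | None  # E, in LENGTH_CLASSES (None without lengths)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "i": self.edges[:, 0],
                "j": self.edges[:, 1],
                "hub_class": self.hub_class,
                "module_class": self.module_class,
            }
        )
        if self.length_class is not None:
            df["length_class"] = self.length_class
        return df


def identify_hubs(group_net: Connectome) -> np.ndarray:
    """Hub iff strength > mean+std OR betweenness > mean+std (sample std)."""
    k = degree_strength(group_net)
    b = betweenness_centrality(group_net)
    thr_k = k.mean() + k.std(ddof=1)
    thr_b = b.mean() + b.std(ddof=1)
    return (k > thr_k) | (b > thr_b)


def classify_hub_edges(group_net: Connectome, hubs: np.ndarray) -> np.ndarray:
    iu, ju = group_net.edge_index()
    n_hub_ends = hubs[iu].astype(int) + hubs[ju].astype(int)
    return np.array(["local", "feeder", "rich-club"])[n_hub_ends]


def classify_module_edges(group_net: Connectome, regions: RegionTable) -> np.ndarray:
    iu, ju = group_net.edge_index()
    return np.where(regions.module[iu] == regions.module[ju], "within", "between")


def classify_length_edges(group_net: Connectome) -> np.ndarray:
    """Short iff mean streamline length <= support-wide mean length."""
    if group_net.lengths is None:
        raise ValueError("group network has no lengths matrix")
    iu, ju = group_net.edge_index()
    lengths = group_net.lengths[iu, ju]
    return np.where(lengths <= lengths.mean(), "short", "long")


def classify_edges(group_net: Connectome, regions: RegionTable) -> EdgeClassification:
    iu, ju = group_net.edge_index()
    hubs = identify_hubs(group_net)
    return EdgeClassification(
        edges=np.column_stack([iu, ju]),
        hubs=hubs,
        hub_class=classify_hub_edges(group_net, hubs),
        module_class=classify_module_edges(group_net, regions),
        length_class=(
            classify_length_edges(group_net) if group_net.lengths is not None else None
        ),
    )


def edge_type_strength(scan_conn: Connectome, classification: EdgeClassification) -> dict:
    """Per-type mean weight of one scan over the group-support edges.

    Scans missing an edge contribute zero, so the quantity is comparable
    across scans.  Empty types are reported as NaN.
    """
    iu = classification.edges[:, 0]
    ju = classification.edges[:, 1]
    w = scan_conn.weights[iu, ju]
    out = {}
    taxonomies = {
        "hub": (classification.hub_class, HUB_CLASSES),
        "module": (classification.module_class, MODULE_CLASSES),
        "length": (classification.length_class, LENGTH_CLASSES),
    }
    for name, (labels, classes) in taxonomies.items():
        if labels is None:
            continue
        for cls in classes:
            mask = labels == cls
            out[f"{name}:{cls}"] = float(w[mask].mean()) if mask.any() else float("nan")
    return out


def edge_type_strength_table(cohort, classification: EdgeClassification) -> pd.DataFrame:
    """One row per scan: subject, wave and mean strength per edge type."""
    rows = []
    for s in cohort.scans:
        row = {"subject": s.subject_id, "wave": s.wave}
        row.update(edge_type_strength(s.connectome, classification))
        rows.append(row)
    return pd.DataFrame(rows)
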
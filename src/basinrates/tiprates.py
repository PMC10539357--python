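"""Per-tip speciation-rate statistics.

Two tip-level estimators of recent speciation rate read off a
time-calibrated tree:

* the equal-splits statistic ES and its inverse DR — for tip *i* with
  root-to-tip edge lengths ``l_1`` (pendant) to ``l_N`` (rootmost),
  ``ES_i = sum_j l_j * 2**-(j-1)`` and ``DR_i = 1 / ES_i`` (My^-1); and
* a node-density rate — the number of splits on the root-to-tip path
  (root included) divided by the root-to-tip distance.

Edge indexing for ES starts at the pendant edge and halves rootward (the
standard equal-splits convention).  A k-furcation counts as (k-1) splits
at the same age: crossing it rootward multiplies the ES weight by
``2**-(k-1)``, and it contributes (k-1) to the node-density numerator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .treeio import Phylogeny

__all__ = ["equal_splits_rate", "node_density_rate", "tip_rate_table"]


def equal_splits_rate(tree: Phylogeny) -> pd.DataFrame:
    """Equal-splits statistic and DR speciation rate for every tip.

    Returns a DataFrame indexed by species with columns ``ES`` (My) and
    ``DR`` (My^-1); ``DR * ES == 1`` exactly.
    """
    tips = tree.tip_indices
    es = np.zeros(tips.shape[0])
    for r, t in enumerate(tips):
        w = 1.0
        i = t
        acc = 0.0
        while i != tree.root:
            bl = tree.branch_length[i]
            if bl <= 0:
                raise ValueError(f"non-positive branch length on path to {tree.labels[t]!r}")
            acc += w * bl
            p = tree.parent[i]
            k = len(tree.children[p])
            w *= 2.0 ** (-(k - 1))
            i = p
        acc += w * tree.root_length  # stem sits above the root split
        es[r] = acc
    if (es <= 0).any():
        raise ValueError("zero-length root-to-tip path")
    return pd.DataFrame(
        {"ES": es, "DR": 1.0 / es}, index=pd.Index(tree.tip_labels, name="species")
    )


def node_density_rate(tree: Phylogeny) -> pd.DataFrame:
    """Node-density speciation rate: splits on the root-to-tip path / depth."""
    tips = tree.tip_indices
    depths = tree.tip_depths
    rates = np.zeros(tips.shape[0])
    for r, t in enumerate(tips):
        if depths[r] <= 0:
            raise ValueError(f"zero root-to-tip distance at {tree.labels[t]!r}")
        splits = 0
        i = t
        while i != tree.root:
            p = tree.parent[i]
            splits += len(tree.children[p]) - 1
            i = p
        rates[r] = splits / depths[r]
    return pd.DataFrame(
        {"node_density": rates}, index=pd.Index(tree.tip_labels, name="species")
    )


def tip_rate_table(tree: Phylogeny) -> pd.DataFrame:
    """ES, DR and node-density rates in one table (TSV-ready)."""
    return equal_splits_rate(tree).join(node_density_rate(tree))
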
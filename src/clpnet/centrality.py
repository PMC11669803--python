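"""Expected-influence and bridge centralities for directed panel networks.

For a weight matrix W (rows = wave-1 senders, columns = wave-2 receivers),
with the autoregressive diagonal removed:

* out-EI of node i  = sum_j |W[i, j]|       (influence the node sends)
* in-EI of node j   = sum_i |W[i, j]|       (influence the node receives)
* bridge out-EI / in-EI restrict those sums to edges whose other endpoint
  belongs to a different construct (PLEs, depression, anxiety, life events),
  measuring how much a node transmits to or absorbs from outside its own
  construct.

Absolute-value sums are the default, matching the verbal definitions above;
``signed=True`` sums raw weights instead (kept for sensitivity analyses).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .network import CLPNetwork


def _prepared(net: CLPNetwork, signed: bool) -> np.ndarray:
    w = net.cross_lagged  # diagonal removed, copy
    return w if signed else np.abs(w)


def in_ei(net: CLPNetwork, node: str, signed: bool = False) -> float:
    """Sum of absolute weights of edges pointing to ``node`` (diagonal excluded)."""
    j = net.node_index(node)
    return float(_prepared(net, signed)[:, j].sum())


def out_ei(net: CLPNetwork, node: str, signed: bool = False) -> float:
    """Sum of absolute weights of edges going out of ``node`` (diagonal excluded)."""
    i = net.node_index(node)
    return float(_prepared(net, signed)[i, :].sum())


def bridge_ei(
    net: CLPNetwork, node: str, direction: str, signed: bool = False
) -> float:
    """Expected influence restricted to edges crossing construct boundaries."""
    if direction not in {"in", "out"}:
        raise ValueError("direction must be 'in' or 'out'")
    k = net.node_index(node)
    construct = net.construct_labels[k]
    if not construct:
        raise ValueError(f"node {node!r} has no construct label")
    other = np.array([c != construct for c in net.construct_labels])
    w = _prepared(net, signed)
    if direction == "out":
        return float(w[k, other].sum())
    return float(w[other, k].sum())


def centrality_table(net: CLPNetwork, signed: bool = False) -> pd.DataFrame:
    """All four indices for every node, autoregressive effects removed.

    Returns a DataFrame indexed by node with columns ``construct``,
    ``in_ei``, ``out_ei``, ``bridge_in_ei``, ``bridge_out_ei``.
    """
    w = _prepared(net, signed)
    labels = net.node_labels
    constructs = np.asarray(net.construct_labels)
    cross = constructs[:, None] != constructs[None, :]
    return pd.DataFrame(
        {
            "construct": net.construct_labels,
            "in_ei": w.sum(axis=0),
            "out_ei": w.sum(axis=1),
            "bridge_in_ei": (w * cross).sum(axis=0),
            "bridge_out_ei": (w * cross).sum(axis=1),
        },
        index=pd.Index(labels, name="node"),
    )


CENTRALITY_INDICES = ["in_ei", "out_ei", "bridge_in_ei", "bridge_out_ei"]
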
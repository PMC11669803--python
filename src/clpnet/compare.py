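"""Comparison of two estimated cross-lagged panel networks.

Three views, mirroring how two-group panel networks are usually contrasted:
the Pearson correlation between the vectorized edge-weight matrices, the
proportion of one network's edges replicated in the other, and per-index
Pearson correlations of the centrality vectors (autoregressive effects
removed throughout by default).

Replication is reference-based and deliberately asymmetric: an edge of the
reference network (a nonzero cross-lagged entry) replicates iff the same
cell is nonzero *with the same sign* in the other network; a lenient
nonzero-only mode exists for sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import CLPNetwork


def _check_aligned(a: CLPNetwork, b: CLPNetwork) -> None:
    if a.node_labels != b.node_labels:
        diff = sorted(set(a.node_labels) ^ set(b.node_labels)) or a.node_labels
        raise ValueError(f"node sets differ between networks: {diff}")


@dataclass
class ComparisonResult:
    matrix_r: float
    matrix_p: float
    replication_proportion: float
    replicated_edges: int
    reference_edges: int
    centrality_r: dict[str, float]
    centrality_p: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "matrix_correlation": {"r": self.matrix_r, "p": self.matrix_p},
            "edge_replication": {
                "proportion": self.replication_proportion,
                "replicated": self.replicated_edges,
                "total": self.reference_edges,
            },
            "centrality_correlations": {
                k: {"r": self.centrality_r[k], "p": self.centrality_p[k]}
                for k in self.centrality_r
            },
        }


def matrix_correlation(
    net_a: CLPNetwork, net_b: CLPNetwork, include_diagonal: bool = False
) -> tuple[float, float]:
    """Pearson r (and p) over the vectorized off-diagonal edge weights."""
    _check_aligned(net_a, net_b)
    p = len(net_a.node_labels)
    if include_diagonal:
        va, vb = net_a.weights.ravel(), net_b.weights.ravel()
    else:
        mask = ~np.eye(p, dtype=bool)
        va, vb = net_a.weights[mask], net_b.weights[mask]
    if np.std(va) == 0 or np.std(vb) == 0:
        raise ValueError("constant edge-weight vector; correlation undefined")
    r, pval = stats.pearsonr(va, vb)
    return float(r), float(pval)


def edge_replication_proportion(
    reference: CLPNetwork,
    other: CLPNetwork,
    require_same_sign: bool = True,
    threshold: float = 0.0,
) -> tuple[float, int, int]:
    """Fraction of the reference's cross-lagged edges present in ``other``.

    An edge exists where |weight| > ``threshold`` (0 keeps every surviving
    LASSO coefficient). Returns (proportion, replicated, total); a reference
    without edges yields proportion NaN.
    """
    _check_aligned(reference, other)
    wr, wo = reference.cross_lagged, other.cross_lagged
    ref_edges = np.abs(wr) > threshold
    total = int(ref_edges.sum())
    if total == 0:
        return float("nan"), 0, 0
    present = np.abs(wo) > threshold
    if require_same_sign:
        ok = ref_edges & present & (np.sign(wr) == np.sign(wo))
    else:
        ok = ref_edges & present
    replicated = int(ok.sum())
    return replicated / total, replicated, total


def centrality_correlation(
    table_a: pd.DataFrame, table_b: pd.DataFrame, index: str
) -> tuple[float, float]:
    """Pearson r (and p) across nodes for one centrality index."""
    for t in (table_a, table_b):
        if index not in t.columns:
            raise KeyError(f"centrality index {index!r} not in table")
    if not table_a.index.equals(table_b.index):
        raise ValueError("centrality tables cover different nodes")
    a = table_a[index].to_numpy(dtype=float)
    b = table_b[index].to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError(f"constant {index} vector; correlation undefined")
    r, pval = stats.pearsonr(a, b)
    return float(r), float(pval)


def compare_networks(
    net_a: CLPNetwork,
    net_b: CLPNetwork,
    table_a: pd.DataFrame | None = None,
    table_b: pd.DataFrame | None = None,
) -> ComparisonResult:
    """Full two-network comparison (A as replication reference)."""
    from .centrality import CENTRALITY_INDICES, centrality_table

    table_a = centrality_table(net_a) if table_a is None else table_a
    table_b = centrality_table(net_b) if table_b is None else table_b
    r, pval = matrix_correlation(net_a, net_b)
    prop, repl, total = edge_replication_proportion(net_a, net_b)
    cr, cp = {}, {}
    for idx in CENTRALITY_INDICES:
        cr[idx], cp[idx] = centrality_correlation(table_a, table_b, idx)
    return ComparisonResult(r, pval, prop, repl, total, cr, cp)
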
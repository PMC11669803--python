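"""Edge accuracy and centrality stability by bootstrapping.

Two resampling schemes, following the usual accuracy/stability workflow for
estimated symptom networks:

* **Nonparametric bootstrap** — participants resampled with replacement,
  the CLPN refit per resample, percentile 95% confidence intervals per
  edge. Wide intervals indicate imprecise edges. The stored resample
  weights also drive pairwise edge-difference tests.
* **Case-drop bootstrap** — increasing fractions of participants dropped
  without replacement; at each drop level the correlation (across the 24
  nodes) between subsample and full-sample centrality indices is recorded.
  The correlation-stability (CS) coefficient of an index is the largest
  drop fraction at which at least ``prob_threshold`` (default 95%) of
  subsample correlations stay at or above ``cor_threshold`` (default 0.7);
  CS >= 0.25 is conventionally read as acceptable stability, > 0.5 as
  strong.

Resamples that leave any node with zero variance are redrawn (counted); a
degenerate dataset where every redraw fails raises.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centrality import CENTRALITY_INDICES, centrality_table
from .network import CLPNetwork, FitConfig, fit_clpn

_MAX_REDRAW_FACTOR = 50


def _as_matrix(block) -> np.ndarray:
    from .scoring import NodeScores

    if isinstance(block, NodeScores):
        return block.data.to_numpy(dtype=float)
    if isinstance(block, pd.DataFrame):
        return block.to_numpy(dtype=float)
    return np.asarray(block, dtype=float)


def _labels_of(block) -> list[str] | None:
    from .scoring import NodeScores

    if isinstance(block, NodeScores):
        return list(block.data.columns)
    if isinstance(block, pd.DataFrame):
        return list(block.columns)
    return None


def _covariate_rows(covariates, idx):
    if covariates is None:
        return None
    if isinstance(covariates, pd.DataFrame):
        return covariates.iloc[idx]
    return np.asarray(covariates)[idx]


def _has_variance(x: np.ndarray, y: np.ndarray) -> bool:
    return bool((x.std(axis=0) > 0).all() and (y.std(axis=0) > 0).all())


@dataclass
class BootstrapResult:
    """Per-edge bootstrap distribution summaries (percentile method)."""

    iterations: int
    seed: int
    node_labels: list[str]
    weights: np.ndarray  # (iterations, p, p) resampled edge matrices
    lower: np.ndarray
    upper: np.ndarray
    mean: np.ndarray
    redraws: int = 0
    ci_level: float = 0.95

    def edge_samples(self, source: str, target: str) -> np.ndarray:
        i = self.node_labels.index(source)
        j = self.node_labels.index(target)
        return self.weights[:, i, j]

    def ci_table(self) -> pd.DataFrame:
        rows = []
        p = len(self.node_labels)
        for i in range(p):
            for j in range(p):
                rows.append(
                    {
                        "source": self.node_labels[i],
                        "target": self.node_labels[j],
                        "mean": self.mean[i, j],
                        "lower": self.lower[i, j],
                        "upper": self.upper[i, j],
                    }
                )
        return pd.DataFrame(rows)


def bootstrap_edge_cis(
    wave1,
    wave2,
    covariates=None,
    config: FitConfig | None = None,
    iterations: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Nonparametric bootstrap of the edge weights (resample participants)."""
    if iterations < 2:
        raise ValueError("iterations must be >= 2")
    config = config or FitConfig()
    x, y = _as_matrix(wave1), _as_matrix(wave2)
    labels = _labels_of(wave1) or [f"node{i}" for i in range(x.shape[1])]
    n, p = x.shape
    if not _has_variance(x, y):
        raise ValueError("a node has zero variance in the full sample")
    rng = np.random.default_rng(seed)
    boots = np.empty((iterations, p, p))
    redraws = 0
    max_redraws = _MAX_REDRAW_FACTOR * iterations
    b = 0
    while b < iterations:
        idx = rng.integers(0, n, size=n)
        if not _has_variance(x[idx], y[idx]):
            redraws += 1
            if redraws > max_redraws:
                raise ValueError(
                    "could not draw a resample with positive node variances"
                )
            continue
        net = fit_clpn(
            pd.DataFrame(x[idx], columns=labels),
            pd.DataFrame(y[idx], columns=labels),
            _covariate_rows(covariates, idx),
            config,
        )
        boots[b] = net.weights
        b += 1
    alpha = 0.025
    return BootstrapResult(
        iterations=iterations,
        seed=seed,
        node_labels=labels,
        weights=boots,
        lower=np.quantile(boots, alpha, axis=0),
        upper=np.quantile(boots, 1 - alpha, axis=0),
        mean=boots.mean(axis=0),
        redraws=redraws,
    )


def edge_difference_test(
    boot: BootstrapResult,
    edge_a: tuple[str, str],
    edge_b: tuple[str, str],
    ci_level: float = 0.95,
) -> bool:
    """True when the bootstrap CI of (edge_a - edge_b) excludes zero."""
    if tuple(edge_a) == tuple(edge_b):
        raise ValueError("edge_a and edge_b are the same edge")
    diff = boot.edge_samples(*edge_a) - boot.edge_samples(*edge_b)
    half = (1 - ci_level) / 2
    lo, hi = np.quantile(diff, [half, 1 - half])
    return not (lo <= 0.0 <= hi)


@dataclass
class StabilityResult:
    """Case-drop correlation samples per drop level and centrality index."""

    grid: np.ndarray  # drop proportions, ascending
    correlations: dict[str, np.ndarray]  # index -> (len(grid), iterations)
    iterations: int
    seed: int
    cor_threshold: float = 0.7
    prob_threshold: float = 0.95
    redraws: int = 0

    def curve(self, index: str) -> pd.DataFrame:
        """Per-level summary quantiles of the correlation samples."""
        c = self.correlations[index]
        return pd.DataFrame(
            {
                "drop_proportion": self.grid,
                "median": np.median(c, axis=1),
                "q05": np.quantile(c, 0.05, axis=1),
                "q95": np.quantile(c, 0.95, axis=1),
                "prop_above_threshold": (c >= self.cor_threshold).mean(axis=1),
            }
        )


def _centrality_vectors(net: CLPNetwork) -> dict[str, np.ndarray]:
    t = centrality_table(net)
    return {idx: t[idx].to_numpy() for idx in CENTRALITY_INDICES}


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    # a constant vector carries no ranking information: count as 0 agreement
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def case_drop_bootstrap(
    wave1,
    wave2,
    covariates=None,
    config: FitConfig | None = None,
    grid=None,
    iterations: int = 250,
    seed: int = 0,
) -> StabilityResult:
    """Case-drop bootstrap of the centrality indices.

    ``grid`` is the set of drop proportions (default 10%..75% by 5%). At
    each level, ``iterations`` subsamples without replacement are refit and
    their centrality vectors correlated with the full-sample vectors.
    """
    config = config or FitConfig()
    grid = np.arange(0.10, 0.751, 0.05) if grid is None else np.sort(
        np.asarray(grid, dtype=float)
    )
    if (grid < 0).any() or (grid >= 1).any():
        raise ValueError("drop proportions must lie in [0, 1)")
    x, y = _as_matrix(wave1), _as_matrix(wave2)
    labels = _labels_of(wave1) or [f"node{i}" for i in range(x.shape[1])]
    n, p = x.shape
    smallest = int(round((1 - grid.max()) * n))
    if smallest < 10 * p:
        raise ValueError(
            f"smallest retained subsample ({smallest}) is below 10 x node "
            f"count ({10 * p}); shrink the grid or enlarge the sample"
        )
    full = fit_clpn(
        pd.DataFrame(x, columns=labels),
        pd.DataFrame(y, columns=labels),
        covariates,
        config,
    )
    full_cent = _centrality_vectors(full)
    rng = np.random.default_rng(seed)
    cors = {idx: np.empty((len(grid), iterations)) for idx in CENTRALITY_INDICES}
    redraws = 0
    max_redraws = _MAX_REDRAW_FACTOR * iterations * len(grid)
    for g, drop in enumerate(grid):
        m = int(round((1 - drop) * n))
        b = 0
        while b < iterations:
            if drop == 0.0:
                idx = np.arange(n)
            else:
                idx = rng.choice(n, size=m, replace=False)
            if not _has_variance(x[idx], y[idx]):
                redraws += 1
                if redraws > max_redraws:
                    raise ValueError(
                        "could not draw a subsample with positive node variances"
                    )
                continue
            net = fit_clpn(
                pd.DataFrame(x[idx], columns=labels),
                pd.DataFrame(y[idx], columns=labels),
                _covariate_rows(covariates, idx),
                config,
            )
            sub = _centrality_vectors(net)
            for ix in CENTRALITY_INDICES:
                cors[ix][g, b] = _safe_corr(sub[ix], full_cent[ix])
            b += 1
    return StabilityResult(
        grid=grid,
        correlations=cors,
        iterations=iterations,
        seed=seed,
        redraws=redraws,
    )


def cs_coefficient(stab: StabilityResult, index: str) -> float:
    """Correlation-stability coefficient of one centrality index.

    The largest drop proportion, reached contiguously from the smallest grid
    value, at which >= ``prob_threshold`` of the subsample correlations are
    >= ``cor_threshold``; 0 when the criterion already fails at the smallest
    level.
    """
    if index not in stab.correlations:
        raise KeyError(f"no stability samples for index {index!r}")
    c = stab.correlations[index]
    ok = (c >= stab.cor_threshold).mean(axis=1) >= stab.prob_threshold
    cs = 0.0
    for level, good in zip(stab.grid, ok):
        if not good:
            break
        cs = float(level)
    return cs
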
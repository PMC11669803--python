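"""End-to-end orchestration: file I/O, group split, estimation, reporting.

``run_pipeline`` executes the full analysis on a two-wave panel dataset:
score instruments -> apply exclusions -> split by the baseline PLEs
screening cut-off -> per-group standardization and CLPN fit -> centrality
-> optional bootstrap accuracy/stability -> two-group comparison. Every
artifact is written under the output directory together with a JSON
manifest (seed, config hash, package version, per-stage counts) from which
the run can be regenerated.

One global seed fans out to per-stage seeds through
``stage_seed(global_seed, stage)`` (a SeedSequence over (seed, stage tag)),
so any stage can be rerun in isolation with the same stream.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from . import nodes as _nd
from .centrality import centrality_table
from .compare import compare_networks
from .network import CLPNetwork, FitConfig, display_threshold, fit_clpn
from .robustness import bootstrap_edge_cis, case_drop_bootstrap, cs_coefficient
from .scoring import (
    PLES_CUTOFF,
    NodeScores,
    PanelDataset,
    analyzed_subset,
    apply_exclusions,
    cape_weighted_score,
    classify_ples,
    score_nodes,
)

_STAGE_TAGS = {"simulate": 1, "fit_positive": 2, "fit_negative": 3,
               "bootstrap": 4, "casedrop": 5}


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a stage-specific 31-bit seed from the global seed."""
    tag = _STAGE_TAGS.get(stage)
    if tag is None:
        raise KeyError(f"unknown pipeline stage {stage!r}")
    return int(
        np.random.SeedSequence([int(global_seed), tag]).generate_state(1)[0]
        % (2**31)
    )


# ---------------------------------------------------------------------------
# dataset I/O


def read_panel_csv(path: str | Path, bounds_check: bool = True) -> PanelDataset:
    """Read a panel dataset CSV with typed, bounds-checked item columns.

    Raises on missing required columns, and (when ``bounds_check``) on item
    values outside their response scale, naming the first offending cells.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, parse_dates=["timestamp"])
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty input file") from None
    required = ["id", "wave", "timestamp", "response_time_seconds"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    item_cols = [c for c in _nd.ALL_ITEMS if c in df.columns]
    if not item_cols:
        raise ValueError(f"{path}: no instrument item columns found")
    if bounds_check:
        problems = []
        for col in item_cols:
            lo, hi = _nd.ITEM_SCALES[col]
            vals = df[col]
            bad = vals.notna() & ((vals < lo) | (vals > hi))
            for row in df.index[bad][:3]:
                problems.append(f"row {row}, column {col}: value {vals[row]!r}")
        if problems:
            head = "; ".join(problems[:10])
            raise ValueError(f"{path}: item values out of range: {head}")
    return PanelDataset(df)


def write_panel_csv(data: PanelDataset, path: str | Path) -> None:
    data.records.to_csv(path, index=False)


def write_network_csv(net: CLPNetwork, path: str | Path) -> None:
    net.to_frame().to_csv(path, float_format="%.17g")


def read_network_csv(
    path: str | Path, construct_labels: list[str] | None = None
) -> CLPNetwork:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    labels = list(df.index)
    if construct_labels is None:
        construct_labels = (
            list(_nd.CONSTRUCT_LABELS)
            if labels == list(_nd.NODE_LABELS)
            else ["all"] * len(labels)
        )
    return CLPNetwork(
        weights=df.to_numpy(dtype=float),
        node_labels=labels,
        construct_labels=construct_labels,
        lambdas=np.full(len(labels), np.nan),
        n=0,
    )


def export_graphml(net: CLPNetwork, path: str | Path, threshold: float = 0.0) -> None:
    """Write the directed weighted network for external graph tools."""
    g = nx.DiGraph()
    for label, construct in zip(net.node_labels, net.construct_labels):
        g.add_node(label, construct=construct)
    edges = display_threshold(net, threshold)
    for row in edges.itertuples():
        g.add_edge(row.source, row.target, weight=float(row.weight),
                   autoregressive=bool(row.autoregressive))
    nx.write_graphml(g, str(path))


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Everything a full run needs; serialized into the manifest."""

    out_dir: str | Path
    dataset_path: str | Path | None = None
    cutoff: float = PLES_CUTOFF
    inclusive_cutoff: bool = True
    fit: FitConfig = field(default_factory=FitConfig)
    bootstrap_iterations: int = 0  # 0 skips edge-CI bootstrap
    casedrop_iterations: int = 0  # 0 skips stability
    casedrop_grid: tuple = tuple(np.round(np.arange(0.10, 0.751, 0.05), 2))
    display_edge_threshold: float = 0.05
    min_group_n: int = 200
    seed: int = 0

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["out_dir"] = str(self.out_dir)
        d["dataset_path"] = (
            None if self.dataset_path is None else str(self.dataset_path)
        )
        d["casedrop_grid"] = [float(g) for g in self.casedrop_grid]
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"pipeline stage {stage!r} failed: {message}")
        self.stage = stage


def _complete_case_split(
    data: PanelDataset, cutoff: float, inclusive: bool
):
    """Node scores per wave, complete cases, split by baseline screen."""
    w1 = data.wave(1)
    w2 = data.wave(2)
    common = w1.index.intersection(w2.index)
    w1, w2 = w1.loc[common], w2.loc[common]
    s1 = score_nodes(w1[_nd.ALL_ITEMS], 1)
    s2 = score_nodes(w2[_nd.ALL_ITEMS], 2)
    score_b = cape_weighted_score(w1[_nd.CAPE_ITEMS])
    cls_b = classify_ples(score_b, cutoff, inclusive)
    score_f = cape_weighted_score(w2[_nd.CAPE_ITEMS])
    cls_f = classify_ples(score_f, cutoff, inclusive)
    complete = (
        s1.data.notna().all(axis=1)
        & s2.data.notna().all(axis=1)
        & cls_b.notna()
    )
    keep = common[complete]
    covs = [c for c in _nd.COVARIATES if c in w1.columns]
    out = {}
    for name, positive in (("positive", True), ("negative", False)):
        ids = keep[(cls_b.loc[keep] == positive).to_numpy(dtype=bool)]
        out[name] = (
            NodeScores(1, s1.data.loc[ids]),
            NodeScores(2, s2.data.loc[ids]),
            w1.loc[ids, covs] if covs else None,
        )
    return out, cls_b.loc[keep], cls_f.loc[keep]


def run_pipeline(config: PipelineConfig, data: PanelDataset | None = None) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "clpnet",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_jsonable(),
        "config_hash": config.config_hash(),
        "stages": {},
        "complete": False,
    }

    def fail(stage, exc):
        manifest["stages"][stage] = {"error": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise PipelineError(stage, str(exc)) from exc

    # ---- load
    if data is None:
        try:
            data = read_panel_csv(config.dataset_path)
        except Exception as exc:
            fail("load", exc)
    manifest["stages"]["load"] = {"records": data.n_records}

    # ---- exclusions
    try:
        clean, flow = apply_exclusions(data)
        clean = analyzed_subset(clean)
    except Exception as exc:
        fail("exclusions", exc)
    (out / "flow_report.json").write_text(json.dumps(flow.to_dict(), indent=2))
    manifest["stages"]["exclusions"] = flow.to_dict()

    # ---- score and split
    try:
        groups, cls_b, cls_f = _complete_case_split(
            clean, config.cutoff, config.inclusive_cutoff
        )
    except Exception as exc:
        fail("split", exc)
    sizes = {g: len(groups[g][0].data) for g in groups}
    for g, n in sizes.items():
        if n < config.min_group_n:
            fail(
                "split",
                ValueError(
                    f"group {g!r} has n={n} < min_group_n={config.min_group_n}"
                ),
            )
    manifest["stages"]["split"] = {
        "cutoff": config.cutoff,
        "n_positive": sizes["positive"],
        "n_negative": sizes["negative"],
    }

    # ---- per-group estimation
    nets, tables = {}, {}
    for g in ("positive", "negative"):
        s1, s2, covs = groups[g]
        fit_cfg = FitConfig(**{**asdict(config.fit),
                               "seed": stage_seed(config.seed, f"fit_{g}")})
        try:
            net = fit_clpn(s1, s2, covs, fit_cfg)
        except Exception as exc:
            fail(f"fit_{g}", exc)
        nets[g] = net
        s1.data.to_csv(out / f"node_scores_w1_{g}.csv")
        s2.data.to_csv(out / f"node_scores_w2_{g}.csv")
        write_network_csv(net, out / f"network_{g}.csv")
        display_threshold(net, config.display_edge_threshold).to_csv(
            out / f"edges_{g}.csv", index=False
        )
        export_graphml(net, out / f"network_{g}.graphml")
        tables[g] = centrality_table(net)
        tables[g].to_csv(out / f"centrality_{g}.csv")
        manifest["stages"][f"fit_{g}"] = {
            "n": net.n,
            "nonzero_cross_lagged": int((net.cross_lagged != 0).sum()),
        }

    # ---- robustness (optional)
    for g in ("positive", "negative"):
        s1, s2, covs = groups[g]
        if config.bootstrap_iterations > 0:
            try:
                boot = bootstrap_edge_cis(
                    s1, s2, covs, config.fit,
                    iterations=config.bootstrap_iterations,
                    seed=stage_seed(config.seed, "bootstrap"),
                )
            except Exception as exc:
                fail(f"bootstrap_{g}", exc)
            boot.ci_table().to_csv(out / f"edge_cis_{g}.csv", index=False)
            manifest["stages"][f"bootstrap_{g}"] = {
                "iterations": boot.iterations, "redraws": boot.redraws
            }
        if config.casedrop_iterations > 0:
            try:
                stab = case_drop_bootstrap(
                    s1, s2, covs, config.fit,
                    grid=np.asarray(config.casedrop_grid),
                    iterations=config.casedrop_iterations,
                    seed=stage_seed(config.seed, "casedrop"),
                )
            except Exception as exc:
                fail(f"casedrop_{g}", exc)
            cs = {ix: cs_coefficient(stab, ix) for ix in stab.correlations}
            curves = pd.concat(
                {ix: stab.curve(ix) for ix in stab.correlations},
                names=["index"],
            )
            curves.to_csv(out / f"stability_curves_{g}.csv")
            (out / f"cs_coefficients_{g}.json").write_text(
                json.dumps(cs, indent=2)
            )
            manifest["stages"][f"casedrop_{g}"] = {"cs": cs}

    # ---- comparison
    try:
        comp = compare_networks(
            nets["positive"], nets["negative"],
            tables["positive"], tables["negative"],
        )
    except Exception as exc:
        fail("compare", exc)
    (out / "comparison.json").write_text(json.dumps(comp.to_dict(), indent=2))
    manifest["stages"]["compare"] = comp.to_dict()

    manifest["complete"] = True
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
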
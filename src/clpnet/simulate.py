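"""Seeded two-wave cohort simulator with known cross-lagged ground truth.

The generative model is a linear two-wave system over the 24 latent node
scores eta (3 PLEs factors, 9 depression items, 7 anxiety items, 5
life-event factors):

    eta1 ~ N(0, Sigma)                          wave-1 latents
    eta2 = eta1 @ T + C_c @ B + eps             wave-2 latents

with T the 24x24 standardized truth matrix (diagonal = autoregressive
effects), C_c the mean-centred covariate matrix, B per-covariate effect
rows, and eps ~ N(0, diag(noise_sd^2)). Observed Likert items are produced
per node by

    item = clip(round(intercept + loading * eta + item noise), lo, hi)

The CAPE item intercept is calibrated by bisection on an independent
simulated quantile so that the realized fraction of weighted scores at or
above the 1.57 screening cut-off matches ``prevalence_target`` (13.5% by
default, the positive-screen rate the downstream group split assumes).

Administrative artifacts (duplicate submissions, sub-5-minute speeders,
psychotic-history and interview-refusal flags, follow-up loss) are injected
on top so the exclusion cascade can be exercised end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nodes as _nd
from .scoring import PLES_CUTOFF, PanelDataset, cape_weighted_score

_CAL_STREAM = 202  # sub-stream tags for seed fan-out
_ARTIFACT_STREAM = 77


def default_truth_matrix(
    n_cross_edges: int = 30,
    magnitude_range: tuple[float, float] = (0.15, 0.35),
    autoregressive: float = 0.25,
    negative_fraction: float = 0.2,
    seed: int = 12345,
) -> np.ndarray:
    """Sparse standardized cross-lagged truth with autoregressive diagonal.

    Edge positions and magnitudes are drawn from a fixed internal seed so the
    default is a constant of the package, not of the cohort seed.
    """
    rng = np.random.default_rng(seed)
    p = _nd.N_NODES
    t = np.zeros((p, p))
    np.fill_diagonal(t, autoregressive)
    off = [(i, j) for i in range(p) for j in range(p) if i != j]
    picks = rng.choice(len(off), size=n_cross_edges, replace=False)
    lo, hi = magnitude_range
    for k in picks:
        i, j = off[k]
        mag = rng.uniform(lo, hi)
        sign = -1.0 if rng.random() < negative_fraction else 1.0
        t[i, j] = sign * mag
    return t


def default_wave1_covariance(
    within: float = 0.4, between: float = 0.1
) -> np.ndarray:
    """Unit-variance block covariance: higher correlation within constructs."""
    labels = _nd.CONSTRUCT_LABELS
    p = _nd.N_NODES
    cov = np.full((p, p), between)
    for i in range(p):
        for j in range(p):
            if labels[i] == labels[j]:
                cov[i, j] = within
    np.fill_diagonal(cov, 1.0)
    return cov


def noise_sd_for_r2(
    truth: np.ndarray, wave1_cov: np.ndarray, r2: float = 0.3
) -> np.ndarray:
    """Per-node noise SD giving each wave-2 node the requested latent R^2.

    Signal variance of node j is t_j' Sigma t_j with t_j the j-th column of
    the truth matrix; noise variance is set to signal * (1 - r2) / r2. Nodes
    with no incoming effects get unit noise.
    """
    if not 0 < r2 < 1:
        raise ValueError("r2 must be in (0, 1)")
    sig = np.einsum("ij,ik,kj->j", truth, wave1_cov, truth)
    out = np.where(sig > 0, np.sqrt(sig * (1 - r2) / r2), 1.0)
    return out


@dataclass
class SimulationConfig:
    """Cohort-generation parameters; defaults define the shipped conditions."""

    n_participants: int = 3000
    seed: int = 0
    truth_matrix: np.ndarray = field(default_factory=default_truth_matrix)
    wave1_covariance: np.ndarray = field(default_factory=default_wave1_covariance)
    noise_sd: np.ndarray | float | None = None  # None -> R^2 ~= 0.3 per node
    covariate_effects: dict[str, float | np.ndarray] = field(
        default_factory=lambda: {"sex": 0.05, "mental_history": 0.15}
    )
    prevalence_target: float = 0.135
    ples_cutoff: float = PLES_CUTOFF
    item_loading: float = 0.8
    item_noise_sd: float = 0.6
    item_intercepts: dict[str, float] = field(
        default_factory=lambda: {"phq": 1.7, "gad": 1.7, "aslec": 1.8}
    )
    duplicate_rate: float = 0.0
    speeder_rate: float = 0.0
    psychotic_history_rate: float = 0.0
    refusal_rate: float = 0.0
    followup_loss_rate: float = 0.0

    def __post_init__(self) -> None:
        p = _nd.N_NODES
        self.truth_matrix = np.asarray(self.truth_matrix, dtype=float)
        if self.truth_matrix.shape != (p, p):
            raise ValueError(f"truth_matrix must be {p}x{p}")
        self.wave1_covariance = np.asarray(self.wave1_covariance, dtype=float)
        if self.wave1_covariance.shape != (p, p):
            raise ValueError(f"wave1_covariance must be {p}x{p}")
        if not np.allclose(self.wave1_covariance, self.wave1_covariance.T):
            raise ValueError("wave1_covariance must be symmetric")
        try:
            np.linalg.cholesky(self.wave1_covariance)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "wave1_covariance is not positive-definite"
            ) from exc
        if self.noise_sd is None:
            self.noise_sd = noise_sd_for_r2(
                self.truth_matrix, self.wave1_covariance
            )
        self.noise_sd = np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), (p,)
        ).copy()
        if (self.noise_sd < 0).any():
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.prevalence_target < 1:
            raise ValueError("prevalence_target must be in (0, 1)")
        for name in (
            "duplicate_rate",
            "speeder_rate",
            "psychotic_history_rate",
            "refusal_rate",
            "followup_loss_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class GroundTruth:
    """Generation parameters and latent states echoed back for validation."""

    truth_matrix: np.ndarray
    realized_prevalence: float
    seed: int
    cape_intercept: float
    noise_sd: np.ndarray
    prevalence_target: float
    latent_wave1: np.ndarray | None = None  # n x 24, pre-discretization
    latent_wave2: np.ndarray | None = None


# ---------------------------------------------------------------------------
# item generation


def _node_items_and_intercepts(config: SimulationConfig):
    """(node index, item column, intercept) triples in canonical item order."""
    out = []
    for k, node in enumerate(_nd.NODE_LABELS):
        construct = _nd.CONSTRUCT_LABELS[k]
        if construct == "PLEs":
            mu = None  # calibrated
        elif construct == "depression":
            mu = config.item_intercepts["phq"]
        elif construct == "anxiety":
            mu = config.item_intercepts["gad"]
        else:
            mu = config.item_intercepts["aslec"]
        for item in _nd.items_of_node(node):
            out.append((k, item, mu))
    return out


def _discretize(
    latent: np.ndarray, mu: float, config: SimulationConfig,
    noise: np.ndarray, lo: int, hi: int,
) -> np.ndarray:
    x = mu + config.item_loading * latent + noise
    return np.clip(np.rint(x), lo, hi).astype(int)


def _generate_items(
    latents: np.ndarray,
    cape_intercept: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    cols = {}
    for k, item, mu in _node_items_and_intercepts(config):
        lo, hi = _nd.ITEM_SCALES[item]
        mu = cape_intercept if mu is None else mu
        noise = rng.normal(0.0, config.item_noise_sd, size=len(latents))
        cols[item] = _discretize(latents[:, k], mu, config, noise, lo, hi)
    return pd.DataFrame(cols)


def _calibrate_cape_intercept(
    config: SimulationConfig, n_cal: int = 20000, tol: float = 1e-4
) -> float:
    """Bisection on the CAPE item intercept hitting the prevalence target.

    Uses an independent calibration draw (seed fan-out) of PLEs latents and
    fixed item noise, so the positive fraction is deterministic and
    non-decreasing in the intercept.
    """
    rng = np.random.default_rng([config.seed, _CAL_STREAM])
    idx = [i for i, c in enumerate(_nd.CONSTRUCT_LABELS) if c == "PLEs"]
    cov = config.wave1_covariance[np.ix_(idx, idx)]
    lat = rng.standard_normal((n_cal, len(idx))) @ np.linalg.cholesky(cov).T
    items = [(k, item) for k, item, mu in _node_items_and_intercepts(config) if mu is None]
    noise = rng.normal(0.0, config.item_noise_sd, size=(n_cal, len(items)))

    def positive_fraction(mu: float) -> float:
        total = np.zeros(n_cal)
        for c, (k, item) in enumerate(items):
            lo, hi = _nd.ITEM_SCALES[item]
            total += _discretize(lat[:, k], mu, config, noise[:, c], lo, hi)
        score = total / len(items)
        return float((score >= config.ples_cutoff).mean())

    lo_mu, hi_mu = 0.0, 5.0
    f_lo, f_hi = positive_fraction(lo_mu), positive_fraction(hi_mu)
    if not f_lo <= config.prevalence_target <= f_hi:
        raise ValueError(
            f"prevalence target {config.prevalence_target} outside the "
            f"achievable range [{f_lo:.4f}, {f_hi:.4f}] of the item model"
        )
    for _ in range(60):
        mid = 0.5 * (lo_mu + hi_mu)
        if positive_fraction(mid) < config.prevalence_target:
            lo_mu = mid
        else:
            hi_mu = mid
        if hi_mu - lo_mu < tol:
            break
    return 0.5 * (lo_mu + hi_mu)


# ---------------------------------------------------------------------------
# cohort generation


def _covariate_frame(n: int, rng: np.random.Generator) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": rng.integers(17, 23, size=n),
            "sex": rng.integers(0, 2, size=n),
            "ethnicity_han": (rng.random(n) < 0.9).astype(int),
            "birth_rural": (rng.random(n) < 0.5).astype(int),
            "chronic_condition": (rng.random(n) < 0.1).astype(int),
            "mental_history": (rng.random(n) < 0.05).astype(int),
            "family_mental_history": (rng.random(n) < 0.05).astype(int),
        }
    )


def _covariate_effect_matrix(config: SimulationConfig) -> tuple[list[str], np.ndarray]:
    names = list(config.covariate_effects)
    rows = []
    for name in names:
        if name not in _nd.COVARIATES:
            raise ValueError(f"unknown covariate {name!r} in covariate_effects")
        eff = np.broadcast_to(
            np.asarray(config.covariate_effects[name], dtype=float),
            (_nd.N_NODES,),
        )
        rows.append(eff)
    b = np.vstack(rows) if rows else np.zeros((0, _nd.N_NODES))
    return names, b


def generate_cohort(
    config: SimulationConfig,
) -> tuple[PanelDataset, GroundTruth]:
    """Generate a two-wave cohort with known cross-lagged structure.

    Returns the item-level panel dataset (administrative artifacts included
    when their rates are nonzero) and the ground truth, which carries the
    pre-discretization latent node scores of the retained participants.
    Identical config and seed give identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    p = _nd.N_NODES

    chol = np.linalg.cholesky(config.wave1_covariance)
    eta1 = rng.standard_normal((n, p)) @ chol.T

    cov = _covariate_frame(n, rng)
    names, b = _covariate_effect_matrix(config)
    c_centered = (
        cov[names].to_numpy(dtype=float) - cov[names].to_numpy(dtype=float).mean(axis=0)
        if names
        else np.zeros((n, 0))
    )
    eps = rng.standard_normal((n, p)) * config.noise_sd
    eta2 = eta1 @ config.truth_matrix + c_centered @ b + eps

    cape_mu = _calibrate_cape_intercept(config)
    items1 = _generate_items(eta1, cape_mu, config, rng)
    items2 = _generate_items(eta2, cape_mu, config, rng)

    realized = float(
        (cape_weighted_score(items1[_nd.CAPE_ITEMS]) >= config.ples_cutoff).mean()
    )

    ids = [f"P{i:06d}" for i in range(n)]
    t1 = pd.Timestamp("2021-10-01") + pd.to_timedelta(np.arange(n), unit="min")
    t2 = pd.Timestamp("2022-10-01") + pd.to_timedelta(np.arange(n), unit="min")

    def wave_frame(wave, ts, items):
        base = pd.DataFrame(
            {
                "id": ids,
                "wave": wave,
                "timestamp": ts,
                "response_time_seconds": rng.uniform(600, 2400, size=n).round(1),
                "psychotic_history": 0,
                "refused_interview": 0,
            }
        )
        return pd.concat(
            [base, cov.reset_index(drop=True), items.reset_index(drop=True)],
            axis=1,
        )

    w1 = wave_frame(1, t1, items1)
    w2 = wave_frame(2, t2, items2)
    if config.followup_loss_rate > 0:
        n_lost = int(round(config.followup_loss_rate * n))
        lost = rng.choice(n, size=n_lost, replace=False)
        w2 = w2.drop(index=lost)
    records = pd.concat([w1, w2], ignore_index=True)

    data = PanelDataset(records, artifact_ledger={"followup_lost": n - len(w2)})
    truth = GroundTruth(
        truth_matrix=config.truth_matrix.copy(),
        realized_prevalence=realized,
        seed=config.seed,
        cape_intercept=cape_mu,
        noise_sd=config.noise_sd.copy(),
        prevalence_target=config.prevalence_target,
        latent_wave1=eta1,
        latent_wave2=eta2,
    )
    data = inject_admin_artifacts(data, config)
    return data, truth


def inject_admin_artifacts(
    data: PanelDataset, config: SimulationConfig
) -> PanelDataset:
    """Add duplicates, speeders and exclusion flags per the config rates.

    Counts are deterministic (``round(rate * n)``) given the seed; artifact
    groups are drawn disjointly so the exclusion cascade removes exactly the
    injected counts. The ledger on the returned dataset records each count.
    """
    rng = np.random.default_rng([config.seed, _ARTIFACT_STREAM])
    rec = data.records.copy()
    ledger = dict(data.artifact_ledger or {})

    w1_idx = rec.index[rec["wave"] == 1].to_numpy()
    n1 = len(w1_idx)
    n_dup = int(round(config.duplicate_rate * n1))
    n_speed = int(round(config.speeder_rate * n1))
    n_psych = int(round(config.psychotic_history_rate * n1))
    n_ref = int(round(config.refusal_rate * n1))
    if n_dup + n_speed + n_psych + n_ref > n1:
        raise ValueError("artifact rates exceed the available baseline records")

    chosen = rng.choice(w1_idx, size=n_dup + n_speed + n_psych + n_ref, replace=False)
    dup_rows, speed_rows = chosen[:n_dup], chosen[n_dup : n_dup + n_speed]
    psych_rows = chosen[n_dup + n_speed : n_dup + n_speed + n_psych]
    ref_rows = chosen[n_dup + n_speed + n_psych :]

    if n_speed:
        rec.loc[speed_rows, "response_time_seconds"] = rng.uniform(
            60, 295, size=n_speed
        ).round(1)
    if n_psych:
        ids = rec.loc[psych_rows, "id"]
        rec.loc[rec["id"].isin(ids), "psychotic_history"] = 1
    if n_ref:
        ids = rec.loc[ref_rows, "id"]
        rec.loc[rec["id"].isin(ids), "refused_interview"] = 1
    if n_dup:
        dups = rec.loc[dup_rows].copy()
        dups["timestamp"] = dups["timestamp"] + pd.Timedelta(days=1)
        dups["response_time_seconds"] = rng.uniform(600, 2400, size=n_dup).round(1)
        rec = pd.concat([rec, dups], ignore_index=True)

    ledger.update(
        duplicates=n_dup, speeders=n_speed,
        psychotic_history=n_psych, refusals=n_ref,
    )
    return PanelDataset(rec.reset_index(drop=True), ledger)


# ---------------------------------------------------------------------------
# ground-truth export


def export_truth(truth: GroundTruth, path: str | Path) -> None:
    """Write the truth matrix (CSV, labelled) plus a JSON parameter sidecar.

    ``path`` is the CSV path; the sidecar lands next to it with suffix
    ``.json``. Latent states are not exported. Round-trips losslessly at
    full float precision.
    """
    path = Path(path)
    try:
        pd.DataFrame(
            truth.truth_matrix, index=_nd.NODE_LABELS, columns=_nd.NODE_LABELS
        ).to_csv(path, float_format="%.17g")
        sidecar = {
            "seed": truth.seed,
            "realized_prevalence": truth.realized_prevalence,
            "prevalence_target": truth.prevalence_target,
            "cape_intercept": truth.cape_intercept,
            "noise_sd": truth.noise_sd.tolist(),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    except OSError as exc:
        raise OSError(f"cannot write ground truth to {path}: {exc}") from exc


def import_truth(path: str | Path) -> GroundTruth:
    """Re-load a ground truth written by :func:`export_truth`."""
    path = Path(path)
    mat = pd.read_csv(path, index_col=0, float_precision="round_trip")
    side = json.loads(path.with_suffix(".json").read_text())
    return GroundTruth(
        truth_matrix=mat.to_numpy(dtype=float),
        realized_prevalence=side["realized_prevalence"],
        seed=side["seed"],
        cape_intercept=side["cape_intercept"],
        noise_sd=np.asarray(side["noise_sd"], dtype=float),
        prevalence_target=side["prevalence_target"],
    )
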
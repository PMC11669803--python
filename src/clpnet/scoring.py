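"""Instrument scoring, screening cut-off, exclusion flow and transition rates.

Scales
------
CAPE-P15  15 items, 1-4. The whole-scale *weighted score* is the sum of valid
          item scores divided by the number of valid items; participants at or
          above the screening cut-off (default 1.57) screen positive for
          psychotic-like experiences (PLEs). Three subtype factors (PI, BEs,
          PAs) are scored as means of their items.
PHQ-9     9 items, 1-4, used item-wise as depression nodes.
GAD-7     7 items, 1-4, used item-wise as anxiety nodes.
ASLEC     27 adverse-life-event items, 1-5, scored into five factors.

Missing data: a factor/scale score is missing when fewer than
``completeness`` (default 0.8) of its items are valid; the CAPE whole-scale
weighted score is exempt (its definition already averages over valid items,
requiring only one).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nodes as _nd

PLES_CUTOFF = 1.57
SPEEDER_SECONDS = 300.0  # responses faster than 5 minutes are excluded


# ---------------------------------------------------------------------------
# containers


@dataclass
class InstrumentSpec:
    """An instrument: ordered items, response scale and factor structure."""

    name: str
    items: list[str]
    scale_min: int
    scale_max: int
    factors: dict[str, list[str]] = field(default_factory=dict)
    scoring_mode: str = "factor_mean"  # {weighted_mean, sum, factor_mean}

    def __post_init__(self) -> None:
        if self.scale_min >= self.scale_max:
            raise ValueError(f"{self.name}: scale_min must be < scale_max")
        item_set = set(self.items)
        seen: set[str] = set()
        for fname, fitems in self.factors.items():
            unknown = set(fitems) - item_set
            if unknown:
                raise ValueError(
                    f"{self.name}: factor {fname!r} references unknown items "
                    f"{sorted(unknown)}"
                )
            overlap = set(fitems) & seen
            if overlap:
                raise ValueError(
                    f"{self.name}: items {sorted(overlap)} appear in more "
                    "than one factor"
                )
            seen |= set(fitems)


def default_instrument_specs() -> dict[str, InstrumentSpec]:
    return {
        "cape": InstrumentSpec(
            "cape", list(_nd.CAPE_ITEMS), 1, 4, dict(_nd.CAPE_FACTORS), "weighted_mean"
        ),
        "phq": InstrumentSpec("phq", list(_nd.PHQ_ITEMS), 1, 4),
        "gad": InstrumentSpec("gad", list(_nd.GAD_ITEMS), 1, 4),
        "aslec": InstrumentSpec(
            "aslec", list(_nd.ASLEC_ITEMS), 1, 5, dict(_nd.ASLEC_FACTORS)
        ),
    }


@dataclass
class PanelDataset:
    """Two-wave panel: one row per submitted record (participant x wave).

    ``records`` carries administrative metadata, covariates and the item
    columns; ``artifact_ledger`` echoes injected artifact counts when the
    dataset came from the simulator.
    """

    records: pd.DataFrame
    artifact_ledger: dict[str, int] | None = None

    @property
    def n_records(self) -> int:
        return len(self.records)

    def participants(self) -> np.ndarray:
        return self.records["id"].unique()

    def wave(self, wave: int) -> pd.DataFrame:
        """Per-participant frame for one wave, indexed by participant id."""
        sub = self.records[self.records["wave"] == wave]
        if sub["id"].duplicated().any():
            raise ValueError(
                f"wave {wave} holds duplicate participant records; "
                "run apply_exclusions first"
            )
        return sub.set_index("id")


@dataclass
class NodeScores:
    """n x 24 matrix of scored network nodes for one wave."""

    wave: int
    data: pd.DataFrame  # columns = NODE_LABELS, index = participant id

    def __post_init__(self) -> None:
        missing = [c for c in _nd.NODE_LABELS if c not in self.data.columns]
        if missing:
            raise ValueError(f"node columns missing: {missing}")
        self.data = self.data[_nd.NODE_LABELS]
        if np.isinf(self.data.to_numpy(dtype=float)).any():
            raise ValueError("node scores contain infinities")

    @property
    def node_labels(self) -> list[str]:
        return list(_nd.NODE_LABELS)

    @property
    def construct_labels(self) -> list[str]:
        return list(_nd.CONSTRUCT_LABELS)

    def matrix(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def dropna(self) -> "NodeScores":
        return NodeScores(self.wave, self.data.dropna())


# ---------------------------------------------------------------------------
# scale scoring


def cape_weighted_score(items: pd.DataFrame | pd.Series) -> pd.Series | float:
    """CAPE-P15 weighted score: sum of valid items / number of valid items.

    Accepts one participant (Series) or many (DataFrame, items in columns).
    Rows with no valid item yield NaN.
    """
    if isinstance(items, pd.Series):
        return float("nan") if items.notna().sum() == 0 else float(items.mean())
    return items.mean(axis=1, skipna=True)


def classify_ples(
    score: pd.Series | float, cutoff: float = PLES_CUTOFF, inclusive: bool = True
):
    """Screen scores against the PLEs cut-off.

    ``inclusive`` controls the boundary: positive iff score >= cutoff
    (default) or strictly > cutoff. Missing scores classify as missing.
    Returns a nullable-boolean Series (True = positive) or, for a scalar
    input, True/False/None.
    """
    if np.isscalar(score):
        if score is None or (isinstance(score, float) and np.isnan(score)):
            return None
        return bool(score >= cutoff if inclusive else score > cutoff)
    s = pd.Series(score, dtype=float)
    pos = s >= cutoff if inclusive else s > cutoff
    return pos.astype("boolean").mask(s.isna())


def score_factors(
    items: pd.DataFrame,
    spec: InstrumentSpec,
    completeness: float = 0.8,
) -> pd.DataFrame:
    """Score each factor as the mean of its valid items.

    A factor score is missing when fewer than ``completeness`` of its items
    are valid. ``scoring_mode == "sum"`` rescales the mean by the item count
    (sum over valid items inflated to the full factor length), kept for
    sensitivity analyses.
    """
    if not spec.factors:
        raise ValueError(f"{spec.name}: no factor map defined")
    unknown = [
        c for f in spec.factors.values() for c in f if c not in items.columns
    ]
    if unknown:
        raise ValueError(f"{spec.name}: items absent from data: {unknown}")
    out = {}
    for fname, fitems in spec.factors.items():
        block = items[fitems]
        mean = block.mean(axis=1, skipna=True)
        enough = block.notna().sum(axis=1) >= completeness * len(fitems)
        score = mean.where(enough)
        if spec.scoring_mode == "sum":
            score = score * len(fitems)
        out[fname] = score
    return pd.DataFrame(out, index=items.index)


def cronbach_alpha(items: pd.DataFrame) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum(item variances)/var(total)).

    Sample variances (ddof=1) over complete cases. Requires >= 2 items,
    >= 3 complete rows and a non-constant total score.
    """
    x = items.dropna().to_numpy(dtype=float)
    n, k = x.shape
    if k < 2:
        raise ValueError("Cronbach's alpha needs at least 2 items")
    if n < 3:
        raise ValueError("Cronbach's alpha needs at least 3 complete cases")
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total score has zero variance; alpha undefined")
    item_var = x.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


# ---------------------------------------------------------------------------
# node-score assembly


def score_nodes(
    wave_items: pd.DataFrame,
    wave: int,
    specs: dict[str, InstrumentSpec] | None = None,
    completeness: float = 0.8,
) -> NodeScores:
    """Assemble the 24 network node scores for one wave.

    PLEs nodes are CAPE subtype factor means, depression/anxiety nodes are
    the raw PHQ-9/GAD-7 items, life-event nodes are ASLEC factor means.
    """
    specs = specs or default_instrument_specs()
    cape = score_factors(wave_items, specs["cape"], completeness)
    aslec = score_factors(wave_items, specs["aslec"], completeness)
    cols = {n: cape[n] for n in _nd.PLES_NODES}
    for node in _nd.PHQ_NODES + _nd.GAD_NODES:
        cols[node] = wave_items[_nd.items_of_node(node)[0]].astype(float)
    for node in _nd.ASLEC_NODES:
        cols[node] = aslec[node]
    return NodeScores(wave, pd.DataFrame(cols, index=wave_items.index))


# ---------------------------------------------------------------------------
# exclusion flow


@dataclass
class FlowReport:
    """Cohort-flow ledger: baseline records removed at each exclusion step."""

    baseline_collected: int
    duplicates_removed: int
    speeders_removed: int
    psychotic_history_removed: int
    refusals_removed: int
    valid_baseline: int
    lost_to_followup: int
    analyzed: int

    def to_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def apply_exclusions(data: PanelDataset) -> tuple[PanelDataset, FlowReport]:
    """Apply the exclusion cascade and report counts removed at each step.

    Order: (1) duplicate records per (participant, wave) — the earliest
    timestamp is kept; (2) records with response time under 5 minutes;
    (3) participants with a history of psychotic disorder; (4) participants
    who refused the verification interview. Step counts in the flow report
    refer to baseline (wave-1) records, so that
    ``baseline_collected - sum(step removals) == valid_baseline``; wave-2
    records of excluded participants are removed alongside. A participant is
    valid at baseline with a surviving wave-1 record, and analyzed with
    surviving records at both waves.
    """
    required = ["id", "wave", "timestamp", "response_time_seconds"]
    missing = [c for c in required if c not in data.records.columns]
    if missing:
        raise ValueError(f"metadata column(s) missing: {missing}")
    rec = data.records

    def _w1(df: pd.DataFrame) -> int:
        return int((df["wave"] == 1).sum())

    baseline_collected = _w1(rec)

    keep = rec.sort_values("timestamp", kind="mergesort")
    keep = keep[~keep.duplicated(subset=["id", "wave"], keep="first")]
    n_dup = baseline_collected - _w1(keep)

    fast = keep["response_time_seconds"] < SPEEDER_SECONDS
    n_speed = _w1(keep[fast])
    keep = keep[~fast]

    if "psychotic_history" in keep.columns:
        psych_ids = set(keep.loc[keep["psychotic_history"].astype(bool), "id"])
    else:
        psych_ids = set()
    n_psych = _w1(keep[keep["id"].isin(psych_ids)])
    keep = keep[~keep["id"].isin(psych_ids)]

    if "refused_interview" in keep.columns:
        ref_ids = set(keep.loc[keep["refused_interview"].astype(bool), "id"])
    else:
        ref_ids = set()
    n_ref = _w1(keep[keep["id"].isin(ref_ids)])
    keep = keep[~keep["id"].isin(ref_ids)]

    w1_ids = set(keep.loc[keep["wave"] == 1, "id"])
    w2_ids = set(keep.loc[keep["wave"] == 2, "id"])
    valid_baseline = len(w1_ids)
    analyzed = len(w1_ids & w2_ids)

    report = FlowReport(
        baseline_collected=baseline_collected,
        duplicates_removed=n_dup,
        speeders_removed=n_speed,
        psychotic_history_removed=n_psych,
        refusals_removed=n_ref,
        valid_baseline=valid_baseline,
        lost_to_followup=valid_baseline - analyzed,
        analyzed=analyzed,
    )
    # conservation audit: baseline in - per-step removals = baseline out
    assert (
        baseline_collected - n_dup - n_speed - n_psych - n_ref == valid_baseline
    ), "flow-report counts do not conserve baseline records"
    out = PanelDataset(
        keep.sort_index().reset_index(drop=True), data.artifact_ledger
    )
    return out, report


def analyzed_subset(data: PanelDataset) -> PanelDataset:
    """Restrict to participants with records at both waves (post-exclusion)."""
    rec = data.records
    w1 = set(rec.loc[rec["wave"] == 1, "id"])
    w2 = set(rec.loc[rec["wave"] == 2, "id"])
    both = w1 & w2
    return PanelDataset(
        rec[rec["id"].isin(both)].reset_index(drop=True), data.artifact_ledger
    )


# ---------------------------------------------------------------------------
# transition descriptives


@dataclass
class TransitionRates:
    """Persistence and incidence of screen-positive status across waves."""

    baseline_positive: int
    baseline_negative: int
    persisting: int
    incident: int

    @property
    def persistence(self) -> float:
        if self.baseline_positive == 0:
            return float("nan")
        return self.persisting / self.baseline_positive

    @property
    def incidence(self) -> float:
        if self.baseline_negative == 0:
            return float("nan")
        return self.incident / self.baseline_negative


def transition_rates(
    baseline: pd.Series, wave2: pd.Series
) -> TransitionRates:
    """Persistence/incidence from aligned boolean screen classifications.

    persistence = positive at both waves / baseline positives;
    incidence = newly positive at wave 2 / baseline negatives.
    Participants with a missing classification at either wave are dropped.
    """
    df = pd.DataFrame({"b": baseline, "w2": wave2}).dropna()
    b = df["b"].astype(bool)
    w2 = df["w2"].astype(bool)
    return TransitionRates(
        baseline_positive=int(b.sum()),
        baseline_negative=int((~b).sum()),
        persisting=int((b & w2).sum()),
        incident=int((~b & w2).sum()),
    )
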
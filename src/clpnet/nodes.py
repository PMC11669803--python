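"""Node and construct registry for the 24-symptom panel network.

The network layer has 24 nodes drawn from four constructs:

* psychotic-like experiences (PLEs): the three CAPE-P15 subtype factors —
  persecutory ideation (PI), bizarre experiences (BEs) and perceptual
  abnormalities (PAs);
* depressive symptoms: the nine PHQ-9 items;
* anxiety symptoms: the seven GAD-7 items;
* adverse life events: five ASLEC factors (being punished, loss, adjustment,
  interpersonal stress, academic stress).

Item-to-factor maps are configurable; the defaults below are the shipped
convention (the CAPE subtype assignment and the ASLEC factor blocks are not
uniquely fixed by the instruments' short names).
"""

from __future__ import annotations

PLES_NODES = ["PI", "BEs", "PAs"]
PHQ_NODES = [f"PHQ{i}" for i in range(1, 10)]
GAD_NODES = [f"GAD{i}" for i in range(1, 8)]
ASLEC_NODES = [f"A{i}" for i in range(1, 6)]

NODE_LABELS: list[str] = PLES_NODES + PHQ_NODES + GAD_NODES + ASLEC_NODES

CONSTRUCT_OF: dict[str, str] = (
    {n: "PLEs" for n in PLES_NODES}
    | {n: "depression" for n in PHQ_NODES}
    | {n: "anxiety" for n in GAD_NODES}
    | {n: "life_events" for n in ASLEC_NODES}
)

CONSTRUCT_LABELS: list[str] = [CONSTRUCT_OF[n] for n in NODE_LABELS]

N_NODES = len(NODE_LABELS)  # 24

CAPE_ITEMS = [f"cape_{i:02d}" for i in range(1, 16)]
PHQ_ITEMS = [f"phq_{i:02d}" for i in range(1, 10)]
GAD_ITEMS = [f"gad_{i:02d}" for i in range(1, 8)]
ASLEC_ITEMS = [f"aslec_{i:02d}" for i in range(1, 28)]

# CAPE-P15 positive-symptom subtypes: 5 persecutory, 7 bizarre, 3 perceptual.
CAPE_FACTORS: dict[str, list[str]] = {
    "PI": [f"cape_{i:02d}" for i in (1, 2, 4, 6, 7)],
    "BEs": [f"cape_{i:02d}" for i in (3, 5, 8, 9, 10, 11, 12)],
    "PAs": [f"cape_{i:02d}" for i in (13, 14, 15)],
}

# ASLEC factors used as network nodes, contiguous item blocks (7/3/6/5/6).
# A1 being punished, A2 loss, A3 adjustment, A4 interpersonal, A5 academic.
ASLEC_FACTORS: dict[str, list[str]] = {
    "A1": [f"aslec_{i:02d}" for i in range(1, 8)],
    "A2": [f"aslec_{i:02d}" for i in range(8, 11)],
    "A3": [f"aslec_{i:02d}" for i in range(11, 17)],
    "A4": [f"aslec_{i:02d}" for i in range(17, 22)],
    "A5": [f"aslec_{i:02d}" for i in range(22, 28)],
}

ITEM_SCALES: dict[str, tuple[int, int]] = (
    {c: (1, 4) for c in CAPE_ITEMS + PHQ_ITEMS + GAD_ITEMS}
    | {c: (1, 5) for c in ASLEC_ITEMS}
)

ALL_ITEMS: list[str] = CAPE_ITEMS + PHQ_ITEMS + GAD_ITEMS + ASLEC_ITEMS

COVARIATES: list[str] = [
    "age",
    "sex",
    "ethnicity_han",
    "birth_rural",
    "chronic_condition",
    "mental_history",
    "family_mental_history",
]

ADMIN_COLUMNS: list[str] = [
    "id",
    "wave",
    "timestamp",
    "response_time_seconds",
    "psychotic_history",
    "refused_interview",
]


def items_of_node(node: str) -> list[str]:
    """Item columns feeding a network node (singleton for PHQ/GAD items)."""
    if node in CAPE_FACTORS:
        return CAPE_FACTORS[node]
    if node in PHQ_NODES:
        return [f"phq_{int(node[3:]):02d}"]
    if node in GAD_NODES:
        return [f"gad_{int(node[3:]):02d}"]
    if node in ASLEC_FACTORS:
        return ASLEC_FACTORS[node]
    raise KeyError(f"unknown node {node!r}")
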
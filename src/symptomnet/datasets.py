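"""Questionnaire subscale datasets and variable naming conventions.

The analysis operates on per-participant sum scores of 11 EDI-2 subscales
(eating-disorder psychopathology) and 5 CTQ subscales (childhood
maltreatment).  Variables are tagged with a role — ``"ED"`` for symptom
nodes, ``"CM"`` for maltreatment nodes — because the shortest-pathway
analysis treats maltreatment as an external field feeding the symptom
network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: EDI-2 subscales, in canonical column order.
ED_NODES: tuple[str, ...] = (
    "ineffectiveness",
    "social_insecurity",
    "drive_for_thinness",
    "interoceptive_awareness",
    "maturity_fear",
    "body_dissatisfaction",
    "perfectionism",
    "interpersonal_distrust",
    "impulsivity",
    "bulimia",
    "asceticism",
)

#: CTQ maltreatment subscales, in canonical column order.
CM_NODES: tuple[str, ...] = (
    "emotional_neglect",
    "emotional_abuse",
    "sexual_abuse",
    "physical_neglect",
    "physical_abuse",
)

#: Full canonical variable order: symptoms first, maltreatment last.
ALL_NODES: tuple[str, ...] = ED_NODES + CM_NODES

#: The two "ED-specific" symptom nodes used as shortest-path targets.
ED_SPECIFIC_NODES: tuple[str, ...] = ("body_dissatisfaction", "bulimia")


def default_roles(names: list[str] | tuple[str, ...]) -> dict[str, str]:
    """Map each variable name to ``"CM"`` or ``"ED"`` by convention."""
    return {n: ("CM" if n in CM_NODES else "ED") for n in names}


class DatasetError(ValueError):
    """Raised for structurally invalid subscale data."""


@dataclass
class SubscaleDataset:
    """A subjects x variables table of integer subscale scores.

    Parameters
    ----------
    scores
        DataFrame with one row per participant and one integer column per
        subscale.  No missing cells are allowed (ingestion is
        complete-case; see :func:`symptomnet.io.read_scores`).
    variable_role
        Mapping variable name -> ``"CM"`` or ``"ED"``.
    group_label
        Free-text sample label (e.g. ``"BN"`` or ``"BED"``).
    provenance
        ``"synthetic"`` or ``"file"``, optionally with a seed or filename,
        e.g. ``"synthetic(seed=7)"``.
    """

    scores: pd.DataFrame
    variable_role: dict[str, str] = field(default_factory=dict)
    group_label: str = ""
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        if not isinstance(self.scores, pd.DataFrame):
            self.scores = pd.DataFrame(self.scores)
        if self.scores.isna().any().any():
            raise DatasetError("score table contains missing cells")
        if not self.variable_role:
            self.variable_role = default_roles(list(self.scores.columns))
        unknown = set(self.scores.columns) - set(self.variable_role)
        if unknown:
            raise DatasetError(f"variables without a role: {sorted(unknown)}")

    @property
    def variable_names(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.scores)

    @property
    def n_variables(self) -> int:
        return self.scores.shape[1]

    @property
    def cm_nodes(self) -> list[str]:
        return [v for v in self.variable_names if self.variable_role[v] == "CM"]

    @property
    def ed_nodes(self) -> list[str]:
        return [v for v in self.variable_names if self.variable_role[v] == "ED"]

    def values(self) -> np.ndarray:
        """Scores as a float matrix (subjects x variables)."""
        return self.scores.to_numpy(dtype=float)
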
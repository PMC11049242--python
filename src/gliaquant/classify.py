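"""Rule-based morphological classification of microglia.

A cell is *branched* ("resting"-like, ramified) when at least
``min_criteria`` of {S < 0.5, NP > 7, TL > 140 µm, A > 2400 µm²} hold, and
*amoeboid* ("activated"-like) when at least ``min_criteria`` of
{S > 0.7, NP < 3, TL < 60 µm, A < 1500 µm²} hold; anything else is
*transitional*. All comparisons are strict, so a cell sitting exactly on a
threshold does not satisfy that criterion. Under the default rule
(min_criteria = 3) no cell can qualify for both classes: each parameter
contributes to at most one side, so at most 4 of the 8 predicates can hold
at once.

Volume is carried in the morphology vector but takes no part in the rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .morpho3d import CellMorphology

BRANCHED = "branched"
AMOEBOID = "amoeboid"
TRANSITIONAL = "transitional"
CLASSES = (BRANCHED, AMOEBOID, TRANSITIONAL)


@dataclass(frozen=True)
class ClassifierRule:
    """Thresholds of the two per-class criterion sets.

    The branched and amoeboid intervals of every parameter must be
    disjoint (e.g. ``sphericity_branched_max ≤ sphericity_amoeboid_min``).
    """

    sphericity_branched_max: float = 0.5
    n_processes_branched_min: int = 7      # NP > 7
    total_length_branched_min: float = 140.0
    area_branched_min: float = 2400.0
    sphericity_amoeboid_min: float = 0.7
    n_processes_amoeboid_max: int = 3      # NP < 3
    total_length_amoeboid_max: float = 60.0
    area_amoeboid_max: float = 1500.0
    min_criteria: int = 3

    def __post_init__(self) -> None:
        if not 1 <= self.min_criteria <= 4:
            raise ValueError("min_criteria must be in [1, 4]")
        disjoint = (
            self.sphericity_branched_max <= self.sphericity_amoeboid_min
            and self.n_processes_amoeboid_max <= self.n_processes_branched_min
            and self.total_length_amoeboid_max <= self.total_length_branched_min
            and self.area_amoeboid_max <= self.area_branched_min
        )
        if not disjoint:
            raise ValueError("branched and amoeboid intervals must be disjoint")

    # bool() coercion matters: numpy scalar comparisons yield np.bool_,
    # whose ``+`` is logical-or, which would collapse the criterion count
    def branched_criteria(self, s: float, np_: float, tl: float, a: float) -> int:
        return sum(
            map(
                bool,
                (
                    s < self.sphericity_branched_max,
                    np_ > self.n_processes_branched_min,
                    tl > self.total_length_branched_min,
                    a > self.area_branched_min,
                ),
            )
        )

    def amoeboid_criteria(self, s: float, np_: float, tl: float, a: float) -> int:
        return sum(
            map(
                bool,
                (
                    s > self.sphericity_amoeboid_min,
                    np_ < self.n_processes_amoeboid_max,
                    tl < self.total_length_amoeboid_max,
                    a < self.area_amoeboid_max,
                ),
            )
        )


DEFAULT_RULE = ClassifierRule()


@dataclass
class MorphClass:
    """Classification outcome for one cell."""

    label: str
    n_branched_criteria: int
    n_amoeboid_criteria: int


def classify_cell(m: CellMorphology, rule: ClassifierRule = DEFAULT_RULE) -> MorphClass:
    """Assign branched / amoeboid / transitional to one morphology vector.

    Raises ``ValueError`` naming the offending parameter when S, NP, TL or
    A is missing or non-finite.
    """
    for name, val in (
        ("sphericity", m.sphericity),
        ("n_processes", m.n_processes),
        ("total_length", m.total_length),
        ("surface_area", m.surface_area),
    ):
        if val is None or not math.isfinite(float(val)):
            raise ValueError(f"parameter {name!r} is missing or not finite")
    nb = rule.branched_criteria(m.sphericity, m.n_processes, m.total_length, m.surface_area)
    na = rule.amoeboid_criteria(m.sphericity, m.n_processes, m.total_length, m.surface_area)
    if nb >= rule.min_criteria and na >= rule.min_criteria:
        # unreachable under any valid (disjoint-interval) rule with
        # min_criteria ≥ 3; defensive for permissive custom rules
        label = BRANCHED if nb >= na else AMOEBOID
    elif nb >= rule.min_criteria:
        label = BRANCHED
    elif na >= rule.min_criteria:
        label = AMOEBOID
    else:
        label = TRANSITIONAL
    return MorphClass(label, nb, na)


def classify_population(
    cells: list[CellMorphology], rule: ClassifierRule = DEFAULT_RULE
) -> tuple[dict[str, float], pd.DataFrame]:
    """Per-class percentages plus the per-cell label table."""
    if not cells:
        raise ValueError("empty cell list")
    rows = []
    for i, m in enumerate(cells):
        c = classify_cell(m, rule)
        rows.append(
            {
                "cell_index": i,
                "label": c.label,
                "n_branched_criteria": c.n_branched_criteria,
                "n_amoeboid_criteria": c.n_amoeboid_criteria,
            }
        )
    table = pd.DataFrame(rows)
    pct = {
        cls: 100.0 * float((table["label"] == cls).sum()) / len(cells)
        for cls in CLASSES
    }
    return pct, table


def classify_table(df: pd.DataFrame, rule: ClassifierRule = DEFAULT_RULE) -> pd.DataFrame:
    """Append label and criteria-count columns to a morphology table.

    Expects the column layout written by :func:`gliaquant.morpho3d.measure_all`
    (lengths in µm, areas in µm²).
    """
    required = {"sphericity", "n_processes", "total_length", "surface_area"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"morphology table lacks columns: {sorted(missing)}")
    out = df.copy()
    labels, nbs, nas = [], [], []
    for _, row in df.iterrows():
        m = CellMorphology(
            sphericity=row["sphericity"],
            n_processes=row["n_processes"],
            total_length=row["total_length"],
            mean_length=row.get("mean_length", np.nan),
            surface_area=row["surface_area"],
            volume=row.get("volume", np.nan),
            ramification_index=row.get("ramification_index", np.nan),
        )
        c = classify_cell(m, rule)
        labels.append(c.label)
        nbs.append(c.n_branched_criteria)
        nas.append(c.n_amoeboid_criteria)
    out["label"] = labels
    out["n_branched_criteria"] = nbs
    out["n_amoeboid_criteria"] = nas
    return out
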
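"""Curation of raw assay records into a deduplicated, binary-labeled table.

Records carry a relation code ("=", "<", ">") and a Ki in nM. Exact values
("=") are labeled active if Ki < 1000 nM and inactive if Ki >= 1000 nM.
Censored records are kept only when the bound forces an unequivocal class:
"> v" forces inactive iff v >= 1000 nM; "< v" forces active iff v <= 1000 nM.
Duplicate compounds (same canonical SMILES) are merged by averaging their
"=" Ki values; censored duplicates of an unambiguous class vote for the
class but contribute no value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ACTIVE = "active"
INACTIVE = "inactive"
DISCARD = "discard"

RELATIONS = ("=", "<", ">")

#: activity threshold in nM, the field's usual cut between active/inactive
DEFAULT_THRESHOLD_NM = 1000.0


@dataclass(frozen=True)
class ActivityRecord:
    """One assay row: compound id, SMILES, relation code, Ki in nM."""

    compound_id: str
    smiles: str
    relation: str
    ki: float

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise ValueError(
                f"unknown relation {self.relation!r}; expected one of {RELATIONS}"
            )
        if not self.ki > 0:
            raise ValueError("ki must be > 0 nM")


def classify_record(
    relation: str, ki_nM: float, threshold_nM: float = DEFAULT_THRESHOLD_NM
) -> str:
    """Classify one record as 'active', 'inactive' or 'discard'.

    Exact values split at the threshold (active strictly below). A censored
    record survives only if its bound forces the class: ``> v`` is inactive
    when v >= threshold (Ki > v >= threshold); ``< v`` is active when
    v <= threshold (Ki < v <= threshold). Anything else is ambiguous and
    discarded.
    """
    if relation not in RELATIONS:
        raise ValueError(
            f"unknown relation {relation!r}; expected one of {RELATIONS}"
        )
    if not ki_nM > 0:
        raise ValueError("ki must be > 0 nM")
    if relation == "=":
        return ACTIVE if ki_nM < threshold_nM else INACTIVE
    if relation == ">":
        return INACTIVE if ki_nM >= threshold_nM else DISCARD
    # relation == "<"
    return ACTIVE if ki_nM <= threshold_nM else DISCARD


def deduplicate(
    records: list[ActivityRecord], threshold_nM: float = DEFAULT_THRESHOLD_NM
) -> pd.DataFrame:
    """Merge records into one row per unique SMILES.

    Returns a curated table indexed by SMILES with columns ``mean_ki``
    (arithmetic mean of the "=" values, NaN for censored-only compounds),
    ``label``, ``n_merged``, ``rsd`` (percent relative SD of the merged
    "=" values) and ``flagged`` (True when an "=" consensus contradicts a
    censored record, or censored records disagree; "=" takes precedence).

    Discarded (ambiguous censored) records never contribute.
    """
    rows = []
    by_smiles: dict[str, list[ActivityRecord]] = {}
    for rec in records:
        by_smiles.setdefault(rec.smiles, []).append(rec)

    for smiles, group in by_smiles.items():
        kept = [
            (r, classify_record(r.relation, r.ki, threshold_nM)) for r in group
        ]
        kept = [(r, c) for r, c in kept if c != DISCARD]
        if not kept:
            continue
        exact = [r for r, _ in kept if r.relation == "="]
        censored_labels = {c for r, c in kept if r.relation != "="}
        flagged = False
        if exact:
            values = np.array([r.ki for r in exact], float)
            mean_ki = float(values.mean())
            label = ACTIVE if mean_ki < threshold_nM else INACTIVE
            rsd = (
                float(100.0 * values.std(ddof=1) / values.mean())
                if len(values) > 1
                else 0.0
            )
            # "=" consensus wins over any contradicting censored record
            flagged = bool(censored_labels - {label})
        else:
            if len(censored_labels) > 1:
                # mutually contradictory censored bounds; unmergeable
                label = sorted(censored_labels)[0]
                flagged = True
            else:
                label = next(iter(censored_labels))
            mean_ki = float("nan")
            rsd = float("nan")
        rows.append(
            {
                "smiles": smiles,
                "mean_ki": mean_ki,
                "label": label,
                "n_merged": len(kept),
                "rsd": rsd,
                "flagged": flagged,
                "compound_id": kept[0][0].compound_id,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "smiles",
            "mean_ki",
            "label",
            "n_merged",
            "rsd",
            "flagged",
            "compound_id",
        ],
    )
    return out.set_index("smiles")


def read_activity_csv(
    path,
    id_col: str = "compound_id",
    smiles_col: str = "smiles",
    relation_col: str = "relation",
    ki_col: str = "ki_nM",
) -> list[ActivityRecord]:
    """Read an assay-export CSV with a configurable column mapping."""
    df = pd.read_csv(path)
    return [
        ActivityRecord(
            compound_id=str(row[id_col]),
            smiles=str(row[smiles_col]),
            relation=str(row[relation_col]).strip(),
            ki=float(row[ki_col]),
        )
        for _, row in df.iterrows()
    ]


def curate(
    records: list[ActivityRecord], threshold_nM: float = DEFAULT_THRESHOLD_NM
) -> pd.DataFrame:
    """Full curation: relation-aware classification then SMILES deduplication."""
    return deduplicate(records, threshold_nM=threshold_nM)
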
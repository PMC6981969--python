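"""Docking-score calibration, ligand efficiency and pose RMSD.

Binding energies are in kcal/mol and more negative means a better binder,
so the decision convention throughout is "active iff energy <= cutoff".
Cutoffs are calibrated on labeled compounds either by maximising
sensitivity + specificity (Youden-style) or by demanding 100% specificity
(no inactive compound below the cutoff). Ligand-efficiency variants
normalise the energy by a molecular size or lipophilicity property.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

#: ligand-efficiency variants -> property column they divide by
LE_VARIANTS = {
    "mw": "mw",
    "heavy_atoms": "heavy_atoms",
    "carbon_atoms": "carbon_atoms",
    "logp": "logp",
    "logp_sq": "logp",  # energy / logP^2
    "wiener": "wiener",
    "tsa": "tsa",
    "mcgowan_vol": "mcgowan_vol",
    "vdw_mcgowan": "vdw_mcgowan",
    "vdw_zaz": "vdw_zaz",
}


@dataclass(frozen=True)
class CutpointResult:
    """An energy threshold with its calibration metrics (percent)."""

    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    objective: str

    def as_dict(self) -> dict:
        return {
            "cutoff_kcal_mol": self.cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "objective": self.objective,
        }


def _validate(energies, labels):
    energies = np.asarray(energies, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind in "OU":
        labels = (labels == "active").astype(int)
    labels = labels.astype(int)
    if energies.shape != labels.shape:
        raise ValueError("energies and labels must align")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present to calibrate a cutoff")
    if not np.isfinite(energies).all():
        raise ValueError("energies must be finite")
    return energies, labels


def _metrics_at(energies, labels, cutoff) -> tuple[float, float, float]:
    pred = energies <= cutoff  # lower energy = predicted active
    pos, neg = labels == 1, labels == 0
    sens = 100.0 * (pred & pos).sum() / pos.sum()
    spec = 100.0 * (~pred & neg).sum() / neg.sum()
    acc = 100.0 * (pred == (labels == 1)).mean()
    return sens, spec, acc


def _candidate_cutoffs(energies: np.ndarray) -> np.ndarray:
    """Midpoints of adjacent sorted unique energies, plus sentinels."""
    uniq = np.unique(energies)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])


def _auc(energies, labels) -> float:
    return 100.0 * roc_auc_score(labels, -energies)


def optimal_cutpoint(energies, labels) -> CutpointResult:
    """Cutoff maximising sensitivity + specificity on calibration data.

    All midpoints between adjacent sorted unique energies are scanned;
    ties in the objective break toward higher specificity, then toward the
    more stringent (lower) cutoff.
    """
    energies, labels = _validate(energies, labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    best = None
    for cutoff in _candidate_cutoffs(energies):
        pred = energies <= cutoff
        tp = int((pred & (labels == 1)).sum())
        tn = int((~pred & (labels == 0)).sum())
        # exact integer objective: tp/P + tn/N compared as tp*N + tn*P
        key = (tp * n_neg + tn * n_pos, tn, -cutoff)
        if best is None or key > best[0]:
            best = (key, float(cutoff))
    cutoff = best[1]
    sens, spec, acc = _metrics_at(energies, labels, cutoff)
    return CutpointResult(
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        auc=_auc(energies, labels),
        objective="max sens+spec",
    )


def max_specificity_cutpoint(energies, labels) -> CutpointResult:
    """Least stringent cutoff with 100% specificity on calibration data.

    The cutoff sits strictly below the minimum inactive energy (at the
    midpoint to the next lower observed energy). An inactive compound tying
    the active minimum leaves no admissible cutoff and raises.
    """
    energies, labels = _validate(energies, labels)
    min_inactive = energies[labels == 0].min()
    min_active = energies[labels == 1].min()
    if min_inactive == min_active:
        raise ValueError(
            "100% specificity unattainable: an inactive compound ties the "
            f"active minimum energy ({min_active:.3f} kcal/mol)"
        )
    below = energies[energies < min_inactive]
    if below.size:
        cutoff = float((below.max() + min_inactive) / 2.0)
    else:
        cutoff = float(min_inactive - 1.0)
    sens, spec, acc = _metrics_at(energies, labels, cutoff)
    return CutpointResult(
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        auc=_auc(energies, labels),
        objective="max specificity",
    )


def apply_energy_cutoff(table: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Rows whose ``energy`` passes the cutoff (energy <= cutoff), order kept."""
    return table[table["energy"] <= cutoff]


def ligand_efficiency(energy: float, properties: dict, variant: str):
    """Binding energy normalised by a molecular property.

    ``variant`` selects the divisor (molecular weight, heavy-atom count,
    carbon count, logP, squared logP, Wiener index, total surface area,
    McGowan volume, or a van der Waals volume estimate). A missing or zero
    property yields None (flagged missing, never 0).
    """
    if variant not in LE_VARIANTS:
        raise ValueError(
            f"unknown variant {variant!r}; available: {sorted(LE_VARIANTS)}"
        )
    prop = properties.get(LE_VARIANTS[variant])
    if prop is None or (isinstance(prop, float) and np.isnan(prop)) or prop == 0:
        return None
    prop = float(prop)
    if variant == "logp_sq":
        return energy / prop**2
    return energy / prop


def ligand_efficiency_table(
    table: pd.DataFrame, properties: pd.DataFrame, variants=None
) -> pd.DataFrame:
    """LE matrix: one column per variant, joined on compound id."""
    variants = list(variants or LE_VARIANTS)
    merged = table.merge(properties, on="id", how="left")
    out = pd.DataFrame({"id": merged["id"]})
    for v in variants:
        out[v] = [
            le if (le := ligand_efficiency(row["energy"], row.to_dict(), v)) is not None
            else np.nan
            for _, row in merged.iterrows()
        ]
    return out


def rmsd(coords_a, coords_b) -> float:
    """Root-mean-square deviation (Angstrom) between corresponding atoms.

    No superposition is performed: docked poses share the receptor frame.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    return float(np.sqrt(((a - b) ** 2).sum(axis=-1).mean()))


def read_docking_csv(path) -> pd.DataFrame:
    """Docking table CSV with columns id, energy, sd (label optional)."""
    df = pd.read_csv(path)
    required = {"id", "energy"}
    if not required <= set(df.columns):
        raise ValueError(f"docking table needs columns {sorted(required)}")
    if (df.get("sd", pd.Series(dtype=float)) < 0).any():
        raise ValueError("pose-cluster sd must be >= 0")
    return df


def load_screening_hits() -> pd.DataFrame:
    """Published LeDock binding energies for the 89 virtual-screening hits.

    Mean best-cluster energy (kcal/mol) with the pose-cluster SD, for the
    compounds predicted active by the stacked c-src QSAR models and used to
    validate the 100%-specificity energy cutoff.
    """
    from importlib.resources import files

    path = files("qsarstack").joinpath("data/ledock_screening_hits.csv")
    with path.open() as fh:
        return pd.read_csv(fh)
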
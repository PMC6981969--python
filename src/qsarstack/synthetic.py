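"""Synthetic activity records, descriptor matrices and docking tables.

The generator emulates the statistical structure of a curated kinase
inhibition dataset: a 286 active / 752 inactive class split, descriptor
columns that are informative (class-conditionally shifted Gaussians),
pure noise, quasi-constant, or pairwise highly correlated; duplicate
assay records with relation codes and jittered Ki; and docking energies
drawn from class-conditional normal distributions (defaults -8.02 vs
-7.29 kcal/mol, the calibration-set class means).

SMILES strings are synthetic tokens — the chemistry is not real, only the
statistics the downstream filters and models assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from qsarstack.curation import ActivityRecord

# correlation planted within each correlated pair (|r| > 0.9 by construction)
TARGET_PAIR_R = 0.95

# multiplicative lognormal sigma for duplicate-Ki jitter; the relative SD of
# exp(N(0, s)) is sqrt(exp(s^2)-1) ~ s, kept under the ~14% seen for
# replicated assay values in curated ChEMBL-style data
KI_JITTER_SIGMA = 0.12


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic labeled descriptor dataset.

    Attributes
    ----------
    n_active, n_inactive : int
        Class sizes; defaults give the 286/752 study split.
    n_informative : int
        Columns whose class means differ by ``effect_size`` (in SD units).
    n_noise : int
        Label-independent standard-normal columns.
    n_quasi_constant : int
        Columns with fewer than 1% of entries off a single mode value.
    n_correlated_pairs : int
        Pairs (base, echo) with Pearson r > 0.9 by construction.
    effect_size : float
        Standardized mean shift of informative columns between classes.
    duplicate_fraction : float
        Fraction of activity records emitted twice with jittered Ki.
    seed : int
        All randomness derives from this seed; identical spec + seed
        gives bit-identical output.
    """

    n_active: int = 286
    n_inactive: int = 752
    n_informative: int = 20
    n_noise: int = 60
    n_quasi_constant: int = 10
    n_correlated_pairs: int = 5
    effect_size: float = 1.0
    duplicate_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_active,
            self.n_inactive,
            self.n_informative,
            self.n_noise,
            self.n_quasi_constant,
            self.n_correlated_pairs,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 <= self.duplicate_fraction < 1:
            raise ValueError("duplicate_fraction must be in [0, 1)")


@dataclass
class LabeledDataset:
    """Descriptor matrix with binary activity labels and compound ids."""

    X: pd.DataFrame
    y: np.ndarray  # 1 = active, 0 = inactive
    ids: list[str] = field(default_factory=list)
    # ground-truth column roles, for planted-structure recovery tests
    column_roles: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_compounds(self) -> int:
        return len(self.X)

    @property
    def class_counts(self) -> tuple[int, int]:
        """(n_active, n_inactive)."""
        return int(self.y.sum()), int((1 - self.y).sum())


def generate_labeled_dataset(spec: SyntheticSpec) -> LabeledDataset:
    """Draw a labeled descriptor matrix with planted structure.

    Informative columns are unit-variance Gaussians whose class means are
    ``effect_size`` apart (actives shifted upward). Each correlated pair is
    built as a base informative-style column plus Gaussian noise scaled so
    the pair correlation is ~0.95. Quasi-constant columns hold a single
    mode value with exactly ``floor(0.005*n)`` entries displaced, keeping
    them under the 1% variant rule for every n.
    """
    if spec.n_active == 0 or spec.n_inactive == 0:
        raise ValueError(
            "both classes must be non-empty: downstream class-conditional "
            "metrics are undefined otherwise"
        )
    rng = np.random.default_rng(spec.seed)
    n = spec.n_active + spec.n_inactive
    y = np.concatenate([np.ones(spec.n_active, int), np.zeros(spec.n_inactive, int)])
    perm = rng.permutation(n)
    y = y[perm]

    cols: dict[str, np.ndarray] = {}
    roles: dict[str, list[str]] = {
        "informative": [],
        "noise": [],
        "quasi_constant": [],
        "correlated_base": [],
        "correlated_echo": [],
    }

    shift = spec.effect_size
    for i in range(spec.n_informative):
        name = f"inf_{i:03d}"
        cols[name] = rng.standard_normal(n) + shift * y
        roles["informative"].append(name)

    for i in range(spec.n_noise):
        name = f"noise_{i:03d}"
        cols[name] = rng.standard_normal(n)
        roles["noise"].append(name)

    # echo = base + eps * sigma with sigma chosen so corr(base, echo) ~ r
    sigma = float(np.sqrt(1.0 / TARGET_PAIR_R**2 - 1.0))
    for i in range(spec.n_correlated_pairs):
        base_name, echo_name = f"corr_{i:03d}a", f"corr_{i:03d}b"
        base = rng.standard_normal(n) + shift * y
        cols[base_name] = base
        cols[echo_name] = base + sigma * rng.standard_normal(n)
        roles["correlated_base"].append(base_name)
        roles["correlated_echo"].append(echo_name)

    n_off = int(0.005 * n)
    for i in range(spec.n_quasi_constant):
        name = f"qc_{i:03d}"
        col = np.zeros(n)
        if n_off > 0:
            off_idx = rng.choice(n, size=n_off, replace=False)
            col[off_idx] = 1.0
        cols[name] = col
        roles["quasi_constant"].append(name)

    X = pd.DataFrame(cols)
    ids = [f"CPD{i:06d}" for i in range(n)]
    X.index = pd.Index(ids, name="compound_id")
    return LabeledDataset(X=X, y=y, ids=ids, column_roles=roles)


def _synthetic_smiles(rng: np.random.Generator, idx: int) -> str:
    """Opaque SMILES-like token; unique per idx, not real chemistry."""
    alphabet = "CNOSPFclnos123456()=#"
    tail = "".join(rng.choice(list(alphabet), size=12))
    return f"C{idx}{tail}"


def generate_activity_records(
    n: int,
    duplicate_fraction: float = 0.0,
    seed: int = 0,
    relation_probs: tuple[float, float, float] = (0.8, 0.1, 0.1),
    active_fraction: float = 0.28,
) -> list[ActivityRecord]:
    """Emit raw assay records with relation codes and optional duplicates.

    ``relation_probs`` gives the proportions of "=", "<", ">" records.
    Duplicates share the SMILES of a base record and carry a lognormally
    jittered Ki (relative SD ~12%, matching the low replicate variability
    of curated assay data).
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= duplicate_fraction < 1:
        raise ValueError("duplicate_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    records: list[ActivityRecord] = []
    relations = rng.choice(["=", "<", ">"], size=n, p=list(relation_probs))
    is_active = rng.random(n) < active_fraction
    for i in range(n):
        # actives around 100 nM, inactives around 10000 nM (log-uniform-ish)
        base = 100.0 if is_active[i] else 10_000.0
        ki = float(base * rng.lognormal(0.0, 1.0))
        records.append(
            ActivityRecord(
                compound_id=f"SYN{i:06d}",
                smiles=_synthetic_smiles(rng, i),
                relation=str(relations[i]),
                ki=ki,
            )
        )
    n_dup = int(round(duplicate_fraction * n))
    if n_dup > 0:
        dup_idx = rng.choice(n, size=n_dup, replace=False)
        for j, i in enumerate(dup_idx):
            base_rec = records[i]
            jitter = rng.lognormal(0.0, KI_JITTER_SIGMA)
            records.append(
                ActivityRecord(
                    compound_id=f"SYND{j:05d}",
                    smiles=base_rec.smiles,
                    relation=base_rec.relation,
                    ki=base_rec.ki * float(jitter),
                )
            )
    return records


def generate_docking_scores(
    labels: np.ndarray,
    mean_active: float = -8.02,
    mean_inactive: float = -7.29,
    sd: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Class-conditional docking energies (kcal/mol) for labeled compounds.

    Returns a docking table with columns ``id``, ``energy``, ``sd`` and
    ``label``. Defaults reproduce the calibration-set class means of the
    LeDock binding-energy distributions.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("label vector must be non-empty")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    means = np.where(labels == 1, mean_active, mean_inactive)
    energies = means + sd * rng.standard_normal(labels.size)
    # per-compound pose-cluster SD, folded normal around the draw SD
    cluster_sd = np.abs(rng.normal(0.7, 0.25, size=labels.size))
    return pd.DataFrame(
        {
            "id": [f"CPD{i:06d}" for i in range(labels.size)],
            "energy": energies,
            "sd": cluster_sd,
            "label": np.where(labels == 1, "active", "inactive"),
        }
    )


def write_activity_csv(records: list[ActivityRecord], path) -> None:
    """Write records in the assay-export CSV dialect the curation module reads."""
    pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "smiles": [r.smiles for r in records],
            "relation": [r.relation for r in records],
            "ki_nM": [r.ki for r in records],
        }
    ).to_csv(path, index=False)


def write_descriptor_csv(dataset: LabeledDataset, path) -> None:
    """Write the descriptor matrix with a label column, header row of names."""
    out = dataset.X.copy()
    out["activity"] = np.where(dataset.y == 1, "active", "inactive")
    out.to_csv(path)
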
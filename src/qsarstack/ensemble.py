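"""Majority-vote stacking of gated models over a screening library.

Each gated model casts a binary active/inactive vote per compound; the
vote fraction ranks the screening library. The 50% tier is a strict
majority (> 50% of votes), while the 75% and 90% tiers use >= so the
tiers nest. Votes can be restricted to the models in whose applicability
domain the compound falls, which changes the denominator per compound.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: published decision tiers (percent of models voting active)
TIERS = (50.0, 75.0, 90.0)


def _as_matrix(predictions) -> pd.DataFrame:
    df = pd.DataFrame(predictions)
    if df.shape[1] == 0:
        raise ValueError("empty model set: at least one model must vote")
    return df.astype(int)


def _selected(fraction: pd.Series, threshold: float) -> pd.Series:
    """Strict majority at the 50% tier, inclusive at higher tiers."""
    if not 0 < threshold <= 100:
        raise ValueError("threshold must be in (0, 100]")
    if threshold == 50.0:
        return fraction > threshold
    return fraction >= threshold


def vote_table(
    predictions, ad_mask=None
) -> pd.DataFrame:
    """Per-compound vote counts and fractions.

    ``predictions`` is a compounds x models binary matrix (DataFrame rows
    indexed by compound id). With ``ad_mask`` (same shape, True where the
    compound is inside that model's applicability domain) a model's vote
    counts only where the mask is True and the per-compound denominator
    becomes the number of in-domain models; compounds inside no model's
    domain get ``models_total = 0`` and a NaN fraction (reported, never
    tiered).
    """
    pred = _as_matrix(predictions)
    if ad_mask is None:
        mask = pd.DataFrame(
            np.ones(pred.shape, dtype=bool), index=pred.index, columns=pred.columns
        )
    else:
        mask = pd.DataFrame(ad_mask).astype(bool)
        if mask.shape != pred.shape:
            raise ValueError("ad_mask shape must match predictions")
        mask.index, mask.columns = pred.index, pred.columns
    votes = (pred.where(mask, 0)).sum(axis=1)
    totals = mask.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fraction = 100.0 * votes / totals.replace(0, np.nan)
    return pd.DataFrame(
        {
            "votes_active": votes,
            "models_total": totals,
            "vote_fraction": fraction,
        }
    )


def vote(predictions, threshold: float) -> pd.DataFrame:
    """Compounds selected at a vote-fraction tier (unmasked votes)."""
    table = vote_table(predictions)
    return table[_selected(table.vote_fraction, threshold)]


def vote_with_ad(predictions, ad_mask, threshold: float) -> pd.DataFrame:
    """Tier selection with votes limited to in-applicability-domain models."""
    table = vote_table(predictions, ad_mask=ad_mask)
    covered = table.models_total > 0
    return table[covered & _selected(table.vote_fraction.fillna(-1.0), threshold)]


def no_coverage(predictions, ad_mask) -> pd.DataFrame:
    """Compounds inside no model's applicability domain (reported separately)."""
    table = vote_table(predictions, ad_mask=ad_mask)
    return table[table.models_total == 0]


def tier_report(predictions, ad_mask=None) -> pd.DataFrame:
    """Ranked hit table with the highest tier each compound reaches."""
    table = vote_table(predictions, ad_mask=ad_mask)
    tier = pd.Series("none", index=table.index, dtype=object)
    for t in TIERS:  # ascending, later assignments overwrite
        sel = _selected(table.vote_fraction.fillna(-1.0), t)
        tier[sel] = f">={t:.0f}%"
    table["final_tier"] = tier
    return table.sort_values("vote_fraction", ascending=False)


def collapse_duplicates(table: pd.DataFrame, smiles: pd.Series) -> pd.DataFrame:
    """Collapse screening entries sharing a structure (canonical SMILES).

    Multiple library ids can denote the same substance; the entry with the
    best vote fraction represents the structure.
    """
    merged = table.join(smiles.rename("smiles"))
    best = merged.sort_values("vote_fraction", ascending=False)
    return best[~best.smiles.duplicated()].drop(columns="smiles")


def exclude_training_members(
    table: pd.DataFrame, training_smiles: set[str], smiles: pd.Series
) -> pd.DataFrame:
    """Drop screening hits already present in the training set."""
    merged = table.join(smiles.rename("smiles"))
    keep = ~merged.smiles.isin(training_smiles)
    return merged[keep].drop(columns="smiles")


def confirmation_rate(n_confirmed: int, n_total: int) -> float:
    """Percent of predicted hits confirmed by external assay evidence."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_confirmed <= n_total:
        raise ValueError("n_confirmed must be in [0, n_total]")
    return 100.0 * n_confirmed / n_total
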
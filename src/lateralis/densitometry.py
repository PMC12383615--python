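"""Projection-density lateralization and downstream output proportions.

The fluorescence density index normalizes every measurement in a region
by the mean density of that region's contralateral samples, so the mean
contralateral index is exactly 1 by construction and ipsilateral indices
read directly as fold-change versus the contralateral side. Downstream
output proportions are per-animal labeled-cell fractions averaged across
animals, keeping only regions present in at least half of the animals.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .stats import StatResult, two_group

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("region", "side", "density")


def density_index(
    records: pd.DataFrame, per_animal: bool = False
) -> pd.DataFrame:
    """Add a ``density_index`` column: density / mean contralateral density.

    Normalization groups are per region by default, pooling animals (the
    convention consistent with unpaired side comparisons at small n);
    ``per_animal=True`` instead normalizes within each (region, animal)
    pair, which requires both sides per animal.

    Raises
    ------
    ValueError
        If any group lacks contralateral samples or has a nonpositive
        contralateral mean.
    """
    for col in REQUIRED_COLUMNS:
        if col not in records.columns:
            raise ValueError(f"missing column {col!r}")
    group_cols = ["region", "animal_id"] if per_animal else ["region"]
    if per_animal and "animal_id" not in records.columns:
        raise ValueError("per_animal normalization needs an animal_id column")

    out = records.copy()
    out["density_index"] = np.nan
    for key, grp in out.groupby(group_cols, sort=False):
        contra = grp.loc[grp["side"] == "contra", "density"]
        if contra.empty:
            raise ValueError(f"group {key}: no contralateral samples")
        cmean = float(contra.mean())
        if cmean <= 0:
            raise ValueError(f"group {key}: contralateral mean {cmean} <= 0")
        out.loc[grp.index, "density_index"] = grp["density"] / cmean
    return out


def compare_sides(
    indexed: pd.DataFrame, region: str, paired: bool = False
) -> StatResult:
    """Wilcoxon comparison of density indices, ipsi vs contra, one region.

    Unpaired exact rank-sum by default; ``paired=True`` pairs per animal
    (signed-rank), requiring an ``animal_id`` column with both sides.
    """
    grp = indexed[indexed["region"] == region]
    if grp.empty:
        raise ValueError(f"no records for region {region!r}")
    if paired:
        wide = grp.pivot_table(
            index="animal_id", columns="side", values="density_index"
        ).dropna()
        return two_group(wide["ipsi"], wide["contra"], paired=True)
    ipsi = grp.loc[grp["side"] == "ipsi", "density_index"].to_numpy()
    contra = grp.loc[grp["side"] == "contra", "density_index"].to_numpy()
    return two_group(ipsi, contra, paired=False)


def output_proportions(
    counts: pd.DataFrame, min_presence_fraction: float = 0.5
) -> pd.DataFrame:
    """Per-region labeled-cell output fractions, mean +/- SEM over animals.

    ``counts`` has columns animal_id, region, count. Within each animal,
    fractions are count / total (summing to 1 before any filtering);
    animals with zero total are excluded with a log entry. Regions with a
    nonzero count in fewer than ``min_presence_fraction`` of the retained
    animals are dropped, mirroring the at-least-half-of-animals reporting
    rule. Absent (animal, region) pairs count as zero when averaging.
    """
    for col in ("animal_id", "region", "count"):
        if col not in counts.columns:
            raise ValueError(f"missing column {col!r}")
    wide = counts.pivot_table(
        index="animal_id", columns="region", values="count",
        aggfunc="sum", fill_value=0.0,
    )
    totals = wide.sum(axis=1)
    zero = totals == 0
    if zero.any():
        for animal in wide.index[zero]:
            logger.warning("animal %s has zero total count; excluded", animal)
        wide = wide[~zero]
        totals = totals[~zero]
    if wide.empty:
        raise ValueError("no animals with nonzero counts")

    fractions = wide.div(totals, axis=0)
    n_animals = len(fractions)
    presence = (wide > 0).sum(axis=0)
    keep = presence >= math.ceil(min_presence_fraction * n_animals)

    mean = fractions.mean(axis=0)
    sem = (
        fractions.std(axis=0, ddof=1) / np.sqrt(n_animals)
        if n_animals > 1
        else pd.Series(0.0, index=fractions.columns)
    )
    out = pd.DataFrame(
        {
            "mean_fraction": mean[keep],
            "sem": sem[keep],
            "n_animals_present": presence[keep],
        }
    )
    out.index.name = "region"
    return out.sort_values("mean_fraction", ascending=False).reset_index()


def read_density_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df


def read_counts_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("animal_id", "region", "count"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df
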
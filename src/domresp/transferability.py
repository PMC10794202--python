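"""Spatial transferability of molecule-specific environmental responses.

A molecule's MER is transferable when it agrees between independently
fitted sample groups.  Inter-regionally, MERs fitted per region are
compared pairwise (Pearson r and OLS slope over the shared molecules,
overall and per compound class).  Intra-regionally, the samples of one
region are split in half by nutrient level — all C(n, n/2) labeled
assignments of the levels to groups A and B (252 for 10 levels) — MERs
are fitted per group, and the distribution of agreement statistics over
splits summarizes within-region consistency.

All molecules with defined MERs enter the comparisons (the full -1..+1
range is needed), not only significant ones.  Molecule identity across
groups is the exact elemental composition via the shared molecule_id.
"""

from __future__ import annotations

import logging
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .formulas import SampleFrame
from .mer import DEFAULT_OCCUPANCY_FRACTION, MERTable, compute_mer_table

logger = logging.getLogger("domresp")


class TransferabilityError(ValueError):
    """Raised for invalid transferability computations."""


def enumerate_half_splits(levels) -> list[tuple[tuple, tuple]]:
    """All labeled half-splits of an even set of levels into groups A and B.

    Choosing which levels form group A (the complement is B) gives
    C(n, n/2) ordered assignments — 252 for the 10 nutrient levels.
    """
    levels = list(levels)
    n = len(levels)
    if n < 2 or n % 2:
        raise TransferabilityError("need an even number (>= 2) of distinct levels")
    if len(set(levels)) != n:
        raise TransferabilityError("levels must be distinct")
    half = n // 2
    splits = []
    for group_a in combinations(levels, half):
        group_b = tuple(l for l in levels if l not in group_a)
        splits.append((group_a, group_b))
    assert len(splits) == comb(n, half)
    return splits


def _agreement(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Pearson r, OLS slope of b on a, and one-sided F p for the fit."""
    n = len(a)
    fit = stats.linregress(a, b)
    # one-sided F test of the regression (identical to the slope F test
    # for simple OLS): F = t^2 on (1, n-2) df
    if np.isnan(fit.stderr) or fit.stderr == 0:
        p = 0.0 if abs(fit.rvalue) == 1.0 else float("nan")
    else:
        t = fit.slope / fit.stderr
        p = float(stats.f.sf(t**2, 1, n - 2))
    return float(fit.rvalue), float(fit.slope), p


def mer_agreement(
    mers_a: MERTable | pd.DataFrame,
    mers_b: MERTable | pd.DataFrame,
    classes: pd.Series | None = None,
    group_a_label: str = "A",
    group_b_label: str = "B",
    min_molecules: int = 3,
) -> pd.DataFrame:
    """Agreement records between two MER tables over their shared molecules.

    One ``all_molecules`` record plus one per compound class with at
    least ``min_molecules`` shared members.  ``classes`` maps
    molecule_id -> compound class.  Rows with undefined MERs in either
    table are excluded.
    """
    ta = (mers_a.table if isinstance(mers_a, MERTable) else mers_a)["rho"].dropna()
    tb = (mers_b.table if isinstance(mers_b, MERTable) else mers_b)["rho"].dropna()
    common = ta.index.intersection(tb.index)
    records = []
    base = {"group_a_label": group_a_label, "group_b_label": group_b_label}
    if len(common) < min_molecules:
        logger.info(
            "groups %s/%s share %d molecules (< %d); no agreement fitted",
            group_a_label,
            group_b_label,
            len(common),
            min_molecules,
        )
        return pd.DataFrame(
            [dict(base, scope="all_molecules", pearson_r=np.nan, ols_slope=np.nan,
                  ols_p=np.nan, n_molecules=len(common))]
        )
    scopes = [("all_molecules", common)]
    if classes is not None:
        cls_common = classes.loc[classes.index.intersection(common)]
        for cls in sorted(cls_common.unique()):
            scopes.append((cls, cls_common.index[cls_common == cls]))
    for scope, ids in scopes:
        if len(ids) < min_molecules:
            continue
        a, b = ta.loc[ids].values, tb.loc[ids].values
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            r, slope, p = np.nan, np.nan, np.nan
        else:
            r, slope, p = _agreement(a, b)
        records.append(
            dict(base, scope=scope, pearson_r=r, ols_slope=slope, ols_p=p,
                 n_molecules=len(ids))
        )
    return pd.DataFrame(records)


def intra_regional_transferability(
    frame: SampleFrame,
    covariate_name: str = "water_temp_C",
    levels_column: str = "nutrient_mgN_L",
    occupancy_fraction: float = DEFAULT_OCCUPANCY_FRACTION,
    max_splits: int | None = None,
    seed: int = 0,
    min_group_samples: int = 3,
) -> pd.DataFrame:
    """Agreement of independently fitted MERs over half-splits of the levels.

    For every labeled half-split of the distinct values in
    ``levels_column`` (a random subset of ``max_splits`` when the full
    enumeration is larger), MERs are fitted on each group's full sample
    set (occupancy per group) and the overall agreement recorded.
    Returns one row per usable split with ``pearson_r``, ``ols_slope``,
    ``ols_p``, ``n_molecules`` and the group-A levels.
    """
    levels = sorted(frame.samples[levels_column].unique())
    splits = enumerate_half_splits(levels)
    if max_splits is not None and max_splits < len(splits):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(splits), size=max_splits, replace=False)
        splits = [splits[i] for i in sorted(idx)]
    rows = []
    for group_a, group_b in splits:
        ids_a = frame.samples.index[frame.samples[levels_column].isin(group_a)]
        ids_b = frame.samples.index[frame.samples[levels_column].isin(group_b)]
        if len(ids_a) < min_group_samples or len(ids_b) < min_group_samples:
            logger.info("split %s skipped: a group has too few samples", group_a)
            continue
        mers_a = compute_mer_table(
            frame, covariate_name, occupancy_fraction=occupancy_fraction,
            sample_ids=ids_a,
        )
        mers_b = compute_mer_table(
            frame, covariate_name, occupancy_fraction=occupancy_fraction,
            sample_ids=ids_b,
        )
        rec = mer_agreement(mers_a, mers_b).iloc[0]
        rows.append(
            {
                "group_a_levels": ",".join(str(l) for l in group_a),
                "pearson_r": rec["pearson_r"],
                "ols_slope": rec["ols_slope"],
                "ols_p": rec["ols_p"],
                "n_molecules": rec["n_molecules"],
            }
        )
    if not rows:
        raise TransferabilityError("no usable half-split")
    return pd.DataFrame(rows)


def summarize_agreement(records: pd.DataFrame) -> dict:
    """Mean r and mean slope over splits (the violin-plot statistics)."""
    return {
        "mean_r": float(records["pearson_r"].mean()),
        "mean_slope": float(records["ols_slope"].mean()),
        "n_splits": int(records.shape[0]),
    }
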
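"""MER continuum: magnitude bins, removal scenarios and their summaries.

To profile how molecular traits and composition change towards stronger
thermal responses, molecules are separated into positive- and negative-
MER groups, sorted by |MER| and cut into equal-count bins (100 by
default, i.e. 1% of molecules per bin).  Scenario k then removes the
weakest k-1 bins and summarizes the retained molecules: removal
percentage, share of significant MERs, mean/median/lowest MER, mean
(+/- s.e.) molecular traits, and per-compound-class richness
percentages.  All molecules with a defined MER enter, not only
significant ones — the point is a continuum of effect sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mer import MERTable
from .traits import COMPOUND_CLASSES

logger = logging.getLogger("domresp")

DEFAULT_N_BINS = 100
# Traits summarized along the continuum (means +/- s.e. across molecules).
CONTINUUM_TRAITS = ("GFE", "AI_mod", "H_C", "O_C", "NOSC")


class ContinuumError(ValueError):
    """Raised for invalid continuum computations."""


def bin_by_magnitude(mers: MERTable | pd.DataFrame, n_bins: int = DEFAULT_N_BINS) -> dict:
    """Equal-count |MER| bins within each sign group.

    Returns ``{"positive": df, "negative": df}`` where each df has the
    sign group's molecules (rho > 0 / rho < 0) with columns ``rho``,
    ``significant`` and ``bin`` (1-based; bin 1 = lowest magnitude).
    Ties in |rho| break by molecule_id, so assignment is deterministic.
    When a group is smaller than ``n_bins`` the bin count drops to the
    group size with a warning; molecules with rho exactly 0 or NaN
    belong to neither group.
    """
    table = mers.table if isinstance(mers, MERTable) else mers
    if n_bins < 1:
        raise ContinuumError("need at least one bin")
    out = {}
    for sign, mask in (("positive", table["rho"] > 0), ("negative", table["rho"] < 0)):
        group = table.loc[mask, ["rho", "significant"]].copy()
        if group.empty:
            out[sign] = group.assign(bin=pd.Series(dtype=int))
            continue
        group["abs_rho"] = group["rho"].abs()
        # sort by |rho|, ties broken by molecule_id (the index)
        group = group.sort_index().sort_values("abs_rho", kind="stable")
        b = min(n_bins, len(group))
        if b < n_bins:
            logger.warning(
                "%s group has %d molecules < %d bins; using %d bins",
                sign,
                len(group),
                n_bins,
                b,
            )
        group["bin"] = _equal_count_bins(len(group), b)
        out[sign] = group.drop(columns="abs_rho")
    return out


def _equal_count_bins(n: int, n_bins: int) -> np.ndarray:
    """1-based bin labels for n sorted items; remainders go to the lowest bins."""
    base = n // n_bins
    rem = n % n_bins
    sizes = np.full(n_bins, base)
    sizes[:rem] += 1
    return np.repeat(np.arange(1, n_bins + 1), sizes)


def removal_scenarios(
    bins: dict,
    traits: pd.DataFrame,
    trait_columns=CONTINUUM_TRAITS,
) -> pd.DataFrame:
    """Summaries for every sequential-removal scenario in both sign groups.

    Scenario k retains bins k..B.  ``traits`` is the per-molecule trait
    table (with ``compound_class``) indexed by molecule_id.  Output is a
    long DataFrame keyed by (sign_group, scenario_index) with the MER
    statistics, ``mean_<t>``/``se_<t>`` per trait and ``pct_class_<c>``
    per compound class (summing to 100 over retained molecules).
    """
    rows = []
    for sign, group in bins.items():
        if group.empty:
            continue
        n_total = len(group)
        b = int(group["bin"].max())
        missing = group.index.difference(traits.index)
        if len(missing):
            raise ContinuumError(f"traits missing for molecules {list(missing)[:5]}")
        for k in range(1, b + 1):
            retained = group[group["bin"] >= k]
            rho = retained["rho"]
            abs_rho = rho.abs()
            lowest = rho.loc[abs_rho.idxmin()]
            row = {
                "sign_group": sign,
                "scenario_index": k,
                "n_retained": len(retained),
                "lowest_mer_retained": float(lowest),
                "pct_molecules_removed": 100.0 * (n_total - len(retained)) / n_total,
                "pct_significant": 100.0
                * retained["significant"].fillna(False).mean(),
                "mean_mer": float(rho.mean()),
                "median_mer": float(rho.median()),
            }
            tr = traits.loc[retained.index]
            for t in trait_columns:
                vals = tr[t].values
                row[f"mean_{t}"] = float(np.mean(vals))
                row[f"se_{t}"] = (
                    float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
                    if len(vals) > 1
                    else 0.0
                )
            class_counts = tr["compound_class"].value_counts()
            for cls in COMPOUND_CLASSES:
                row[f"pct_class_{cls}"] = 100.0 * class_counts.get(cls, 0) / len(retained)
            rows.append(row)
    if not rows:
        raise ContinuumError("no molecules in either sign group")
    return pd.DataFrame(rows)


def significance_cutoff_scenario(summaries: pd.DataFrame, sign_group: str) -> int | None:
    """First scenario at which every retained MER in the group is significant.

    Returns None when the group never reaches 100% significance.
    """
    sub = summaries[summaries["sign_group"] == sign_group].sort_values("scenario_index")
    hit = sub[sub["pct_significant"] >= 100.0 - 1e-9]
    if hit.empty:
        logger.info("sign group %s never reaches 100%% significant MERs", sign_group)
        return None
    return int(hit["scenario_index"].iloc[0])
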
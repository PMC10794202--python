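"""Molecule-specific environmental responses (MER).

A MER is the Spearman rank correlation between one molecule's relative
abundance and an environmental covariate (water temperature by default)
across samples.  Positive and negative values identify warm-accumulating
and warm-depleting molecules; the magnitude is the effect size.

Low-occurrence molecules inflate type-I error, so a majority rule keeps
only molecules detected in more than a third of the samples used to fit
MERs.  Samples where a retained molecule is absent enter the correlation
with relative abundance 0 (a real observation of depletion); excluding
zeros is available as an option.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .formulas import SampleFrame

logger = logging.getLogger("domresp")

DEFAULT_ALPHA = 0.05
DEFAULT_OCCUPANCY_FRACTION = 1.0 / 3.0


class MERError(ValueError):
    """Raised for invalid MER computations."""


@dataclass
class MERTable:
    """Per-molecule effect sizes against one covariate.

    ``table`` has one row per retained molecule with columns
    ``rho, p_value, n_samples, significant`` indexed by molecule_id.
    Rows with undefined rho (constant abundance) carry NaN and
    ``significant = False``; downstream consumers skip them.
    """

    table: pd.DataFrame
    covariate_name: str = "water_temp_C"
    alpha: float = DEFAULT_ALPHA
    occupancy_threshold: int = 0

    def __post_init__(self) -> None:
        finite = self.table["rho"].dropna()
        if (finite.abs() > 1 + 1e-12).any():
            raise MERError("|rho| > 1 in MER table")

    @property
    def molecule_ids(self) -> pd.Index:
        return self.table.index

    def valid(self) -> pd.DataFrame:
        """Rows with a defined rho."""
        return self.table[self.table["rho"].notna()]

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"].fillna(False)]


def occupancy_threshold(n_samples: int, fraction: float = DEFAULT_OCCUPANCY_FRACTION) -> int:
    """Minimum detection count for the majority rule: ceil(n * fraction).

    Applied to the sample count of the partition used to fit MERs; with
    the default third, 80% partitions of 150 and 180 samples give the
    thresholds 40 and 48.
    """
    if n_samples < 1:
        raise MERError("need at least one sample")
    if not (0 < fraction <= 1):
        raise MERError("occupancy fraction must be in (0, 1]")
    return math.ceil(n_samples * fraction)


def _rank(values: np.ndarray, axis: int = -1) -> np.ndarray:
    return stats.rankdata(values, axis=axis, method="average")


def spearman_rho_matrix(abundance: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Spearman rho of each abundance row against the covariate.

    Pearson correlation of average-ranked vectors; rows with zero rank
    variance (constant abundance) give NaN.
    """
    abundance = np.atleast_2d(np.asarray(abundance, dtype=float))
    cov = np.asarray(covariate, dtype=float)
    if abundance.shape[1] != cov.shape[0]:
        raise MERError("abundance and covariate lengths differ")
    ra = _rank(abundance, axis=1)
    rc = _rank(cov)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rc = rc - rc.mean()
    denom = np.sqrt((ra**2).sum(axis=1) * (rc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = ra @ rc / denom
    rho[denom == 0] = np.nan
    return np.clip(rho, -1.0, 1.0, out=rho)


def spearman_p_values(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Spearman rho via the t approximation with n-2 df."""
    rho = np.asarray(rho, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    p[np.isnan(rho)] = np.nan
    return p


def _exact_permutation_p(abundance: np.ndarray, covariate: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided permutation p for tiny n (all n! covariate orders)."""
    n = len(covariate)
    ra = _rank(abundance) - (n + 1) / 2
    rc = _rank(covariate) - (n + 1) / 2
    denom = math.sqrt((ra**2).sum() * (rc**2).sum())
    if denom == 0:
        return float("nan")
    perms = np.array(list(permutations(range(n))))
    rho_perm = rc[perms] @ ra / denom
    return float(np.mean(np.abs(rho_perm) >= abs(rho_obs) - 1e-12))


def spearman_mer(
    abundance,
    covariate,
    molecule_id: str = "",
    alpha: float = DEFAULT_ALPHA,
    exact_small_n: bool = True,
    small_n_cutoff: int = 10,
) -> dict:
    """MER record for one molecule: rho, p, n and the significance flag.

    Ties get average ranks; p-values use the t approximation with n-2
    degrees of freedom, or an exact permutation test when n is below
    ``small_n_cutoff`` (all n! orderings).  A constant abundance or
    covariate leaves rho undefined (NaN) and the record flagged.
    """
    abundance = np.asarray(abundance, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if abundance.shape != covariate.shape or abundance.ndim != 1:
        raise MERError("abundance and covariate must be equal-length vectors")
    n = abundance.shape[0]
    if n < 3:
        raise MERError("need at least 3 samples for a rank correlation")
    rho = float(spearman_rho_matrix(abundance[None, :], covariate)[0])
    if np.ptp(covariate) == 0:
        rho = float("nan")
    if math.isnan(rho):
        p = float("nan")
    elif exact_small_n and n < small_n_cutoff:
        p = _exact_permutation_p(abundance, covariate, rho)
    else:
        p = float(spearman_p_values(np.array([rho]), n)[0])
    return {
        "molecule_id": molecule_id,
        "rho": rho,
        "p_value": p,
        "n_samples": n,
        "significant": bool(p <= alpha) if not math.isnan(rho) else False,
    }


def compute_mer_table(
    frame: SampleFrame,
    covariate_name: str = "water_temp_C",
    alpha: float = DEFAULT_ALPHA,
    occupancy_fraction: float = DEFAULT_OCCUPANCY_FRACTION,
    sample_ids=None,
    include_zeros: bool = True,
) -> MERTable:
    """Fit MERs for every molecule passing the occupancy filter.

    ``sample_ids`` restricts the fit to a partition (e.g. the 80% MER
    dataset of a resampling replicate); the occupancy threshold is then
    computed from that partition's size.  With ``include_zeros`` False,
    each molecule's correlation uses only the samples where it was
    detected (never fewer than 3).
    """
    if sample_ids is None:
        sample_ids = list(frame.sample_ids)
    else:
        sample_ids = list(sample_ids)
    n = len(sample_ids)
    if n < 3:
        raise MERError("need at least 3 samples to compute MERs")
    cov = frame.covariate(covariate_name).loc[sample_ids].values
    rel = frame.rel_abundance.loc[:, sample_ids].values
    inten = frame.intensity.loc[:, sample_ids].values

    threshold = occupancy_threshold(n, occupancy_fraction)
    occupancy = (inten > 0).sum(axis=1)
    keep = occupancy >= threshold
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "occupancy filter (>= %d of %d samples): retained %d, dropped %d molecules",
            threshold,
            n,
            int(keep.sum()),
            n_dropped,
        )
    ids = frame.molecule_ids[keep]
    rel = rel[keep]

    if include_zeros:
        rho = spearman_rho_matrix(rel, cov)
        if np.ptp(cov) == 0:
            rho[:] = np.nan
        p = spearman_p_values(rho, n)
        n_used = np.full(len(ids), n)
    else:
        rho = np.empty(len(ids))
        p = np.empty(len(ids))
        n_used = np.empty(len(ids), dtype=int)
        for i in range(len(ids)):
            mask = rel[i] > 0
            n_used[i] = int(mask.sum())
            if n_used[i] < 3 or np.ptp(cov[mask]) == 0 or np.ptp(rel[i, mask]) == 0:
                rho[i] = np.nan
                p[i] = np.nan
                continue
            rho[i] = spearman_rho_matrix(rel[i][None, mask], cov[mask])[0]
            p[i] = spearman_p_values(np.array([rho[i]]), n_used[i])[0]

    table = pd.DataFrame(
        {
            "rho": rho,
            "p_value": p,
            "n_samples": n_used,
            "significant": (p <= alpha) & ~np.isnan(rho),
        },
        index=pd.Index(ids, name="molecule_id"),
    )
    return MERTable(
        table, covariate_name=covariate_name, alpha=alpha, occupancy_threshold=threshold
    )
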
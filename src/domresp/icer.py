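"""Compositional-level environmental response indicator (iCER).

The iCER of one sample is the relative-abundance-weighted mean of the
per-molecule effect sizes (MERs) present in that sample:

    iCER = sum(MER_i * I_i) / sum(I_i)

Positive/negative iCER means the assemblage is dominated by warm-
accumulating/warm-depleting molecules; 0 means the two groups balance.

Because iCER is built from MERs, the two must come from statistically
independent data: each resampling replicate splits the samples 80:20
into a MER (training) and an iCER (evaluation) partition, fits MERs on
the training samples only (occupancy re-filtered from the training
size), scores iCER on the evaluation samples, and the per-sample iCER
is averaged over the replicates where the sample was held out.  999
replicates by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .formulas import SampleFrame
from .mer import (
    DEFAULT_ALPHA,
    DEFAULT_OCCUPANCY_FRACTION,
    MERTable,
    occupancy_threshold,
    spearman_p_values,
    spearman_rho_matrix,
)

logger = logging.getLogger("domresp")

DEFAULT_SPLIT_RATIO = 0.8
DEFAULT_N_REPS = 999


class ICERError(ValueError):
    """Raised for invalid iCER computations."""


@dataclass(frozen=True)
class SplitScheme:
    """One 80:20 partition into a MER (train) and an iCER (test) dataset."""

    replicate_index: int
    train_sample_ids: tuple
    test_sample_ids: tuple
    seed: int

    def __post_init__(self) -> None:
        train, test = set(self.train_sample_ids), set(self.test_sample_ids)
        if train & test:
            raise ICERError("train and test partitions overlap")


@dataclass
class ICERTable:
    """Replicate-averaged iCER per sample, for one or both MER variants.

    ``table`` columns: sample_id, icer, n_replicates, n_molecules, variant
    (``significant_only`` or ``all_mers``).
    """

    table: pd.DataFrame
    covariate_name: str = "water_temp_C"
    alpha: float = DEFAULT_ALPHA
    n_reps: int = 0

    def variant(self, name: str = "significant_only") -> pd.DataFrame:
        out = self.table[self.table["variant"] == name]
        if out.empty:
            raise ICERError(f"no iCER variant {name!r} in table")
        return out.set_index("sample_id")


def make_splits(
    sample_ids,
    ratio: float = DEFAULT_SPLIT_RATIO,
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
) -> list[SplitScheme]:
    """Uniform random 80:20 partitions of the samples, one per replicate.

    Each replicate's RNG is derived from (seed, replicate index), so a
    partial rerun reproduces the same split sequence.  |train| is
    round(ratio * n).
    """
    ids = np.asarray(list(sample_ids))
    n = len(ids)
    if n < 5:
        raise ICERError("need at least 5 samples to split")
    if not (0 < ratio < 1):
        raise ICERError("split ratio must be in (0, 1)")
    n_train = int(round(ratio * n))
    n_train = min(max(n_train, 1), n - 1)
    splits = []
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        perm = rng.permutation(n)
        splits.append(
            SplitScheme(
                replicate_index=rep,
                train_sample_ids=tuple(ids[perm[:n_train]]),
                test_sample_ids=tuple(ids[perm[n_train:]]),
                seed=seed,
            )
        )
    return splits


def icer_of_sample(mers, rel_abundance, significant_only: bool = False) -> float:
    """Eq.-style weighted mean of MERs for one sample.

    ``mers`` maps molecule_id -> rho (a Series or a MERTable);
    ``rel_abundance`` maps molecule_id -> weight for the sample.  Only
    molecules carrying a defined MER and positive weight contribute.
    """
    if isinstance(mers, MERTable):
        table = mers.table
        rho = table["rho"]
        if significant_only:
            rho = rho[table["significant"].fillna(False)]
    else:
        rho = pd.Series(mers, dtype=float)
    rho = rho.dropna()
    w = pd.Series(rel_abundance, dtype=float)
    common = rho.index.intersection(w.index)
    w = w.loc[common]
    rho = rho.loc[common]
    mask = w > 0
    if not mask.any():
        raise ICERError("no MER-carrying molecule with positive abundance in sample")
    return float((rho[mask] * w[mask]).sum() / w[mask].sum())


def _icer_for_variant(
    rho: np.ndarray, valid: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """iCER for each column of ``weights`` using molecules in ``valid``.

    Returns (icer per sample, number of contributing molecules per sample);
    samples with an empty intersection give NaN.
    """
    w = weights[valid]
    m = rho[valid]
    denom = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        icer = (m @ w) / denom
    icer[denom == 0] = np.nan
    n_mol = (w > 0).sum(axis=0)
    return icer, n_mol


def icer_pipeline(
    frame: SampleFrame,
    covariate_name: str = "water_temp_C",
    alpha: float = DEFAULT_ALPHA,
    splits: list[SplitScheme] | None = None,
    n_reps: int = DEFAULT_N_REPS,
    ratio: float = DEFAULT_SPLIT_RATIO,
    seed: int = 0,
    occupancy_fraction: float = DEFAULT_OCCUPANCY_FRACTION,
) -> ICERTable:
    """Full split-resampling iCER computation.

    Per replicate: fit MERs on the training partition (occupancy
    threshold from the training size), compute iCER for each held-out
    sample, in both the significant-only and the all-MERs variant.
    Per-sample iCER is the arithmetic mean over replicates where the
    sample was held out and had a nonempty molecule intersection.
    """
    if splits is None:
        splits = make_splits(frame.sample_ids, ratio=ratio, n_reps=n_reps, seed=seed)
    sample_ids = list(frame.sample_ids)
    pos = {s: i for i, s in enumerate(sample_ids)}
    cov_all = frame.covariate(covariate_name).values
    rel_all = frame.rel_abundance.values
    inten_pos = frame.intensity.values > 0
    n_samples = len(sample_ids)

    sums = {v: np.zeros(n_samples) for v in ("all_mers", "significant_only")}
    counts = {v: np.zeros(n_samples, dtype=int) for v in ("all_mers", "significant_only")}
    mol_sums = {v: np.zeros(n_samples) for v in ("all_mers", "significant_only")}

    for split in splits:
        tr = np.array([pos[s] for s in split.train_sample_ids])
        te = np.array([pos[s] for s in split.test_sample_ids])
        n_tr = len(tr)
        thresh = occupancy_threshold(n_tr, occupancy_fraction)
        keep = inten_pos[:, tr].sum(axis=1) >= thresh
        if not keep.any():
            logger.warning("replicate %d: no molecule passes occupancy", split.replicate_index)
            continue
        rho = np.full(rel_all.shape[0], np.nan)
        rho[keep] = spearman_rho_matrix(rel_all[np.ix_(keep, tr)], cov_all[tr])
        p = spearman_p_values(rho, n_tr)
        valid = ~np.isnan(rho)
        sig = valid & (p <= alpha)
        weights = rel_all[:, te]
        for variant, mask in (("all_mers", valid), ("significant_only", sig)):
            if not mask.any():
                continue
            icer, n_mol = _icer_for_variant(rho, mask, weights)
            good = ~np.isnan(icer)
            sums[variant][te[good]] += icer[good]
            counts[variant][te[good]] += 1
            mol_sums[variant][te[good]] += n_mol[good]

    rows = []
    for variant in ("significant_only", "all_mers"):
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_icer = sums[variant] / counts[variant]
            mean_mol = mol_sums[variant] / counts[variant]
        never = counts[variant] == 0
        if never.any():
            logger.warning(
                "%d samples never held out (or empty intersection) for variant %s",
                int(never.sum()),
                variant,
            )
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": sample_ids,
                    "icer": mean_icer,
                    "n_replicates": counts[variant],
                    "n_molecules": mean_mol,
                    "variant": variant,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    return ICERTable(table, covariate_name=covariate_name, alpha=alpha, n_reps=len(splits))


@dataclass
class SensitivityResult:
    """Warming sensitivity of iCER and its dependence on nutrients.

    ``per_level`` has one row per nutrient level (slope of iCER vs the
    covariate, its p-value, sample count); ``slope_of_slopes`` is the OLS
    slope of those slopes against nutrient concentration, and
    ``sensitivity_increase_pct`` expresses it as a percentage of the mean
    per-level slope, per mg N L^-1.
    """

    per_level: pd.DataFrame
    slope_of_slopes: float
    slope_of_slopes_p: float
    mean_slope: float
    sensitivity_increase_pct: float


def sensitivity_analysis(
    icer_table: ICERTable | pd.DataFrame,
    metadata: pd.DataFrame,
    covariate_name: str = "water_temp_C",
    nutrient_column: str = "nutrient_mgN_L",
    variant: str = "significant_only",
    min_samples: int = 3,
) -> SensitivityResult:
    """Per-nutrient-level iCER-vs-temperature slopes and their nutrient trend."""
    if isinstance(icer_table, ICERTable):
        icer = icer_table.variant(variant)["icer"]
    else:
        icer = icer_table.set_index("sample_id")["icer"]
    meta = metadata.loc[icer.index]
    records = []
    for level, group in meta.groupby(nutrient_column):
        y = icer.loc[group.index].dropna()
        x = pd.to_numeric(group.loc[y.index, covariate_name])
        if len(y) < min_samples or np.ptp(x.values) == 0:
            logger.info("nutrient level %s skipped (%d usable samples)", level, len(y))
            continue
        fit = stats.linregress(x.values, y.values)
        records.append(
            {
                "nutrient": float(level),
                "slope": fit.slope,
                "slope_p": fit.pvalue,
                "intercept": fit.intercept,
                "n_samples": len(y),
            }
        )
    per_level = pd.DataFrame(records)
    if per_level.shape[0] < 2:
        raise ICERError("need at least 2 nutrient levels with fitted slopes")
    trend = stats.linregress(per_level["nutrient"].values, per_level["slope"].values)
    mean_slope = float(per_level["slope"].mean())
    pct = 100.0 * trend.slope / mean_slope if mean_slope != 0 else float("nan")
    return SensitivityResult(
        per_level=per_level,
        slope_of_slopes=float(trend.slope),
        slope_of_slopes_p=float(trend.pvalue),
        mean_slope=mean_slope,
        sensitivity_increase_pct=float(pct),
    )
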
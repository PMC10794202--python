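"""Synthetic DOM datasets with planted thermal-response structure.

Emulates the two experimental designs the analyses were built for:

* field — microcosms at 16 elevations spread over three mountain
  regions (subtropical wet, temperate arid, subarctic), 10 nutrient
  levels x 3 replicates each, 480 samples; water temperature declines
  with elevation within each region's measured range.
* lab — 3 climate-zone inocula x 7 incubation temperatures (5-35 C)
  x 4 replicates, 84 sealed microcosms with headspace gas sampling on
  days 5, 12, 19, 26 and 33.

Each molecule gets a valid CHNOPS composition, a true response class
(warm-accumulating / warm-depleting / null) and a target Spearman
effect size; its latent intensity is a lognormal baseline times a
monotone exponential function of standardized water temperature, with
multiplicative lognormal noise and random dropout, then closed to
relative abundances per sample.  Warm-accumulating molecules are drawn
preferentially from high-GFE compositions by default (the
field-experiment regime); the linkage direction is a dial.

The generator captures monotone abundance-temperature structure and
compositional closure.  It does not emulate instrument mass accuracy,
ionization-efficiency differences, correlated molecule families or
peak-intensity heteroscedasticity beyond the lognormal model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt

import numpy as np
import pandas as pd

from .decomposition import MOLAR_MASS_C, MOLAR_VOLUME_STP, GasSeries
from .formulas import ElementComposition, SampleFrame, frame_from_arrays, validate_assignment
from .traits import gfe, nosc

# Field design: (region, elevations m a.s.l., water-temperature range C).
FIELD_REGIONS = (
    ("Laojun", (3822, 3505, 2915, 2580, 2286), (11.4, 21.1)),
    ("Dangjin", (3905, 3477, 3050, 2670, 2214, 1750), (10.4, 23.0)),
    ("Balggesvarri", (750, 550, 350, 170, 20), (19.6, 25.2)),
)

NUTRIENT_LEVELS = (0.0, 0.45, 1.80, 4.05, 7.65, 11.25, 15.75, 21.60, 28.80, 36.00)

LAB_ZONES = ("subtropical", "transitional", "temperate")
LAB_TEMPERATURES = (5, 10, 15, 20, 25, 30, 35)
GAS_SAMPLING_DAYS = (5, 12, 19, 26, 33)


class SynthError(ValueError):
    """Raised for infeasible synthetic scenarios."""


@dataclass
class SynthScenario:
    """Parameters of one synthetic dataset.

    ``fraction_warm_accumulating``/``fraction_warm_depleting`` set the
    response-class mix (the remainder is null); the default is the
    warm-accumulating-dominant regime.  ``effect_size_range`` is the
    target |Spearman rho| interval for responsive molecules.
    ``noise_sigma`` is the lognormal sigma (natural log) of the
    multiplicative intensity noise; ``dropout`` the per-cell probability
    of a missing peak.  ``gfe_linkage`` > 0 biases warm-accumulating
    molecules toward higher GFE (field direction), < 0 toward lower
    (lab direction).
    """

    design: str = "field"  # field | lab | custom
    replicates: int | None = None  # defaults: 3 (field/custom), 4 (lab)
    nutrient_levels: tuple = NUTRIENT_LEVELS
    n_molecules: int = 300
    fraction_warm_accumulating: float = 0.75
    fraction_warm_depleting: float = 0.15
    effect_size_range: tuple = (0.3, 0.9)
    noise_sigma: float = 0.4
    dropout: float = 0.05
    gfe_linkage: float = 1.0
    nutrient_amplification: float = 0.0  # relative effect gain per mg N L^-1
    seed: int = 0
    # custom-design sample grid: list of (region, elevation, water_temp)
    custom_sites: tuple = ()

    def __post_init__(self) -> None:
        if not (0 <= self.fraction_warm_accumulating <= 1
                and 0 <= self.fraction_warm_depleting <= 1
                and self.fraction_warm_accumulating + self.fraction_warm_depleting <= 1):
            raise SynthError("response-class fractions must lie in [0, 1] and sum <= 1")
        lo, hi = self.effect_size_range
        if not (0 < lo <= hi < 1):
            raise SynthError("effect sizes must lie in (0, 1)")


def _sites(scenario: SynthScenario) -> pd.DataFrame:
    """The sample grid: one row per microcosm with region/elevation/temp/nutrient."""
    rows = []
    reps = scenario.replicates
    if scenario.design == "field":
        reps = 3 if reps is None else reps
        for region, elevations, (t_lo, t_hi) in FIELD_REGIONS:
            elev_sorted = sorted(elevations)
            # water temperature declines with elevation within the region's range
            for elev, temp in zip(elev_sorted, np.linspace(t_hi, t_lo, len(elevations))):
                for nutrient in scenario.nutrient_levels:
                    for rep in range(1, reps + 1):
                        rows.append((region, elev, temp, nutrient, rep))
    elif scenario.design == "lab":
        reps = 4 if reps is None else reps
        for zone in LAB_ZONES:
            for temp in LAB_TEMPERATURES:
                for rep in range(1, reps + 1):
                    rows.append((zone, 0.0, float(temp), 0.0, rep))
    elif scenario.design == "custom":
        reps = 3 if reps is None else reps
        if not scenario.custom_sites:
            raise SynthError("custom design requires custom_sites")
        for region, elev, temp in scenario.custom_sites:
            for nutrient in scenario.nutrient_levels:
                for rep in range(1, reps + 1):
                    rows.append((region, elev, temp, nutrient, rep))
    else:
        raise SynthError(f"unknown design {scenario.design!r}")
    df = pd.DataFrame(
        rows, columns=["region", "elevation_m", "water_temp_C", "nutrient_mgN_L", "replicate"]
    )
    width = len(str(len(df)))
    df.index = pd.Index([f"S{i + 1:0{width}d}" for i in range(len(df))], name="sample_id")
    return df


def _draw_compositions(n: int, rng: np.random.Generator) -> list[ElementComposition]:
    """Random valid CHNOPS compositions (unique formulas)."""
    seen: set[str] = set()
    comps: list[ElementComposition] = []
    attempts = 0
    while len(comps) < n:
        attempts += 1
        if attempts > 200 * n:
            raise SynthError("could not draw enough valid compositions")
        c = int(rng.integers(5, 31))
        h = int(round(c * rng.uniform(0.4, 2.2)))
        o = int(round(c * rng.uniform(0.05, 1.0)))
        nn = int(rng.choice([0, 0, 0, 1, 1, 2]))
        s = int(rng.random() < 0.1)
        p = int(rng.random() < 0.05)
        comp = ElementComposition(C=c, H=max(h, 1), N=nn, O=max(o, 1), P=p, S=s)
        ok, _ = validate_assignment(comp)
        if not ok:
            continue
        key = comp.formula
        if key in seen:
            continue
        seen.add(key)
        comps.append(comp)
    return comps


def _assign_responses(
    comps: list[ElementComposition], scenario: SynthScenario, rng: np.random.Generator
) -> pd.DataFrame:
    """Response classes and target effect sizes, GFE-biased selection."""
    n = len(comps)
    gfe_values = np.array([gfe(nosc(c)) for c in comps])
    z = (gfe_values - gfe_values.mean()) / (gfe_values.std() or 1.0)
    n_acc = int(round(scenario.fraction_warm_accumulating * n))
    n_dep = int(round(scenario.fraction_warm_depleting * n))
    if n_acc + n_dep > n:
        n_dep = n - n_acc
    order = np.arange(n)
    # weighted sampling without replacement: Gumbel-max trick on log-weights
    logw = scenario.gfe_linkage * z
    keys = logw + rng.gumbel(size=n)
    acc_idx = order[np.argsort(-keys)][:n_acc]
    remaining = np.setdiff1d(order, acc_idx)
    keys_dep = -scenario.gfe_linkage * z[remaining] + rng.gumbel(size=len(remaining))
    dep_idx = remaining[np.argsort(-keys_dep)][:n_dep]
    response = np.full(n, "null", dtype=object)
    response[acc_idx] = "accumulating"
    response[dep_idx] = "depleting"
    lo, hi = scenario.effect_size_range
    magnitude = rng.uniform(lo, hi, size=n)
    target = np.where(response == "accumulating", magnitude,
                      np.where(response == "depleting", -magnitude, 0.0))
    return pd.DataFrame({"response": response, "target_rho": target, "gfe": gfe_values})


def generate(scenario: SynthScenario) -> tuple[SampleFrame, pd.DataFrame]:
    """Generate a SampleFrame and its ground-truth table.

    The latent log-intensity of molecule j in sample s is

        log I_js = b_j + beta_j * t_s + eps,  eps ~ N(0, noise_sigma^2)

    with t the standardized water temperature and beta_j chosen so the
    latent abundance-temperature correlation matches the target effect
    size: beta = rho / sqrt(1 - rho^2) * noise_sigma (t has unit
    variance across samples).  Intensities are closed to sum 1 per
    sample after dropout.
    """
    rng = np.random.default_rng(scenario.seed)
    samples = _sites(scenario)
    comps = _draw_compositions(scenario.n_molecules, rng)
    truth = _assign_responses(comps, scenario, rng)

    temp = samples["water_temp_C"].values
    t_std = (temp - temp.mean()) / (temp.std() or 1.0)
    rho = truth["target_rho"].values
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = rho / np.sqrt(1.0 - rho**2) * scenario.noise_sigma
    if scenario.nutrient_amplification:
        nutrient = samples["nutrient_mgN_L"].values
        gain = 1.0 + scenario.nutrient_amplification * nutrient
        signal = beta[:, None] * (t_std[None, :] * gain[None, :])
    else:
        signal = beta[:, None] * t_std[None, :]

    baseline = rng.normal(0.0, 1.0, size=scenario.n_molecules)
    # Closure adds a common drift -d log(sum)/dt to every molecule's share
    # trend; balance it by giving the group trending against the majority
    # enough baseline mass that the abundance-weighted drift is ~zero, so
    # planted signs survive the compositional normalization.
    pos, neg = beta > 0, beta < 0
    if pos.any() and neg.any():
        w = np.exp(baseline)
        drift_pos = float((w[pos] * beta[pos]).sum())
        drift_neg = float((w[neg] * beta[neg]).sum())
        if drift_pos > 0 and drift_neg < 0:
            baseline[neg] += np.log(-drift_pos / drift_neg)
    noise = rng.normal(0.0, scenario.noise_sigma, size=(scenario.n_molecules, len(samples)))
    log_intensity = baseline[:, None] + signal + noise
    intensity = np.exp(log_intensity)
    if scenario.dropout > 0:
        drop = rng.random(intensity.shape) < scenario.dropout
        intensity[drop] = 0.0
        # keep every sample nonempty
        empty_cols = ~(intensity > 0).any(axis=0)
        intensity[0, empty_cols] = np.exp(baseline[0])

    frame = frame_from_arrays(comps, intensity, samples)
    truth = truth.copy()
    truth.index = frame.molecule_ids
    truth.insert(0, "formula", frame.molecules["formula"].values)
    truth["beta"] = beta
    return frame, truth


def generate_gas(
    scenario: SynthScenario,
    coupling: float = 0.08,
    base_rate: float = 1.0,
    gas: str = "CO2",
    noise_sigma: float = 0.005,
    headspace_volume: float = 0.006,
    sediment_dry_mass: float = 5.0,
    seed: int | None = None,
) -> tuple[list[GasSeries], pd.DataFrame]:
    """Headspace gas series for a lab-style scenario with a planted rate.

    The true release rate of a microcosm at temperature T is
    ``base_rate + coupling * (T - 5)`` (ug C g^-1 d^-1, floored at 0),
    inverted through the rate equation to per-interval ppm and jittered
    with multiplicative lognormal noise (default sigma 0.005, the order
    of gas-chromatography replicate precision; the slope fit amplifies
    concentration error about threefold because only the first sampling
    interval differs in length).  Defaults keep CO2 rates inside the
    observed 0.7-4.2 band; use base_rate=0.02, coupling=0.004 for a
    CH4-like series.  Returns the series plus a truth table of planted
    rates.
    """
    if scenario.design != "lab":
        raise SynthError("gas series are generated for the lab design")
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    samples = _sites(scenario)
    days = np.array(GAS_SAMPLING_DAYS, dtype=float)
    intervals = np.diff(np.concatenate([[0.0], days]))
    conv = headspace_volume / MOLAR_VOLUME_STP * MOLAR_MASS_C / sediment_dry_mass
    series, truth_rows = [], []
    for sid, row in samples.iterrows():
        rate = max(0.0, base_rate + coupling * (row["water_temp_C"] - 5.0))
        dcdt = rate / conv  # ppm per day
        conc = dcdt * intervals * np.exp(rng.normal(0.0, noise_sigma, size=len(intervals)))
        series.append(
            GasSeries(
                sample_id=sid,
                gas=gas,
                times=days,
                concentrations=conc,
                headspace_volume=headspace_volume,
                sediment_dry_mass=sediment_dry_mass,
            )
        )
        truth_rows.append({"sample_id": sid, "gas": gas, "true_rate": rate,
                           "water_temp_C": row["water_temp_C"]})
    return series, pd.DataFrame(truth_rows)


def write_tables(frame: SampleFrame, truth: pd.DataFrame, out_dir) -> dict:
    """Write the three standard CSVs plus truth.csv; returns the paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "molecules": out / "molecules.csv",
        "intensity": out / "intensity.csv",
        "metadata": out / "metadata.csv",
        "truth": out / "truth.csv",
    }
    frame.molecules[["formula"]].to_csv(paths["molecules"])
    frame.intensity.to_csv(paths["intensity"])
    frame.samples.to_csv(paths["metadata"])
    truth.to_csv(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
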
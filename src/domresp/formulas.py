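"""Molecular formulas and tabular inputs for DOM datasets.

Parses and validates CHNOPS molecular formulas as assigned from
ultrahigh-resolution (FT-ICR) mass spectra, and assembles the three
standard input tables (molecule table, intensity matrix, sample
metadata) into a :class:`SampleFrame` with per-sample relative
abundances.

Formula assignment itself (from m/z peaks) is out of scope: this module
consumes already-assigned formulas and only re-checks the published
elemental-ratio plausibility criteria.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("domresp")

ELEMENTS = ("C", "H", "N", "O", "P", "S")

# Monoisotopic masses (Da), IUPAC/CODATA values.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or chemically invalid formula input."""


class LoadError(ValueError):
    """Raised when the input tables are inconsistent."""


@dataclass(frozen=True)
class ElementComposition:
    """Element counts of one neutral molecule.

    ``Z`` is the net charge; measured ions are singly charged negative
    but formula lists hold the neutral forms, so ``Z = 0`` by default.
    """

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    P: int = 0
    S: int = 0
    Z: int = 0

    def __post_init__(self) -> None:
        for el in ELEMENTS:
            if getattr(self, el) < 0:
                raise FormulaError(f"negative count for element {el}")

    def counts(self) -> dict[str, int]:
        return {el: getattr(self, el) for el in ELEMENTS}

    @property
    def formula(self) -> str:
        return serialize_formula(self)


def parse_formula(text: str) -> ElementComposition:
    """Parse a Hill-style element-count string over C, H, N, O, P, S.

    Implicit counts of one ("CH4") are handled; omitted elements are 0.

    >>> parse_formula("C6H12O6")
    ElementComposition(C=6, H=12, N=0, O=6, P=0, S=0, Z=0)
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {el: 0 for el in ELEMENTS}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaError(
                f"unparseable token {text[pos:match.start()]!r} in formula {text!r}"
            )
        if not match.group(0):
            continue
        symbol, digits = match.group(1), match.group(2)
        if symbol not in ELEMENTS:
            raise FormulaError(f"unknown element symbol {symbol!r} in formula {text!r}")
        if counts[symbol]:
            raise FormulaError(f"element {symbol} repeated in formula {text!r}")
        counts[symbol] = int(digits) if digits else 1
        pos = match.end()
    if pos != len(text):
        raise FormulaError(f"unparseable trailing text {text[pos:]!r} in formula {text!r}")
    return ElementComposition(**counts)


def serialize_formula(comp: ElementComposition) -> str:
    """Hill-order string (C, H, then alphabetical) omitting zero counts."""
    parts = []
    for el in ("C", "H", "N", "O", "P", "S"):
        n = getattr(comp, el)
        if n == 1:
            parts.append(el)
        elif n > 1:
            parts.append(f"{el}{n}")
    if not parts:
        raise FormulaError("cannot serialize an empty composition")
    return "".join(parts)


def validate_assignment(
    comp: ElementComposition, require_oxygen: bool = False
) -> tuple[bool, list[str]]:
    """Check the elemental-ratio plausibility criteria used in formula assignment.

    The criteria are 0.333 <= H/C <= 2.25, O/C <= 1, N/C < 0.5, S/C < 0.2,
    P/C < 0.1 and (S + P)/C < 0.2, with the boundaries exactly as printed
    (H/C bounds inclusive, the rest as stated).  Returns ``(passed, reasons)``
    where *reasons* lists every violated criterion.

    ``require_oxygen`` additionally flags O = 0 formulas (assignment allows
    C/H/O counts from one upward, so oxygen-free formulas are unusual but
    accepted by default).
    """
    if comp.C < 1:
        raise FormulaError("elemental ratios undefined for C = 0")
    c = comp.C
    reasons: list[str] = []
    hc = comp.H / c
    if not (0.333 <= hc <= 2.25):
        reasons.append(f"H/C = {hc:.4g} outside [0.333, 2.25]")
    if comp.O / c > 1:
        reasons.append(f"O/C = {comp.O / c:.4g} > 1")
    if comp.N / c >= 0.5:
        reasons.append(f"N/C = {comp.N / c:.4g} >= 0.5")
    if comp.S / c >= 0.2:
        reasons.append(f"S/C = {comp.S / c:.4g} >= 0.2")
    if comp.P / c >= 0.1:
        reasons.append(f"P/C = {comp.P / c:.4g} >= 0.1")
    if (comp.S + comp.P) / c >= 0.2:
        reasons.append(f"(S+P)/C = {(comp.S + comp.P) / c:.4g} >= 0.2")
    if require_oxygen and comp.O == 0:
        reasons.append("O = 0 (oxygen-free formula)")
    return (not reasons, reasons)


def monoisotopic_mass(comp: ElementComposition) -> float:
    """Neutral monoisotopic mass in Da from the embedded element masses."""
    total = sum(MONOISOTOPIC_MASS[el] * getattr(comp, el) for el in ELEMENTS)
    if total <= 0:
        raise FormulaError("empty composition has no mass")
    return total


@dataclass(frozen=True)
class MoleculeRecord:
    """One assigned molecular formula with its identity and mass."""

    molecule_id: str
    composition: ElementComposition
    measured_mz: float | None = None
    neutral_mass: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            object.__setattr__(self, "neutral_mass", monoisotopic_mass(self.composition))


@dataclass(frozen=True)
class SampleMetadata:
    """Experimental metadata for one microcosm sample."""

    sample_id: str
    region: str
    elevation: float
    water_temp: float
    nutrient: float
    replicate: int
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.water_temp):
            raise LoadError(f"non-finite water temperature for sample {self.sample_id}")
        if self.nutrient < 0:
            raise LoadError(f"negative nutrient level for sample {self.sample_id}")


# Canonical metadata column names in the delimited-text interface.
METADATA_COLUMNS = {
    "region": "region",
    "elevation": "elevation_m",
    "water_temp": "water_temp_C",
    "nutrient": "nutrient_mgN_L",
    "replicate": "replicate",
}


class SampleFrame:
    """Intensity matrix (molecules x samples) joined to sample metadata.

    ``rel_abundance`` holds, per sample, each molecule's signal intensity
    normalized to the sum of all assigned-peak intensities in that sample;
    a zero means the molecule was not detected there.  The normalization
    denominator is the whole-sample total and is never recomputed after
    subsetting molecules (downstream indicators normalize internally).
    """

    def __init__(
        self,
        molecules: pd.DataFrame,
        samples: pd.DataFrame,
        intensity: pd.DataFrame,
    ) -> None:
        if not molecules.index.is_unique:
            raise LoadError("duplicated molecule_id values")
        if not samples.index.is_unique:
            raise LoadError("duplicated sample_id values")
        if (intensity.values < 0).any():
            bad = intensity.index[(intensity.values < 0).any(axis=1)].tolist()
            raise LoadError(f"negative intensities for molecules {bad}")
        if list(intensity.index) != list(molecules.index):
            raise LoadError("intensity rows do not match the molecule table")
        if list(intensity.columns) != list(samples.index):
            raise LoadError("intensity columns do not match the metadata table")
        self.molecules = molecules
        self.samples = samples
        self.intensity = intensity.astype(float)
        totals = self.intensity.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = self.intensity.values / totals.values
        rel[:, totals.values == 0] = 0.0
        self.rel_abundance = pd.DataFrame(
            rel, index=self.intensity.index, columns=self.intensity.columns
        )

    @property
    def n_molecules(self) -> int:
        return self.molecules.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def molecule_ids(self) -> pd.Index:
        return self.molecules.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.samples.index

    def covariate(self, name: str) -> pd.Series:
        if name not in self.samples.columns:
            raise LoadError(
                f"covariate column {name!r} not in metadata "
                f"(available: {list(self.samples.columns)})"
            )
        values = pd.to_numeric(self.samples[name], errors="coerce")
        if values.isna().any():
            missing = list(self.samples.index[values.isna()])
            raise LoadError(f"covariate {name!r} missing/non-numeric for samples {missing}")
        return values

    def subset_samples(self, sample_ids: Sequence[str]) -> "SampleFrame":
        ids = list(sample_ids)
        return SampleFrame(
            self.molecules, self.samples.loc[ids], self.intensity.loc[:, ids]
        )

    def compositions(self) -> list[ElementComposition]:
        return [
            ElementComposition(
                C=int(r.C), H=int(r.H), N=int(r.N), O=int(r.O), P=int(r.P), S=int(r.S)
            )
            for r in self.molecules.itertuples()
        ]


def _read_table(path_or_df) -> pd.DataFrame:
    if isinstance(path_or_df, pd.DataFrame):
        return path_or_df.copy()
    path = Path(path_or_df)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    return pd.read_csv(path, sep=sep)


def _molecule_table_to_counts(table: pd.DataFrame) -> pd.DataFrame:
    if "molecule_id" not in table.columns:
        raise LoadError("molecule table must have a molecule_id column")
    out = pd.DataFrame({"molecule_id": table["molecule_id"].astype(str)})
    if "formula" in table.columns:
        comps = [parse_formula(f) for f in table["formula"]]
        for el in ELEMENTS:
            out[el] = [getattr(c, el) for c in comps]
    elif set(ELEMENTS) <= set(table.columns):
        for el in ELEMENTS:
            out[el] = table[el].astype(int).values
    else:
        raise LoadError("molecule table needs a 'formula' column or C,H,N,O,P,S columns")
    out["formula"] = [
        serialize_formula(ElementComposition(**{el: int(row[el]) for el in ELEMENTS}))
        for _, row in out.iterrows()
    ]
    if "mz" in table.columns:
        out["mz"] = pd.to_numeric(table["mz"], errors="coerce").values
    return out.set_index("molecule_id")


def load_sample_frame(
    molecule_table,
    intensity_table,
    metadata_table,
    require_oxygen: bool = False,
    drop_invalid: bool = True,
) -> SampleFrame:
    """Assemble the three input tables into a :class:`SampleFrame`.

    Tables may be file paths (CSV/TSV by extension) or DataFrames.
    Molecules failing :func:`validate_assignment` are dropped with a
    logged count (or kept when ``drop_invalid`` is False).
    """
    molecules = _molecule_table_to_counts(_read_table(molecule_table))
    if molecules.index.duplicated().any():
        dup = molecules.index[molecules.index.duplicated()].unique().tolist()
        raise LoadError(f"duplicated molecule_id values: {dup}")

    intensity = _read_table(intensity_table)
    first = intensity.columns[0]
    intensity[first] = intensity[first].astype(str)
    intensity = intensity.set_index(first)
    intensity.index.name = "molecule_id"
    if intensity.index.duplicated().any():
        dup = intensity.index[intensity.index.duplicated()].unique().tolist()
        raise LoadError(f"duplicated molecule_id rows in intensity table: {dup}")

    meta = _read_table(metadata_table)
    if "sample_id" not in meta.columns:
        raise LoadError("metadata table must have a sample_id column")
    meta["sample_id"] = meta["sample_id"].astype(str)
    meta = meta.set_index("sample_id")
    if meta.index.duplicated().any():
        dup = meta.index[meta.index.duplicated()].unique().tolist()
        raise LoadError(f"duplicated sample_id values: {dup}")

    missing_mol = intensity.index.difference(molecules.index)
    if len(missing_mol):
        raise LoadError(f"intensity rows without molecule records: {list(missing_mol)}")
    missing_samp = [c for c in intensity.columns if c not in meta.index]
    if missing_samp:
        raise LoadError(f"intensity columns without metadata: {missing_samp}")

    molecules = molecules.loc[intensity.index]
    meta = meta.loc[list(intensity.columns)]

    values = intensity.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        raise LoadError("non-numeric entries in the intensity table")
    if (values.values < 0).any():
        bad = values.index[(values.values < 0).any(axis=1)].tolist()
        raise LoadError(f"negative intensities for molecules {bad}")

    if drop_invalid:
        keep, n_dropped = [], 0
        for mol_id, row in molecules.iterrows():
            comp = ElementComposition(**{el: int(row[el]) for el in ELEMENTS})
            ok, _ = validate_assignment(comp, require_oxygen=require_oxygen)
            if ok:
                keep.append(mol_id)
            else:
                n_dropped += 1
        if n_dropped:
            logger.info(
                "dropped %d of %d molecules failing elemental-ratio criteria",
                n_dropped,
                molecules.shape[0],
            )
        molecules = molecules.loc[keep]
        values = values.loc[keep]

    return SampleFrame(molecules, meta, values)


def frame_from_arrays(
    compositions: Iterable[ElementComposition],
    intensity: np.ndarray,
    samples: pd.DataFrame,
    molecule_ids: Sequence[str] | None = None,
) -> SampleFrame:
    """Build a SampleFrame directly from in-memory arrays (no validation drop)."""
    comps = list(compositions)
    if molecule_ids is None:
        width = len(str(len(comps)))
        molecule_ids = [f"M{i + 1:0{width}d}" for i in range(len(comps))]
    molecules = pd.DataFrame(
        {el: [getattr(c, el) for c in comps] for el in ELEMENTS},
        index=pd.Index(molecule_ids, name="molecule_id"),
    )
    molecules["formula"] = [serialize_formula(c) for c in comps]
    intensity_df = pd.DataFrame(
        np.asarray(intensity, dtype=float), index=molecules.index, columns=samples.index
    )
    return SampleFrame(molecules, samples, intensity_df)
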
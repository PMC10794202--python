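"""Molecular traits, thermodynamics and van Krevelen compound classes.

Fifteen per-molecule traits are computed from the elemental composition:
mass, carbon number, modified aromaticity index (AI_mod), double bond
equivalents (DBE) and the derived DBE−O, (DBE−O)/C and DBE−AI, the
standard Gibbs free energy of the carbon-oxidation half reaction (GFE),
the CH2-based Kendrick mass defect, the nominal oxidation state of
carbon (NOSC), and the five element/carbon ratios.

NOSC summarizes how oxidized the average carbon atom is (−4 for methane,
+4 for CO2); GFE is an affine function of NOSC, so higher NOSC means a
thermodynamically more favorable molecule for oxidative degradation.

Compound classes follow the van Krevelen (H/C vs O/C) scheme refined by
AI_mod, with aromaticity rules taking precedence so the published,
partially overlapping conditions form a deterministic partition.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .formulas import ElementComposition, FormulaError, monoisotopic_mass

# Kendrick CH2 base: exact mass of a CH2 unit.
CH2_EXACT_MASS = 14.01565

GFE_INTERCEPT = 60.3  # kJ (mol C)^-1 at NOSC = 0
GFE_SLOPE = -28.5  # kJ (mol C)^-1 per NOSC unit

COMPOUND_CLASSES = (
    "LowO_unsaturated",
    "HighO_unsaturated",
    "Aliphatics",
    "Peptides",
    "FattyAcids_Carbohydrates",
    "Aromatics",
    "CondensedAromatics",
)

TRAIT_COLUMNS = (
    "mass",
    "n_C",
    "AI_mod",
    "DBE",
    "DBE_O",
    "DBE_O_per_C",
    "DBE_AI",
    "GFE",
    "kdefect_CH2",
    "NOSC",
    "H_C",
    "O_C",
    "N_C",
    "P_C",
    "S_C",
)


def nosc(comp: ElementComposition) -> float:
    """Nominal oxidation state of carbon.

    NOSC = -((-Z + 4C + H - 3N - 2O + 5P - 2S)/C) + 4, bounded in [-4, +4]
    for neutral CHNOPS molecules.
    """
    if comp.C < 1:
        raise FormulaError("NOSC undefined for C = 0")
    num = -comp.Z + 4 * comp.C + comp.H - 3 * comp.N - 2 * comp.O + 5 * comp.P - 2 * comp.S
    return -(num / comp.C) + 4


def gfe(nosc_value: float) -> float:
    """Standard Gibbs free energy of the carbon-oxidation half reaction.

    GFE = 60.3 - 28.5 * NOSC, in kJ (mol C)^-1.  Positive values mean the
    oxidation must be coupled to reduction of a terminal electron acceptor;
    larger values mean a less thermodynamically favorable molecule.
    """
    return GFE_INTERCEPT + GFE_SLOPE * nosc_value


def _aromaticity_index(comp: ElementComposition, modified: bool = True) -> float:
    """Aromaticity index; the modified form halves the O contribution.

    Clamped to 0 when negative or when the denominator (C bound in the
    carbon skeleton) is non-positive — the field convention.
    """
    o_weight = 0.5 if modified else 1.0
    num = 1 + comp.C - o_weight * comp.O - comp.S - 0.5 * comp.H
    den = comp.C - o_weight * comp.O - comp.S - comp.N - comp.P
    if den <= 0:
        return 0.0
    return max(0.0, num / den)


def structural_traits(
    comp: ElementComposition,
    mass: float | None = None,
    dbe_ai_modified: bool = True,
) -> dict[str, float]:
    """All fifteen traits for one molecule, keyed by TRAIT_COLUMNS.

    ``mass`` defaults to the computed neutral monoisotopic mass; a
    measured m/z-derived mass may be passed instead.  ``dbe_ai_modified``
    selects whether DBE−AI subtracts the modified (default) or the
    unmodified aromaticity index.
    """
    if comp.C < 1:
        raise FormulaError("traits undefined for C = 0")
    if mass is None:
        mass = monoisotopic_mass(comp)
    if mass <= 0:
        raise FormulaError("mass must be positive")
    c = comp.C
    dbe = 1 + (2 * c - comp.H + comp.N + comp.P) / 2
    ai_mod = _aromaticity_index(comp, modified=True)
    ai = _aromaticity_index(comp, modified=dbe_ai_modified)
    kendrick_mass = mass * 14 / CH2_EXACT_MASS
    nosc_value = nosc(comp)
    return {
        "mass": mass,
        "n_C": float(c),
        "AI_mod": ai_mod,
        "DBE": dbe,
        "DBE_O": dbe - comp.O,
        "DBE_O_per_C": (dbe - comp.O) / c,
        "DBE_AI": dbe - ai,
        "GFE": gfe(nosc_value),
        "kdefect_CH2": round(kendrick_mass) - kendrick_mass,
        "NOSC": nosc_value,
        "H_C": comp.H / c,
        "O_C": comp.O / c,
        "N_C": comp.N / c,
        "P_C": comp.P / c,
        "S_C": comp.S / c,
    }


def classify(traits: dict[str, float] | pd.Series, comp: ElementComposition) -> str:
    """Assign one of the seven compound classes.

    Precedence makes the published overlapping thresholds a partition:
    condensed aromatics (AI_mod >= 0.67), aromatics (0.5 <= AI_mod < 0.67),
    fatty acids & carbohydrates (H/C > 2.0 or O/C >= 0.9), peptides
    (1.5 <= H/C <= 2.0, O/C < 0.9, N > 0), aliphatics (same, N = 0),
    then high-O (0.5 <= O/C <= 0.9) vs low-O (O/C < 0.5) unsaturated.
    Comparisons are exact (benzene's AI_mod = 2/3 falls just below 0.67).
    """
    ai = traits["AI_mod"]
    hc = traits["H_C"]
    oc = traits["O_C"]
    if ai >= 0.67:
        return "CondensedAromatics"
    if ai >= 0.5:
        return "Aromatics"
    if hc > 2.0 or oc >= 0.9:
        return "FattyAcids_Carbohydrates"
    if 1.5 <= hc <= 2.0:
        return "Peptides" if comp.N > 0 else "Aliphatics"
    if oc >= 0.5:
        return "HighO_unsaturated"
    return "LowO_unsaturated"


def compute_trait_table(
    compositions: Sequence[ElementComposition],
    molecule_ids: Sequence[str] | None = None,
    masses: Sequence[float] | None = None,
    dbe_ai_modified: bool = True,
) -> pd.DataFrame:
    """Trait table (one row per molecule, 15 trait columns + compound_class)."""
    if molecule_ids is None:
        width = len(str(len(compositions)))
        molecule_ids = [f"M{i + 1:0{width}d}" for i in range(len(compositions))]
    if not len(compositions):
        return pd.DataFrame(
            columns=list(TRAIT_COLUMNS) + ["compound_class"],
            index=pd.Index([], name="molecule_id"),
        )
    rows = []
    for i, comp in enumerate(compositions):
        mass = None if masses is None else masses[i]
        tr = structural_traits(comp, mass=mass, dbe_ai_modified=dbe_ai_modified)
        tr["compound_class"] = classify(tr, comp)
        rows.append(tr)
    table = pd.DataFrame(rows, index=pd.Index(molecule_ids, name="molecule_id"))
    return table[list(TRAIT_COLUMNS) + ["compound_class"]]


def weighted_mean_trait(trait_values, weights) -> float:
    """Intensity-weighted compositional mean of a trait.

    Sum(trait_i * I_i) / Sum(I_i) with relative abundances I_i as weights;
    invariant to uniform rescaling of the weights.
    """
    values = np.asarray(trait_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if values.shape != w.shape:
        raise ValueError("trait values and weights must have the same length")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total == 0:
        raise ValueError("weights sum to zero")
    return float(values @ w / total)
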
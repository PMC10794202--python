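import numpy as np
import pandas as pd
import pytest

from domresp import SynthScenario, generate


@pytest.fixture(scope="session")
def field_data():
    """Default synthetic field design (480 samples) with ground truth."""
    return generate(SynthScenario(design="field", seed=11))


@pytest.fixture(scope="session")
def lab_scenario():
    return SynthScenario(design="lab", seed=11)


@pytest.fixture()
def tiny_tables():
    """Three hand-sized input tables consistent with each other."""
    molecules = pd.DataFrame(
        {"molecule_id": ["m1", "m2", "m3"], "formula": ["C6H12O6", "C16H10O2", "C10H16N2O4"]}
    )
    intensity = pd.DataFrame(
        {"molecule_id": ["m1", "m2", "m3"], "sA": [1.0, 1.0, 2.0], "sB": [0.0, 1.0, 3.0]}
    )
    metadata = pd.DataFrame(
        {
            "sample_id": ["sA", "sB"],
            "region": ["R", "R"],
            "elevation_m": [100, 200],
            "water_temp_C": [20.0, 15.0],
            "nutrient_mgN_L": [0.0, 0.45],
            "replicate": [1, 1],
        }
    )
    return molecules, intensity, metadata


def brute_force_spearman(x, y):
    """Independent Spearman oracle: average ranks + explicit Pearson formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def avg_rank(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sorted_v[j] == sorted_v[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2.0
            i = j
        return ranks

    rx, ry = avg_rank(x), avg_rank(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    return float(rx @ ry / denom) if denom else float("nan")
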
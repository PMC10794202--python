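import numpy as np
import pandas as pd
import pytest

from domresp import (
    bin_by_magnitude,
    compute_mer_table,
    compute_trait_table,
    removal_scenarios,
    significance_cutoff_scenario,
)
from domresp.continuum import ContinuumError, _equal_count_bins


def _mer_df(rhos, significant=None, ids=None):
    n = len(rhos)
    if ids is None:
        ids = [f"m{i}" for i in range(n)]
    if significant is None:
        significant = [True] * n
    return pd.DataFrame(
        {"rho": rhos, "p_value": 0.01, "n_samples": 30, "significant": significant},
        index=pd.Index(ids, name="molecule_id"),
    )


class TestBinning:
    def test_two_per_bin(self):
        rhos = np.linspace(0.01, 0.99, 200)
        bins = bin_by_magnitude(_mer_df(rhos), n_bins=100)
        pos = bins["positive"]
        assert (pos["bin"].value_counts() == 2).all()
        # bin 1 holds the two smallest rho
        assert set(pos[pos["bin"] == 1]["rho"]) == {rhos[0], rhos[1]}
        assert bins["negative"].empty

    def test_hand_sorted_oracle(self):
        rhos = [0.5, -0.2, 0.1, 0.9, -0.7, 0.3, -0.4, 0.65, 0.05, -0.05]
        bins = bin_by_magnitude(_mer_df(rhos), n_bins=5)
        pos = bins["positive"]
        # positive sorted by magnitude: 0.05, 0.1, 0.3, 0.5, 0.65, 0.9 -> 6 in 5 bins
        assert list(pos["rho"]) == [0.05, 0.1, 0.3, 0.5, 0.65, 0.9]
        assert list(pos["bin"]) == [1, 1, 2, 3, 4, 5]
        neg = bins["negative"]
        assert list(neg["rho"]) == [-0.05, -0.2, -0.4, -0.7]
        assert list(neg["bin"]) == [1, 2, 3, 4]

    def test_ties_broken_by_molecule_id_deterministically(self):
        rhos = [0.5, 0.5, 0.5, 0.5]
        a = bin_by_magnitude(_mer_df(rhos, ids=["d", "b", "a", "c"]), n_bins=2)
        b = bin_by_magnitude(_mer_df(rhos, ids=["d", "b", "a", "c"]), n_bins=2)
        assert list(a["positive"].index) == ["a", "b", "c", "d"]
        pd.testing.assert_frame_equal(a["positive"], b["positive"])

    def test_small_group_reduces_bin_count(self):
        bins = bin_by_magnitude(_mer_df([0.1, 0.2, 0.3]), n_bins=100)
        assert bins["positive"]["bin"].max() == 3

    def test_remainders_go_to_lowest_bins(self):
        labels = _equal_count_bins(7, 5)
        assert list(labels) == [1, 1, 2, 2, 3, 4, 5]


def _traits_for(ids, rng=None):
    rng = rng or np.random.default_rng(0)
    from domresp.formulas import ElementComposition

    comps = [
        ElementComposition(C=int(c), H=int(h), O=int(o))
        for c, h, o in zip(
            rng.integers(6, 20, len(ids)),
            rng.integers(8, 30, len(ids)),
            rng.integers(1, 8, len(ids)),
        )
    ]
    return compute_trait_table(comps, molecule_ids=list(ids))


class TestRemovalScenarios:
    @pytest.fixture()
    def fixture_10(self):
        rhos = [0.5, -0.2, 0.1, 0.9, -0.7, 0.3, -0.4, 0.65, 0.05, -0.05]
        sig = [True, False, False, True, True, True, True, True, False, False]
        mers = _mer_df(rhos, significant=sig)
        bins = bin_by_magnitude(mers, n_bins=5)
        traits = _traits_for(mers.index)
        return mers, bins, traits

    def test_first_scenario_removes_nothing(self, fixture_10):
        _, bins, traits = fixture_10
        out = removal_scenarios(bins, traits)
        first = out[(out["scenario_index"] == 1)]
        assert (first["pct_molecules_removed"] == 0).all()

    def test_last_scenario_keeps_top_bin_only(self, fixture_10):
        _, bins, traits = fixture_10
        out = removal_scenarios(bins, traits)
        pos = out[out["sign_group"] == "positive"]
        last = pos[pos["scenario_index"] == pos["scenario_index"].max()].iloc[0]
        assert last["n_retained"] == 1
        assert last["lowest_mer_retained"] == pytest.approx(0.9)

    def test_hand_computed_summaries(self, fixture_10):
        mers, bins, traits = fixture_10
        out = removal_scenarios(bins, traits)
        pos3 = out[(out["sign_group"] == "positive") & (out["scenario_index"] == 3)].iloc[0]
        # 6 positive molecules in 5 bins: bin 1 = {0.05, 0.1}, then one per
        # bin; scenario 3 retains bins 3..5
        retained = [0.5, 0.65, 0.9]
        assert pos3["n_retained"] == len(retained)
        assert pos3["mean_mer"] == pytest.approx(np.mean(retained))
        assert pos3["median_mer"] == pytest.approx(np.median(retained))
        assert pos3["lowest_mer_retained"] == pytest.approx(0.5)
        assert pos3["pct_molecules_removed"] == pytest.approx(100 * 3 / 6)
        assert pos3["pct_significant"] == pytest.approx(100.0)
        ids = mers[mers["rho"].isin(retained)].index
        assert pos3["mean_GFE"] == pytest.approx(traits.loc[ids, "GFE"].mean())
        se = traits.loc[ids, "GFE"].std(ddof=1) / np.sqrt(len(ids))
        assert pos3["se_GFE"] == pytest.approx(se)

    def test_class_percentages_sum_to_100(self, fixture_10):
        _, bins, traits = fixture_10
        out = removal_scenarios(bins, traits)
        pct_cols = [c for c in out.columns if c.startswith("pct_class_")]
        np.testing.assert_allclose(out[pct_cols].sum(axis=1).values, 100.0, atol=1e-6)

    def test_mean_abs_mer_monotone_and_counts_decrease_by_bin_size(self, field_data):
        frame, _ = field_data
        mers = compute_mer_table(frame)
        traits = compute_trait_table(
            frame.compositions(), molecule_ids=list(frame.molecule_ids)
        )
        bins = bin_by_magnitude(mers, n_bins=20)
        out = removal_scenarios(bins, traits)
        for sign in ("positive", "negative"):
            sub = out[out["sign_group"] == sign].sort_values("scenario_index")
            abs_means = sub["mean_mer"].abs().values
            assert (np.diff(abs_means) >= -1e-12).all()
            lowest = sub["lowest_mer_retained"].abs().values
            assert (np.diff(lowest) >= -1e-12).all()
            sizes = bins[sign]["bin"].value_counts().sort_index().values
            retained = sub["n_retained"].values
            assert (retained[:-1] - retained[1:] == sizes[:-1]).all()

    def test_bin_width_robustness(self, field_data):
        """1%-style and 2%-style binnings agree along the |MER| axis."""
        frame, _ = field_data
        mers = compute_mer_table(frame)
        traits = compute_trait_table(
            frame.compositions(), molecule_ids=list(frame.molecule_ids)
        )
        fine = removal_scenarios(bin_by_magnitude(mers, n_bins=40), traits)
        coarse = removal_scenarios(bin_by_magnitude(mers, n_bins=20), traits)
        for sign in ("positive", "negative"):
            f = fine[fine["sign_group"] == sign].sort_values("lowest_mer_retained")
            c = coarse[coarse["sign_group"] == sign].sort_values("lowest_mer_retained")
            interp = np.interp(
                c["lowest_mer_retained"], f["lowest_mer_retained"], f["mean_GFE"]
            )
            assert np.max(np.abs(interp - c["mean_GFE"].values)) < 2.0  # kJ (mol C)^-1


class TestSignificanceCutoff:
    def test_all_significant_gives_first_scenario(self):
        mers = _mer_df([0.1, 0.2, 0.3, 0.4], significant=[True] * 4)
        out = removal_scenarios(bin_by_magnitude(mers, n_bins=4), _traits_for(mers.index))
        assert significance_cutoff_scenario(out, "positive") == 1

    def test_none_significant_gives_missing(self):
        mers = _mer_df([0.1, 0.2], significant=[False, False])
        out = removal_scenarios(bin_by_magnitude(mers, n_bins=2), _traits_for(mers.index))
        assert significance_cutoff_scenario(out, "positive") is None

    def test_planted_threshold_matches_hand_determined_bin(self):
        rhos = [0.1, 0.2, 0.3, 0.45, 0.5, 0.6, 0.7, 0.8]
        sig = [r > 0.4 for r in rhos]
        mers = _mer_df(rhos, significant=sig)
        out = removal_scenarios(bin_by_magnitude(mers, n_bins=8), _traits_for(mers.index))
        # bins 1..8 hold one molecule each; significance starts at bin 4 (0.45)
        assert significance_cutoff_scenario(out, "positive") == 4

    def test_empty_groups_rejected(self):
        mers = _mer_df([], ids=[])
        with pytest.raises(ContinuumError):
            removal_scenarios(bin_by_magnitude(mers), _traits_for([]))
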
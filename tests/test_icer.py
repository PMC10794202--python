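import numpy as np
import pandas as pd
import pytest
from scipy import stats

from domresp import (
    SynthScenario,
    compute_mer_table,
    frame_from_arrays,
    generate,
    icer_of_sample,
    icer_pipeline,
    make_splits,
    sensitivity_analysis,
)
from domresp.formulas import ElementComposition
from domresp.icer import ICERError

from conftest import brute_force_spearman


class TestMakeSplits:
    def test_partition_sizes(self):
        splits = make_splits([f"s{i}" for i in range(10)], n_reps=5, seed=0)
        for s in splits:
            assert len(s.train_sample_ids) == 8
            assert len(s.test_sample_ids) == 2
            assert set(s.train_sample_ids) | set(s.test_sample_ids) == {
                f"s{i}" for i in range(10)
            }

    def test_deterministic_under_seed(self):
        ids = [f"s{i}" for i in range(20)]
        a = make_splits(ids, n_reps=10, seed=7)
        b = make_splits(ids, n_reps=10, seed=7)
        assert [s.train_sample_ids for s in a] == [s.train_sample_ids for s in b]
        c = make_splits(ids, n_reps=10, seed=8)
        assert [s.train_sample_ids for s in a] != [s.train_sample_ids for s in c]

    def test_prefix_stability_for_partial_reruns(self):
        ids = [f"s{i}" for i in range(20)]
        long = make_splits(ids, n_reps=10, seed=3)
        short = make_splits(ids, n_reps=4, seed=3)
        assert [s.test_sample_ids for s in long[:4]] == [s.test_sample_ids for s in short]

    def test_test_appearance_counts_near_binomial_expectation(self):
        ids = [f"s{i}" for i in range(150)]
        splits = make_splits(ids, n_reps=999, seed=1)
        counts = pd.Series(0, index=ids)
        for s in splits:
            counts.loc[list(s.test_sample_ids)] += 1
        assert counts.mean() == pytest.approx(999 * 0.2, abs=0.01)
        assert counts.between(150, 250).all()

    def test_bad_ratio_rejected(self):
        with pytest.raises(ICERError):
            make_splits(list("abcdef"), ratio=1.2)


class TestICEROfSample:
    def test_balanced_opposite_mers_give_zero(self):
        assert icer_of_sample({"a": 0.5, "b": -0.5}, {"a": 0.5, "b": 0.5}) == 0.0

    def test_constant_mers_any_weights(self):
        mers = {m: 0.5 for m in "abcd"}
        weights = {"a": 0.1, "b": 0.4, "c": 0.2, "d": 0.3}
        assert icer_of_sample(mers, weights) == pytest.approx(0.5)

    def test_hand_weighted_mean(self):
        assert icer_of_sample({"a": 0.8, "b": -0.4}, {"a": 0.75, "b": 0.25}) == pytest.approx(0.5)

    def test_scale_invariance(self):
        mers = {"a": 0.8, "b": -0.4, "c": 0.1}
        w = {"a": 0.2, "b": 0.5, "c": 0.3}
        doubled = {k: 2 * v for k, v in w.items()}
        assert icer_of_sample(mers, w) == pytest.approx(icer_of_sample(mers, doubled))

    def test_bounded_by_max_abs_mer_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(1, 20))
            mers = dict(zip(map(str, range(n)), rng.uniform(-1, 1, n)))
            weights = dict(zip(map(str, range(n)), rng.uniform(0, 1, n)))
            if sum(weights.values()) == 0:
                continue
            icer = icer_of_sample(mers, weights)
            assert abs(icer) <= max(abs(v) for v in mers.values()) + 1e-12

    def test_empty_intersection_errors(self):
        with pytest.raises(ICERError):
            icer_of_sample({"a": 0.5}, {"b": 1.0})


def _pipeline_frame(seed=0, n_mol=4, n_samp=10):
    rng = np.random.default_rng(seed)
    comps = [ElementComposition(C=6 + i, H=12, O=6) for i in range(n_mol)]
    temps = np.linspace(5, 25, n_samp)
    intensity = rng.uniform(0.5, 2.0, size=(n_mol, n_samp))
    samples = pd.DataFrame(
        {
            "region": "R",
            "elevation_m": 0.0,
            "water_temp_C": temps,
            "nutrient_mgN_L": 0.0,
            "replicate": 1,
        },
        index=pd.Index([f"s{i}" for i in range(n_samp)], name="sample_id"),
    )
    return frame_from_arrays(comps, intensity, samples)


class TestICERPipeline:
    def test_single_replicate_matches_hand_computation(self):
        """One split, recomputed step by step with independent pieces."""
        frame = _pipeline_frame()
        splits = make_splits(frame.sample_ids, n_reps=1, seed=5)
        result = icer_pipeline(frame, splits=splits)
        (split,) = splits
        cov = frame.samples["water_temp_C"]
        expected = {}
        for sid in split.test_sample_ids:
            mers_hand = {}
            for mol in frame.molecule_ids:
                abund = frame.rel_abundance.loc[mol, list(split.train_sample_ids)]
                mers_hand[mol] = brute_force_spearman(
                    abund.values, cov.loc[list(split.train_sample_ids)].values
                )
            w = frame.rel_abundance.loc[:, sid]
            expected[sid] = sum(mers_hand[m] * w[m] for m in mers_hand) / w.sum()
        got = result.variant("all_mers")["icer"]
        for sid, val in expected.items():
            assert got.loc[sid] == pytest.approx(val, abs=1e-12)

    def test_identical_abundances_give_equal_icer(self):
        n_mol, n_samp = 3, 12
        comps = [ElementComposition(C=6 + i, H=12, O=6) for i in range(n_mol)]
        intensity = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, n_samp))
        samples = pd.DataFrame(
            {
                "region": "R",
                "elevation_m": 0.0,
                "water_temp_C": np.linspace(5, 25, n_samp),
                "nutrient_mgN_L": 0.0,
                "replicate": 1,
            },
            index=pd.Index([f"s{i}" for i in range(n_samp)], name="sample_id"),
        )
        frame = frame_from_arrays(comps, intensity, samples)
        result = icer_pipeline(frame, n_reps=10, seed=0)
        icer = result.variant("all_mers")["icer"].dropna()
        # constant abundance => rho undefined for every molecule => no iCER
        # at all; with tiny per-sample jitter they would all be equal. Use
        # the all-NaN outcome as the degenerate-case contract.
        assert icer.empty

    def test_icer_tracks_temperature_on_planted_data(self, field_data):
        frame, _ = field_data
        result = icer_pipeline(frame, n_reps=40, seed=2)
        icer = result.variant("significant_only")["icer"].dropna()
        temp = frame.samples.loc[icer.index, "water_temp_C"]
        assert stats.spearmanr(icer, temp).statistic > 0.9

    def test_significant_only_and_all_mers_strongly_correlated(self, field_data):
        frame, _ = field_data
        result = icer_pipeline(frame, n_reps=30, seed=3)
        a = result.variant("significant_only")["icer"]
        b = result.variant("all_mers")["icer"]
        mask = a.notna() & b.notna()
        assert np.corrcoef(a[mask], b[mask])[0, 1] > 0.9

    def test_icer_bounded_by_max_abs_mer(self, field_data):
        frame, _ = field_data
        mers = compute_mer_table(frame)
        bound = mers.table["rho"].abs().max()
        result = icer_pipeline(frame, n_reps=10, seed=4)
        icer = result.table["icer"].dropna()
        assert (icer.abs() <= bound + 1e-9).all()

    def test_replicate_averaging_converges(self, field_data):
        """Across-replicate averaging stabilizes the per-sample iCER."""
        frame, _ = field_data
        few = icer_pipeline(frame, n_reps=8, seed=5).variant("all_mers")["icer"]
        many = icer_pipeline(frame, n_reps=64, seed=5).variant("all_mers")["icer"]
        ref = icer_pipeline(frame, n_reps=64, seed=99).variant("all_mers")["icer"]
        mask = few.notna() & many.notna() & ref.notna()
        err_few = (few[mask] - ref[mask]).std()
        err_many = (many[mask] - ref[mask]).std()
        assert err_many < err_few


class TestSensitivity:
    @staticmethod
    def _icer_table(slopes_by_nutrient, temps, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows, meta = [], []
        i = 0
        for nutrient, slope in slopes_by_nutrient.items():
            for t in temps:
                sid = f"s{i}"
                icer = slope * t + rng.normal(0, noise)
                rows.append({"sample_id": sid, "icer": icer, "variant": "significant_only"})
                meta.append({"sample_id": sid, "water_temp_C": t, "nutrient_mgN_L": nutrient})
                i += 1
        return (
            pd.DataFrame(rows),
            pd.DataFrame(meta).set_index("sample_id"),
        )

    def test_identical_slopes_give_zero_trend(self):
        temps = np.linspace(5, 25, 6)
        icer, meta = self._icer_table({0.0: 0.02, 10.0: 0.02, 20.0: 0.02}, temps)
        res = sensitivity_analysis(icer, meta)
        assert res.slope_of_slopes == pytest.approx(0.0, abs=1e-12)
        assert res.sensitivity_increase_pct == pytest.approx(0.0, abs=1e-9)

    def test_planted_nutrient_dependence_recovered(self):
        temps = np.linspace(5, 25, 8)
        slopes = {n: 0.02 + 0.001 * n for n in (0.0, 4.0, 8.0, 16.0, 32.0)}
        icer, meta = self._icer_table(slopes, temps, noise=0.01, seed=1)
        res = sensitivity_analysis(icer, meta)
        assert res.slope_of_slopes == pytest.approx(0.001, rel=0.10)

    def test_constant_icer_all_zero(self):
        temps = np.linspace(5, 25, 5)
        icer, meta = self._icer_table({0.0: 0.0, 10.0: 0.0}, temps)
        res = sensitivity_analysis(icer, meta)
        assert (res.per_level["slope"] == 0).all()
        assert res.slope_of_slopes == 0.0

    def test_single_level_errors(self):
        temps = np.linspace(5, 25, 5)
        icer, meta = self._icer_table({0.0: 0.02}, temps)
        with pytest.raises(ICERError):
            sensitivity_analysis(icer, meta)
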
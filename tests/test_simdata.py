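"""Simulator: template truth consistency, reproducibility, noise model."""

import numpy as np
import pandas as pd
import pytest

from homeobias import pairclass
from homeobias.errors import InvalidParameterError
from homeobias.simdata import (
    DEFAULT_TEMPLATE_MIX,
    SimConfig,
    default_templates,
    simulate_dataset,
    simulate_depth,
)


class TestTemplates:
    def test_requires_fold_change_above_one(self):
        with pytest.raises(InvalidParameterError):
            default_templates(1.0)

    def test_template_count_and_coverage(self):
        templates = default_templates(4.0)
        assert len(templates) >= 13
        categories = {t.truth.category for t in templates}
        # every category of the twelve-state framework is represented
        assert categories == {
            "NoChange", "I", "II", "III", "IV", "V", "VI",
            "VII", "VIII", "IX", "X", "XI", "XII",
        }
        mechanisms = {t.truth.mechanism for t in templates if t.truth.group in ("ELD_A", "ELD_C")}
        assert {"dominant_down", "nondominant_down", "both_down"} <= mechanisms
        # the nondominant-up mechanism appears jointly with dominant-down
        # (an exact pair total pinned to one parent cannot rise otherwise)
        assert "dominant_down_nondominant_up" in mechanisms

    def test_worked_examples(self):
        by_name = {t.name: t for t in default_templates(4.0)}
        assert by_name["no_change"].truth.category == "NoChange"
        t = by_name["eld_A_higher_domdown"]
        assert t.means == (4, 1, 3, 1)
        assert t.truth.category == "IV"
        assert (t.truth.change_A, t.truth.change_C) == ("down", "unchanged")
        t = by_name["additivity_I"]
        assert t.means == (1, 4, 1, 1.5)
        assert t.truth.category == "I"

    @pytest.mark.parametrize("fold_change", [1.5, 2.0, 4.0, 10.0])
    def test_truth_labels_equal_exact_classifier(self, fold_change):
        for t in default_templates(fold_change):
            lab = pairclass.truth_label(*t.means)
            assert lab == t.truth

    def test_label_symmetry_under_genome_swap(self):
        swap = {
            "IV": "II", "II": "IV", "IX": "XI", "XI": "IX", "I": "XII",
            "XII": "I", "V": "VIII", "VIII": "V", "III": "X", "X": "III",
            "VI": "VI", "VII": "VII", "NoChange": "NoChange",
        }
        for t in default_templates(4.0):
            mirrored = pairclass.truth_label(t.mu_Co, t.mu_Ar, t.mu_Cn, t.mu_An)
            assert mirrored.category == swap[t.truth.category]


class TestSimulateDataset:
    def test_fixed_seed_reproducibility(self):
        cfg = SimConfig(n_pairs=200, seed=42)
        a, b = simulate_dataset(cfg), simulate_dataset(cfg)
        pd.testing.assert_frame_equal(a.parent_a.data, b.parent_a.data)
        pd.testing.assert_frame_equal(a.polyploid.data, b.polyploid.data)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_zero_cv_replicates_equal_true_means(self):
        cfg = SimConfig(
            n_pairs=50, template_mix={"trans_up_VI": 1.0}, cv=0.0, seed=1
        )
        d = simulate_dataset(cfg)
        vals = d.parent_a.data.to_numpy()
        assert (vals == vals[:, [0]]).all()  # identical replicates
        base = d.truth["base_mean"].to_numpy()
        assert np.array_equal(vals[:, 0], base)  # template mean is 1 * base

    def test_replicate_cv_close_to_requested(self):
        cfg = SimConfig(
            n_pairs=4000, template_mix={"trans_up_VI": 1.0}, cv=0.3,
            n_replicates=10, seed=5,
        )
        d = simulate_dataset(cfg)
        vals = d.parent_a.data.to_numpy()
        cv = (vals.std(axis=1, ddof=1) / vals.mean(axis=1)).mean()
        assert cv == pytest.approx(0.3, rel=0.05)

    def test_truth_table_covers_every_pair(self):
        d = simulate_dataset(SimConfig(n_pairs=100, seed=9))
        assert set(d.truth["pair_id"]) == set(d.pair_map["pair_id"])
        assert set(d.truth["template"]) <= set(DEFAULT_TEMPLATE_MIX)

    def test_null_mix_flags_about_five_percent(self):
        # type-I error of the progeny bias test under the lognormal null
        fracs = []
        for seed in range(10):
            cfg = SimConfig(
                n_pairs=1000, template_mix={"no_change": 1.0}, seed=300 + seed
            )
            d = simulate_dataset(cfg)
            ds = pairclass.PairDataset.from_tables(
                d.pair_map, d.parent_a, d.parent_c, d.polyploid
            )
            bias = pairclass.classify_bias_table(ds)
            fracs.append((bias["progeny_state"] != "EQ").mean())
        n_total = 10 * 1000
        band = 3 * np.sqrt(0.05 * 0.95 / n_total)
        assert abs(np.mean(fracs) - 0.05) <= band

    def test_rejects_bad_configs(self):
        with pytest.raises(InvalidParameterError):
            SimConfig(n_pairs=10, template_mix={})
        with pytest.raises(InvalidParameterError):
            SimConfig(n_pairs=10, template_mix={"no_change": 0.5})
        with pytest.raises(InvalidParameterError):
            SimConfig(n_pairs=10, cv=-0.1)
        with pytest.raises(InvalidParameterError):
            SimConfig(n_pairs=10, n_replicates=1)
        with pytest.raises(InvalidParameterError):
            SimConfig(n_pairs=10, fold_change=0.9)


class TestSimulateDepth:
    def test_window_means_match_poisson_expectation(self):
        track = simulate_depth({"A01": 100_000}, 30.0, seed=2)
        means = track.groupby(track["pos"].sub(1) // 10_000)["depth"].mean()
        # Poisson SD of a 10-kb window mean is sqrt(30/10000)
        assert np.abs(means - 30).max() < 5 * np.sqrt(30 / 10_000)

    def test_zero_mean_depth_gives_all_zero_track(self):
        track = simulate_depth({"C01": 5000}, {"C01": 0.0}, seed=3)
        assert (track["depth"] == 0).all()
        assert len(track) == 5000

    def test_same_seed_identical_track(self):
        a = simulate_depth({"A01": 10_000}, 20.0, seed=7)
        b = simulate_depth({"A01": 10_000}, 20.0, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_rejects_negative_depth(self):
        with pytest.raises(InvalidParameterError):
            simulate_depth({"A01": 100}, -1.0)
        with pytest.raises(InvalidParameterError):
            simulate_depth({"A01": 0}, 10.0)
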
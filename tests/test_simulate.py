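"""Synthetic-data generator: proportion laws, mixtures, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cytostand import (
    SimulationConfig,
    apply_spillover,
    builtin_panel,
    draw_population_proportions,
    simulate_experiment,
    simulate_proportion_model,
    synthesize_events,
)
from cytostand.frames import FLUORO, SpilloverMatrix
from cytostand.simulate import logit, truth_masks


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"sigma_center": -0.1},
            {"doublet_frac": 1.0},
            {"dead_frac": -0.2},
            {"events_per_file": 0},
            {"panels": ("Th17",)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestProportionModel:
    def test_zero_variance_gives_exact_half(self, rng):
        df = simulate_proportion_model(0.0, 0.0, 0.0, 0.0, rng=rng)
        assert (df["p"] == 0.5).all()

    def test_sample_effects_shared_across_centers_and_replicates(self, rng):
        df = simulate_proportion_model(0.0, 1.0, 0.0, 0.0, rng=rng)
        # all files of one sample share an identical proportion
        assert (df.groupby("sample")["p"].nunique() == 1).all()
        assert df.groupby("sample")["p"].first().nunique() == 3

    def test_logit_mean_matches_normal_law(self):
        # Monte-Carlo check of the stated law: mean logit(p) -> mu
        rng = np.random.default_rng(7)
        mu, sd = float(logit(0.2)), 0.3
        draws = [
            simulate_proportion_model(mu, 0.0, 0.0, sd, 1, 1, 1, rng)["y"].iloc[0]
            for _ in range(10_000)
        ]
        assert abs(np.mean(draws) - mu) < 3 * sd / np.sqrt(10_000)

    def test_center_free_draws_indistinguishable_across_centers(self):
        # with sigma_center = 0, per-center mean logits pass a one-way
        # ANOVA F-test at alpha = 0.01 in >= 45 of 50 seeded runs
        passes = 0
        for seed in range(50):
            df = simulate_proportion_model(
                -1.0, 0.5, 0.0, 0.2, rng=np.random.default_rng(seed)
            )
            resid = df["y"] - df.groupby("sample")["y"].transform("mean")
            groups = [g.to_numpy() for _, g in resid.groupby(df["center"])]
            _, p = stats.f_oneway(*groups)
            passes += p > 0.01
        assert passes >= 45


class TestDrawPopulationProportions:
    def test_effects_constant_within_sample_and_center(self, rng):
        cfg = SimulationConfig(n_centers=3, n_samples=2, n_replicates=2)
        panel = builtin_panel("T-cell")
        gt = draw_population_proportions(cfg, panel, rng)
        assert gt.alpha.groupby(["sample", "cell_type"])["alpha"].nunique().eq(1).all()
        # replicates of one (center, sample) share effects but differ by residual
        lp = gt.leaf_proportions
        per_file = lp.pivot_table(
            index=["center", "sample", "replicate"], columns="cell_type", values="p_true"
        )
        assert per_file.shape[0] == 3 * 2 * 2

    def test_leaf_sum_leaves_other_remainder(self, rng):
        cfg = SimulationConfig(sigma_sample=1.0, sigma_center=1.0, sigma_residual=1.0)
        panel = builtin_panel("B-cell")
        gt = draw_population_proportions(cfg, panel, rng)
        sums = gt.leaf_proportions.groupby(["center", "sample", "replicate"])["p_true"].sum()
        assert (sums <= 0.99 + 1e-12).all()

    def test_truth_table_respects_denominators(self, rng):
        cfg = SimulationConfig(n_centers=2, n_samples=1, n_replicates=1)
        panel = builtin_panel("Treg")
        gt = draw_population_proportions(cfg, panel, rng)
        truth = gt.population_truth(panel)
        one = truth[(truth["center"] == 0)].set_index("population")["proportion"]
        leaves = gt.file_leaf_proportions(0, 0, 0)
        treg = sum(leaves[k] for k in ("treg_mem", "treg_naive", "treg_act"))
        # memory Treg is reported as % of total Treg, not of CD4
        expected = (leaves["treg_mem"] + leaves["treg_act"]) / treg
        assert one["Memory T-regulatory"] == pytest.approx(expected, rel=1e-12)


class TestSynthesizeEvents:
    def test_degenerate_mixture_hits_mean_exactly(self):
        cfg = SimulationConfig(
            marker_sd=0.0, doublet_frac=0.0, dead_frac=0.0, debris_frac=0.0
        )
        panel = builtin_panel("T-cell")
        props = {ct.name: 0.0 for ct in panel.cell_types}
        props["cd4_naive"] = 1.0
        frame, labels = synthesize_events(props, panel, 500, np.random.default_rng(0), cfg)
        assert (labels["cell_type"] == "cd4_naive").all()
        mean = panel.cell_types[0].mean_vector(panel.fluoro_markers)
        fl = frame.data[:, frame.roles(FLUORO)]
        expected = np.broadcast_to(np.sinh(mean) * cfg.cofactor, fl.shape)
        np.testing.assert_allclose(fl, expected, rtol=1e-12)

    def test_doublet_count_is_binomial(self):
        cfg = SimulationConfig(doublet_frac=0.1, debris_frac=0.0, dead_frac=0.0)
        panel = builtin_panel("T-cell")
        props = {ct.name: ct.baseline for ct in panel.cell_types}
        n, reps = 10_000, 5
        ks = []
        for seed in range(reps):
            _, labels = synthesize_events(props, panel, n, np.random.default_rng(seed), cfg)
            ks.append(int(labels["is_doublet"].sum()))
        # mean of `reps` Binomial(n, 0.1) counts, 3-sigma band for the mean
        assert abs(np.mean(ks) - n * 0.1) < 3 * np.sqrt(n * 0.1 * 0.9 / reps)

    def test_label_frequencies_follow_multinomial_law(self):
        cfg = SimulationConfig(doublet_frac=0.0, debris_frac=0.0, dead_frac=0.0)
        panel = builtin_panel("B-cell")
        props = {ct.name: 0.0 for ct in panel.cell_types}
        props["tcell"], props["naive_b"] = 0.3, 0.7
        n = 10_000
        _, labels = synthesize_events(props, panel, n, np.random.default_rng(5), cfg)
        for name, p in (("tcell", 0.3), ("naive_b", 0.7)):
            k = int((labels["cell_type"] == name).sum())
            assert abs(k / n - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_empirical_proportions_converge_to_truth(self, tcell_experiment):
        panel = tcell_experiment.panels["T-cell"]
        f = tcell_experiment.files[0]
        ok = ~(f.labels[["is_doublet", "is_debris"]].any(axis=1))
        n = int(ok.sum())
        for ct in panel.cell_types:
            p = f.leaf_proportions[ct.name]
            k = int(((f.labels["cell_type"] == ct.name) & ok).sum())
            assert abs(k / n - p) < 3 * np.sqrt(p * (1 - p) / n) + 1e-9

    def test_rejects_invalid_proportions(self, rng):
        cfg = SimulationConfig()
        panel = builtin_panel("T-cell")
        props = {ct.name: 0.2 for ct in panel.cell_types}  # sums to 2
        with pytest.raises(ValueError, match="sum"):
            synthesize_events(props, panel, 100, rng, cfg)


class TestApplySpillover:
    def test_identity_is_noop(self, tcell_experiment):
        f = tcell_experiment.files[0]
        S = SpilloverMatrix.identity([c for c in f.frame.detectors if c not in ("FSC-A", "FSC-H", "SSC-A", "FITC-A")])
        out = apply_spillover(f.frame, S)
        np.testing.assert_array_equal(out.data, f.frame.data)

    def test_hand_computed_two_channel_mixing(self):
        from cytostand.frames import ChannelInfo, EventFrame

        frame = EventFrame(
            np.array([[100.0, 0.0]]),
            [ChannelInfo("A", "x", "fluorescence"), ChannelInfo("B", "y", "fluorescence")],
        )
        S = SpilloverMatrix(np.array([[1.0, 0.1], [0.0, 1.0]]), ["A", "B"])
        out = apply_spillover(frame, S)
        np.testing.assert_allclose(out.data, [[100.0, 10.0]])

    def test_dimension_mismatch_rejected(self, tcell_experiment):
        f = tcell_experiment.files[0]
        S = SpilloverMatrix.identity(["PE-A", "APC-A"])
        with pytest.raises(ValueError, match="detectors"):
            apply_spillover(f.frame, S)


class TestDeterminism:
    def test_same_seed_bit_identical_experiment(self):
        cfg = SimulationConfig(
            n_centers=2, n_samples=1, n_replicates=1, events_per_file=500, panels=("Treg",), seed=9
        )
        a, b = simulate_experiment(cfg), simulate_experiment(cfg)
        for fa, fb in zip(a.files, b.files):
            np.testing.assert_array_equal(fa.frame.data, fb.frame.data)
            pd.testing.assert_frame_equal(fa.labels, fb.labels)
        pd.testing.assert_frame_equal(a.truth_table(), b.truth_table())

    def test_truth_masks_exclude_doublets_dead_and_debris(self, tcell_experiment):
        f = tcell_experiment.files[0]
        panel = tcell_experiment.panels["T-cell"]
        masks = truth_masks(panel, f.labels)
        bad = (f.labels["is_doublet"] | f.labels["is_debris"] | f.labels["is_dead"]).to_numpy()
        for m in masks.values():
            assert not (m & bad).any()
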
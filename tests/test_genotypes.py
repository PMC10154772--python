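import numpy as np
import pytest

from paleogen.genotypes import (
    EigenstratFormatError,
    GenotypeMatrix,
    call_pseudohaploid,
    ld_prune,
    mask_transitions,
    read_eigenstrat,
    read_observations,
    to_pseudodiploid,
    trim_terminal,
    write_eigenstrat,
    write_observations,
)
from paleogen.simulate import (
    DamageModel,
    apply_damage,
    simulate_frequencies,
    simulate_genotypes,
    simulate_observations,
    simulate_panel,
)


class TestTrimTerminal:
    def test_zero_is_identity(self, obs_factory):
        obs = obs_factory([(0, "s", "C", 37, 60, 5)])
        assert len(trim_terminal(obs, 0)) == 1

    def test_terminal_removed_internal_kept(self, obs_factory):
        obs = obs_factory([
            (0, "s", "C", 37, 60, 2),    # dist5 = 2 -> removed
            (0, "s", "C", 37, 62, 3),    # dist5 = 3, dist3 = 60 -> kept
        ])
        out = trim_terminal(obs, 2)
        assert len(out) == 1
        assert out.frame["dist5"].iloc[0] == 3

    def test_surviving_fraction_uniform(self):
        panel = simulate_panel(50_000, seed=1)
        model = simulate_frequencies(panel, 1, [0.1], seed=2)
        G = simulate_genotypes(model, np.ones((1, 1)), seed=3)
        rng = np.random.default_rng(4)
        import pandas as pd

        n = 100_000
        d5 = rng.integers(1, 66, n)
        obs = G  # placeholder silence
        frame = pd.DataFrame({
            "snp_index": rng.integers(0, 50_000, n),
            "sample_id": np.array(["s"] * n, dtype=object),
            "base": np.array(["C"] * n, dtype="U1"),
            "base_quality": np.full(n, 37),
            "fragment_length": np.full(n, 65),
            "dist5": d5,
            "dist3": 65 + 1 - d5,
        })
        from paleogen.simulate import ObservationSet

        out = trim_terminal(ObservationSet(frame), 2)
        frac = len(out) / n
        expected = 61 / 65
        assert abs(frac - expected) < 3 * np.sqrt(expected * (1 - expected) / n)

    def test_negative_rejected(self, obs_factory):
        obs = obs_factory([(0, "s", "C", 37, 60, 5)])
        with pytest.raises(ValueError):
            trim_terminal(obs, -1)


class TestCallPseudohaploid:
    def test_low_quality_missing(self, obs_factory, tiny_panel):
        obs = obs_factory([(0, "s", "C", 29, 60, 10)])
        calls = call_pseudohaploid(obs, tiny_panel, min_bq=30, seed=1,
                                   samples=["s"])
        assert calls.calls[0, 0] == -1

    def test_all_alt_calls_alt(self, obs_factory, tiny_panel):
        obs = obs_factory([(1, "s", "G", 37, 60, 10)] * 5)
        calls = call_pseudohaploid(obs, tiny_panel, seed=2, samples=["s"])
        assert calls.calls[0, 1] == 1

    def test_off_panel_base_dropped(self, obs_factory, tiny_panel):
        # SNP 2 is A/C; a T observation matches neither allele
        obs = obs_factory([(2, "s", "T", 37, 60, 10)])
        calls = call_pseudohaploid(obs, tiny_panel, seed=3, samples=["s"])
        assert calls.calls[0, 2] == -1

    def test_uniform_choice(self):
        panel = simulate_panel(10_000, seed=4)
        import pandas as pd

        n = len(panel)
        frame = pd.DataFrame({
            "snp_index": np.repeat(np.arange(n), 2),
            "sample_id": np.array(["s"] * (2 * n), dtype=object),
            "base": np.empty(2 * n, dtype="U1"),
            "base_quality": np.full(2 * n, 37),
            "fragment_length": np.full(2 * n, 65),
            "dist5": np.tile([10, 20], n),
            "dist3": 65 + 1 - np.tile([10, 20], n),
        })
        frame.loc[0::2, "base"] = panel.ref
        frame.loc[1::2, "base"] = panel.alt
        from paleogen.simulate import ObservationSet

        calls = call_pseudohaploid(ObservationSet(frame), panel, seed=5)
        frac_alt = (calls.calls == 1).mean()
        assert abs(frac_alt - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_order_independent(self, small_panel):
        model = simulate_frequencies(small_panel, 1, [0.1], seed=6)
        G = simulate_genotypes(model, np.ones((2, 1)), seed=7,
                               sample_ids=["a", "b"])
        obs = simulate_observations(G, small_panel, coverage=3.0, seed=8)
        shuffled = obs.with_frame(obs.frame.sample(frac=1, random_state=0))
        c1 = call_pseudohaploid(obs, small_panel, seed=9)
        c2 = call_pseudohaploid(shuffled, small_panel, seed=9)
        assert np.array_equal(c1.calls, c2.calls)
        assert c1.samples == c2.samples

    def test_seeded_determinism(self, small_panel):
        model = simulate_frequencies(small_panel, 1, [0.1], seed=10)
        G = simulate_genotypes(model, np.ones((1, 1)), seed=11)
        obs = simulate_observations(G, small_panel, coverage=2.0, seed=12)
        c1 = call_pseudohaploid(obs, small_panel, seed=13)
        c2 = call_pseudohaploid(obs, small_panel, seed=13)
        assert np.array_equal(c1.calls, c2.calls)


class TestToPseudodiploid:
    def test_mapping(self, tiny_panel):
        from paleogen.genotypes import HaploidCallSet

        calls = HaploidCallSet(
            samples=["s"], panel=tiny_panel,
            calls=np.array([[0, 1, -1, 0]], dtype=np.int8),
        )
        G = to_pseudodiploid(calls)
        assert list(G.counts[0]) == [0, 2, -1, 0]
        assert G.ploidy[0] == "pseudo_haploid"


class TestMaskTransitions:
    def test_ct_excluded_ac_retained(self, tiny_panel, matrix_factory):
        G = matrix_factory(np.zeros((1, 4)), tiny_panel)
        masked = mask_transitions(G)
        assert list(masked.panel.snp_id) == ["s3", "s4"]

    def test_all_transversions_identity(self, matrix_factory):
        panel = simulate_panel(100, transition_fraction=0.0, seed=1)
        G = matrix_factory(np.zeros((2, 100)), panel)
        assert mask_transitions(G).n_snps == 100

    def test_count(self, matrix_factory):
        panel = simulate_panel(500, transition_fraction=0.8, seed=2)
        n_tv = int(panel.is_transversion.sum())
        G = matrix_factory(np.zeros((1, 500)), panel)
        assert mask_transitions(G).n_snps == n_tv

    def test_idempotent(self, matrix_factory):
        panel = simulate_panel(300, seed=3)
        G = matrix_factory(np.zeros((1, 300)), panel)
        once = mask_transitions(G)
        twice = mask_transitions(once)
        assert np.array_equal(once.panel.snp_id, twice.panel.snp_id)

    def test_empty_result_error(self, matrix_factory):
        panel = simulate_panel(50, transition_fraction=1.0, seed=4)
        G = matrix_factory(np.zeros((1, 50)), panel)
        with pytest.raises(ValueError):
            mask_transitions(G)


class TestLdPrune:
    def test_duplicate_column_removed(self, matrix_factory):
        panel = simulate_panel(10, seed=1)
        rng = np.random.default_rng(2)
        col = rng.integers(0, 3, size=(50, 1))
        counts = rng.integers(0, 3, size=(50, 10))
        counts[:, 3] = col[:, 0]
        counts[:, 7] = col[:, 0]
        G = matrix_factory(counts, panel)
        kept = ld_prune(G)
        assert 3 in kept and 7 not in kept

    def test_independent_snps_mostly_retained(self, matrix_factory):
        panel = simulate_panel(300, seed=3)
        rng = np.random.default_rng(4)
        p = rng.uniform(0.2, 0.8, 300)
        counts = rng.binomial(2, p, size=(2000, 300))
        G = matrix_factory(counts, panel)
        kept = ld_prune(G)
        assert len(kept) > 0.99 * 300

    def test_r2_one_removes_nothing(self, matrix_factory):
        panel = simulate_panel(30, seed=5)
        rng = np.random.default_rng(6)
        counts = rng.integers(0, 3, size=(20, 30))
        counts[:, 1] = counts[:, 0]  # r2 exactly 1, not > 1
        G = matrix_factory(counts, panel)
        assert len(ld_prune(G, r2_max=1.0)) == 30

    def test_subset_and_order(self, matrix_factory):
        panel = simulate_panel(100, seed=7)
        rng = np.random.default_rng(8)
        counts = rng.integers(0, 3, size=(40, 100))
        kept = ld_prune(matrix_factory(counts, panel))
        assert np.all(np.diff(kept) > 0)
        assert set(kept) <= set(range(100))

    def test_window_step_validation(self, matrix_factory):
        panel = simulate_panel(10, seed=9)
        G = matrix_factory(np.zeros((5, 10)), panel)
        with pytest.raises(ValueError):
            ld_prune(G, window=2, step=5)

    def test_missing_handled(self, matrix_factory):
        panel = simulate_panel(60, seed=10)
        rng = np.random.default_rng(11)
        counts = rng.integers(0, 3, size=(30, 60))
        counts[rng.random(counts.shape) < 0.2] = -1
        G = matrix_factory(counts, panel)
        kept = ld_prune(G)
        assert len(kept) >= 1


class TestEigenstratIO:
    def test_round_trip(self, tmp_path, matrix_factory):
        panel = simulate_panel(80, seed=1)
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 3, size=(7, 80))
        counts[rng.random(counts.shape) < 0.15] = -1
        G = matrix_factory(counts, panel)
        prefix = str(tmp_path / "data")
        write_eigenstrat(G, prefix)
        back = read_eigenstrat(prefix)
        assert back.samples == G.samples
        assert np.array_equal(back.counts, G.counts)
        assert np.array_equal(back.panel.snp_id.astype(str),
                              G.panel.snp_id.astype(str))
        assert np.array_equal(back.panel.ref, G.panel.ref)

    def test_missing_is_nine(self, tmp_path, matrix_factory):
        panel = simulate_panel(3, seed=3)
        G = matrix_factory(np.array([[0, -1, 2]]), panel)
        prefix = str(tmp_path / "m")
        write_eigenstrat(G, prefix)
        geno = (tmp_path / "m.geno").read_text().splitlines()
        assert [g for g in geno] == ["0", "9", "2"]

    def test_dimension_mismatch(self, tmp_path, matrix_factory):
        panel = simulate_panel(5, seed=4)
        G = matrix_factory(np.zeros((3, 5)), panel)
        prefix = str(tmp_path / "bad")
        write_eigenstrat(G, prefix)
        lines = (tmp_path / "bad.geno").read_text().splitlines()
        (tmp_path / "bad.geno").write_text("\n".join(lines[:-1]) + "\n")
        with pytest.raises(EigenstratFormatError):
            read_eigenstrat(prefix)

    def test_sample_mismatch(self, tmp_path, matrix_factory):
        panel = simulate_panel(4, seed=5)
        G = matrix_factory(np.zeros((2, 4)), panel)
        prefix = str(tmp_path / "bad2")
        write_eigenstrat(G, prefix)
        with open(f"{prefix}.ind", "a") as fh:
            fh.write("extra\tU\tpop\n")
        with pytest.raises(EigenstratFormatError):
            read_eigenstrat(prefix)

    def test_observation_tsv_round_trip(self, tmp_path, small_panel):
        model = simulate_frequencies(small_panel, 1, [0.1], seed=6)
        G = simulate_genotypes(model, np.ones((1, 1)), seed=7)
        obs = simulate_observations(G, small_panel, coverage=1.0, seed=8)
        path = str(tmp_path / "obs.tsv")
        write_observations(obs, small_panel, path)
        back = read_observations(path, small_panel)
        assert np.array_equal(back.frame["snp_index"], obs.frame["snp_index"])
        assert np.array_equal(back.frame["base"], obs.frame["base"])


class TestDamageCallInteraction:
    def test_transversion_homozygote_calls_never_flip(self):
        """C>T / G>A cannot map one transversion allele onto the other, so a
        homozygous site can change only to missing, never to the opposite
        allele."""
        panel = simulate_panel(4000, transition_fraction=0.0, seed=1)
        model = simulate_frequencies(panel, 1, [0.15], seed=2)
        G = simulate_genotypes(model, np.ones((1, 1)), seed=3)
        obs = simulate_observations(G, panel, coverage=2.0, seed=4)
        damaged = apply_damage(obs, panel, DamageModel(d_max5=0.9, d_max3=0.9),
                               seed=5)
        c_und = call_pseudohaploid(obs, panel, seed=6, samples=G.samples)
        c_dam = call_pseudohaploid(damaged, panel, seed=6, samples=G.samples)
        hom = (G.counts[0] == 0) | (G.counts[0] == 2)
        truth_allele = (G.counts[0] == 2).astype(np.int8)
        for calls in (c_und, c_dam):
            site_ok = (calls.calls[0] == -1) | (calls.calls[0] == truth_allele)
            assert np.all(site_ok[hom])
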
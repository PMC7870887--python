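"""The synthetic-panel generator: reproducibility and statistical structure."""

import numpy as np
import pytest

from germpanel import harmonize, identity
from germpanel.synthetic import (
    SimConfig,
    array_subset,
    plant_mislabels,
    self_fertilize,
    simulate_panel,
    simulate_study,
)


def _clean_config(**kw):
    defaults = dict(
        seed=123, n_pops=2, n_per_pop=10, n_chrom=1, chrom_len_bp=500_000,
        n_sites_per_chrom=200, n_mislabels=0, n_duplicates=0,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestReproducibility:
    def test_identical_seed_bitwise_identical(self):
        cfg = SimConfig(seed=99)
        s1, s2 = simulate_study(cfg), simulate_study(SimConfig(seed=99))
        np.testing.assert_array_equal(s1.seq.geno, s2.seq.geno)
        np.testing.assert_array_equal(s1.array.geno, s2.array.geno)
        assert [s.key for s in s1.seq.sites] == [s.key for s in s2.seq.sites]
        assert s1.truth.mislabels == s2.truth.mislabels
        assert s1.truth.duplicate_groups == s2.truth.duplicate_groups

    def test_different_seed_differs(self):
        s1 = simulate_study(SimConfig(seed=1))
        s2 = simulate_study(SimConfig(seed=2))
        assert (s1.seq.geno != s2.seq.geno).any()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, divergence=1.5)
        with pytest.raises(ValueError):
            SimConfig(seed=1, n_mislabels=3)  # must be even
        with pytest.raises(ValueError):
            SimConfig(seed=1, n_pops=1, n_mislabels=2)  # needs 2 pops
        with pytest.raises(ValueError):
            SimConfig(seed=1, n_sites_per_chrom=10**7, chrom_len_bp=10**6)


class TestSelfing:
    def test_residual_heterozygosity_binomial(self):
        rng = np.random.default_rng(0)
        geno = np.ones((100, 100), dtype=np.int8)  # 10,000 initially het cells
        out = self_fertilize(geno, generations=6, rng=rng)
        p = 0.5**6
        expected = 10_000 * p
        sd = np.sqrt(10_000 * p * (1 - p))
        assert abs(int((out == 1).sum()) - expected) <= 3 * sd
        # resolved cells split evenly between the homozygote classes
        n0, n2 = int((out == 0).sum()), int((out == 2).sum())
        assert abs(n0 - n2) <= 3 * np.sqrt((n0 + n2) * 0.25) + 1

    def test_zero_generations_is_identity(self):
        rng = np.random.default_rng(0)
        geno = np.array([[0, 1, 2, -1]], dtype=np.int8)
        np.testing.assert_array_equal(self_fertilize(geno, 0, rng), geno)

    def test_panel_heterozygosity_is_low_for_inbreds(self):
        panel, _ = simulate_panel(_clean_config(selfing_generations=6))
        het = (panel.geno == 1).mean()
        assert het < 0.05  # inbred regime


def _mean_ibs(panel, ids_a, ids_b):
    sim = identity.ibs_similarity(panel, min_shared=1)
    vals = [
        sim.get(a, b) for a in ids_a for b in ids_b if a != b
    ]
    return float(np.mean(vals))


class TestPopulationStructure:
    def test_zero_divergence_makes_populations_exchangeable(self):
        # populations draw separate founder pools, which adds ~2pq/F of
        # within-population drift similarity even at divergence 0; a large
        # pool makes that term negligible and the groups exchangeable
        panel, truth = simulate_panel(
            _clean_config(divergence=0.0, seed=21, founder_haplotypes_per_pop=64)
        )
        pop0 = [s for s, p in truth.sample_pop.items() if p == 0]
        pop1 = [s for s, p in truth.sample_pop.items() if p == 1]
        within = (_mean_ibs(panel, pop0, pop0) + _mean_ibs(panel, pop1, pop1)) / 2
        between = _mean_ibs(panel, pop0, pop1)
        assert abs(within - between) < 0.01

    def test_divergence_orders_similarities(self):
        panel, truth = simulate_panel(_clean_config(divergence=0.3, seed=22))
        pop0 = [s for s, p in truth.sample_pop.items() if p == 0]
        pop1 = [s for s, p in truth.sample_pop.items() if p == 1]
        within = (_mean_ibs(panel, pop0, pop0) + _mean_ibs(panel, pop1, pop1)) / 2
        between = _mean_ibs(panel, pop0, pop1)
        assert within > between


class TestArraySubset:
    def test_error_free_subset_matches_source(self):
        cfg = _clean_config(
            geno_error_rate=0.0, missing_rate=0.0,
            array_swap_fraction=0.0, array_flip_fraction=0.0, array_fraction=0.5,
        )
        rng = np.random.default_rng(cfg.seed)
        panel, _ = simulate_panel(cfg, rng=rng)
        arr = array_subset(panel, cfg, rng=rng)
        lookup = {s.key: j for j, s in enumerate(panel.sites)}
        for j, site in enumerate(arr.sites):
            np.testing.assert_array_equal(
                arr.geno[:, j], panel.geno[:, lookup[site.key]]
            )

    def test_fraction_one_keeps_every_site(self):
        cfg = _clean_config(
            array_fraction=1.0, geno_error_rate=0.0, missing_rate=0.0,
            array_swap_fraction=0.0, array_flip_fraction=0.0,
        )
        rng = np.random.default_rng(cfg.seed)
        panel, _ = simulate_panel(cfg, rng=rng)
        arr = array_subset(panel, cfg, rng=rng)
        assert [s.key for s in arr.sites] == [s.key for s in panel.sites]
        np.testing.assert_array_equal(arr.geno, panel.geno)

    def test_flip_count_binomial(self):
        cfg = _clean_config(
            geno_error_rate=0.02, missing_rate=0.0, array_fraction=1.0,
            array_swap_fraction=0.0, array_flip_fraction=0.0, seed=31,
        )
        rng = np.random.default_rng(cfg.seed)
        panel, _ = simulate_panel(cfg, rng=rng)
        arr = array_subset(panel, cfg, rng=rng)
        hom = ((panel.geno == 0) | (panel.geno == 2))
        n_hom = int(hom.sum())
        flipped = int((panel.geno != arr.geno)[hom].sum())
        expected = n_hom * cfg.geno_error_rate
        sd = np.sqrt(n_hom * cfg.geno_error_rate * (1 - cfg.geno_error_rate))
        assert abs(flipped - expected) <= 3 * sd

    def test_representation_jitter_is_genotype_neutral(self):
        # swapped/flipped site records change, but after harmonization the
        # merged matrix must equal the source genotypes at retained sites
        cfg = _clean_config(geno_error_rate=0.0, missing_rate=0.0, seed=41)
        rng = np.random.default_rng(cfg.seed)
        panel, _ = simulate_panel(cfg, rng=rng)
        arr = array_subset(panel, cfg, rng=rng)
        res = harmonize.merge_panels(panel, arr)
        assert res.n_allele_swapped > 0  # jitter actually exercised
        block_a = res.panel.geno[: panel.n_samples]
        block_b = res.panel.geno[panel.n_samples :]
        np.testing.assert_array_equal(block_a, block_b)


class TestPlantedEvents:
    def test_zero_events_leave_mapping_untouched(self):
        study = simulate_study(_clean_config())
        assert study.truth.mislabels == []
        assert study.truth.duplicate_groups == []
        assert study.truth.expected_map == {s: s for s in study.seq.samples}
        assert study.array.n_samples == study.seq.n_samples

    def test_events_recorded_in_truth(self):
        study = simulate_study(SimConfig(seed=77))
        assert len(study.truth.mislabels) == 2          # 4 affected samples
        assert len(study.truth.duplicate_groups) == 2
        for a, b in study.truth.mislabels:
            assert study.truth.sample_pop[a] != study.truth.sample_pop[b]
            assert study.truth.true_match[a] == b
        for src, dup in study.truth.duplicate_groups:
            i = study.array.sample_index(src)
            j = study.array.sample_index(dup)
            np.testing.assert_array_equal(study.array.geno[i], study.array.geno[j])

    def test_mislabel_swap_moves_genotypes(self):
        cfg = SimConfig(seed=88)
        rng = np.random.default_rng(cfg.seed)
        panel, truth = simulate_panel(cfg, rng=rng)
        arr = array_subset(panel, cfg, rng=rng)
        planted, truth2 = plant_mislabels(arr, truth, rng=rng)
        (sa, sb) = truth2.mislabels[0]
        ia, ib = arr.sample_index(sa), arr.sample_index(sb)
        np.testing.assert_array_equal(planted.geno[ia], arr.geno[ib])
        np.testing.assert_array_equal(planted.geno[ib], arr.geno[ia])

    def test_truth_json_roundtrip(self, tmp_path):
        import json

        study = simulate_study(SimConfig(seed=5))
        study.truth.to_json(tmp_path / "truth.json")
        data = json.loads((tmp_path / "truth.json").read_text())
        assert data["config"]["seed"] == 5
        assert len(data["mislabels"]) == 2

    def test_metadata_frame_covers_all_samples(self):
        study = simulate_study(SimConfig(seed=5))
        meta = study.truth.metadata_frame()
        assert set(meta["sample_id"]) == set(study.seq.samples)
        assert set(meta["species"]) == {"G. max", "G. soja"}
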
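import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from lakecohorts import ConfigurationError, SimulationConfig, simulate
from lakecohorts.bedgraph import read_bedgraph, write_bedgraph


def _tree_digest(root: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(Path(root).rglob("*")):
        if p.is_file():
            h.update(str(p.relative_to(root)).encode())
            h.update(p.read_bytes())
    return h.hexdigest()


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(cohort_sizes=(300,)),  # exceeds n_species
            dict(noise_sd=-0.1),
            dict(coverage_target=0.0),
            dict(genome_length_range=(5e6, 1e6)),
            dict(completeness_range=(0.0, 0.9)),
            dict(oxygen_coupled_cohort=9),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kwargs).validate()

    def test_json_round_trip(self, tmp_path, small_config):
        small_config.to_json(tmp_path / "cfg.json")
        assert SimulationConfig.from_json(tmp_path / "cfg.json") == small_config


class TestCatalogGeneration:
    def test_full_completeness_means_assembly_equals_truth(self):
        cfg = SimulationConfig(
            n_species=10, n_samples=5, cohort_sizes=(4,), completeness_range=(1.0, 1.0), seed=1
        )
        catalog, sizes = simulate.simulate_catalog(cfg)
        for g in catalog:
            assert g.assembly_size == pytest.approx(sizes[g.id])

    def test_fixed_completeness_scales_assembly(self):
        cfg = SimulationConfig(
            n_species=10, n_samples=5, cohort_sizes=(4,), completeness_range=(0.8, 0.8), seed=1
        )
        catalog, sizes = simulate.simulate_catalog(cfg)
        for g in catalog:
            assert g.assembly_size == pytest.approx(0.8 * sizes[g.id])

    def test_determinism(self):
        cfg = SimulationConfig(n_species=200, n_samples=5, cohort_sizes=(10,), seed=7)
        cat1, s1 = simulate.simulate_catalog(cfg)
        cat2, s2 = simulate.simulate_catalog(cfg)
        assert cat1 == cat2
        assert s1.equals(s2)

    def test_genera_with_five_plus_members_exist(self, small_catalog):
        catalog, _ = small_catalog
        counts = pd.Series([g.genus for g in catalog]).value_counts()
        assert (counts >= 5).any()


class TestAbundanceGeneration:
    def test_columns_close_to_one(self, small_community):
        abundance, _, _ = small_community
        assert np.allclose(abundance.sum(axis=0), 1.0, atol=1e-9)

    def test_noiseless_cohort_is_perfectly_correlated(self):
        cfg = SimulationConfig(
            n_species=30, n_samples=40, cohort_sizes=(6,), noise_sd=0.0, loading=1.0, seed=3
        )
        catalog, _ = simulate.simulate_catalog(cfg)
        abundance, labels, _ = simulate.simulate_abundances(catalog, cfg)
        members = labels.index[labels == "cohort_1"]
        la = np.log(abundance.loc[members].to_numpy())
        corr = np.corrcoef(la)
        assert np.allclose(corr, 1.0, atol=1e-9)

    def test_background_pairs_uncorrelated_at_large_n(self):
        cfg = SimulationConfig(n_samples=500, seed=9)
        catalog, _ = simulate.simulate_catalog(cfg)
        abundance, labels, _ = simulate.simulate_abundances(catalog, cfg)
        bg = labels.index[labels == "background"][:2]
        la = np.log(abundance.loc[bg].to_numpy())
        assert abs(np.corrcoef(la)[0, 1]) < 0.15

    def _mean_within_cohort_corr(self, loading, noise_sd, seed):
        cfg = SimulationConfig(
            n_species=60,
            n_samples=120,
            cohort_sizes=(10, 10),
            loading=loading,
            noise_sd=noise_sd,
            oxygen_coupled_cohort=None,
            seed=seed,
        )
        catalog, _ = simulate.simulate_catalog(cfg)
        abundance, labels, _ = simulate.simulate_abundances(catalog, cfg)
        vals = []
        for c in ("cohort_1", "cohort_2"):
            la = np.log(abundance.loc[labels.index[labels == c]].to_numpy())
            corr = np.corrcoef(la)
            iu = np.triu_indices_from(corr, k=1)
            vals.append(corr[iu].mean())
        return np.mean(vals)

    def test_planted_signal_monotone_in_loading_and_noise(self):
        seeds = range(3)
        weak = np.mean([self._mean_within_cohort_corr(0.5, 0.8, s) for s in seeds])
        stronger_loading = np.mean([self._mean_within_cohort_corr(1.0, 0.8, s) for s in seeds])
        less_noise = np.mean([self._mean_within_cohort_corr(0.5, 0.4, s) for s in seeds])
        assert stronger_loading >= weak
        assert less_noise >= weak


class TestDepthProfiles:
    def test_mean_depth_matches_expected_coverage(self, rng):
        # Poisson law of large numbers at >= 1e5 bp (1000 windows of 100 bp)
        ab = pd.DataFrame({"s": [1.0]}, index=["g"])
        sizes = pd.Series({"g": 1e5})
        cfg = SimulationConfig(
            n_species=1, n_samples=1, cohort_sizes=(1,), coverage_target=10.0, seed=2
        )
        import tempfile

        with tempfile.TemporaryDirectory() as d:
            simulate.simulate_depth_profiles(ab, sizes, cfg, d, rng)
            profiles = read_bedgraph(Path(d) / "bedgraph" / "s.bedgraph", window=100)
        # GE = coverage_target * n_species = 10, abundance 1 => coverage 10
        assert profiles["g"].mean() == pytest.approx(10.0, rel=0.02)

    def test_zero_abundance_species_gets_single_zero_interval(self, tmp_path, rng):
        ab = pd.DataFrame({"s": [1.0, 0.0]}, index=["g1", "g2"])
        sizes = pd.Series({"g1": 5e4, "g2": 5e4})
        cfg = SimulationConfig(n_species=2, n_samples=1, cohort_sizes=(1,), seed=2)
        simulate.simulate_depth_profiles(ab, sizes, cfg, tmp_path, rng)
        lines = [
            l for l in (tmp_path / "bedgraph" / "s.bedgraph").read_text().splitlines()
            if l.startswith("g2\t")
        ]
        assert lines == ["g2\t0\t50000\t0"]

    def test_bedgraph_round_trip_identity(self, tmp_path, rng):
        profiles = {f"g{i}": rng.poisson(3, size=rng.integers(5, 50)).astype(float) for i in range(5)}
        write_bedgraph(tmp_path / "x.bedgraph", profiles, window=100)
        back = read_bedgraph(tmp_path / "x.bedgraph", window=100)
        for g, d in profiles.items():
            assert np.array_equal(back[g], d)


class TestKoTable:
    def test_zero_slope_decouples_size(self, small_catalog):
        catalog, _ = small_catalog
        cfg = SimulationConfig(
            n_species=len(catalog), n_samples=5, cohort_sizes=(8, 8),
            genome_length_range=(3e5, 6e5), ko_slope=0.0, seed=11,
        )
        modules = simulate.synthetic_modules()
        ko_table, comp = simulate.simulate_ko_table(catalog, modules, cfg)
        sizes = np.array([g.estimated_size for g in catalog])
        mean_comp = comp.mean(axis=1).to_numpy()
        assert abs(np.corrcoef(sizes, mean_comp)[0, 1]) < 0.3

    def test_positive_slope_couples_size(self):
        cfg = SimulationConfig(
            n_species=300, n_samples=5, cohort_sizes=(10,), ko_slope=1.5, seed=4
        )
        catalog, _ = simulate.simulate_catalog(cfg)
        modules = simulate.synthetic_modules()
        ko_table, comp = simulate.simulate_ko_table(catalog, modules, cfg)
        sizes = np.array([g.estimated_size for g in catalog])
        r = np.corrcoef(sizes, comp.mean(axis=1).to_numpy())[0, 1]
        assert r > 0.5

    def test_saturation_gives_full_completeness(self, small_catalog):
        from lakecohorts import module_completeness

        modules = simulate.synthetic_modules()
        all_kos = {ko for m in modules for ko in m.kos()}
        for m in modules:
            assert module_completeness(m, all_kos) == pytest.approx(100.0)

    def test_empty_module_list_rejected(self, small_catalog, small_config):
        catalog, _ = small_catalog
        with pytest.raises(ConfigurationError):
            simulate.simulate_ko_table(catalog, [], small_config)


class TestRunDeterminism:
    def test_fixed_seed_byte_identical_run(self, tmp_path):
        cfg = SimulationConfig(
            n_species=20, n_samples=6, cohort_sizes=(5,), genome_length_range=(2e5, 3e5), seed=17
        )
        simulate.simulate_run(cfg, tmp_path / "a")
        simulate.simulate_run(cfg, tmp_path / "b")
        assert _tree_digest(tmp_path / "a") == _tree_digest(tmp_path / "b")
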
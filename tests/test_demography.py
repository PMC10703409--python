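"""Simulation-stage contracts: demographic models, coalescent expectations,
sweep signatures, dataset assembly."""

import numpy as np
import pytest
from scipy import stats as sps

from sweepnet.demography import (
    DemographyModel,
    ParameterError,
    PopulationHistory,
    SimRegionParams,
    SweepParams,
    build_three_pop_demography,
    generate_dataset,
    load_dataset,
    save_dataset,
    simulate_neutral,
    simulate_sweep,
    wf_trajectory_end_frequency,
)
from sweepnet.stats import garud_h1, harmonic_number


class TestDemographyModels:
    def test_three_epoch_sizes(self, single_pop_dem):
        assert single_pop_dem.size_at(0) == 20_000
        assert single_pop_dem.size_at(2_999) == 20_000
        assert single_pop_dem.size_at(3_200) == 2_000
        assert single_pop_dem.size_at(4_000) == 10_000
        assert single_pop_dem.epochs == ((0, 20_000), (3_000, 2_000), (3_500, 10_000))

    def test_three_pop_structure(self):
        dem = build_three_pop_demography()
        assert dem.population_names == ("YRI", "CEU", "CHB")
        assert dem.generation_time_years == 25
        mig = dem.migration
        off_diagonal = mig[~np.eye(3, dtype=bool)]
        assert (off_diagonal > 0).all()
        # growth since the CEU/CHB split
        assert dem.size_at(0, "CEU") > dem.size_at(900, "CEU")
        assert dem.size_at(1_000, "CEU") == pytest.approx(1_861)

    def test_invalid_models_rejected(self):
        with pytest.raises(ParameterError):
            PopulationHistory("p", ((0, 1000, 0), (100, -5, 0)))
        with pytest.raises(ParameterError):
            PopulationHistory("p", ((0, 1000, 0), (0, 500, 0)))
        with pytest.raises(ParameterError):
            DemographyModel(
                populations=(PopulationHistory("p", ((0, 100.0, 0),)),),
                migration=np.zeros((1, 1)),
            )

    def test_collapsed_history_flattens_growth(self):
        dem = build_three_pop_demography()
        coll = dem.collapsed("CEU")
        assert len(coll.populations) == 1
        assert coll.migration is None
        # growth epochs become constant at their recent-boundary size;
        # older epoch boundaries are preserved
        assert coll.size_at(0) == pytest.approx(dem.size_at(0, "CEU"))
        assert coll.size_at(910) == pytest.approx(dem.size_at(0, "CEU"))
        assert coll.size_at(1_000) == pytest.approx(1_861)


class TestNeutralSimulation:
    def test_matrix_contract(self, single_pop_dem):
        m = simulate_neutral(single_pop_dem, SimRegionParams(seed=5))
        assert m.alleles.shape[0] == 128
        assert m.segregating_mask().all()
        assert (np.diff(m.positions) > 0).all()
        assert m.positions.min() >= 0 and m.positions.max() < 80_000
        assert m.label == "neutral"

    def test_seed_reproducibility(self, single_pop_dem):
        r = SimRegionParams(seed=42)
        a = simulate_neutral(single_pop_dem, r)
        b = simulate_neutral(single_pop_dem, r)
        assert np.array_equal(a.alleles, b.alleles)
        assert np.array_equal(a.positions, b.positions)
        c = simulate_neutral(single_pop_dem, SimRegionParams(seed=43))
        assert not np.array_equal(a.positions, c.positions)

    def test_watterson_and_pi_match_closed_forms(self):
        # constant-size model: E[S] = theta * H_{n-1}, E[pi] = theta,
        # with theta = 4 N mu L
        const = DemographyModel(
            populations=(PopulationHistory("pop0", ((0.0, 10_000.0, 0.0),)),)
        )
        n, reps = 128, 1000
        theta = 4 * 10_000 * 1.5e-8 * 80_000
        expected_s = theta * harmonic_number(n - 1)
        s_vals = []
        for i in range(reps):
            m = simulate_neutral(const, SimRegionParams(seed=10_000 + i))
            s_vals.append(m.n_sites)
        se = np.std(s_vals, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(s_vals) - expected_s) < 3 * se
        assert expected_s == pytest.approx(260, rel=0.01)

        # pairwise differences at n=2 estimate theta directly
        pi_vals = []
        for i in range(1000):
            m = simulate_neutral(
                const, SimRegionParams(seed=50_000 + i, n_haplotypes=2)
            )
            pi_vals.append(np.sum(m.alleles[0] != m.alleles[1]))
        se = np.std(pi_vals, ddof=1) / np.sqrt(len(pi_vals))
        assert abs(np.mean(pi_vals) - theta) < 3 * se

    def test_three_pop_neutral_smoke(self):
        dem = build_three_pop_demography()
        m = simulate_neutral(dem, SimRegionParams(seed=7, n_haplotypes=128), population="CEU")
        assert m.n_haplotypes == 128
        assert m.segregating_mask().all()


class TestSweepSimulation:
    def test_invalid_selection_rejected(self):
        with pytest.raises(ParameterError):
            SweepParams(s_het=0.0)
        with pytest.raises(ParameterError):
            SweepParams(s_het=0.01, position_fraction=1.5)

    def test_trajectory_conditioned_on_survival(self):
        rng = np.random.default_rng(0)
        sweep = SweepParams(s_het=0.01)
        for _ in range(20):
            x, attempts = wf_trajectory_end_frequency(rng, sweep, 20_000)
            assert 0 < x < 1
            assert attempts <= sweep.max_retries

    def test_seed_reproducibility(self, single_pop_dem):
        r = SimRegionParams(seed=9)
        sw = SweepParams(s_het=0.01)
        a = simulate_sweep(single_pop_dem, r, sw)
        b = simulate_sweep(single_pop_dem, r, sw)
        assert np.array_equal(a.alleles, b.alleles)
        assert a.label == "sweep"
        assert a.provenance["engine"] == "msprime-structured-coalescent"

    def test_sweep_reduces_diversity_and_raises_h1(self, paired_batches):
        neutral, swept = paired_batches
        s_neu = np.array([m.n_sites for m in neutral], dtype=float)
        s_swp = np.array([m.n_sites for m in swept], dtype=float)
        assert sps.mannwhitneyu(s_swp, s_neu, alternative="less").pvalue < 0.01
        h_neu = np.array([garud_h1(m) for m in neutral])
        h_swp = np.array([garud_h1(m) for m in swept])
        assert sps.mannwhitneyu(h_swp, h_neu, alternative="greater").pvalue < 0.01

    def test_three_pop_sweep_smoke(self):
        dem = build_three_pop_demography()
        region = SimRegionParams(seed=21)
        sw = SweepParams(s_het=0.01, target_population="CEU")
        m = simulate_sweep(dem, region, sw)
        assert m.n_haplotypes == 128
        assert m.label == "sweep"
        assert m.provenance["population"] == "CEU"


class TestDatasetGeneration:
    def test_split_sizes_and_balance(self, single_pop_dem):
        ds = generate_dataset(
            single_pop_dem,
            SimRegionParams(seed=1, n_haplotypes=16, sequence_length_bp=20_000),
            SweepParams(s_het=0.01),
            n_per_class=20,
            seed=3,
        )
        assert len(ds) == 40
        sizes = {k: len(v) for k, v in ds.splits.items()}
        assert sizes == {"train": 32, "val": 4, "test": 4}
        all_idx = np.concatenate(list(ds.splits.values()))
        assert len(np.unique(all_idx)) == 40  # disjoint, exhaustive
        for split in ds.splits:
            labels = ds.subset_labels(split)
            assert labels.sum() * 2 == len(labels)  # balanced

    def test_bad_fractions_rejected(self, single_pop_dem):
        with pytest.raises(ParameterError):
            generate_dataset(
                single_pop_dem,
                SimRegionParams(seed=1),
                SweepParams(s_het=0.01),
                n_per_class=10,
                split_fractions=(0.7, 0.2, 0.2),
            )

    def test_archive_round_trip(self, single_pop_dem, tmp_path):
        ds = generate_dataset(
            single_pop_dem,
            SimRegionParams(seed=2, n_haplotypes=10, sequence_length_bp=10_000),
            SweepParams(s_het=0.01),
            n_per_class=10,
            seed=5,
        )
        save_dataset(ds, tmp_path / "ds")
        back = load_dataset(tmp_path / "ds")
        assert np.array_equal(back.labels, ds.labels)
        for a, b in zip(ds.samples, back.samples):
            assert np.array_equal(a.alleles, b.alleles)
            assert np.allclose(a.positions, b.positions)
        assert back.metadata["engine"] == ds.metadata["engine"]
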
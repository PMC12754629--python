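"""Synthetic microcosm generator: design combinatorics, tolerance curves,
determinism, and the generative model's closed-form ground truth."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from salbef import (
    CommunityDesign,
    DesignInfeasibleError,
    NoGrowthWarning,
    SimulationConfig,
    StrainProfile,
    composition_table,
    design_communities,
    generate_strain_library,
    read_experiment,
    simulate_experiment,
    simulate_mixture,
    simulate_monocultures,
    tolerance_yield,
    write_experiment,
)


def _profiles_equal(a, b):
    return all(
        (p.strain_id, p.genus, p.s_opt, p.sigma_tol, p.y_max)
        == (q.strain_id, q.genus, q.s_opt, q.sigma_tol, q.y_max)
        for p, q in zip(a, b)
    )


class TestStrainLibrary:
    def test_default_library_counts_and_ranges(self):
        lib = generate_strain_library(SimulationConfig(seed=7))
        assert len(lib) == 40
        assert len({p.strain_id for p in lib}) == 40
        assert all(0.0 <= p.s_opt <= 30.0 for p in lib)
        assert all(p.sigma_tol > 0 and p.y_max > 0 for p in lib)
        # congeneric strains exist: 32 genus labels for 40 strains
        assert len({p.genus for p in lib}) == 32

    def test_minimal_feasible_library(self):
        cfg = SimulationConfig(n_strains=5, richness_levels=(5,), replicate_counts=(1,))
        assert len(generate_strain_library(cfg)) == 5

    def test_deterministic_for_fixed_seed(self):
        cfg = SimulationConfig(seed=3)
        assert _profiles_equal(generate_strain_library(cfg), generate_strain_library(cfg))

    def test_every_culture_salinity_covered_within_one_sigma(self):
        for seed in (0, 1, 2, 99):
            cfg = SimulationConfig(seed=seed)
            lib = generate_strain_library(cfg)
            for s in cfg.salinities:
                assert any(abs(s - p.s_opt) <= p.sigma_tol for p in lib)

    def test_infeasible_richness_rejected(self):
        with pytest.raises(DesignInfeasibleError):
            SimulationConfig(n_strains=4, richness_levels=(5,), replicate_counts=(1,))

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            StrainProfile("X", "Gen", s_opt=31.0, sigma_tol=1.0, y_max=1.0)
        with pytest.raises(ValueError):
            StrainProfile("X", "Gen", s_opt=5.0, sigma_tol=0.0, y_max=1.0)


class TestToleranceYield:
    strain = StrainProfile("S1", "Halomonas", s_opt=10.0, sigma_tol=5.0, y_max=1.0)

    def test_peak_at_optimum(self):
        assert tolerance_yield(self.strain, 10.0) == pytest.approx(1.0, abs=0)

    def test_one_sigma_away(self):
        # direct evaluation of the Gaussian form at s_opt + sigma
        assert tolerance_yield(self.strain, 15.0) == pytest.approx(math.exp(-0.5), rel=1e-12)

    def test_two_sigma_away(self):
        assert tolerance_yield(self.strain, 20.0) == pytest.approx(math.exp(-2.0), rel=1e-12)

    def test_negative_salinity_rejected(self):
        with pytest.raises(ValueError):
            tolerance_yield(self.strain, -1.0)

    @given(st.floats(0.0, 30.0))
    @settings(deadline=None)
    def test_bounded_by_y_max(self, salinity):
        y = tolerance_yield(self.strain, salinity)
        assert 0.0 < y <= self.strain.y_max


class TestMonocultures:
    def test_table_shape(self, default_config, default_experiment):
        table = default_experiment.monocultures
        assert len(table) == 40 * 5  # strain x salinity
        assert table.groupby(["strain_id", "salinity_pct"]).size().max() == 1

    def test_noiseless_equals_tolerance_curve(self):
        cfg = SimulationConfig(seed=5, noise_sd=0.0)
        lib = generate_strain_library(cfg)
        table = simulate_monocultures(lib, cfg)
        by_id = {p.strain_id: p for p in lib}
        for row in table.itertuples(index=False):
            expected = tolerance_yield(by_id[row.strain_id], row.salinity_pct)
            if expected < cfg.detection_floor:
                expected = 0.0
            assert row[2] == pytest.approx(expected, rel=1e-12, abs=0)

    def test_noisy_run_reproducible(self):
        cfg = SimulationConfig(seed=5, noise_sd=0.1)
        lib = generate_strain_library(cfg)
        pd.testing.assert_frame_equal(
            simulate_monocultures(lib, cfg), simulate_monocultures(lib, cfg)
        )

    def test_detection_floor_zeroes_small_yields(self):
        cfg = SimulationConfig(seed=5, noise_sd=0.0, detection_floor=0.01)
        table = simulate_monocultures(generate_strain_library(cfg), cfg)
        small = table[table["yield"] > 0]["yield"]
        assert (small >= cfg.detection_floor).all()
        assert (table["yield"] == 0).any()  # some strains fail at far salinities


class TestCommunityDesign:
    def test_default_group_structure(self, default_config, default_experiment):
        designs = default_experiment.designs
        assert len(designs) == 31
        by_group = {}
        for d in designs:
            by_group.setdefault(d.group, []).append(d)
        assert {g: len(ds) for g, ds in by_group.items()} == {"A": 4, "B": 8, "C": 16, "D": 3}
        assert {ds[0].richness for ds in by_group.values()} == {5, 10, 20, 40}
        # distinct member sets within A-C; D is the single full composition
        for g in "ABC":
            sets = [frozenset(d.members) for d in by_group[g]]
            assert len(set(sets)) == len(sets)
        d_sets = {frozenset(d.members) for d in by_group["D"]}
        assert len(d_sets) == 1 and len(next(iter(d_sets))) == 40
        # equal inoculation
        for d in designs:
            assert all(v == pytest.approx(1.0 / d.richness) for v in d.ry_expected.values())

    def test_forced_single_pair(self):
        cfg = SimulationConfig(n_strains=2, richness_levels=(2,), replicate_counts=(1,))
        lib = generate_strain_library(cfg)
        designs = design_communities(lib, cfg)
        assert len(designs) == 1
        assert set(designs[0].members) == {p.strain_id for p in lib}

    def test_too_many_replicates_infeasible(self):
        cfg = SimulationConfig(
            n_strains=5, richness_levels=(3,), replicate_counts=(math.comb(5, 3) + 1,)
        )
        with pytest.raises(DesignInfeasibleError):
            design_communities(generate_strain_library(cfg), cfg)

    def test_exhaustible_combination_space(self):
        # exactly C(5,3)=10 distinct communities must all be produced
        cfg = SimulationConfig(n_strains=5, richness_levels=(3,), replicate_counts=(10,))
        designs = design_communities(generate_strain_library(cfg), cfg)
        assert len({frozenset(d.members) for d in designs}) == 10

    def test_stratified_sampling_spans_tolerance_classes(self):
        cfg = SimulationConfig(seed=2, stratified_communities=True)
        lib = generate_strain_library(cfg)
        designs = design_communities(lib, cfg)
        s_opt = {p.strain_id: p.s_opt for p in lib}
        quartiles = np.quantile([p.s_opt for p in lib], [0.25, 0.5, 0.75])
        for d in designs:
            if d.richness < 20:
                classes = {int(np.searchsorted(quartiles, s_opt[m])) for m in d.members}
                assert len(classes) >= 3  # members drawn across tolerance classes

    def test_membership_subset_of_library(self, default_experiment):
        ids = {p.strain_id for p in default_experiment.library}
        for d in default_experiment.designs:
            assert set(d.members) <= ids


class TestMixtureModel:
    def _design(self, n, ids=None):
        ids = ids or [f"S{i}" for i in range(1, n + 1)]
        return CommunityDesign("X1", "X", tuple(ids), {i: 1.0 / n for i in ids})

    def test_worked_two_species_complementarity_case(self):
        # N=2, M=(10,20), phi=0.2, theta=0, noise off:
        # Y_O = 15*(1+0.2*0.5) = 16.5, shares (1/3, 2/3)
        cfg = SimulationConfig(
            n_strains=2,
            richness_levels=(2,),
            replicate_counts=(1,),
            salinities=(5.0,),
            theta_by_salinity={5.0: 0.0},
            phi_by_salinity={5.0: 0.2},
            noise_sd=0.0,
        )
        design = self._design(2)
        mono = {("S1", 5.0): 10.0, ("S2", 5.0): 20.0}
        ob = simulate_mixture(design, mono, cfg, 5.0)
        assert ob.y_o == pytest.approx(16.5, rel=1e-12)
        assert ob.member_yields["S1"] / ob.y_o == pytest.approx(1 / 3, rel=1e-12)
        assert ob.member_yields["S2"] / ob.y_o == pytest.approx(2 / 3, rel=1e-12)

    def test_null_mixture_matches_expected_yield(self):
        cfg = SimulationConfig(
            n_strains=3, richness_levels=(3,), replicate_counts=(1,), salinities=(5.0,),
            theta_by_salinity={}, phi_by_salinity={}, noise_sd=0.0,
        )
        design = self._design(3)
        mono = {("S1", 5.0): 1.0, ("S2", 5.0): 2.0, ("S3", 5.0): 3.0}
        ob = simulate_mixture(design, mono, cfg, 5.0)
        assert ob.y_o == pytest.approx(2.0, rel=1e-12)  # mean of M at 1/N each
        for sid, m in (("S1", 1.0), ("S2", 2.0), ("S3", 3.0)):
            assert ob.member_yields[sid] == pytest.approx(m / 3, rel=1e-12)

    def test_no_growth_yields_zero_with_warning(self):
        cfg = SimulationConfig(
            n_strains=2, richness_levels=(2,), replicate_counts=(1,), salinities=(5.0,),
            detection_floor=0.01, noise_sd=0.0,
        )
        design = self._design(2)
        mono = {("S1", 5.0): 0.0, ("S2", 5.0): 0.005}
        with pytest.warns(NoGrowthWarning):
            ob = simulate_mixture(design, mono, cfg, 5.0)
        assert ob.y_o == 0.0
        assert all(v == 0.0 for v in ob.member_yields.values())

    @given(seed=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=25)
    def test_member_yields_sum_to_total(self, seed):
        cfg = SimulationConfig(
            n_strains=6, richness_levels=(4,), replicate_counts=(2,), salinities=(3.0, 9.0),
            theta_by_salinity={3.0: 0.4, 9.0: 0.8},
            phi_by_salinity={3.0: 0.3, 9.0: 0.1},
            noise_sd=0.15, seed=seed,
        )
        exp = simulate_experiment(cfg)
        totals = exp.member_yields.groupby(["community_id", "salinity_pct"])["yield"].sum()
        for row in exp.observations.itertuples(index=False):
            assert totals[(row.community_id, row.salinity_pct)] == pytest.approx(
                row.Y_O, rel=1e-9, abs=1e-300
            )


class TestExperimentIO:
    def test_experiment_determinism(self):
        cfg = SimulationConfig(seed=21)
        a, b = simulate_experiment(cfg), simulate_experiment(cfg)
        pd.testing.assert_frame_equal(a.monocultures, b.monocultures)
        pd.testing.assert_frame_equal(a.observations, b.observations)
        pd.testing.assert_frame_equal(a.member_yields, b.member_yields)

    def test_round_trip(self, tmp_path, default_experiment):
        counts = write_experiment(default_experiment, tmp_path)
        assert counts["monocultures.csv"] == 200
        assert counts["observations.csv"] == 155
        back = read_experiment(tmp_path)
        pd.testing.assert_frame_equal(back.monocultures, default_experiment.monocultures)
        pd.testing.assert_frame_equal(back.observations, default_experiment.observations)
        pd.testing.assert_frame_equal(back.member_yields, default_experiment.member_yields)
        assert back.config.to_dict() == default_experiment.config.to_dict()
        assert _profiles_equal(back.library, default_experiment.library)
        assert [d.community_id for d in back.designs] == [
            d.community_id for d in default_experiment.designs
        ]
        assert all(
            a.members == b.members and a.ry_expected == pytest.approx(b.ry_expected)
            for a, b in zip(back.designs, default_experiment.designs)
        )

    def test_empty_observation_table_round_trips(self, tmp_path, default_experiment):
        from dataclasses import replace as dc_replace

        empty = default_experiment.observations.iloc[0:0]
        exp = dc_replace(default_experiment, observations=empty)
        write_experiment(exp, tmp_path)
        back = read_experiment(tmp_path)
        assert len(back.observations) == 0
        assert list(back.observations.columns) == list(empty.columns)

    def test_composition_table_sums_to_one(self, default_experiment):
        comp = composition_table(default_experiment, groups=("D",))
        assert set(comp.community_id) == {"D1", "D2", "D3"}
        sums = comp.groupby(["community_id", "salinity_pct"]).proportion.sum()
        assert np.allclose(sums, 1.0, atol=1e-9)
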
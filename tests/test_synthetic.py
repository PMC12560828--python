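"""Synthetic-data generators: determinism, model structure, edge cases."""

import numpy as np
import pandas as pd
import pytest

from vialtox.design import AssaySchedule, ScreenDesign, TruthParams
from vialtox.synthetic import (simulate_body_burden, simulate_docking,
                               simulate_lpr, simulate_morphology,
                               write_synthetic_bundle)


class TestDesignTypes:
    def test_concentrations_must_increase_from_zero(self):
        with pytest.raises(ValueError):
            ScreenDesign(concentrations=(0.0, 10.0, 5.0))
        with pytest.raises(ValueError):
            ScreenDesign(concentrations=(1.0, 5.0))

    def test_truth_invariants(self):
        with pytest.raises(ValueError):
            TruthParams(slope_b=-1.0)
        with pytest.raises(ValueError):
            TruthParams(bmc50_true=0.0)
        with pytest.raises(ValueError):
            TruthParams(g=1.0)

    def test_paper_design_defaults(self, design):
        assert design.concentrations == (0.0, 3.125, 6.25, 12.5, 25.0, 50.0)
        assert design.embryos_per_treatment == 32

    def test_schedule_must_tile_window(self):
        with pytest.raises(ValueError):
            AssaySchedule(tracked_window=(0, 100),
                          epochs=(("light", 0, 50), ("dark", 60, 100)))


class TestMorphology:
    def test_seed_reproducibility_byte_identical(self, design):
        truth = TruthParams(sigma_vial=0.4)
        a = simulate_morphology(design, truth, 99)
        b = simulate_morphology(design, truth, 99)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_empirical_rate_at_bmc_matches_curve(self):
        # at d = BMC50: p = g + (1-g)/2 = 0.525
        design = ScreenDesign(concentrations=(0.0, 20.0),
                              vials_per_treatment=1, embryos_per_vial=100_000)
        truth = TruthParams(g=0.05, bmc50_true=20.0, slope_b=4.0,
                            sigma_vial=0.0)
        df = simulate_morphology(design, truth, 4)
        rate = df[df.conc_um == 20.0].response.mean()
        se = np.sqrt(0.525 * 0.475 / 100_000)
        assert abs(rate - 0.525) < 3 * se

    def test_zero_background_controls_all_negative(self, design):
        truth = TruthParams(g=0.0, sigma_vial=2.0)
        df = simulate_morphology(design, truth, 8)
        assert df[df.conc_um == 0.0].response.sum() == 0

    def test_large_n_rates_converge_to_curve(self):
        from conftest import loglogistic_curve

        design = ScreenDesign(vials_per_treatment=1, embryos_per_vial=100_000)
        truth = TruthParams(sigma_vial=0.0)
        df = simulate_morphology(design, truth, 12)
        rates = df.groupby("conc_um").response.mean()
        expected = loglogistic_curve(rates.index.to_numpy())
        np.testing.assert_allclose(rates.to_numpy(), expected, atol=0.006)


class TestLpr:
    def test_reproducible_and_shaped(self, design, schedule):
        truth = TruthParams(lpr_effect=-1.0)
        a = simulate_lpr(design, truth, schedule, 5)
        b = simulate_lpr(design, truth, schedule, 5)
        pd.testing.assert_frame_equal(a, b)
        n_bins = int((1440 - 360) / 6)
        assert len(a) == 6 * 32 * n_bins

    def test_dark_phase_shift_targets_threshold(self, design, schedule):
        truth = TruthParams(lpr_effect=-2.0)
        df = simulate_lpr(design, truth, schedule, 6,
                          effect_threshold_um=25.0)
        dark = df[df.t_start_s.between(540, 719)]
        lo = np.log(dark[dark.conc_um == 0.0].movement).mean()
        hi = np.log(dark[dark.conc_um == 50.0].movement).mean()
        mid = np.log(dark[dark.conc_um == 12.5].movement).mean()
        assert hi < lo - 1.0 and abs(mid - lo) < 0.5

    def test_full_exclusion_triggers_treatment_removal(self, design, schedule):
        from vialtox.lpr import apply_exclusions

        truth = TruthParams()
        df = simulate_lpr(design, truth, schedule, 7, exclusion_prob=1.0)
        retained, removed = apply_exclusions(df)
        assert retained.empty and len(removed) == 6


class TestBodyBurden:
    def test_noise_free_roundtrip_recovers_uptake(self):
        from vialtox.burden import body_burden_table

        truths = {"naphthalene": TruthParams(uptake_true=0.1303,
                                             measurement_cv=0.0)}
        df = simulate_body_burden(["naphthalene"], truths, 1,
                                  timepoints=(24,), n_replicates=2)
        tab = body_burden_table(df)
        np.testing.assert_allclose(tab.uptake_ratio, 0.1303, rtol=1e-12)

    def test_t_test_calibration_between_identical_truths(self):
        from vialtox.stats import student_t_two_sided

        truths = {"naphthalene": TruthParams(uptake_true=0.1,
                                             measurement_cv=0.1)}
        rej = 0
        reps = 400
        for s in range(reps):
            df = simulate_body_burden(["naphthalene"], truths, s,
                                      timepoints=(24, 48), reduction_48h=0.0)
            a = df[df.timepoint_hpf == 24].ng_per_mL
            b = df[df.timepoint_hpf == 48].ng_per_mL
            if student_t_two_sided(a, b).p_value <= 0.05:
                rej += 1
        assert rej / reps == pytest.approx(0.05, abs=0.035)


class TestDocking:
    def test_planted_protein_ranks_first_when_shift_dominates(self):
        from vialtox.docking import rank_proteins, reduce_min_energy

        chems = [f"c{i}" for i in range(5)]
        prots = [f"P{i}" for i in range(10)]
        df = simulate_docking(chems, prots, planted=["P3"], seed=2,
                              sigma=0.3, planted_shift=-8.0)
        ranks = rank_proteins(reduce_min_energy(df))
        assert (ranks["P3"] == 1).all()

    def test_single_pocket_reduction_is_identity(self):
        from vialtox.docking import reduce_min_energy

        df = simulate_docking(["c"], ["P1", "P2"], seed=3, n_pockets=1,
                              methods=("sequence",))
        mins = reduce_min_energy(df)
        merged = mins.merge(df, on=["chemical", "protein"],
                            suffixes=("_min", ""))
        np.testing.assert_allclose(merged.energy_kcal_mol_min,
                                   merged.energy_kcal_mol)

    def test_null_top10_membership_roughly_uniform(self):
        from vialtox.docking import rank_proteins, reduce_min_energy, \
            top_k_membership

        chems = [f"c{i}" for i in range(8)]
        prots = [f"P{i:02d}" for i in range(40)]
        hits = np.zeros(len(prots))
        for s in range(20):
            df = simulate_docking(chems, prots, seed=s)
            ranks = rank_proteins(reduce_min_energy(df))
            _, member = top_k_membership(ranks, 10)
            for p in member.columns:
                hits[prots.index(p)] += member[p].sum()
        # each protein has expected membership 8*20*10/40 = 40
        assert hits.mean() == pytest.approx(40, rel=0.05)
        assert hits.std() < 20

    def test_pocketless_rejected(self):
        with pytest.raises(ValueError):
            simulate_docking(["c"], ["P"], n_pockets=0)


class TestBundle:
    def test_bundle_writes_all_tables_and_manifest(self, tmp_path):
        truths = {"naphthalene": TruthParams()}
        manifest = write_synthetic_bundle(tmp_path, ["naphthalene"], truths,
                                          17)
        for name in manifest["tables"]:
            assert (tmp_path / name).exists()
        assert manifest["seed"] == 17
        assert (tmp_path / "manifest.json").exists()

    def test_bundle_deterministic(self, tmp_path):
        truths = {"naphthalene": TruthParams()}
        write_synthetic_bundle(tmp_path / "a", ["naphthalene"], truths, 23)
        write_synthetic_bundle(tmp_path / "b", ["naphthalene"], truths, 23)
        for name in ("morphology.csv", "traces.csv", "body_burden.csv",
                     "docking.csv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()
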
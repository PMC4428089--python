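"""Phantom generator: geometry, ground-truth sidecar, cohort simulation."""

import numpy as np
import pytest

from lungmorph import (CohortSimSpec, PhantomSpec, make_breath_pair,
                       phantom_truth, reconstruct_dense, simulate_cohort,
                       sparsify, spearman)
from lungmorph.phantom import PhantomSizingError
from lungmorph.pft import derive_columns


class TestBreathPairGeometry:
    def test_zero_displacement_gives_identical_phases(self):
        spec = PhantomSpec(lung_semi_axes=(30, 40, 60),
                           diaphragm_displacement=0.0,
                           ap_expansion=1.0, lr_expansion=1.0,
                           spacing=(2, 2, 2), shape="cuboid")
        pair, truth = make_breath_pair(spec)
        assert np.array_equal(pair.inspiration.grid, pair.expiration.grid)
        assert truth.volume_ratio == 1.0

    def test_cuboid_box_arithmetic(self, cuboid_pair):
        pair, truth = cuboid_pair
        # 100x150x200 mm box displaced 50 mm caudally
        assert truth.median_chords_exp == {"LR": 100, "AP": 150, "CC": 200}
        assert truth.median_chords_insp["CC"] == 250
        assert truth.volume_ratio == pytest.approx(1.25)
        # voxelized inspiration CC extent
        cc_any = pair.inspiration.grid.any(axis=(0, 1))
        extent = cc_any.sum() * pair.inspiration.spacing[2]
        assert extent == pytest.approx(250.0, abs=1.5)

    def test_dome_cc_ratio_closed_form(self):
        spec = PhantomSpec(lung_semi_axes=(40, 60, 100),
                           diaphragm_displacement=40.0, shape="dome",
                           ap_expansion=1.0, lr_expansion=1.0)
        truth = phantom_truth(spec)
        assert truth.ratios["CC"] == pytest.approx(1 + 40 * np.sqrt(2) / 100)

    def test_dome_cc_median_matches_chord_cdf_integration(self):
        # independent oracle: dense sampling of the chord-length
        # distribution L(u) = d + c*sqrt(1-u), u uniform on [0,1)
        c, d = 100.0, 40.0
        u = (np.arange(200_000) + 0.5) / 200_000
        for disp in (0.0, d):
            chords = disp + c * np.sqrt(1 - u)
            spec = PhantomSpec(lung_semi_axes=(40, 60, c),
                               diaphragm_displacement=disp, shape="dome")
            truth = phantom_truth(spec)
            assert truth.median_chords_insp["CC"] == pytest.approx(
                np.median(chords), rel=1e-4)

    def test_seed_determinism_bit_identical(self):
        spec = PhantomSpec(noise_amplitude=1.0, seed=11,
                           spacing=(3, 3, 3))
        p1, _ = make_breath_pair(spec)
        p2, _ = make_breath_pair(spec)
        assert np.array_equal(p1.inspiration.grid, p2.inspiration.grid)
        assert np.array_equal(p1.expiration.grid, p2.expiration.grid)
        p3, _ = make_breath_pair(PhantomSpec(noise_amplitude=1.0, seed=12,
                                             spacing=(3, 3, 3)))
        assert not np.array_equal(p1.expiration.grid, p3.expiration.grid)

    def test_voxel_volume_converges_to_analytic(self):
        errs = []
        for s in (3.7, 0.9):
            spec = PhantomSpec(lung_semi_axes=(40, 60, 100),
                               diaphragm_displacement=30.0,
                               spacing=(s, s, s), shape="dome")
            pair, truth = make_breath_pair(spec)
            measured = pair.expiration.volume_ml / 2.0  # two lungs
            errs.append(abs(measured - truth.volume_exp_ml)
                        / truth.volume_exp_ml)
        assert errs[1] < errs[0]
        assert errs[1] < 0.01

    @pytest.mark.parametrize("bad", [
        dict(lung_semi_axes=(0, 40, 60)),
        dict(spacing=(1.4, 0.0, 1.5)),
        dict(shape="sphere"),
        dict(ap_expansion=-1.0),
        dict(shape="dome", diaphragm_displacement=-5.0),
        dict(noise_amplitude=-1.0),
    ])
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(ValueError):
            PhantomSpec(**bad)

    def test_explicit_grid_too_small(self):
        with pytest.raises(PhantomSizingError):
            make_breath_pair(PhantomSpec(grid_shape=(10, 10, 10)))


class TestSparsify:
    def test_step_one_roundtrip_is_identity(self, cuboid_pair):
        pair, _ = cuboid_pair
        rec = reconstruct_dense(sparsify(pair.expiration, 1))
        assert np.array_equal(rec.grid, pair.expiration.grid)

    def test_step_two_keeps_even_slices_verbatim(self):
        from lungmorph import MaskVolume
        rng = np.random.default_rng(0)
        grid = rng.random((5, 6, 9)) > 0.5
        grid[2, 3, :] = True  # ensure non-empty
        mask = MaskVolume(grid, (1, 1, 1))
        ann = sparsify(mask, 2)
        assert ann.indices == [0, 2, 4, 6, 8]
        for i in ann.indices:
            assert np.array_equal(ann.slices[i], grid[:, :, i])

    def test_invalid_inputs(self, cuboid_pair):
        pair, _ = cuboid_pair
        with pytest.raises(ValueError):
            sparsify(pair.expiration, 0)
        from lungmorph import MaskVolume
        with pytest.raises(ValueError):
            sparsify(MaskVolume(np.zeros((4, 4, 4), bool), (1, 1, 1)), 2)

    def test_step_two_reconstruction_volume_close(self, dome_pair):
        pair, _ = dome_pair
        for phase in (pair.inspiration, pair.expiration):
            rec = reconstruct_dense(sparsify(phase, 2))
            err = abs(rec.grid.sum() - phase.grid.sum()) / phase.grid.sum()
            assert err < 0.02


class TestCohortSimulation:
    def test_same_seed_identical_cohort(self):
        spec = CohortSimSpec(seed=5)
        a = simulate_cohort(spec, make_phantoms=False).table
        b = simulate_cohort(spec, make_phantoms=False).table
        assert a.equals(b)

    def test_zero_noise_monotone_link_gives_perfect_spearman(self):
        sim = simulate_cohort(CohortSimSpec(noise_sd=0.0, seed=2),
                              make_phantoms=False)
        pat = sim.table[sim.table.group == "patient"]
        res = spearman(pat["cc_ratio_true"], pat["fvc_supine_pct"])
        assert res.r == pytest.approx(1.0)

    def test_group_structure(self):
        sim = simulate_cohort(CohortSimSpec(n_patients=4, n_controls=3,
                                            seed=1), make_phantoms=False)
        assert (sim.table.group == "patient").sum() == 4
        assert (sim.table.group == "control").sum() == 3
        assert sim.table.subject_id.is_unique

    def test_null_generator_mann_whitney_calibration(self):
        # equal group means: exact test at alpha=0.05 must reject at
        # approximately (at most, by discreteness) the nominal rate
        from lungmorph import mann_whitney
        rej = 0
        reps = 600
        for rep in range(reps):
            sim = simulate_cohort(
                CohortSimSpec(cc_ratio_means=(1.5, 1.5), seed=50_000 + rep),
                make_phantoms=False)
            t = sim.table
            p = mann_whitney(t[t.group == "patient"]["cc_ratio_true"],
                             t[t.group == "control"]["cc_ratio_true"]).p_value
            rej += p < 0.05
        assert 0.02 <= rej / reps <= 0.08

    def test_phantom_truth_matches_drawn_ratio(self):
        sim = simulate_cohort(CohortSimSpec(n_patients=2, n_controls=2,
                                            seed=9))
        for _, row in sim.table.iterrows():
            truth = sim.pairs[row.subject_id][1]
            assert truth.ratios["CC"] == pytest.approx(row.cc_ratio_true,
                                                       abs=1e-9)

    def test_weakness_structure_of_default_cohort(self):
        # weak-diaphragm patients should mostly flag postural drops
        sim = simulate_cohort(CohortSimSpec(seed=4), make_phantoms=False)
        df = derive_columns(sim.table)
        pat = df[df.group == "patient"]
        ctl = df[df.group == "control"]
        assert pat["delta_fvc_pct"].median() > ctl["delta_fvc_pct"].median()
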
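"""Phantom generator: determinism, calibration, analytic occupancy oracle."""

import dataclasses

import numpy as np
import pytest

from iansegmap import (
    CohortDistributions,
    PhantomParams,
    generate_cohort,
    generate_subject_side,
    truth_occupancy,
    truth_reference_slice,
)
from iansegmap.errors import ParameterError
from iansegmap.phantom import rasterize_truth_masks


class TestGenerateSubjectSide:
    def test_same_seed_bitwise_identical(self):
        p = PhantomParams(seed=3)
        mri1, cbct1, t1 = generate_subject_side(p)
        mri2, cbct2, t2 = generate_subject_side(PhantomParams(seed=3))
        assert np.array_equal(mri1.data, mri2.data)
        assert np.array_equal(cbct1.data, cbct2.data)
        assert t1.true_diameters == t2.true_diameters

    def test_noiseless_centered_nerve_contrast(self):
        p = PhantomParams(noise_sd=0.0, nerve_offset=(0.0, 0.0))
        mri, cbct, truth = generate_subject_side(p)
        # nerve center is hyperintense relative to canal interior on every slice
        col = int(truth.nerve_center_mm[0] / p.mri_spacing)
        row = int(truth.nerve_center_mm[1] / p.mri_spacing)
        edge_val = mri.data[:, 1, 1]  # bone background corner
        assert (mri.data[:, row, col] > edge_val + 0.2).all()
        # CBCT never shows the nerve: interior is flat around the nerve position
        ccol = int(truth.nerve_center_mm[0] / p.cbct_spacing)
        crow = int(truth.nerve_center_mm[1] / p.cbct_spacing)
        patch = cbct.data[0, crow - 2 : crow + 3, ccol - 2 : ccol + 3]
        assert np.ptp(patch) < 1e-6

    def test_calibrated_coronal_canal_diameter(self):
        """Canal semiaxes (1.95, 2.65) give a 5.3 mm coronal CBCT diameter."""
        p = PhantomParams(canal_semiaxes=(1.95, 2.65), noise_sd=0.0)
        _, _, truth = generate_subject_side(p)
        assert truth.true_diameters[("IAC", "CBCT", "coronal")] == pytest.approx(5.3)
        # MRI canal carries the modality scale
        sa, sb = p.modality_scale
        assert truth.true_diameters[("IAC", "MRI", "coronal")] == pytest.approx(
            2 * 2.65 * sb
        )

    def test_modality_consistency_of_canal_masks(self):
        """CBCT and rescaled-MRI canal rasters agree to Dice >= 0.99."""
        p = PhantomParams(noise_sd=0.0)
        _, _, truth = generate_subject_side(p)
        h = 0.05
        cb_mask, _ = rasterize_truth_masks(truth, "CBCT", spacing=h)
        mri_mask, _ = rasterize_truth_masks(truth, "MRI", spacing=h)
        # sample the MRI mask at CBCT-grid points mapped through modality_scale
        xc, yc = truth.canal_center_mm
        sa, sb = p.modality_scale
        ny, nx = cb_mask.shape
        X, Y = np.meshgrid((np.arange(nx) + 0.5) * h, (np.arange(ny) + 0.5) * h)
        cols = np.clip(((xc + (X - xc) * sa) / h).astype(int), 0, mri_mask.shape[1] - 1)
        rows = np.clip(((yc + (Y - yc) * sb) / h).astype(int), 0, mri_mask.shape[0] - 1)
        rescaled = mri_mask[rows, cols]
        dice = 2 * (cb_mask & rescaled).sum() / (cb_mask.sum() + rescaled.sum())
        assert dice >= 0.99

    def test_invalid_params_name_the_invariant(self):
        with pytest.raises(ParameterError, match="does not fit inside the canal"):
            PhantomParams(nerve_offset=(1.5, 0.0))
        with pytest.raises(ParameterError, match="spacings"):
            PhantomParams(mri_spacing=0.0)
        with pytest.raises(ParameterError, match="n_slices"):
            PhantomParams(n_slices=0)

    def test_protruding_flag_overrides_fit_invariant(self):
        p = PhantomParams(nerve_offset=(1.5, 0.0), allow_protruding=True)
        generate_subject_side(p)  # does not raise


class TestTruthOccupancy:
    def test_nerve_filling_canal_gives_all_ones(self):
        p = PhantomParams(
            canal_semiaxes=(2.0, 2.6),
            modality_scale=(1.0, 1.0),
            nerve_semiaxes=(2.0, 2.6),
            nerve_offset=(0.0, 0.0),
            noise_sd=0.0,
        )
        _, _, truth = generate_subject_side(p)
        occ = truth_occupancy(truth)
        assert np.allclose(occ.fractions, 1.0)
        assert occ.visible.all()

    def test_point_nerve_vanishing_occupancy(self):
        """An epsilon nerve occupies only the middle segments, vanishingly.

        The midline passes through the nerve midpoint by construction, so a
        disk of any positive radius straddles the upper/lower middle pair;
        no other segment may receive signal and the fractions tend to zero.
        """
        p = PhantomParams(nerve_semiaxes=(0.02, 0.02), nerve_offset=(0.4, 0.3),
                          noise_sd=0.0)
        _, _, truth = generate_subject_side(p)
        occ = truth_occupancy(truth, n_grid=2500)
        nonzero = set(np.flatnonzero(occ.fractions > 0) + 1)
        assert nonzero and nonzero <= {2, 5}
        assert occ.fractions.max() < 0.005

    def test_area_weighted_sum_equals_nerve_area(self):
        p = PhantomParams(noise_sd=0.0)
        _, _, truth = generate_subject_side(p)
        occ = truth_occupancy(truth)
        nerve_area = np.pi * np.prod(truth.nerve_semiaxes_mm)
        total = float(np.sum(occ.fractions * occ.segment_areas_mm2))
        assert total == pytest.approx(nerve_area, rel=0.01)

    def test_half_semiaxis_disk_matches_independent_quadrature(self):
        """Centered nerve at half the canal semiaxes vs a jittered-grid count."""
        p = PhantomParams(
            canal_semiaxes=(2.0, 2.6),
            modality_scale=(1.0, 1.0),
            nerve_semiaxes=(1.0, 1.3),
            nerve_offset=(0.0, 0.0),
            noise_sd=0.0,
        )
        _, _, truth = generate_subject_side(p)
        occ = truth_occupancy(truth)
        oracle = _jittered_quadrature(truth, n=1200, seed=0)
        assert np.abs(occ.fractions - oracle).max() < 0.01

    def test_quadrature_refinement_is_stable(self):
        _, _, truth = generate_subject_side(PhantomParams(noise_sd=0.0))
        coarse = truth_occupancy(truth, n_grid=600)
        fine = truth_occupancy(truth, n_grid=2400)
        assert np.abs(coarse.fractions - fine.fractions).max() < coarse.tolerance_estimate


def _jittered_quadrature(truth, n, seed):
    """Independent membership count over >= 10^6 jittered sample points."""
    rng = np.random.default_rng(seed)
    A, B = truth.canal_semiaxes_mm["MRI"]
    xc, yc = truth.canal_center_mm
    nx0, ny0 = truth.nerve_center_mm
    na, nb = truth.nerve_semiaxes_mm
    gx = xc - A + (np.arange(n) + rng.random(n)) * (2 * A / n)
    gy = yc - B + (np.arange(n) + rng.random(n)) * (2 * B / n)
    X, Y = np.meshgrid(gx, gy)
    in_canal = ((X - xc) / A) ** 2 + ((Y - yc) / B) ** 2 <= 1
    in_nerve = ((X - nx0) / na) ** 2 + ((Y - ny0) / nb) ** 2 <= 1
    # the analytic construction: baseline horizontal, chord through the canal
    t_half = A * np.sqrt(max(0.0, 1 - ((ny0 - yc) / B) ** 2))
    t_lo, t_hi = (xc - t_half) - nx0, (xc + t_half) - nx0
    sgn = 1.0 if truth.side == "left" else -1.0
    t = sgn * (X - nx0)
    tl, th = (t_lo, t_hi) if sgn > 0 else (-t_hi, -t_lo)
    c1, c2 = tl + (th - tl) / 3, tl + 2 * (th - tl) / 3
    s = ny0 - Y  # superior positive
    seg = np.where(s > 0, 1, 4) + np.where(t > c2, 0, np.where(t < c1, 2, 1))
    seg[~in_canal] = 0
    counts = np.bincount(seg.ravel(), minlength=7)[1:7]
    hits = np.bincount(seg.ravel(), weights=(in_nerve & in_canal).ravel(), minlength=7)[1:7]
    return hits / np.maximum(counts, 1)


class TestGenerateCohort:
    def test_fixed_seed_reproducible(self):
        c1 = generate_cohort(5, seed=9)
        c2 = generate_cohort(5, seed=9)
        assert len(c1) == len(c2)
        for a, b in zip(c1, c2):
            assert a.subject_id == b.subject_id and a.side == b.side
            assert np.array_equal(a.mri.data, b.mri.data)

    def test_design_scale_19_subjects(self):
        """19 subjects with 1/19 missing-side probability: ~36 nerves."""
        cohort = generate_cohort(19, seed=1)
        assert 30 <= len(cohort) <= 38
        assert len({s.subject_id for s in cohort}) <= 19
        for ss in cohort:
            assert ss.truth.retention_label in CohortDistributions().retention_labels

    def test_zero_variance_sides_mirror(self):
        dists = CohortDistributions(
            canal_bl=(1.95, 0.0), canal_si=(2.65, 0.0), nerve_bl=(1.3, 0.0),
            nerve_si=(2.05, 0.0), offset_bl=(0.5, 0.0), offset_si=(0.2, 0.0),
            crest_height=(15.0, 0.0), noise_sd=0.0, asymmetry_sd=0.0,
            missing_side_prob=0.0,
        )
        cohort = generate_cohort(1, dists=dists, seed=0)
        assert [s.side for s in cohort] == ["left", "right"]
        left, right = cohort
        assert np.array_equal(left.mri.data, right.mri.data[:, :, ::-1])

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(ParameterError, match="sd must be >= 0"):
            generate_cohort(2, dists=CohortDistributions(canal_bl=(1.95, -0.1)))

    def test_nerve_always_fits_sampled_canal(self):
        for ss in generate_cohort(8, seed=4):
            p = ss.truth.params
            ea, eb = p.canal_semiaxes_for("min")
            assert abs(p.nerve_offset[0]) + p.nerve_semiaxes[0] <= ea + 1e-9
            assert abs(p.nerve_offset[1]) + p.nerve_semiaxes[1] <= eb + 1e-9


def test_reference_slice_carries_truth_landmarks(noiseless_subject):
    _, _, truth = noiseless_subject
    slc = truth_reference_slice(truth, site="M2", spacing=0.1)
    assert slc.site == "M2"
    assert slc.nerve_midpoint_mm == truth.nerve_center_mm
    assert slc.iac_mask.any()
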
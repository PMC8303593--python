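"""Occupancy scoring, hyperintensity extraction and co-occurrence tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iansegmap import (
    OccupancyRecord,
    PhantomParams,
    build_cooccurrence,
    build_partition,
    extract_nerve_mask,
    generate_subject_side,
    score_occupancy,
    stratify,
    truth_occupancy,
    truth_reference_slice,
)
from iansegmap.errors import InputError, SegmentationError, ShapeError
from iansegmap.geometry import Line, SegmentPartition
from iansegmap.phantom import rasterize_truth_masks


def rectangle_partition(seg_rows=4, seg_cols=5):
    """A toy partition of six equal rectangles (2 bands x 3 columns)."""
    label_map = np.zeros((2 * seg_rows, 3 * seg_cols), dtype=np.int8)
    for band in range(2):
        for col in range(3):
            label_map[
                band * seg_rows : (band + 1) * seg_rows,
                col * seg_cols : (col + 1) * seg_cols,
            ] = band * 3 + col + 1
    line = Line((0.0, 0.0), (1.0, 0.0))
    return SegmentPartition(
        label_map=label_map, spacing=(1.0, 1.0), side="left",
        baseline=line, midline=line, perpendicular_1=line, perpendicular_2=line,
        buccal_direction=(1.0, 0.0), chord_mm=(0.0, 1.0),
    )


class TestScoreOccupancy:
    def test_full_and_empty_nerve(self):
        part = rectangle_partition()
        full = score_occupancy(part, part.label_map > 0)
        assert np.allclose(full.fractions, 1.0) and full.visible.all()
        empty = score_occupancy(part, np.zeros_like(part.label_map, bool))
        assert np.allclose(empty.fractions, 0.0) and not empty.visible.any()

    def test_exactly_half_is_visible(self):
        """The rule is inclusive: half or more than half counts as visible."""
        part = rectangle_partition(seg_rows=4, seg_cols=5)
        nerve = np.zeros_like(part.label_map, bool)
        nerve[:2, :5] = True  # exactly half of segment 1
        rec = score_occupancy(part, nerve, threshold=0.5)
        assert rec.fractions[0] == 0.5
        assert rec.visible[0]

    def test_grid_mismatch_rejected(self):
        part = rectangle_partition()
        with pytest.raises(ShapeError):
            score_occupancy(part, np.zeros((3, 3), bool))

    def test_empty_segment_flagged_as_zero(self):
        part = rectangle_partition()
        part.label_map[part.label_map == 6] = 5  # segment 6 has no pixels
        rec = score_occupancy(part, part.label_map > 0)
        assert rec.empty_segments[5]
        assert rec.fractions[5] == 0.0 and not rec.visible[5]

    def test_phantom_fractions_match_quadrature_oracle(self):
        params = PhantomParams(noise_sd=0.0, nerve_offset=(0.3, 0.4))
        _, _, truth = generate_subject_side(params)
        oracle = truth_occupancy(truth)
        slc = truth_reference_slice(truth, spacing=0.05)
        part = build_partition(slc)
        _, nerve = rasterize_truth_masks(truth, "MRI", spacing=0.05)
        rec = score_occupancy(part, nerve)
        assert np.abs(rec.fractions - oracle.fractions).max() <= 0.02

    @given(st.floats(0.05, 0.95), st.floats(0.05, 0.95))
    @settings(max_examples=30, deadline=None)
    def test_threshold_monotonicity(self, t1, t2):
        """Raising the threshold never increases any visible count."""
        lo, hi = sorted((t1, t2))
        part = rectangle_partition()
        rng = np.random.default_rng(7)
        nerve = rng.random(part.label_map.shape) < 0.5
        v_lo = score_occupancy(part, nerve, threshold=lo).visible
        v_hi = score_occupancy(part, nerve, threshold=hi).visible
        assert v_hi.sum() <= v_lo.sum()
        assert not (v_hi & ~v_lo).any()


class TestExtractNerveMask:
    def test_noiseless_phantom_dice(self):
        params = PhantomParams(noise_sd=0.0)
        _, _, truth = generate_subject_side(params)
        slc = truth_reference_slice(truth)
        _, true_nerve = rasterize_truth_masks(truth, "MRI")
        mask = extract_nerve_mask(slc)
        dice = 2 * (mask & true_nerve).sum() / (mask.sum() + true_nerve.sum())
        assert dice >= 0.95

    def test_uniform_canal_raises(self):
        params = PhantomParams(noise_sd=0.0, nerve_semiaxes=(0.0, 0.0))
        _, _, truth = generate_subject_side(params)
        slc = truth_reference_slice(truth)
        with pytest.raises(SegmentationError, match="contrast"):
            extract_nerve_mask(slc)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_snr10_recovers_area_within_10pct(self, seed):
        # nerve-to-interior contrast is 0.55; SNR 10 => noise sd 0.055
        params = PhantomParams(noise_sd=0.0, seed=seed)
        _, _, truth = generate_subject_side(params)
        rng = np.random.default_rng(seed)
        slc = truth_reference_slice(truth, spacing=0.2, noise_sd=0.055, rng=rng)
        _, true_nerve = rasterize_truth_masks(truth, "MRI", spacing=0.2)
        mask = extract_nerve_mask(slc)
        assert abs(mask.sum() - true_nerve.sum()) <= 0.10 * true_nerve.sum()


def make_records(patterns, site="M3", labels=None):
    recs = []
    for i, pat in enumerate(patterns):
        vis = np.asarray(pat, bool)
        recs.append(
            OccupancyRecord(
                subject_id=f"S{i}", side="left", site=site,
                fractions=vis.astype(float), visible=vis,
                retention_label=(labels[i] if labels else "unknown"),
            )
        )
    return recs


class TestCooccurrence:
    def test_all_visible_gives_100_everywhere(self):
        t = build_cooccurrence(make_records([[1] * 6] * 4), "M3")
        assert np.allclose(t.marginal, 100.0)
        off_diag = t.conditional[~np.eye(6, dtype=bool)]
        assert np.allclose(off_diag, 100.0)

    def test_hand_enumerated_example(self):
        patterns = [[1, 1, 0, 0, 0, 0]] * 3 + [[1, 0, 0, 0, 0, 0]]
        t = build_cooccurrence(make_records(patterns), "M3")
        assert t.marginal[0] == 100.0
        assert t.marginal[1] == 75.0
        assert t.conditional[0, 1] == 75.0  # If segment 1 yes -> segment 2
        assert t.conditional[1, 0] == 100.0  # If segment 2 yes -> segment 1

    def test_joint_count_symmetry_on_random_cohorts(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pats = rng.random((rng.integers(2, 30), 6)) < rng.random(6)
            t = build_cooccurrence(make_records(pats.astype(int).tolist()), "M3")
            n_i = np.diag(t.counts)
            for i in range(6):
                for j in range(6):
                    if i == j:
                        continue
                    lhs = n_i[i] * (t.conditional[i, j] if n_i[i] else 0.0)
                    rhs = n_j = n_i[j] * (t.conditional[j, i] if n_i[j] else 0.0)
                    if n_i[i] and n_i[j]:
                        assert lhs == pytest.approx(rhs)
                        assert lhs == pytest.approx(100.0 * t.counts[i, j])

    def test_zero_count_rows_undefined(self):
        t = build_cooccurrence(make_records([[0, 1, 0, 0, 0, 0]]), "M3")
        assert np.isnan(t.conditional[0]).all()
        assert np.isnan(np.diag(t.conditional)).all()

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            build_cooccurrence([], "M3")
        with pytest.raises(InputError, match="not at site"):
            build_cooccurrence(make_records([[1] * 6], site="M2"), "M3")

    def test_table_frame_layout(self):
        df = build_cooccurrence(make_records([[1] * 6] * 3), "M3").to_frame()
        assert list(df.index) == ["Generally Yes"] + [
            f"If Segment {i} Yes" for i in range(1, 7)
        ]
        assert (df["n"] == 3).all()


class TestStratify:
    def test_single_stratum_equals_pooled(self):
        recs = make_records([[1, 0, 1, 0, 1, 0]] * 5, labels=["type4"] * 5)
        tables = stratify(recs, "M3")
        assert np.array_equal(tables["pooled"].counts, tables["type4"].counts)

    def test_pooled_counts_are_sum_of_strata(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = int(rng.integers(4, 25))
            pats = (rng.random((n, 6)) < 0.6).astype(int).tolist()
            labels = [str(rng.choice(["a", "b", "c"])) for _ in range(n)]
            tables = stratify(make_records(pats, labels=labels), "M3")
            strata = [t for k, t in tables.items() if k != "pooled"]
            assert np.array_equal(
                tables["pooled"].counts, sum(t.counts for t in strata)
            )

    def test_by_none_returns_only_pooled(self):
        tables = stratify(make_records([[1] * 6]), "M3", by="none")
        assert list(tables) == ["pooled"]
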
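"""3D nucleus segmentation, hull-constrained spot detection, zone stats."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import match_foci
from meioquant import (
    SimulationConfig,
    compare_zone_counts,
    counts_by_zone,
    detect_foci,
    double_focus_test,
    render_image_stack,
    segment_nuclei,
)
from meioquant.foci import NucleusRegion, SpotDetectionResult, apply_overrides, zone_summary

VOXEL = (0.125, 0.1, 0.1)


def _ellipsoid_stack(shape=(24, 40, 40), center=(12, 20, 20), radii=(8, 12, 12), value=100.0):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    mask = (
        ((zz - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((xx - center[2]) / radii[2]) ** 2
    ) <= 1
    stack = np.zeros(shape)
    stack[mask] = value
    return stack


class TestSegmentNuclei:
    def test_single_ellipsoid_yields_one_nucleus_at_truth(self):
        stack = _ellipsoid_stack()
        labels, regions, flagged = segment_nuclei(stack, VOXEL)
        assert len(regions) == 1 and not flagged
        expected = ((12 + 0.5) * 0.125, (20 + 0.5) * 0.1, (20 + 0.5) * 0.1)
        assert np.allclose(regions[0].centroid_um, expected, atol=max(VOXEL))

    def test_constant_stack_segments_nothing(self):
        labels, regions, flagged = segment_nuclei(np.zeros((5, 5, 5)), VOXEL)
        assert len(regions) == 0 and labels.max() == 0

    def test_undersized_component_is_flagged_not_returned(self):
        stack = np.zeros((10, 20, 20))
        stack[5, 10, 10] = 100.0  # single bright voxel: far below min volume
        labels, regions, flagged = segment_nuclei(stack, VOXEL, threshold=50.0)
        assert regions == [] and len(flagged) == 1

    def test_rejects_non_3d_input(self):
        with pytest.raises(ValueError):
            segment_nuclei(np.zeros((5, 5)), VOXEL)

    def test_rendered_field_recovers_all_nuclei(self, rendered_field, detection_result):
        _, _, nucleus_truth, _, _ = rendered_field
        nuclei, _ = detection_result
        assert len(nuclei) >= len(nucleus_truth) - 2
        truth = nucleus_truth[["z_um", "y_um", "x_um"]].to_numpy()
        cents = np.array([n.centroid_um for n in nuclei])
        for t in truth:
            assert np.min(np.linalg.norm(cents - t, axis=1)) < 0.5


class TestDetectFoci:
    def test_no_signal_no_foci(self):
        dapi = _ellipsoid_stack()
        _, regions, _ = segment_nuclei(dapi, VOXEL)
        result = detect_foci(np.zeros(dapi.shape), regions, VOXEL)
        assert len(result.foci) == 0

    def test_single_focus_assigned_to_its_nucleus(self):
        from meioquant.simulate import _add_gaussian_spot

        dapi = _ellipsoid_stack()
        _, regions, _ = segment_nuclei(dapi, VOXEL)
        signal = np.zeros(dapi.shape)
        pos = ((12 + 0.5) * 0.125, (20 + 0.5) * 0.1, (20 + 0.5) * 0.1)
        _add_gaussian_spot(signal, pos, (0.3, 0.13, 0.13), VOXEL, 150.0)
        result = detect_foci(signal, regions, VOXEL)
        assert len(result.foci) == 1
        assert int(result.foci.nucleus_id.iloc[0]) == regions[0].nucleus_id

    def test_spot_outside_every_hull_is_discarded(self):
        from meioquant.simulate import _add_gaussian_spot

        dapi = _ellipsoid_stack()
        _, regions, _ = segment_nuclei(dapi, VOXEL)
        signal = np.zeros(dapi.shape)
        _add_gaussian_spot(signal, (0.3, 0.3, 0.3), (0.3, 0.13, 0.13), VOXEL, 150.0)
        result = detect_foci(signal, regions, VOXEL)
        assert len(result.foci) == 0

    def test_precision_and_recall_on_rendered_field(self, rendered_field, detection_result):
        _, _, _, focus_truth, _ = rendered_field
        _, result = detection_result
        det = result.foci[["z_um", "y_um", "x_um"]].to_numpy()
        tru = focus_truth[["z_um", "y_um", "x_um"]].to_numpy()
        tp = match_foci(det, tru, radius_um=0.3)
        assert tp / len(tru) >= 0.95  # recall
        assert tp / len(det) >= 0.95  # precision

    def test_every_reported_focus_inside_its_nucleus_hull(self, detection_result):
        from meioquant.foci import _NucleusHull

        nuclei, result = detection_result
        hulls = {n.nucleus_id: _NucleusHull(n.coords_vox, result.params_used["voxel_size_um"])
                 for n in nuclei}
        for row in result.foci.itertuples():
            assert hulls[int(row.nucleus_id)].contains((row.z_um, row.y_um, row.x_um))

    def test_detection_translation_equivariant(self):
        cfg = SimulationConfig(seed=5, noise_rate=0.0)
        stacks, _, _ = render_image_stack(cfg, n_nuclei=4, mean_foci_per_nucleus=3)
        voxel = tuple(v / 1000 for v in cfg.voxel_size)
        shift = (2, 3, 4)

        def run(dapi, signal):
            _, regions, _ = segment_nuclei(dapi, voxel)
            res = detect_foci(signal, regions, voxel)
            return res.foci[["z_um", "y_um", "x_um"]].to_numpy()

        base = run(stacks["dapi"], stacks["signal"])
        pad = [(s, 0) for s in shift]
        shifted = run(
            np.pad(stacks["dapi"], pad)[: stacks["dapi"].shape[0] + shift[0]],
            np.pad(stacks["signal"], pad)[: stacks["signal"].shape[0] + shift[0]],
        )
        offset = np.array(shift) * np.array(voxel)
        base_sorted = base[np.lexsort(base.T)]
        shifted_sorted = shifted[np.lexsort(shifted.T)] - offset
        assert np.allclose(base_sorted, shifted_sorted, atol=1e-9)

    def test_parameters_echoed_for_provenance(self, detection_result):
        _, result = detection_result
        assert set(result.params_used) >= {"sigma_um", "abs_threshold", "min_distance_um"}


def _synthetic_result(axial_positions, counts):
    """Build a SpotDetectionResult without images."""
    nuclei = [
        NucleusRegion(
            nucleus_id=i + 1,
            centroid_um=(1.0, 1.0, pos * 10),
            volume_um3=10.0,
            coords_vox=np.zeros((4, 3), dtype=int),
            axial_pos=pos,
        )
        for i, pos in enumerate(axial_positions)
    ]
    rows = []
    for nuc, c in zip(nuclei, counts):
        rows += [{"nucleus_id": nuc.nucleus_id, "z_um": 0, "y_um": 0, "x_um": 0,
                  "peak_intensity": 1.0}] * c
    foci = pd.DataFrame(rows, columns=["nucleus_id", "z_um", "y_um", "x_um", "peak_intensity"])
    return SpotDetectionResult(nuclei=nuclei, foci=foci, params_used={})


class TestCountsByZone:
    def test_all_zero_counts(self):
        res = _synthetic_result([0.1, 0.5, 0.9], [0, 0, 0])
        zones = counts_by_zone(res, n_zones=7)
        assert all(all(c == 0 for c in v) for v in zones.values())

    def test_midpoint_position_lands_in_zone_three_of_seven(self):
        res = _synthetic_result([0.5], [2])
        zones = counts_by_zone(res, n_zones=7)
        assert zones[3] == [2]

    def test_zone_dependent_poisson_round_trip(self):
        rng = np.random.default_rng(0)
        means = (0, 0, 2, 5, 5, 3, 1)
        positions, counts = [], []
        for z, mu in enumerate(means):
            for _ in range(150):
                positions.append((z + rng.uniform()) / 7)
                counts.append(int(rng.poisson(mu)))
        zones = counts_by_zone(_synthetic_result(positions, counts), n_zones=7)
        for z, mu in enumerate(means):
            vals = np.array(zones[z])
            se = math.sqrt(max(mu, 0.2) / len(vals))
            assert abs(vals.mean() - mu) <= 3 * se

    def test_overrides_replace_automatic_counts(self):
        res = _synthetic_result([0.5], [2])
        zones = counts_by_zone(res, n_zones=7, overrides={1: 9})
        assert zones[3] == [9]
        with pytest.raises(ValueError):
            apply_overrides({1: 2}, {1: -3})

    def test_zone_summary_quartiles(self):
        df = zone_summary({0: [0, 1, 2, 3, 4], 1: []})
        row = df[df.zone == 0].iloc[0]
        assert row["mean"] == 2.0 and row["median"] == 2.0
        assert np.isnan(df[df.zone == 1].iloc[0]["mean"])


class TestCompareZoneCounts:
    def test_identical_samples_give_p_one(self):
        a = {0: [1, 2, 3, 4]}
        assert compare_zone_counts(a, a)[0] == pytest.approx(1.0)

    def test_complete_separation_matches_rank_enumeration(self):
        """5-vs-5 complete separation: exact two-sided p = 2 / C(10,5)."""
        p = compare_zone_counts({0: [0] * 5}, {0: [9] * 5})[0]
        assert p == pytest.approx(2 / math.comb(10, 5), abs=1e-12)

    def test_empty_zone_gives_nan(self):
        out = compare_zone_counts({0: [1, 2], 1: []}, {0: [3, 4], 1: [5]})
        assert np.isnan(out[1])

    def test_type_one_error_calibration(self):
        """Equal Poisson populations rejected at roughly the nominal rate."""
        rng = np.random.default_rng(42)
        rejections = 0
        reps = 400
        for _ in range(reps):
            a = {0: rng.poisson(5, 30).tolist()}
            b = {0: rng.poisson(5, 30).tolist()}
            if compare_zone_counts(a, b)[0] < 0.05:
                rejections += 1
        assert rejections / reps == pytest.approx(0.05, abs=0.03)


class TestDoubleFocusTest:
    def test_published_interference_table(self):
        """1/227 vs 3/189 double-focus nuclei: p = 0.3338 to 4 decimals."""
        assert double_focus_test(1, 227, 3, 189) == pytest.approx(0.3338, abs=5e-5)

    def test_identical_proportions_give_p_one(self):
        assert double_focus_test(1, 10, 1, 10) == pytest.approx(1.0)

    def test_matches_brute_force_enumeration(self):
        """Oracle: enumerate all 2x2 tables with fixed margins via comb()."""

        def brute(a, na, b, nb):
            doubles, total = a + b, na + nb
            probs = {}
            for k in range(max(0, doubles - nb), min(doubles, na) + 1):
                probs[k] = (
                    math.comb(na, k) * math.comb(nb, doubles - k) / math.comb(total, doubles)
                )
            obs = probs[a]
            return sum(v for v in probs.values() if v <= obs * (1 + 1e-7))

        for table in [(0, 5, 5, 5), (1, 227, 3, 189), (2, 20, 8, 25), (0, 10, 0, 10)]:
            assert double_focus_test(*table) == pytest.approx(brute(*table), rel=1e-10)

    def test_agrees_with_scipy_fisher(self):
        for a, na, b, nb in itertools.product([0, 1, 4], [8, 15], [0, 2, 5], [9, 12]):
            expected = stats.fisher_exact([[a, na - a], [b, nb - b]]).pvalue
            assert double_focus_test(a, na, b, nb) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("args", [(1, 0, 1, 5), (3, 2, 0, 5), (-1, 5, 0, 5)])
    def test_invalid_tables_rejected(self, args):
        with pytest.raises(ValueError):
            double_focus_test(*args)
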
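"""Tests for segmentation, particle measurement, and nuclei counting."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.draw import disk

from myofuse.errors import LabelMapError, NoSingletonsError, ParameterError
from myofuse.preprocess import PipelineParams
from myofuse.synthetic import SceneSpec, generate_viability_scene
from myofuse.viability import (
    area_mode,
    bin_particles,
    clump_nuclei_count,
    clump_nuclei_estimates,
    count_total_nuclei,
    measure_particles,
    watershed_split,
)

from conftest import brute_force_particles


class TestWatershedSplit:
    def test_touching_disks_split_in_two(self):
        mask = np.zeros((40, 60), bool)
        rr, cc = disk((20, 20), 8)
        mask[rr, cc] = True
        rr, cc = disk((20, 36), 8)
        mask[rr, cc] = True
        labels = watershed_split(mask)
        assert labels.max() == 2
        disk_area = np.pi * 8**2
        for k in (1, 2):
            assert (labels == k).sum() == pytest.approx(disk_area, rel=0.08)

    def test_nearest_center_assignment(self):
        # oracle: with two just-touching equal disks every pixel belongs to
        # the label whose seed center is nearer
        mask = np.zeros((40, 60), bool)
        for center in ((20, 20), (20, 36)):
            rr, cc = disk(center, 8)
            mask[rr, cc] = True
        labels = watershed_split(mask)
        rr, cc = np.nonzero(mask)
        d1 = (rr - 20) ** 2 + (cc - 20) ** 2
        d2 = (rr - 20) ** 2 + (cc - 36) ** 2
        strict = d1 != d2
        want = np.where(d1 < d2, labels[20, 20], labels[20, 36])
        agree = (labels[rr, cc] == want)[strict].mean()
        assert agree > 0.97

    def test_single_disk_one_label(self):
        mask = np.zeros((30, 30), bool)
        rr, cc = disk((15, 15), 9)
        mask[rr, cc] = True
        assert watershed_split(mask).max() == 1

    def test_empty_mask_zero_labels(self):
        labels = watershed_split(np.zeros((10, 10), bool))
        assert labels.max() == 0 and labels.shape == (10, 10)

    def test_every_foreground_pixel_labelled(self):
        rng = np.random.default_rng(5)
        mask = ndi.binary_dilation(rng.random((64, 64)) < 0.05, iterations=3)
        labels = watershed_split(mask)
        assert ((labels > 0) == mask).all()

    def test_label_count_at_least_component_count(self):
        rng = np.random.default_rng(6)
        mask = ndi.binary_dilation(rng.random((64, 64)) < 0.08, iterations=2)
        _, n_cc = ndi.label(mask, structure=np.ones((3, 3), bool))
        assert watershed_split(mask).max() >= n_cc


class TestMeasureParticles:
    def test_square_label_arithmetic(self):
        labels = np.zeros((20, 20), np.int32)
        labels[5:15, 5:15] = 1
        pset = measure_particles(labels, 0.5)
        (p,) = list(pset)
        assert p.pixel_count == 100
        assert p.area_um2 == pytest.approx(25.0)
        assert p.centroid == pytest.approx((9.5, 9.5))

    def test_matches_brute_force_tally_on_random_maps(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            labels, _ = ndi.label(rng.random((64, 64)) < 0.3)
            px = float(rng.uniform(0.3, 1.5))
            pset = measure_particles(labels, px)
            oracle = brute_force_particles(labels, px)
            assert len(pset) == len(oracle)
            for p in pset:
                ref = oracle[p.label]
                assert p.pixel_count == ref["pixel_count"]
                assert p.area_um2 == pytest.approx(ref["area_um2"])
                assert p.centroid == pytest.approx(ref["centroid"])

    def test_nonconsecutive_labels_rejected(self):
        labels = np.zeros((5, 5), np.int32)
        labels[0, 0] = 2
        with pytest.raises(LabelMapError):
            measure_particles(labels, 1.0)


def _particles_from_areas(areas, px=1.0):
    """Build a ParticleSet-compatible label map holding given areas is heavy;
    tests below exercise binning purely through the measured areas."""
    from myofuse.viability import Particle, ParticleSet

    particles = [
        Particle(i + 1, int(a), float(a), (0.0, 0.0)) for i, a in enumerate(areas)
    ]
    return ParticleSet(particles, px)


class TestBinParticles:
    def test_partition_with_boundary_gap_resolution(self):
        pset = _particles_from_areas([40, 100, 250, 250.7, 600])
        singles, clumps, debris = bin_particles(pset, PipelineParams())
        assert debris.areas.tolist() == [40]
        assert singles.areas.tolist() == [100, 250]
        assert clumps.areas.tolist() == [250.7, 600]

    def test_empty_input(self):
        singles, clumps, debris = bin_particles(_particles_from_areas([]), PipelineParams())
        assert len(singles) == len(clumps) == len(debris) == 0

    def test_partition_exhaustive_and_disjoint(self):
        areas = np.random.default_rng(8).uniform(1, 600, 200)
        pset = _particles_from_areas(areas)
        singles, clumps, debris = bin_particles(pset, PipelineParams())
        assert len(singles) + len(clumps) + len(debris) == 200


class TestAreaMode:
    def test_unique_mode(self):
        assert area_mode([100, 100, 150]) == 100

    def test_tie_breaks_to_smallest_bin(self):
        assert area_mode([100, 100, 150, 150]) == 100

    def test_empty_raises(self):
        with pytest.raises(NoSingletonsError):
            area_mode([])

    def test_one_um2_binning(self):
        # 120.4 and 119.6 land in the same integer bin
        assert area_mode([120.4, 119.6, 200.0]) == 120


class TestClumpCount:
    @pytest.mark.parametrize(
        "areas,mode,expected",
        [([600], 100, 6), ([300, 520], 100, 8), ([260], 200, 1)],
    )
    def test_nearest_rounding(self, areas, mode, expected):
        assert clump_nuclei_count(areas, mode) == expected

    def test_floor_and_fractional_rules(self):
        assert clump_nuclei_count([390], 100, "floor") == 3
        assert clump_nuclei_count([260, 260], 100, "fractional") == 5  # 5.2 -> 5

    def test_nonpositive_mode_rejected(self):
        with pytest.raises(ParameterError):
            clump_nuclei_count([300], 0.0)

    def test_per_clump_estimates(self):
        est = clump_nuclei_estimates([600, 90], 100)
        assert est.tolist() == [6, 1]


class TestCountTotalNuclei:
    def test_blank_image_total_zero_with_warning(self):
        with pytest.warns(RuntimeWarning):
            res = count_total_nuclei(np.zeros((64, 64), np.uint8), 1.0)
        assert res.count.total == 0
        assert res.density_per_mm2 == 0.0

    def test_density_is_total_over_image_area(self):
        spec = SceneSpec(
            height_px=512, width_px=512, n_single_nuclei=50, seed=2
        )
        dapi, _ = generate_viability_scene(spec)
        res = count_total_nuclei(dapi, spec.pixel_size_um)
        assert res.image_area_mm2 == pytest.approx(
            512 * 512 * spec.pixel_size_um**2 / 1e6
        )
        assert res.density_per_mm2 == pytest.approx(
            res.count.total / res.image_area_mm2
        )

    def test_conservation_across_bins(self):
        spec = SceneSpec(
            height_px=640, width_px=640, n_single_nuclei=60,
            nucleus_area_range_um2=(145, 155), clumps=(4, 3), seed=9,
        )
        dapi, _ = generate_viability_scene(spec)
        res = count_total_nuclei(dapi, spec.pixel_size_um)
        n_labels = int(res.labels.max())
        assert res.count.n_singles + len(res.count.clump_areas) + res.n_debris == n_labels

    def test_adding_disjoint_modal_nucleus_increments_total(self):
        spec = SceneSpec(height_px=512, width_px=512, n_single_nuclei=40,
                         nucleus_area_range_um2=(145, 155), seed=12)
        dapi, _ = generate_viability_scene(spec)
        base = count_total_nuclei(dapi, spec.pixel_size_um)
        # stamp one extra modal-area disk in a free corner
        extra = dapi.copy()
        rr, cc = disk((500, 500), np.sqrt(150 / spec.pixel_size_um**2 / np.pi))
        assert extra[rr, cc].max() <= 30, "corner not free"
        extra[rr, cc] = 200
        res = count_total_nuclei(extra, spec.pixel_size_um)
        assert res.count.total == base.count.total + 1

    def test_recovery_scales_across_counts(self):
        # nine noise-free scenes, true counts 100..420
        from myofuse.cli import pearson_r

        computed, truth_vals = [], []
        for i, n in enumerate(range(100, 421, 40)):
            spec = SceneSpec(n_single_nuclei=n, seed=40 + i)
            dapi, truth = generate_viability_scene(spec)
            res = count_total_nuclei(dapi, spec.pixel_size_um)
            computed.append(res.count.total)
            truth_vals.append(truth.true_total_nuclei)
        computed = np.array(computed, float)
        truth_vals = np.array(truth_vals, float)
        assert pearson_r(computed, truth_vals) >= 0.99
        rel_err = np.abs(computed - truth_vals) / truth_vals
        assert np.median(rel_err) <= 0.02
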
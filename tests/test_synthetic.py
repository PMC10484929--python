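"""Phantom generators: seed determinism, exact truth bookkeeping, reachable
and unreachable densities."""

from dataclasses import replace

import numpy as np
import pytest

from brainfrac import synthetic as syn
from brainfrac.synthetic import (
    PhantomSpec2D,
    PhantomSpec3D,
    PlantedCell,
    generate_brain_volume,
    generate_cortex_slice,
    generate_group_experiment,
    study_fractions,
)


def test_seed_determinism_3d(small_spec):
    spec = small_spec.with_fractions({5: 0.01})
    a1, b1, t1 = generate_brain_volume(spec)
    a2, b2, t2 = generate_brain_volume(spec)
    assert np.array_equal(a1.data, a2.data)
    assert np.array_equal(b1.data, b2.data)
    assert np.array_equal(t1.positive_mask, t2.positive_mask)
    a3, _, _ = generate_brain_volume(replace(spec, seed=spec.seed + 1))
    assert not np.array_equal(a1.data, a3.data)


def test_zero_fractions_give_empty_truth(small_spec):
    spec = replace(small_spec, noise_sigma=0.0)
    _, antibody, truth = generate_brain_volume(spec)
    assert not truth.positive_mask.any()
    assert all(v == 0.0 for v in truth.region_fraction.values())
    # antibody channel is exactly the smooth background
    assert np.ptp(antibody.data[:, 0, :]) <= antibody.data.shape[2] * 0.05 + 1e-5


def test_truth_fractions_equal_brute_force_recount(small_spec):
    spec = small_spec.with_fractions({2: 0.01, 5: 0.025, 6: 0.014})
    _, _, truth = generate_brain_volume(spec)
    labels = truth.atlas.labels
    for rid, stored in truth.region_fraction.items():
        region = labels == rid
        assert stored == truth.positive_mask[region].sum() / region.sum()
    # positive voxels only inside the brain
    assert not (truth.positive_mask & ~truth.brain_mask).any()


def test_requested_fraction_reached_within_one_blob(small_spec):
    spec = small_spec.with_fractions({5: 0.025, 6: 0.014})
    _, _, truth = generate_brain_volume(spec)
    r_half = spec.blob_sigma_vx * np.sqrt(2 * np.log(2))
    blob_vol = 4 / 3 * np.pi * r_half**3
    for rid, target in ((5, 0.025), (6, 0.014)):
        size = (truth.atlas.labels == rid).sum()
        assert abs(truth.region_fraction[rid] - target) <= blob_vol / size + 1e-12


def test_monotone_in_requested_fraction(small_spec):
    planted = []
    for f in (0.005, 0.01, 0.02):
        _, _, truth = generate_brain_volume(small_spec.with_fractions({5: f}))
        planted.append((truth.positive_mask & (truth.atlas.labels == 5)).sum())
    assert planted[0] <= planted[1] <= planted[2]


def test_unreachable_fraction_names_region(small_spec):
    with pytest.raises(ValueError, match="neocortex"):
        generate_brain_volume(small_spec.with_fractions({5: 0.8}))


def test_spec_validation():
    with pytest.raises(ValueError):
        PhantomSpec3D(region_fractions=((99, 0.1),))
    with pytest.raises(ValueError):
        PhantomSpec3D(region_fractions=((1, 1.5),))
    with pytest.raises(ValueError):  # ellipsoid larger than the volume
        PhantomSpec3D(shape_vx=(16, 16, 16), brain_semiaxes_vx=(20, 5, 5))


def test_phantom_atlas_partitions_ellipsoid(small_spec):
    atlas = syn.make_phantom_atlas(small_spec)
    assert sorted(np.unique(atlas.labels)) == list(range(8))
    # all 7 regions non-empty, and labels exist only inside the ellipsoid
    counts = np.bincount(atlas.labels.ravel())
    assert (counts[1:] > 0).all()


def test_annotation_stack_identity_and_spacing(small_spec):
    atlas = syn.make_phantom_atlas(small_spec)
    truth = syn.GroundTruth3D(
        atlas=atlas,
        positive_mask=np.zeros(atlas.labels.shape, bool),
        region_fraction={},
        brain_mask=atlas.brain_mask,
    )
    nz = atlas.labels.shape[0]
    full = syn.generate_annotation_stack(truth, nz, axis=0)
    assert len(full) == nz
    for ann in full:
        assert np.array_equal(ann.label_image, atlas.labels[ann.plane_index])
    sparse = syn.generate_annotation_stack(truth, 16, axis=0)
    idx = [a.plane_index for a in sparse]
    assert idx[0] == 0 and idx[-1] == nz - 1
    spacings = np.diff(idx)
    assert spacings.max() - spacings.min() <= 1
    with pytest.raises(ValueError):
        syn.generate_annotation_stack(truth, 1, axis=0)


class TestCortexSlice:
    def test_no_cells_blank(self):
        images, truth = generate_cortex_slice(PhantomSpec2D(noise_sigma=0.0))
        assert images == {} and truth.empty

    def test_disk_area_oracle(self):
        cell = PlantedCell((100.0, 100.0), 4.0, frozenset({"ccasp3"}))
        _, truth = generate_cortex_slice(PhantomSpec2D(cells=(cell,)))
        # rasterized radius-4 disk at an integer center: 49 px * 0.645^2
        assert truth.area_um2.iloc[0] == pytest.approx(49 * 0.645**2)
        assert 20.3 < truth.area_um2.iloc[0] < 21.2

    def test_membership_fraction(self):
        rng = np.random.default_rng(1)
        from conftest import make_separated_cells

        cells = make_separated_cells(10, rng, extra_channels=[("NeuN", 7)])
        _, truth = generate_cortex_slice(PhantomSpec2D(cells=cells))
        assert truth.channels.str.contains("NeuN").mean() == pytest.approx(0.7)

    def test_overlapping_cells_rejected(self):
        cells = (
            PlantedCell((50.0, 50.0), 4.0, frozenset({"ccasp3"})),
            PlantedCell((50.0, 56.0), 4.0, frozenset({"ccasp3"})),
        )
        with pytest.raises(ValueError, match="separation"):
            generate_cortex_slice(PhantomSpec2D(cells=cells))

    def test_seed_determinism(self, slice_spec):
        i1, _ = generate_cortex_slice(slice_spec)
        i2, _ = generate_cortex_slice(slice_spec)
        assert all(np.array_equal(i1[k], i2[k]) for k in i1)


class TestCohort:
    def test_zero_jitter_reproduces_targets(self, small_spec):
        ctrl, trt = study_fractions(small_spec)
        animals = generate_group_experiment(
            small_spec.with_fractions(ctrl),
            small_spec.with_fractions(trt),
            2,
            2,
            seed=1,
            sigma_log=0.0,
        )
        assert [a.group for a in animals] == ["control"] * 2 + ["treated"] * 2
        for a in animals[:2]:
            assert a.spec.fractions_dict() == pytest.approx(ctrl)
        for a in animals[2:]:
            assert a.spec.fractions_dict() == pytest.approx(trt)

    def test_jitter_is_shared_across_regions(self, small_spec):
        ctrl, trt = study_fractions(small_spec)
        animals = generate_group_experiment(
            small_spec.with_fractions(ctrl),
            small_spec.with_fractions(trt),
            3,
            1,
            seed=5,
            sigma_log=0.3,
        )
        for a in animals[:3]:
            ratios = {rid: f / ctrl[rid] for rid, f in a.spec.fractions_dict().items()}
            vals = list(ratios.values())
            assert max(vals) == pytest.approx(min(vals))

    def test_identical_seed_identical_cohort(self, small_spec):
        ctrl, trt = study_fractions(small_spec)
        args = (small_spec.with_fractions(ctrl), small_spec.with_fractions(trt), 2, 3)
        c1 = generate_group_experiment(*args, seed=9)
        c2 = generate_group_experiment(*args, seed=9)
        assert [a.spec for a in c1] == [a.spec for a in c2]
        c3 = generate_group_experiment(*args, seed=10)
        assert [a.spec for a in c3] != [a.spec for a in c1]
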
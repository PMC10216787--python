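"""Image pipeline: channel combination, segmentation, intensity extraction."""

import numpy as np
import pandas as pd
import pytest

from organodeath import (
    ImageStack,
    IntensityModel,
    NucleusSegmenter,
    OrganoidSegmenter,
    combine_channels,
    extract_intensities,
    make_scene,
    quantify_well,
    render_scene,
    segment_stack,
)
from organodeath.imaging import SegmentationResult
from tests.conftest import small_geometry


def make_stack(geometry, hoechst=None, caspase=None, pi=None, **kw):
    zeros = np.zeros(geometry.shape)
    return ImageStack(
        hoechst=zeros if hoechst is None else hoechst,
        caspase=zeros if caspase is None else caspase,
        pi=zeros if pi is None else pi,
        geometry=geometry,
        **kw,
    )


class TestCombineChannels:
    def test_all_zero_channels_give_zero(self):
        g = small_geometry(64, 1)
        combined = combine_channels(make_stack(g), 0)
        assert not combined.any()

    def test_single_nonzero_channel_proportional(self, rng):
        g = small_geometry(64, 1)
        caspase = rng.uniform(0, 7, size=g.shape)
        combined = combine_channels(make_stack(g, caspase=caspase), 0)
        np.testing.assert_allclose(combined, caspase[0] / caspase[0].max())

    def test_mismatched_shapes_rejected(self):
        g = small_geometry(64, 1)
        with pytest.raises(ValueError):
            make_stack(g, hoechst=np.zeros((1, 32, 32)))

    def test_plane_out_of_range(self):
        g = small_geometry(64, 2)
        with pytest.raises(IndexError):
            combine_channels(make_stack(g), 5)

    def test_organoid_footprint_within_support(self, simple_scene, rendered_simple):
        """Every ground-truth organoid pixel sits above the background
        level of the combined image."""
        stack = ImageStack.from_rendered(rendered_simple)
        for k in range(stack.n_planes):
            mask = rendered_simple.organoid_labels[k] > 0
            if not mask.any():
                continue
            combined = combine_channels(stack, k)
            background = np.median(combined[~mask])
            assert (combined[mask] > background).mean() > 0.99


class TestOrganoidSegmenter:
    def test_blank_image_gives_zero_regions(self):
        g = small_geometry(128, 1)
        labels, table = OrganoidSegmenter().segment(np.zeros((128, 128)), g)
        assert labels.max() == 0 and table.empty

    def test_noise_only_image_gives_zero_regions(self, rng):
        g = small_geometry(128, 1)
        noise = rng.normal(5, 2, size=(128, 128)).clip(0)
        labels, table = OrganoidSegmenter().segment(noise, g)
        assert table.empty

    def test_non_positive_sigma_rejected(self):
        g = small_geometry(64, 1)
        with pytest.raises(ValueError):
            OrganoidSegmenter(gaussian_sigma=0).segment(np.ones((64, 64)), g)

    def test_min_area_default_is_250(self):
        assert OrganoidSegmenter().min_area == 250.0

    def test_debris_filtered_organoids_kept(self, geometry):
        """A field of organoids (cross-sections >= 400 um^2) plus debris
        specks < 250 um^2: exactly the organoid regions are emitted."""
        scene = make_scene(
            geometry,
            n_organoids=3,
            nuclei_per_organoid=8,
            organoid_radius=(18, 24),
            debris_count=10,
            seed=42,
        )
        rendered = render_scene(scene)
        stack = ImageStack.from_rendered(rendered)
        n_true = sum(
            len(np.unique(rendered.organoid_labels[k])) - 1
            for k in range(geometry.n_planes)
        )
        seg = OrganoidSegmenter()
        n_found = 0
        for k in range(geometry.n_planes):
            _, table = seg.segment(combine_channels(stack, k), geometry)
            n_found += len(table)
        assert n_found == n_true

    def test_area_filter_monotonicity(self, simple_stack, geometry):
        """Raising min_area never increases the region count."""
        combined = combine_channels(simple_stack, 0)
        counts = []
        for min_area in (250.0, 500.0, 1000.0, 2000.0):
            _, table = OrganoidSegmenter(min_area=min_area).segment(combined, geometry)
            counts.append(len(table))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_segmented_area_close_to_truth(self, geometry):
        scene = make_scene(
            geometry, n_organoids=1, nuclei_per_organoid=8,
            organoid_radius=(22, 22), seed=13,
        )
        rendered = render_scene(scene)
        stack = ImageStack.from_rendered(rendered)
        seg = OrganoidSegmenter()
        best = 0.0
        for k in range(geometry.n_planes):
            _, table = seg.segment(combine_channels(stack, k), geometry)
            if len(table):
                best = max(best, table["area"].max())
        truth = scene.organoid_areas[1]
        assert best == pytest.approx(truth, rel=0.10)


class TestNucleusSegmenter:
    def test_empty_organoid_mask_gives_no_nuclei(self, rng):
        img = rng.uniform(0, 10, size=(64, 64))
        labels = NucleusSegmenter().segment(img, np.zeros((64, 64), dtype=int))
        assert labels.max() == 0

    def test_recovers_separated_nuclei_exactly(self, geometry):
        """N nuclei at >= 4 sigma spacing inside one organoid are all
        recovered, for N up to 25."""
        for n in (5, 15, 25):
            scene = make_scene(
                geometry, n_organoids=1, nuclei_per_organoid=n,
                organoid_radius=(26, 26), seed=100 + n,
            )
            rendered = render_scene(scene)
            res = segment_stack(ImageStack.from_rendered(rendered))
            assert len(res.nuclei) == n

    def test_nucleus_assigned_to_containing_organoid(self, simple_scene, rendered_simple):
        res = segment_stack(ImageStack.from_rendered(rendered_simple))
        # map segmented organoids back to truth via centroid distance
        g = simple_scene.geometry
        truth = simple_scene.truth_table()
        matched = 0
        for row in res.nuclei.itertuples():
            plane_nuc = res.nucleus_labels[row.plane] == row.nucleus_id
            ys, xs = np.nonzero(plane_nuc)
            cx, cy = xs.mean() * g.pixel_size, ys.mean() * g.pixel_size
            d = np.hypot(truth.x - cx, truth.y - cy)
            true_cell = truth.iloc[int(d.idxmin())]
            # organoid of the nucleus record must cover the true cell centroid
            k = int(true_cell.plane)
            r, c = int(true_cell.y / g.pixel_size), int(true_cell.x / g.pixel_size)
            if res.organoid_labels[k][r, c] == row.organoid_id:
                matched += 1
        assert matched >= 0.95 * len(res.nuclei)


class TestExtractIntensities:
    def test_uniform_channel_gives_constant_means(self):
        g = small_geometry(64, 1)
        caspase = np.full(g.shape, 3.5)
        pi = np.full(g.shape, 1.25)
        stack = make_stack(g, caspase=caspase, pi=pi)
        nuc = np.zeros(g.shape, dtype=int)
        nuc[0, 10:15, 10:15] = 1
        nuc[0, 30:33, 40:44] = 2
        org = np.ones(g.shape, dtype=int)
        records = extract_intensities(stack, nuc, org)
        assert len(records) == 2
        assert (records["mean_caspase"] == 3.5).all()
        assert (records["mean_pi"] == 1.25).all()

    def test_label_swap_swaps_records_only(self, rng):
        g = small_geometry(64, 1)
        stack = make_stack(
            g,
            caspase=rng.uniform(0, 10, g.shape),
            pi=rng.uniform(0, 10, g.shape),
        )
        nuc = np.zeros(g.shape, dtype=int)
        nuc[0, 5:10, 5:10] = 1
        nuc[0, 40:45, 40:45] = 2
        org = np.ones(g.shape, dtype=int)
        a = extract_intensities(stack, nuc, org).set_index("nucleus_id")
        swapped = np.where(nuc == 1, 2, np.where(nuc == 2, 1, 0))
        b = extract_intensities(stack, swapped, org).set_index("nucleus_id")
        assert a.loc[1, "mean_caspase"] == b.loc[2, "mean_caspase"]
        assert a.loc[2, "mean_pi"] == b.loc[1, "mean_pi"]

    def test_apoptotic_nucleus_caspase_dominant(self, geometry):
        scene = make_scene(
            geometry, n_organoids=1, nuclei_per_organoid=8,
            organoid_radius=(22, 24), death_fractions={"apoptotic": 1.0}, seed=3,
        )
        rendered = render_scene(scene)
        res = segment_stack(ImageStack.from_rendered(rendered))
        assert (res.nuclei["mean_caspase"] > res.nuclei["mean_pi"]).all()

    def test_ground_truth_mask_recovers_nominal_intensity(self, geometry):
        """Means over ground-truth nucleus masks track the generator's
        nominal intensities (Gaussian blob profile + body + background)."""
        im = IntensityModel(background_noise_sd=0.0, z_attenuation=0.0)
        scene = make_scene(
            geometry, n_organoids=1, nuclei_per_organoid=6,
            organoid_radius=(22, 24), intensity=im, seed=8,
        )
        rendered = render_scene(scene)
        stack = ImageStack.from_rendered(rendered)
        records = extract_intensities(
            stack, rendered.nucleus_labels, rendered.organoid_labels
        )
        truth = scene.truth_table()
        merged = records.merge(truth, left_on="nucleus_id", right_on="nucleus_id")
        # mean of a Gaussian blob over a 2-sigma disc = peak * (1-e^-2)/2
        blob_factor = (1 - np.exp(-2.0)) / 2.0
        predicted = merged["caspase_mu"] * blob_factor + im.body_intensity + im.background
        np.testing.assert_allclose(merged["mean_caspase"], predicted, rtol=0.12)


class TestQuantifyWell:
    def test_single_plane_counts(self, geometry):
        scene = make_scene(
            geometry, n_organoids=1, nuclei_per_organoid=10,
            organoid_radius=(24, 26), seed=17,
        )
        rendered = render_scene(scene)
        res = segment_stack(ImageStack.from_rendered(rendered))
        load = quantify_well([res], geometry, well_id="B2")
        assert load.n_nuclei == len(res.nuclei)
        assert load.n_organoids == len(res.organoids)
        assert load.sampled_area == geometry.field_area

    def test_duplicating_fields_doubles_counts_not_mean(self, geometry, simple_stack):
        res = segment_stack(simple_stack)
        one = quantify_well([res], geometry)
        two = quantify_well([res, res], geometry)
        assert two.n_nuclei == 2 * one.n_nuclei
        assert two.n_organoids == 2 * one.n_organoids
        assert two.mean_area == pytest.approx(one.mean_area)
        assert two.sampled_area == 2 * one.sampled_area

    def test_zero_fields_rejected(self, geometry):
        with pytest.raises(ValueError):
            quantify_well([], geometry)

    def test_partition_invariant(self, simple_stack):
        """Sum of per-organoid nucleus counts equals the record count and
        every nucleus belongs to exactly one organoid."""
        res = segment_stack(simple_stack)
        assert res.organoids["n_nuclei"].sum() == len(res.nuclei)
        assert (res.nuclei["organoid_id"] > 0).all()
        assert res.nuclei["nucleus_id"].is_unique
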
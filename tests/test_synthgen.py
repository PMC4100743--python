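import numpy as np
import pytest

from patchverify import synthgen
from patchverify.faceio import DEFAULT_GRID
from patchverify.matcher import masked_distance
from patchverify.patch_classifier import BIOMETRIC, NON_BIOMETRIC
from patchverify.synthgen import (
    AccessorySpec,
    SyntheticSpec,
    annotate,
    apply_accessory,
    coverage_fractions,
    default_accessory_pool,
    gallery_probe_split,
    generate_dataset,
    load_dataset,
    make_subject_prototype,
    write_dataset,
)


class TestPrototypes:
    def test_same_seed_gives_identical_pixels(self):
        a = make_subject_prototype(42)
        b = make_subject_prototype(42)
        assert np.array_equal(a.pixels, b.pixels)

    def test_distinct_seeds_give_distinct_textures(self):
        a = make_subject_prototype(1)
        b = make_subject_prototype(2)
        mask = np.ones((5, 5), bool)
        assert masked_distance(a, b, mask, DEFAULT_GRID).distance > 0


class TestApplyAccessory:
    def test_full_patch_footprint_covers_exactly_that_patch(self):
        face = make_subject_prototype(5)
        acc = AccessorySpec("mask_like", (60, 26, 90, 52), "uniform_dark")
        _, coverage = apply_accessory(face, acc, jitter_seed=0, jitter=0)
        frac = coverage_fractions(coverage, DEFAULT_GRID)
        assert frac[2, 1] == 1.0
        assert frac.sum() == 1.0

    def test_sunglasses_row_covers_whole_eye_row(self):
        face = make_subject_prototype(5)
        acc = next(a for a in default_accessory_pool() if a.kind == "sunglasses_like")
        _, coverage = apply_accessory(face, acc, jitter_seed=0, jitter=0)
        frac = coverage_fractions(coverage, DEFAULT_GRID)
        assert np.all(frac[1, :] > 0.5)
        assert frac[0].sum() == frac[2:].sum() == 0.0

    def test_out_of_frame_footprint_rejected(self):
        face = make_subject_prototype(5)
        with pytest.raises(ValueError):
            apply_accessory(face, AccessorySpec("cap_like", (0, 0, 10, 500), "uniform_dark"))

    def test_dark_and_textured_appearances_differ(self):
        face = make_subject_prototype(5)
        footprint = (30, 0, 60, 130)
        dark, _ = apply_accessory(face, AccessorySpec("sunglasses_like", footprint, "uniform_dark"), 1)
        noisy, _ = apply_accessory(face, AccessorySpec("wig_like", footprint, "high_texture_noise"), 1)
        region_d = dark.pixels[30:60].astype(float)
        region_n = noisy.pixels[30:60].astype(float)
        assert region_d.std() < 10 < region_n.std()


class TestAnnotate:
    def _coverage_with_patch_fraction(self, frac):
        cov = np.zeros((150, 130))
        n_rows = int(round(frac * 30))
        cov[0:n_rows, 0:26] = 1.0
        return cov

    def test_barely_majority_coverage_is_non_biometric(self):
        cov = np.zeros((150, 130))
        cov[0:16, 0:26] = 1.0  # 16/30 rows = 0.533
        labels = annotate(cov, DEFAULT_GRID)
        assert labels[0, 0] == NON_BIOMETRIC

    def test_exactly_half_coverage_stays_biometric(self):
        cov = self._coverage_with_patch_fraction(0.5)
        labels = annotate(cov, DEFAULT_GRID)
        assert labels[0, 0] == BIOMETRIC

    def test_clean_image_all_biometric(self):
        labels = annotate(np.zeros((150, 130)), DEFAULT_GRID)
        assert np.all(labels == BIOMETRIC)

    def test_labels_recomputable_from_coverage(self, small_dataset):
        for im in small_dataset.images[:20]:
            assert np.array_equal(
                im.annotation, annotate(im.coverage, small_dataset.spec.grid)
            )


class TestGenerateDataset:
    def test_default_composition_counts(self, full_dataset):
        m = full_dataset.manifest()
        assert (m["split"] == "train").sum() == 322
        assert (m["split"] == "test").sum() == 359
        assert m["subject_id"].nunique() == 75

    def test_every_subject_has_min_neutral_and_disguised(self, full_dataset):
        m = full_dataset.manifest()
        for _, g in m.groupby("subject_id"):
            assert g["is_neutral"].sum() >= 1
            assert (~g["is_neutral"]).sum() >= 5
            assert 6 <= len(g) <= 10

    def test_same_seed_identical_manifest_and_pixels(self):
        spec = SyntheticSpec(n_subjects=6, train_subjects=3,
                             train_total_images=None, test_total_images=None, seed=3)
        a, b = generate_dataset(spec), generate_dataset(spec)
        assert a.manifest().equals(b.manifest())
        for ia, ib in zip(a.images, b.images):
            assert np.array_equal(ia.face.pixels, ib.face.pixels)

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(images_per_subject=(6, 10), disguised_per_subject=6)
        with pytest.raises(ValueError):
            SyntheticSpec(n_subjects=10, train_subjects=5,
                          train_total_images=10, test_total_images=None)

    def test_disguised_images_carry_occluded_annotations(self, small_dataset):
        for im in small_dataset.images:
            n_non_bio = int(np.sum(im.annotation == NON_BIOMETRIC))
            if im.face.is_neutral:
                assert n_non_bio == 0
            else:
                assert n_non_bio >= 1


class TestGalleryProbeSplit:
    def test_default_split_sizes(self, full_dataset):
        gallery, probe = gallery_probe_split(full_dataset, seed=0)
        assert len(gallery) == 200
        assert len(probe) == 159
        assert not set(gallery) & set(probe)

    def test_five_per_subject_with_a_neutral_anchor(self, full_dataset):
        gallery, _ = gallery_probe_split(full_dataset, seed=0)
        by_id = {im.image_id: im for im in full_dataset.split_images("test")}
        per_subject = {}
        for gid in gallery:
            im = by_id[gid]
            per_subject.setdefault(im.subject_id, []).append(im)
        for imgs in per_subject.values():
            assert len(imgs) == 5
            assert any(im.face.is_neutral for im in imgs)

    def test_subject_with_six_images_leaves_one_probe(self):
        spec = SyntheticSpec(n_subjects=6, train_subjects=3,
                             images_per_subject=(6, 6),
                             train_total_images=None, test_total_images=None,
                             seed=13)
        ds = generate_dataset(spec)
        _, probe = gallery_probe_split(ds, seed=0)
        by_id = {im.image_id: im.subject_id for im in ds.split_images("test")}
        counts = {}
        for pid in probe:
            counts[by_id[pid]] = counts.get(by_id[pid], 0) + 1
        assert all(v == 1 for v in counts.values())
        assert len(counts) == 3

    def test_same_seed_identical_split(self, small_dataset):
        assert gallery_probe_split(small_dataset, seed=9) == gallery_probe_split(
            small_dataset, seed=9
        )

    def test_distinct_trials_differ(self, full_dataset):
        g1, _ = gallery_probe_split(full_dataset, seed=1)
        g2, _ = gallery_probe_split(full_dataset, seed=2)
        assert g1 != g2


class TestDatasetIO:
    def test_roundtrip_preserves_pixels_and_annotations(self, tmp_path):
        spec = SyntheticSpec(n_subjects=4, train_subjects=2,
                             train_total_images=None, test_total_images=None, seed=5)
        ds = generate_dataset(spec)
        write_dataset(ds, tmp_path / "ds")
        back = load_dataset(tmp_path / "ds")
        assert back.manifest().equals(ds.manifest())
        for a, b in zip(ds.images, back.images):
            assert np.array_equal(a.face.pixels, b.face.pixels)
            assert np.array_equal(a.annotation, b.annotation)

    def test_genuine_pairs_closer_than_impostor_under_gt_masks(self, small_dataset):
        from patchverify import pipeline

        res = pipeline.verification_run(
            small_dataset, mask_mode="ground_truth", trial_seed=0
        )
        assert np.median(res.genuine[np.isfinite(res.genuine)]) < np.median(
            res.impostor[np.isfinite(res.impostor)]
        )
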
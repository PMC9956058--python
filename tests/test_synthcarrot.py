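"""Corpus generation, the 6:4 / 3:1:1 split arithmetic and the degradation
protocol."""

from collections import Counter

import numpy as np
import pytest

from distilharvest.errors import ConfigurationError
from distilharvest.synthcarrot import (DEFECT_CLASSES, AnnotatedImage,
                                       CorpusSpec, apply_degradation_quota,
                                       build_corpus, degrade_image,
                                       generate_corpus, motion_psf,
                                       read_manifest, write_corpus, _allocate)


def test_five_unique_classes():
    assert len(DEFECT_CLASSES) == 5
    assert len(set(DEFECT_CLASSES)) == 5


def test_empty_corpus_is_not_an_error():
    corpus, plan = generate_corpus(CorpusSpec(per_class_count=0, image_side=96))
    assert corpus == [] and plan.assignments == {}


def test_invalid_ratio_raises():
    with pytest.raises(ConfigurationError):
        CorpusSpec(per_class_count=10, ts_ratio=(6, 0)).validate()


def test_quota_exceeding_student_set_raises():
    with pytest.raises(ConfigurationError):
        CorpusSpec(per_class_count=10, degrade_per_class=(3, 2),
                   image_side=96).validate()


def test_ts_split_counts_exact_when_divisible():
    spec = CorpusSpec(per_class_count=10, image_side=96,
                      degrade_per_class=(0, 0), seed=3)
    _corpus, plan = generate_corpus(spec)
    for cname in DEFECT_CLASSES:
        ids = [i for i in plan.assignments if i.startswith(cname + "_")]
        counts = Counter(plan.assignments[i][0] for i in ids)
        assert counts["T"] == 6 and counts["S"] == 4


def test_split_is_exhaustive_and_disjoint(tiny_spec, tiny_corpus):
    corpus, plan = tiny_corpus
    ids = {im.source_id for im in corpus}
    assert set(plan.assignments) == ids
    assert len(corpus) == 5 * tiny_spec.per_class_count


def test_every_image_has_a_valid_object(tiny_corpus):
    corpus, _plan = tiny_corpus
    for im in corpus:
        assert len(im.objects) >= 1
        im.validate()


def test_phenotypes_are_visually_separable(rng):
    """Class-conditional geometry: the greenroot crown is greener, the
    bifurcate silhouette wider at the tip, breakage shorter than normal."""
    from distilharvest.synthcarrot import _render
    normal = _render("normal", 96, rng)
    green = _render("greenroot", 96, rng)
    broken = _render("breakage", 96, rng)

    def green_excess(im):
        px = im.pixels.astype(int)
        return (px[:, :, 1] - (px[:, :, 0] + px[:, :, 2]) // 2).max()

    assert green_excess(green) > green_excess(normal)
    assert broken.objects[0][4] < normal.objects[0][4]  # box height


def test_determinism_byte_identical(tiny_spec):
    c1, p1 = build_corpus(tiny_spec)
    c2, p2 = build_corpus(tiny_spec)
    assert p1.assignments == p2.assignments
    for a, b in zip(c1, c2):
        assert a.source_id == b.source_id
        assert a.degradation_tag == b.degradation_tag
        assert np.array_equal(a.pixels, b.pixels)
        assert a.objects == b.objects


class TestDegradeImage:
    def test_identity_psf_is_identity(self, tiny_corpus):
        im = tiny_corpus[0][0]
        out = degrade_image(im, factor=1, blur_length=1)
        assert np.array_equal(out.pixels, im.pixels)

    def test_raster_restored_and_tagged(self, tiny_corpus):
        im = tiny_corpus[0][0]
        out = degrade_image(im, factor=2, blur_length=7)
        assert out.pixels.shape == im.pixels.shape
        assert out.degradation_tag == "x2"
        assert out.objects == im.objects

    def test_mean_intensity_preserved_within_one_unit(self, tiny_corpus):
        for im in tiny_corpus[0][:5]:
            for factor in (2, 4):
                out = degrade_image(im, factor, blur_length=7, blur_angle=30.0)
                assert abs(out.pixels.astype(float).mean()
                           - im.pixels.astype(float).mean()) < 1.0

    def test_bad_factor_raises(self, tiny_corpus):
        with pytest.raises(ConfigurationError):
            degrade_image(tiny_corpus[0][0], factor=3)

    def test_psf_is_normalized(self):
        for length, angle in ((1, 0), (7, 0), (9, 45.0), (5, 90.0)):
            psf = motion_psf(length, angle)
            assert np.isclose(psf.sum(), 1.0)
            assert (psf >= 0).all()


class TestDegradationQuota:
    def test_exact_per_class_counts(self, tiny_spec, tiny_corpus):
        corpus, plan = tiny_corpus
        n2, n4 = tiny_spec.degrade_per_class
        for cname in DEFECT_CLASSES:
            tags = Counter(im.degradation_tag for im in corpus
                           if im.source_id.startswith(cname + "_"))
            assert tags["x2"] == n2 and tags["x4"] == n4

    def test_degraded_only_in_student_set(self, tiny_corpus):
        corpus, plan = tiny_corpus
        for im in corpus:
            if im.degradation_tag != "none":
                assert plan.assignments[im.source_id][0] == "S"

    def test_degraded_present_in_all_three_subsets(self, tiny_corpus):
        corpus, plan = tiny_corpus
        subsets = {plan.assignments[im.source_id][1] for im in corpus
                   if im.degradation_tag != "none"}
        assert subsets == {"train", "val", "test"}

    def test_zero_quota_leaves_everything_clean(self):
        spec = CorpusSpec(per_class_count=10, image_side=96,
                          degrade_per_class=(0, 0), seed=5)
        corpus, _ = build_corpus(spec)
        assert all(im.degradation_tag == "none" for im in corpus)

    def test_small_quota_counts(self):
        spec = CorpusSpec(per_class_count=20, image_side=96,
                          degrade_per_class=(3, 2), seed=9)
        corpus, _ = build_corpus(spec)
        tags = Counter(im.degradation_tag for im in corpus
                       if im.source_id.startswith("normal_"))
        assert tags["x2"] == 3 and tags["x4"] == 2
        assert tags["x2"] + tags["x4"] == 5


def test_allocate_largest_remainder():
    assert _allocate(10, (6, 4)) == [6, 4]
    assert _allocate(100, (3, 1, 1)) == [60, 20, 20]
    assert _allocate(7, (3, 1, 1)) == [4, 2, 1]
    assert sum(_allocate(17, (3, 1, 1))) == 17


def test_manifest_roundtrip(tmp_path, tiny_corpus):
    corpus, plan = tiny_corpus
    subset = corpus[:6]
    sub_plan = type(plan)({im.source_id: plan.assignments[im.source_id]
                           for im in subset})
    manifest = write_corpus(subset, sub_plan, tmp_path)
    rows = read_manifest(manifest)
    assert len(rows) == 6
    assert {r["image_id"] for r in rows} == {im.source_id for im in subset}
    label = (tmp_path / "labels" / f"{subset[0].source_id}.txt").read_text()
    parts = label.split()
    assert len(parts) == 5 and parts[0] == str(subset[0].objects[0][0])
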
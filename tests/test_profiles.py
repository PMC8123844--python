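"""Profile features and the five-class rule-based classifier."""

import random

import numpy as np
import pytest

import nucleoprofile as npf
from nucleoprofile import synthetic as syn
from nucleoprofile.profiles import (
    ProfileFeatures,
    ProfileType,
    classify,
    perinucleolar_annulus,
    type_distribution,
)


def _analyzed(ptype: str, seed: int = 40, **overrides):
    image, rec = npf.generate_nucleus(npf.default_spec(ptype, **overrides), 0, seed=seed)
    nucleus = npf.segment_nucleus(image)
    nucleolus = npf.segment_nucleolus(image, nucleus)
    fs = npf.detect_foci(image, nucleus, nucleolus)
    return image, rec, nucleus, nucleolus, fs


class TestAnnulus:
    def test_disjoint_from_nucleolus_and_nonempty(self, t2_nucleus):
        _, rec = t2_nucleus
        annulus = perinucleolar_annulus(rec.nucleolus_mask, rec.nucleus_mask)
        assert annulus.any()
        assert not (annulus & rec.nucleolus_mask).any()

    def test_empty_nucleolus_raises(self):
        with pytest.raises(ValueError):
            perinucleolar_annulus(np.zeros((32, 32), bool))

    def test_planted_ring_centroids_fall_in_annulus(self):
        image, rec, nucleus, nucleolus, fs = _analyzed("T2A", seed=41)
        annulus = perinucleolar_annulus(rec.nucleolus_mask, rec.nucleus_mask)
        ring = [f for f in rec.foci if f.kind == "ring"]
        hits = sum(annulus[int(round(f.row)), int(round(f.col))] for f in ring)
        assert hits >= 0.9 * len(ring)


class TestFeatures:
    def test_t1_fully_nucleolar(self):
        image, rec, nucleus, nucleolus, fs = _analyzed("T1", seed=42)
        feats = npf.compute_features(fs, nucleus, nucleolus, image)
        assert feats.nucleolar_focus_fraction == 1.0

    def test_t2_ring_score_low(self):
        image, rec, nucleus, nucleolus, fs = _analyzed("T2", seed=42)
        feats = npf.compute_features(fs, nucleus, nucleolus, image)
        assert feats.ring_score < 0.5
        assert feats.nucleolar_focus_fraction == 0.0

    def test_t2a_ring_signature(self):
        image, rec, nucleus, nucleolus, fs = _analyzed("T2A", seed=42)
        feats = npf.compute_features(fs, nucleus, nucleolus, image)
        assert feats.ring_score >= 0.5
        assert feats.ring_intensity_ratio > 1.0

    def test_empty_fociset_rejected(self, t2_analysis):
        image, nucleus, nucleolus, _ = t2_analysis
        from nucleoprofile.foci import FociSet

        empty = FociSet([], int(nucleus.sum()), 50.0, np.zeros_like(nucleus, int))
        with pytest.raises(ValueError):
            npf.compute_features(empty, nucleus, nucleolus, image)


class TestClassifyRules:
    def _feats(self, **kw) -> ProfileFeatures:
        base = dict(
            nucleolar_focus_fraction=0.0,
            ring_score=0.0,
            ring_focus_count=0,
            ring_intensity_ratio=0.0,
            large_cluster_area_fraction=0.0,
            nucleolus_brightness_ratio=1.0,
        )
        base.update(kw)
        return ProfileFeatures(**base)

    def test_fully_nucleolar_is_t1(self):
        t, path = classify(self._feats(nucleolar_focus_fraction=1.0))
        assert t is ProfileType.T1 and "T1" in path

    def test_extranucleolar_dark_is_t2(self):
        t, _ = classify(
            self._feats(ring_score=0.08, nucleolus_brightness_ratio=1.0)
        )
        assert t is ProfileType.T2

    def test_clusters_dominate_ring(self):
        t, _ = classify(
            self._feats(
                large_cluster_area_fraction=0.8,
                ring_score=0.9,
                ring_focus_count=10,
                ring_intensity_ratio=1.5,
            )
        )
        assert t is ProfileType.T3

    def test_ring_rule_requires_all_three(self):
        ok = self._feats(ring_score=0.6, ring_focus_count=5, ring_intensity_ratio=1.2)
        assert classify(ok)[0] is ProfileType.T2A
        for degrade in (
            dict(ring_score=0.3),
            dict(ring_focus_count=2),
            dict(ring_intensity_ratio=0.8),
        ):
            feats = self._feats(
                ring_score=0.6, ring_focus_count=5, ring_intensity_ratio=1.2
            )
            for k, v in degrade.items():
                setattr(feats, k, v)
            assert classify(feats)[0] is not ProfileType.T2A

    def test_light_nucleolus_blocks_t2(self):
        t, _ = classify(self._feats(nucleolus_brightness_ratio=2.0))
        assert t is ProfileType.T2B

    def test_missing_nucleolus_restricted(self):
        feats = self._feats(nucleolus_missing=True)
        t, path = classify(feats)
        assert t in {ProfileType.T2, ProfileType.T2B, ProfileType.T3}
        assert "nucleolus not segmented" in path

    def test_every_feature_vector_gets_exactly_one_type(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            feats = self._feats(
                nucleolar_focus_fraction=float(rng.uniform(0, 1)),
                ring_score=float(rng.uniform(0, 1)),
                ring_focus_count=int(rng.integers(0, 20)),
                ring_intensity_ratio=float(rng.uniform(0, 3)),
                large_cluster_area_fraction=float(rng.uniform(0, 1)),
                nucleolus_brightness_ratio=float(rng.uniform(0, 3)),
            )
            t, path = classify(feats)
            assert isinstance(t, ProfileType) and t is not ProfileType.UNLABELED
            assert path


class TestPermutationInvariance:
    def test_focus_order_irrelevant(self):
        image, rec, nucleus, nucleolus, fs = _analyzed("T2A", seed=43)
        t1, _, _ = npf.classify_fociset(fs, nucleus, nucleolus, image)
        shuffled = list(fs.foci)
        random.Random(0).shuffle(shuffled)
        fs.foci = shuffled
        t2, _, _ = npf.classify_fociset(fs, nucleus, nucleolus, image)
        assert t1 == t2


class TestTypeDistribution:
    def test_single_type_is_100_percent(self):
        df = type_distribution([ProfileType.T2])
        assert df.loc[0, "T2_percent"] == 100.0

    def test_even_split(self):
        df = type_distribution([ProfileType.T1] * 5 + [ProfileType.T3] * 5)
        assert df.loc[0, "T1_percent"] == 50.0
        assert df.loc[0, "T3_percent"] == 50.0

    def test_unlabeled_reported_separately(self):
        df = type_distribution(
            [ProfileType.T2, ProfileType.T2, ProfileType.UNLABELED]
        )
        assert df.loc[0, "T2_percent"] == 100.0
        assert df.loc[0, "unlabeled_percent"] == pytest.approx(100 / 3)

    def test_percentages_sum_to_100_per_condition(self):
        types = [ProfileType.T1, ProfileType.T2, ProfileType.T2A, ProfileType.T3]
        df = type_distribution(types * 3, conditions=["A", "B", "C"] * 4)
        pct_cols = [c for c in df.columns if c.endswith("_percent") and c != "unlabeled_percent"]
        for _, row in df.iterrows():
            assert row[pct_cols].sum() == pytest.approx(100.0)

    def test_all_unlabeled_condition_flagged(self):
        with pytest.warns(UserWarning, match="no labeled nuclei"):
            df = type_distribution(
                [ProfileType.UNLABELED, ProfileType.T2],
                conditions=["HU", "CONTROL"],
            )
        hu = df[df.condition == "HU"].iloc[0]
        assert np.isnan(hu["T2_percent"])
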
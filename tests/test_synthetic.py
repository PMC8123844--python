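"""Generator contracts: geometry, rendering, placement predicates,
population bookkeeping and the DNA-content simulator."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.measure import label

import nucleoprofile as npf
from nucleoprofile import synthetic as syn
from nucleoprofile.cellcycle import PhaseFractions
from nucleoprofile.profiles import perinucleolar_annulus


class TestGeometry:
    def test_mask_containment_chain(self):
        for ptype in syn.ProfileTypeName:
            spec = npf.default_spec(ptype)
            masks = syn.make_geometry(spec, seed=3)
            assert not (masks.nucleolus & ~masks.nucleus).any()
            assert not (masks.hc & ~masks.nucleus).any()
            assert not (masks.hc & masks.nucleolus).any()

    def test_hc_fraction_hits_target(self):
        spec = npf.default_spec("T2", hc_target_fraction=0.20)
        masks = syn.make_geometry(spec, seed=1)
        frac = masks.hc.sum() / masks.nucleus.sum()
        assert 0.19 <= frac <= 0.21

    def test_zero_hc_target_gives_empty_mask(self):
        spec = npf.default_spec("T2", hc_target_fraction=0.0)
        masks = syn.make_geometry(spec, seed=1)
        assert not masks.hc.any()

    def test_oversized_nucleolus_rejected(self):
        with pytest.raises(ValueError):
            npf.default_spec("T2", nucleolus_axes=(90.0, 70.0))

    def test_hc_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            npf.default_spec("T2", hc_target_fraction=0.7)


class TestChromatinRender:
    def test_noiseless_hc_pixels_at_configured_level(self):
        spec = npf.default_spec("T2", noise_sd=0.0)
        masks = syn.make_geometry(spec, seed=2)
        chrom = syn.render_chromatin_channel(masks, spec, seed=2)
        assert (chrom[masks.hc] == int(spec.hc_level)).all()

    def test_hc_brighter_than_nucleoplasm(self):
        spec = npf.default_spec("T2", noise_sd=5.0)
        masks = syn.make_geometry(spec, seed=2)
        chrom = syn.render_chromatin_channel(masks, spec, seed=2).astype(float)
        nucleoplasm = masks.nucleus & ~masks.hc & ~masks.nucleolus
        assert chrom[masks.hc].mean() > chrom[nucleoplasm].mean()

    def test_nucleolus_darker_than_nucleoplasm(self):
        spec = npf.default_spec("T2", noise_sd=0.0)
        masks = syn.make_geometry(spec, seed=2)
        chrom = syn.render_chromatin_channel(masks, spec, seed=2).astype(float)
        nucleoplasm = masks.nucleus & ~masks.hc & ~masks.nucleolus
        assert chrom[masks.nucleolus].mean() < chrom[nucleoplasm].mean()


class TestPlantFoci:
    def test_t1_all_centroids_inside_nucleolus(self):
        spec = npf.default_spec("T1")
        masks = syn.make_geometry(spec, seed=4)
        foci, _ = syn.plant_foci(masks, spec, seed=4)
        assert foci
        assert all(masks.nucleolus[int(round(f.row)), int(round(f.col))] for f in foci)

    def test_t2_no_centroid_inside_nucleolus(self):
        spec = npf.default_spec("T2")
        masks = syn.make_geometry(spec, seed=4)
        foci, _ = syn.plant_foci(masks, spec, seed=4)
        assert foci
        assert not any(masks.nucleolus[int(round(f.row)), int(round(f.col))] for f in foci)

    def test_t2a_ring_foci_in_annulus(self):
        spec = npf.default_spec("T2A")
        masks = syn.make_geometry(spec, seed=4)
        foci, degenerate = syn.plant_foci(masks, spec, seed=4)
        assert not degenerate
        ring = [f for f in foci if f.kind == "ring"]
        assert len(ring) >= 4
        annulus = perinucleolar_annulus(masks.nucleolus, masks.nucleus)
        hits = sum(annulus[int(round(f.row)), int(round(f.col))] for f in ring)
        assert hits >= 0.9 * len(ring)

    def test_t2a_degenerate_ring_flagged(self):
        spec = npf.default_spec("T2A", ring_focus_count=3, focus_count=10)
        masks = syn.make_geometry(spec, seed=4)
        with pytest.warns(UserWarning, match="degenerate"):
            _, degenerate = syn.plant_foci(masks, spec, seed=4)
        assert degenerate

    def test_t3_forms_merged_components(self):
        spec = npf.default_spec("T3", cluster_span_px=25.0)
        masks = syn.make_geometry(spec, seed=4)
        foci, _ = syn.plant_foci(masks, spec, seed=4)
        marker = syn.render_marker_channel(foci, masks, spec, seed=4)
        binary = marker > spec.background_level + 40
        labels = label(binary, connectivity=2)
        areas = np.bincount(labels.ravel())[1:]
        singleton = np.pi * spec.focus_radius_px**2
        assert areas.max() >= 5 * singleton


class TestMarkerRender:
    def test_empty_marker_channel_stays_at_floor(self):
        spec = npf.default_spec("T2", appearance="DARK", noise_sd=2.0)
        masks = syn.make_geometry(spec, seed=5)
        marker = syn.render_marker_channel([], masks, spec, seed=5)
        assert marker.max() <= spec.background_level + 4 * spec.noise_sd

    def test_focus_peak_at_centroid(self):
        spec = npf.default_spec("T2", noise_sd=0.0)
        masks = syn.make_geometry(spec, seed=5)
        f = syn.PlantedFocus(row=128.0, col=128.0, radius=3.0, peak=200.0)
        marker = syn.render_marker_channel([f], masks, spec, seed=5)
        assert marker[128, 128] == 200

    def test_light_nucleolus_brighter_than_dark(self):
        base = dict(noise_sd=0.0)
        spec_d = npf.default_spec("T2", appearance="DARK", **base)
        spec_l = npf.default_spec("T2", appearance="LIGHT", **base)
        masks = syn.make_geometry(spec_d, seed=6)
        m_dark = syn.render_marker_channel([], masks, spec_d, seed=6).astype(float)
        m_light = syn.render_marker_channel([], masks, spec_l, seed=6).astype(float)
        assert m_light[masks.nucleolus].mean() > m_dark[masks.nucleolus].mean()


class TestReproducibility:
    def test_same_seed_bit_identical(self):
        spec = npf.default_spec("T2A", noise_sd=5.0)
        img1, _ = npf.generate_nucleus(spec, nucleus_id=3, seed=9)
        img2, _ = npf.generate_nucleus(spec, nucleus_id=3, seed=9)
        assert (img1.chromatin == img2.chromatin).all()
        assert (img1.marker == img2.marker).all()

    def test_different_nucleus_id_differs(self):
        spec = npf.default_spec("T2", noise_sd=5.0)
        img1, _ = npf.generate_nucleus(spec, nucleus_id=0, seed=9)
        img2, _ = npf.generate_nucleus(spec, nucleus_id=1, seed=9)
        assert (img1.chromatin != img2.chromatin).any()


class TestPopulation:
    def test_labeled_count_is_rounded_fraction(self):
        pop = syn.PopulationSpec(
            entries=[
                syn.PopulationEntry(syn.ProfileTypeName.T2, syn.Condition.CONTROL, None, 40)
            ],
            labeled_fraction=0.895,
        )
        result = syn.generate_population(pop, seed=3)
        assert result.ground_truth.labeled.sum() == round(0.895 * 40)

    def test_zero_labeled_fraction_all_unlabeled(self):
        pop = syn.PopulationSpec(
            entries=[
                syn.PopulationEntry(syn.ProfileTypeName.T2, syn.Condition.CONTROL, None, 10)
            ],
            labeled_fraction=0.0,
        )
        result = syn.generate_population(pop, seed=3)
        assert not result.ground_truth.labeled.any()
        assert all(not r.foci for r in result.records)

    def test_type_histogram_exactly_as_requested(self):
        entries = [
            syn.PopulationEntry(t, syn.Condition.CONTROL, None, 4)
            for t in syn.ProfileTypeName
        ]
        result = syn.generate_population(syn.PopulationSpec(entries=entries), seed=3)
        counts = result.ground_truth.profile_type.value_counts()
        assert all(counts[t.value] == 4 for t in syn.ProfileTypeName)

    def test_empty_population_is_valid(self):
        result = syn.generate_population(syn.PopulationSpec(entries=[]), seed=3)
        assert result.images == [] and result.ground_truth.empty

    def test_condition_population_counts_sum(self):
        pop = syn.condition_population(97, "PCC")
        assert pop.total == 97

    def test_population_spec_yaml_roundtrip(self, tmp_path):
        pop = syn.condition_population(12, "HU", noise_sd=3.0)
        path = pop.to_yaml(tmp_path / "pop.yaml")
        back = syn.PopulationSpec.from_yaml(path)
        assert back.total == 12
        assert back.noise_sd == 3.0
        assert back.labeled_fraction == pop.labeled_fraction


class TestDNAContentSimulator:
    def test_pure_g1_low_cv_concentrates_at_mean(self):
        sample = syn.simulate_dna_content(
            PhaseFractions(1, 0, 0), n=500, g1_mean=100, cv=1e-4, seed=1
        )
        assert np.allclose(sample.events, 100, atol=0.5)
        assert (sample.phase_labels == 0).all()

    def test_pure_g2m_mean_within_3_se(self):
        n, cv, g1, r = 5000, 0.05, 100.0, 2.0
        sample = syn.simulate_dna_content(
            PhaseFractions(0, 0, 1), n=n, g1_mean=g1, g2_ratio=r, cv=cv, seed=2
        )
        se = cv * r * g1 / np.sqrt(n)
        assert abs(sample.events.mean() - r * g1) <= 3 * se

    def test_ground_truth_labels_match_multinomial_record(self):
        fr = PhaseFractions(0.655, 0.2617, 0.0833)
        sample = syn.simulate_dna_content(fr, n=10000, seed=3)
        emp = sample.empirical_fractions()
        # the recorded labels ARE the ground truth; fractions close to target
        assert abs(emp.g1 - fr.g1) < 0.02
        label_means = [sample.events[sample.phase_labels == p].mean() for p in range(3)]
        assert label_means[0] < label_means[1] < label_means[2]

    def test_low_tail_matches_monte_carlo_oracle(self):
        """Events below g1_mean * (1 + 3 cv) come almost entirely from G1
        plus the leading edge of S; compare with an independent redraw."""
        fr = PhaseFractions(0.655, 0.2617, 0.0833)
        g1, cv = 100.0, 0.05
        cut = g1 * (1 + 3 * cv)
        sample = syn.simulate_dna_content(fr, n=10000, g1_mean=g1, cv=cv, seed=4)
        rng = np.random.default_rng(12345)
        n_mc = 200_000
        labels = rng.choice(3, size=n_mc, p=[fr.g1, fr.s, fr.g2m])
        draws = np.where(
            labels == 0,
            rng.normal(g1, cv * g1, n_mc),
            np.where(
                labels == 2,
                rng.normal(2 * g1, 2 * cv * g1, n_mc),
                rng.uniform(g1, 2 * g1, n_mc) + rng.normal(0, cv * g1, n_mc),
            ),
        )
        oracle = (draws < cut).mean()
        assert abs((sample.events < cut).mean() - oracle) < 0.02

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            PhaseFractions(0.5, 0.4, 0.2)

    def test_all_events_positive(self):
        sample = syn.simulate_dna_content(
            PhaseFractions(0.9, 0.05, 0.05), n=2000, g1_mean=2.0, cv=0.5, seed=5
        )
        assert (sample.events > 0).all()


class TestGroundTruthInvariants:
    def test_labeled_flag_matches_foci(self):
        spec = npf.default_spec("T2")
        _, rec = npf.generate_nucleus(spec, 0, seed=8, labeled=False)
        assert not rec.labeled and not rec.foci
        _, rec = npf.generate_nucleus(spec, 0, seed=8, labeled=True)
        assert rec.labeled and rec.foci

    def test_centroids_inside_nucleus(self):
        for ptype in syn.ProfileTypeName:
            _, rec = npf.generate_nucleus(npf.default_spec(ptype), 0, seed=8)
            for f in rec.foci:
                assert rec.nucleus_mask[int(round(f.row)), int(round(f.col))]
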
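"""Synthetic specimen fields and the volunteer simulator."""

import math

import numpy as np
import pytest

from palynoscope.cohort import (
    DEFAULT_TAXON_MIX,
    TaxonMix,
    VolunteerProfile,
    default_profiles,
    generate_specimens,
    pareto_shape_for_top_share,
    perfect_profiles,
    simulate_transcriptions,
    top_decile_share,
    truth_annotations,
)
from palynoscope.consensus import Category, aggregate_image
from palynoscope.geometry import Point, TileGrid, tiles_covering


@pytest.fixture(scope="module")
def tiny_grid():
    return TileGrid(4, 4, 1000, 1000, 100.0, 0.125)


class TestGenerateSpecimens:
    def test_zero_density_gives_empty_field(self, tiny_grid):
        assert generate_specimens([tiny_grid], 0.0, seed=0) == []

    def test_negative_density_rejected(self, tiny_grid):
        with pytest.raises(ValueError):
            generate_specimens([tiny_grid], -1.0, seed=0)

    def test_same_seed_reproduces_field(self, tiny_grid):
        a = generate_specimens([tiny_grid], 5000.0, seed=7)
        b = generate_specimens([tiny_grid], 5000.0, seed=7)
        assert a == b

    def test_positions_within_extent_and_taxa_from_mix(self, tiny_grid):
        specs = generate_specimens([tiny_grid], 5000.0, seed=1)
        labels = set(DEFAULT_TAXON_MIX.taxa) | {"indeterminable"}
        for s in specs:
            assert tiny_grid.contains(s.position)
            assert s.taxon in labels
            assert s.identifiable == (s.taxon != "indeterminable")

    def test_poisson_mean_matches_density_times_area(self):
        # the survey-scale check: 207 specimens/cm**2 over ~1.85 cm**2 of
        # unique area should average ~383 specimens; Monte-Carlo mean of the
        # Poisson count must land within 3 SE at 500 replicates
        g = TileGrid(60, 60, 6144, 4090, 120.0, 0.125)
        area = 7 * g.area_cm2
        density = 383.0 / 1.85
        reps, rng_seed = 500, 123
        counts = [
            len(generate_specimens([g] * 7, density, seed=rng_seed + i)) for i in range(reps)
        ]
        expected = density * area
        se = math.sqrt(expected / reps)
        assert abs(np.mean(counts) - expected) < 3 * se


class TestTaxonMix:
    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(ValueError):
            TaxonMix({"a": 0.5, "b": 0.4})

    def test_default_mix_is_valid(self):
        assert math.isclose(sum(DEFAULT_TAXON_MIX.frequencies.values()), 1.0)
        assert 0.0 < DEFAULT_TAXON_MIX.indeterminable_fraction < 1.0


class TestTruthAnnotations:
    def test_core_specimen_annotated_once_as_middle(self, tiny_grid):
        specs = generate_specimens([tiny_grid], 0.0, seed=0)
        sp = _place(tiny_grid, Point(40.0, 40.0))
        anns = truth_annotations([sp], [tiny_grid])
        hits = [a for a in anns.values() if a.detections]
        assert len(hits) == 1
        assert hits[0].detections[0].position_class == "middle"
        assert hits[0].position_answer == "middle"

    def test_overlap_strip_specimen_duplicated_as_edge(self, tiny_grid):
        sp = _place(tiny_grid, Point(90.0, 40.0))  # x in [87.5, 100]: two tiles
        anns = truth_annotations([sp], [tiny_grid])
        hits = [a for a in anns.values() if a.detections]
        assert len(hits) == 2
        assert all(a.detections[0].position_class == "edge" for a in hits)
        assert len(tiles_covering(tiny_grid, sp.position)) == 2

    def test_four_corner_specimen_duplicated_four_times(self, tiny_grid):
        sp = _place(tiny_grid, Point(90.0, 90.0))
        anns = truth_annotations([sp], [tiny_grid])
        assert sum(bool(a.detections) for a in anns.values()) == 4

    def test_every_tile_gets_an_annotation(self, tiny_grid):
        anns = truth_annotations([], [tiny_grid])
        assert len(anns) == 16
        assert all(a.n_specimens == 0 for a in anns.values())


def _place(grid, point, taxon="Nothofagidites"):
    from palynoscope.cohort import Specimen

    return Specimen("s00000", 0, point, 12.0, taxon, True)


class TestSimulateTranscriptions:
    def test_perfect_volunteers_close_every_image_at_quorum(self, tiny_grid):
        specs = generate_specimens([tiny_grid], 3000.0, seed=2)
        truth = truth_annotations(specs, [tiny_grid])
        sim = simulate_transcriptions(truth, specs, perfect_profiles(), seed=0)
        assert all(v.n_responses == 3 for v in sim.verdicts.values())
        assert all(
            v.category in (Category.AGREEMENT_FOSSIL, Category.AGREEMENT_NO_FOSSIL)
            for v in sim.verdicts.values()
        )
        # fossil images validate as fossil, empty ones as no-fossil
        for iid, v in sim.verdicts.items():
            expected = (
                Category.AGREEMENT_FOSSIL if truth[iid].detections else Category.AGREEMENT_NO_FOSSIL
            )
            assert v.category is expected

    def test_certain_false_positives_never_validate_no_fossil(self, tiny_grid):
        truth = truth_annotations([], [tiny_grid])
        profiles = default_profiles(8, seed=0, false_positive_rate=1.0)
        sim = simulate_transcriptions(truth, [], profiles, seed=1)
        assert all(
            v.category is not Category.AGREEMENT_NO_FOSSIL for v in sim.verdicts.values()
        )

    def test_view_counts_bounded_by_serving_policy(self, tiny_grid):
        specs = generate_specimens([tiny_grid], 3000.0, seed=3)
        truth = truth_annotations(specs, [tiny_grid])
        sim = simulate_transcriptions(truth, specs, default_profiles(30, seed=0), seed=4)
        per_image = {}
        for r in sim.responses:
            per_image[r.image_id] = per_image.get(r.image_id, 0) + 1
        assert all(3 <= n <= 4 for n in per_image.values())
        assert len(sim.responses) <= len(truth) * 4

    def test_responses_reaggregate_to_served_verdicts(self, tiny_grid):
        specs = generate_specimens([tiny_grid], 3000.0, seed=5)
        truth = truth_annotations(specs, [tiny_grid])
        sim = simulate_transcriptions(truth, specs, default_profiles(30, seed=1), seed=6)
        grouped = {}
        for r in sim.responses:
            grouped.setdefault(r.image_id, []).append(r)
        for iid, rs in grouped.items():
            assert aggregate_image(rs) == sim.verdicts[iid]

    def test_same_seed_is_deterministic(self, tiny_grid):
        specs = generate_specimens([tiny_grid], 3000.0, seed=2)
        truth = truth_annotations(specs, [tiny_grid])
        profiles = default_profiles(20, seed=0)
        a = simulate_transcriptions(truth, specs, profiles, seed=9)
        b = simulate_transcriptions(truth, specs, profiles, seed=9)
        assert a.responses == b.responses and a.verdicts == b.verdicts

    def test_quorum_above_max_views_rejected(self, tiny_grid):
        truth = truth_annotations([], [tiny_grid])
        with pytest.raises(ValueError):
            simulate_transcriptions(truth, [], perfect_profiles(), quorum=5, max_views=4)

    def test_skips_produce_no_response(self, tiny_grid):
        truth = truth_annotations([], [tiny_grid])
        profiles = default_profiles(50, seed=0, skip_rate=0.5, false_positive_rate=0.0, focus_error_rate=0.0)
        sim = simulate_transcriptions(truth, [], profiles, seed=2)
        # every image still closes with exactly 3 (identical) responses
        assert all(v.n_responses == 3 for v in sim.verdicts.values())


class TestCalibration:
    def test_review_queue_fraction_matches_survey_proportion(self):
        # the survey routed 4192 of 25,200 images (16.6%) to expert review;
        # the default error rates must land within 5 percentage points
        g = TileGrid(30, 30, 6144, 4090, 120.0, 0.125)
        fracs = []
        for seed in range(10):
            specs = generate_specimens([g], 207.0, seed=seed)
            truth = truth_annotations(specs, [g])
            sim = simulate_transcriptions(truth, specs, default_profiles(100, seed=seed), seed=seed + 100)
            vs = list(sim.verdicts.values())
            queue = sum(
                v.category in (Category.AGREEMENT_FOSSIL, Category.NO_AGREEMENT) or v.disputed
                for v in vs
            )
            fracs.append(queue / len(vs))
        assert abs(np.mean(fracs) - 4192 / 25200) < 0.05

    def test_top_decile_of_volunteers_contributes_majority_of_views(self):
        g = TileGrid(20, 20, 6144, 4090, 120.0, 0.125)
        shares = []
        for seed in range(5):
            specs = generate_specimens([g], 207.0, seed=seed)
            truth = truth_annotations(specs, [g])
            sim = simulate_transcriptions(truth, specs, default_profiles(100, seed=seed), seed=seed)
            shares.append(top_decile_share(sim.views_per_volunteer))
        assert np.mean(shares) > 0.5

    def test_better_volunteers_shrink_the_review_queue(self):
        g = TileGrid(15, 15, 6144, 4090, 120.0, 0.125)
        sizes = {}
        for label, overrides in {
            "noisy": dict(false_positive_rate=0.08, focus_error_rate=0.12),
            "sharp": dict(false_positive_rate=0.01, focus_error_rate=0.02),
        }.items():
            total = 0
            for seed in range(5):
                specs = generate_specimens([g], 207.0, seed=seed)
                truth = truth_annotations(specs, [g])
                sim = simulate_transcriptions(
                    truth, specs, default_profiles(50, seed=seed, **overrides), seed=seed
                )
                total += sum(
                    v.category in (Category.AGREEMENT_FOSSIL, Category.NO_AGREEMENT) or v.disputed
                    for v in sim.verdicts.values()
                )
            sizes[label] = total
        assert sizes["sharp"] < sizes["noisy"]


def test_pareto_shape_solves_engagement_skew():
    # closed form: top 10% owning 85% of activity needs alpha ~ 1.076
    alpha = pareto_shape_for_top_share(0.10, 0.85)
    assert 0.1 ** (1.0 - 1.0 / alpha) == pytest.approx(0.85)


def test_profile_validation():
    with pytest.raises(ValueError):
        VolunteerProfile("v", sensitivity=1.5)
    with pytest.raises(ValueError):
        VolunteerProfile("v", activity_weight=0.0)
    with pytest.raises(ValueError):
        VolunteerProfile("v", name_confusion={"a": {"a": 0.5}})
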
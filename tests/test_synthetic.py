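"""Synthetic microscopy generator: determinism, count law, cohorts."""

import numpy as np
import pytest

from wormstage import staging
from wormstage.synthetic import (
    LifespanLaw,
    NoiseModel,
    SimulationConfig,
    generate_cohort,
    generate_worm_image,
    match_spots,
    resolvable_spots,
)


def _small(seed=0, **kw) -> SimulationConfig:
    base = dict(image_height=96, image_width=96, seed=seed)
    base.update(kw)
    return SimulationConfig(**base)


class TestGenerateWormImage:
    def test_degenerate_config_gives_background_only(self):
        cfg = _small(
            base_spot_count=0,
            spot_count_slope=0.0,
            noise_model=NoiseModel(gaussian_sd=0.0, poisson_scale=0.0),
        )
        img, truth = generate_worm_image(cfg, 0.5)
        assert truth.spots == []
        # background + tissue only: bounded by their sum, smooth
        assert img.pixels.max() <= cfg.background_level + cfg.tissue_amplitude + 1e-9

    def test_seeded_determinism(self):
        cfg = _small(seed=11)
        a, _ = generate_worm_image(cfg, 0.7)
        b, _ = generate_worm_image(cfg, 0.7)
        assert np.array_equal(a.pixels, b.pixels)

    def test_pixels_in_unit_range_and_spots_in_bounds(self):
        cfg = _small(seed=3)
        img, truth = generate_worm_image(cfg, 1.0)
        assert img.pixels.min() >= 0 and img.pixels.max() <= 1
        for x, y, r in truth.spots:
            assert 0 <= x < cfg.image_width and 0 <= y < cfg.image_height
            assert r > 0

    def test_mean_spot_count_follows_linear_law(self):
        """Monte-Carlo over the generator's count law: base 5, slope 20 at
        relative age 1 gives a mean count near 25 over 200 replicates."""
        counts = []
        for seed in range(200):
            cfg = _small(seed=seed, base_spot_count=5, spot_count_slope=20.0)
            _, truth = generate_worm_image(cfg, 1.0)
            counts.append(len(truth.spots))
        assert abs(np.mean(counts) - 25.0) < 2.0

    def test_mean_count_monotone_in_age(self):
        means = []
        for age in (0.1, 0.5, 0.9):
            counts = [
                len(generate_worm_image(_small(seed=s), age)[1].spots)
                for s in range(100)
            ]
            means.append(np.mean(counts))
        assert means[0] < means[1] < means[2]

    def test_invalid_relative_age(self):
        with pytest.raises(ValueError):
            generate_worm_image(_small(), 1.5)

    @pytest.mark.parametrize(
        "kw",
        [
            dict(image_height=32),
            dict(spot_intensity_range=(0.05, 0.5)),  # below background
            dict(spot_radius_range=(0.2, 3.0)),
            dict(exposure_label=1.0 / 10.0),
            dict(cluster_tightness=1.5),
        ],
    )
    def test_config_invariants(self, kw):
        with pytest.raises(ValueError):
            _small(**kw)


class TestGenerateCohort:
    def test_fixed_lifespan_row_count_and_labels(self):
        cfg = _small(seed=4)
        law = LifespanLaw(min_days=10, max_days=10)
        cohort = generate_cohort(cfg, 1, lifespan_law=law)
        assert len(cohort.manifest) == 10
        for _, row in cohort.manifest.iterrows():
            fine = staging.assign_fine_class(row["day"], row["lifespan"])
            assert row["stage_fine"] == fine
            assert row["stage_group"] == staging.merge_to_group(fine)

    def test_fine_class_matches_ceiling_rule_for_25_day_lifespan(self):
        cfg = _small(seed=5)
        cohort = generate_cohort(cfg, 1, lifespan_law=LifespanLaw(25, 25))
        for _, row in cohort.manifest.iterrows():
            expected = min(max(int(np.ceil(25 * row["day"] / 25)), 1), 25)
            assert row["stage_fine"] == expected

    def test_zero_individuals_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(_small(), 0)

    def test_manifest_and_images_deterministic(self, tmp_path):
        cfg = _small(seed=9)
        law = LifespanLaw(10, 12)
        a = generate_cohort(cfg, 2, lifespan_law=law, out_dir=tmp_path / "a")
        b = generate_cohort(cfg, 2, lifespan_law=law, out_dir=tmp_path / "b")
        assert a.manifest.equals(b.manifest)
        assert (tmp_path / "a" / "manifest.csv").read_bytes() == (
            tmp_path / "b" / "manifest.csv"
        ).read_bytes()
        for pa in sorted((tmp_path / "a" / "images").iterdir()):
            pb = tmp_path / "b" / "images" / pa.name
            assert pa.read_bytes() == pb.read_bytes()

    def test_lifespans_within_law(self):
        cohort = generate_cohort(_small(seed=2), 5)
        spans = cohort.manifest.groupby("individual_id")["lifespan"].first()
        assert spans.between(10, 30).all()


class TestSpotMatching:
    def test_match_counts(self):
        true = [(10.0, 10.0, 3.0), (50.0, 50.0, 3.0)]
        det = [(11.0, 10.0, 3.0), (80.0, 80.0, 3.0)]
        assert match_spots(true, det, max_dist=6.0) == (1, 1, 1)

    def test_empty_cases(self):
        assert match_spots([], [], 6.0) == (0, 0, 0)
        assert match_spots([(1, 1, 1)], [], 6.0) == (0, 0, 1)
        assert match_spots([], [(1, 1, 1)], 6.0) == (0, 1, 0)

    def test_resolvable_merges_overlapping_cores(self):
        # two spots closer than the sum of their sigmas render as one blob
        spots = [(10.0, 10.0, 4.0), (12.0, 10.0, 4.0), (40.0, 40.0, 4.0)]
        merged = resolvable_spots(spots)
        assert len(merged) == 2
        xs = sorted(s[0] for s in merged)
        assert xs[0] == pytest.approx(11.0)  # equal radii: midpoint
        assert xs[1] == 40.0

    def test_resolvable_keeps_separated_spots(self):
        spots = [(10.0, 10.0, 4.0), (20.0, 10.0, 4.0)]
        assert resolvable_spots(spots) == spots
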
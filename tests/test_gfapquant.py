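"""ROI measurement, seeded placement, per-animal/cohort aggregation."""

import numpy as np
import pandas as pd
import pytest

from hippomech.elastmap import RegionMask
from hippomech.errors import AggregationError, DomainError
from hippomech.gfapquant import (
    FluorescenceImage,
    aggregate_gfap,
    measure_roi,
    sample_rois,
)
from hippomech.synthgen import (
    COHORT_APP_17M,
    COHORT_WT_3M,
    GfapImageParams,
    band_region_mask,
    gfap_intensity_by_label,
    simulate_gfap_image,
)


def uniform_image(level, shape=(100, 100), pixel_size=2.0, **meta):
    return FluorescenceImage(
        pixels=np.full(shape, level, dtype=np.uint8), pixel_size=pixel_size, **meta
    )


class TestMeasureRoi:
    def test_uniform_image(self):
        roi = measure_roi(uniform_image(37), (0, 0, 100, 100))
        assert roi.mean_intensity == 37.0

    def test_half_and_half_symmetry(self):
        px = np.zeros((100, 100), dtype=np.uint8)
        px[:, 50:] = 255
        image = FluorescenceImage(px, pixel_size=1.0)
        roi = measure_roi(image, (0, 0, 100, 100))
        assert roi.mean_intensity == pytest.approx(127.5)

    def test_out_of_bounds(self):
        with pytest.raises(DomainError):
            measure_roi(uniform_image(10), (150, 0, 100, 100))

    def test_invariant_to_plaques_outside_roi(self):
        mask = band_region_mask((300, 300), n_regions=1)
        base = GfapImageParams(
            image_size=(300, 300), pixel_size=1.0, region_intensity={1: 80.0},
            noise_sd=0.0, plaque_density=0.0, seed=0,
        )
        img_plain = simulate_gfap_image(base, mask)
        img_pl, plaques = simulate_gfap_image(
            GfapImageParams(
                image_size=(300, 300), pixel_size=1.0, region_intensity={1: 80.0},
                noise_sd=0.0, plaque_density=40.0, seed=1,
            ),
            mask,
            return_plaque_mask=True,
        )
        # find a 40x40 px window free of plaques
        found = False
        for r0 in range(0, 260, 20):
            for c0 in range(0, 260, 20):
                if not plaques[r0 : r0 + 40, c0 : c0 + 40].any():
                    a = measure_roi(img_plain, (c0, r0, 40, 40))
                    b = measure_roi(img_pl, (c0, r0, 40, 40))
                    assert a.mean_intensity == b.mean_intensity
                    found = True
                    break
            if found:
                break
        assert found


class TestSampleRois:
    def test_five_rois_per_region(self):
        mask = band_region_mask((600, 750))
        params = GfapImageParams(
            region_intensity=gfap_intensity_by_label(COHORT_WT_3M), seed=0
        )
        image = simulate_gfap_image(params, mask, animal="a1", cohort=COHORT_WT_3M)
        rois = sample_rois(image, mask, seed=1)
        counts = pd.Series([r.region for r in rois]).value_counts()
        assert (counts == 5).all() and len(counts) == 10
        areas = [r.bounds_um[2] * r.bounds_um[3] for r in rois]
        assert all(abs(a - 22_500.0) / 22_500.0 < 0.05 for a in areas)

    def test_same_seed_identical_placement(self):
        mask = band_region_mask((600, 750))
        params = GfapImageParams(
            region_intensity=gfap_intensity_by_label(COHORT_WT_3M), seed=0
        )
        image = simulate_gfap_image(params, mask)
        r1 = sample_rois(image, mask, seed=5)
        r2 = sample_rois(image, mask, seed=5)
        assert [r.bounds_um for r in r1] == [r.bounds_um for r in r2]

    def test_region_too_small_skipped(self):
        mask = RegionMask(np.ones((60, 60), dtype=int))  # 120 μm < one ROI
        image = uniform_image(50, shape=(60, 60))
        with pytest.warns(UserWarning, match="region 1"):
            rois = sample_rois(image, mask, seed=0)
        assert rois == []

    def test_fifteen_measurements_per_region_over_three_animals(self):
        # 3 slices × 5 ROIs × (accumulate over 3 animals) = 45; per slice run
        # each region yields 5, so one animal's 3 slices give 15 per region
        mask = band_region_mask((600, 750))
        all_rois = []
        for s in range(3):
            params = GfapImageParams(
                region_intensity=gfap_intensity_by_label(COHORT_WT_3M), seed=s
            )
            image = simulate_gfap_image(
                params, mask, animal="a1", cohort=COHORT_WT_3M, slice_id=f"s{s}"
            )
            all_rois.extend(sample_rois(image, mask, seed=100 + s))
        per_region = pd.Series([r.region for r in all_rois]).value_counts()
        assert (per_region == 15).all()


class TestAggregate:
    def test_single_measurement_identity(self):
        df = pd.DataFrame(
            {"animal": ["a1"], "cohort": ["c"], "region": [6], "mean_intensity": [42.0]}
        )
        per_animal, cohort = aggregate_gfap(df)
        assert per_animal["animal_mean"].iloc[0] == 42.0

    def test_mean_of_three(self):
        df = pd.DataFrame(
            {
                "animal": "a1",
                "cohort": "c",
                "region": 6,
                "mean_intensity": [10.0, 20.0, 30.0],
            }
        )
        per_animal, cohort = aggregate_gfap(df)
        assert per_animal["animal_mean"].iloc[0] == pytest.approx(20.0)
        assert cohort["median"].iloc[0] == pytest.approx(20.0)

    def test_permutation_invariance_and_counts(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "animal": rng.choice(["a1", "a2", "a3"], 90),
                "cohort": "c",
                "region": rng.choice(range(1, 11), 90),
                "mean_intensity": rng.uniform(20, 200, 90),
            }
        )
        p1, c1 = aggregate_gfap(df)
        p2, c2 = aggregate_gfap(df.sample(frac=1.0, random_state=9))
        pd.testing.assert_frame_equal(
            p1.sort_values(list(p1.columns)).reset_index(drop=True),
            p2.sort_values(list(p2.columns)).reset_index(drop=True),
        )
        assert c1["n"].sum() == 90

    def test_empty_input_rejected(self):
        with pytest.raises(AggregationError):
            aggregate_gfap(pd.DataFrame())

    def test_cohort_means_recover_configuration_single_region(self):
        # whole image one region → no boundary bleed; mean within noise SE
        mask = band_region_mask((600, 750), n_regions=1)
        params = GfapImageParams(
            region_intensity={1: 80.0}, noise_sd=6.0, plaque_density=0.0, seed=4
        )
        image = simulate_gfap_image(params, mask, animal="a1", cohort=COHORT_WT_3M)
        rois = sample_rois(image, mask, seed=11)
        _, cohort = aggregate_gfap(rois)
        # each ROI averages 75² pixels; SE ≈ 6/75 ≈ 0.08, plus rounding bias
        assert cohort["mean"].iloc[0] == pytest.approx(80.0, abs=0.5)

    def test_cohort_means_recover_configuration_banded_mask(self):
        # ROIs may include ≤20% of a neighbouring band, so allow bleed of
        # 0.2 × the largest neighbour intensity gap (~22 levels → ~4.4)
        mask = band_region_mask((600, 750))
        params = GfapImageParams(
            region_intensity=gfap_intensity_by_label(COHORT_WT_3M), noise_sd=6.0, seed=4
        )
        image = simulate_gfap_image(params, mask, animal="a1", cohort=COHORT_WT_3M)
        rois = sample_rois(image, mask, seed=11)
        _, cohort = aggregate_gfap(rois)
        from hippomech.synthgen import GFAP_INTENSITY_8BIT

        config = GFAP_INTENSITY_8BIT[COHORT_WT_3M]
        for row in cohort.itertuples(index=False):
            assert row.mean == pytest.approx(config[row.analysis_group], abs=4.5)

    def test_app_brighter_than_wt_in_ca1(self):
        mask = band_region_mask((600, 750))
        means = {}
        for cohort in (COHORT_WT_3M, COHORT_APP_17M):
            params = GfapImageParams(
                region_intensity=gfap_intensity_by_label(cohort),
                plaque_density=20.0 if cohort == COHORT_APP_17M else 0.0,
                seed=6,
            )
            image = simulate_gfap_image(params, mask, animal="a", cohort=cohort)
            _, summary = aggregate_gfap(sample_rois(image, mask, seed=21))
            means[cohort] = summary.set_index("analysis_group")["mean"]
        assert means[COHORT_APP_17M]["CA1_PYR"] > means[COHORT_WT_3M]["CA1_PYR"]
        assert means[COHORT_APP_17M]["CA1_SO_SR"] > means[COHORT_WT_3M]["CA1_SO_SR"]
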
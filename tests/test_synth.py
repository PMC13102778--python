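"""Generator contracts: morphology map, rendering, studies, biomarkers."""

import numpy as np
import pandas as pd
import pytest

from spherovia.features import circularity
from spherovia.segmentation import extract_contour
from spherovia.synth import (
    ATP_UNIT_NM,
    MANIFEST_COLUMNS,
    DoseResponseSpec,
    MorphologyParams,
    SyntheticStudySpec,
    generate_biomarkers,
    generate_dose_response,
    generate_study,
    hill_viability,
    render_spheroid,
    viability_to_morphology,
)
from spherovia.viability import normalize_manifest


class TestMorphologyMap:
    def test_healthy_limit_is_clean_disk(self):
        p = viability_to_morphology(1.0, seed=3)
        assert p.irregularity_amplitude == 0.0
        assert p.core_darkness == 0.0
        assert p.fragment_count == 0

    def test_zero_viability_reaches_configured_maximum(self):
        grid = [viability_to_morphology(v, seed=3)
                for v in np.arange(0.0, 1.01, 0.1)]
        amps = [p.irregularity_amplitude for p in grid]
        assert amps[0] == max(amps)

    @pytest.mark.parametrize("seed", [0, 11, 202])
    def test_cues_monotone_non_increasing_in_viability(self, seed):
        grid = np.arange(0.0, 1.01, 0.1)
        params = [viability_to_morphology(v, seed) for v in grid]
        amps = [p.irregularity_amplitude for p in params]
        darks = [p.core_darkness for p in params]
        assert all(a >= b for a, b in zip(amps, amps[1:]))
        assert all(a >= b for a, b in zip(darks, darks[1:]))

    def test_fragments_only_below_quarter_viability(self):
        for v in np.arange(0.0, 1.3, 0.05):
            p = viability_to_morphology(float(v), seed=5)
            assert (p.fragment_count > 0) == (v < 0.25)

    def test_map_is_deterministic(self):
        assert viability_to_morphology(0.42, 9) == viability_to_morphology(0.42, 9)

    @pytest.mark.parametrize("v", [-0.1, 1.31, 5.0])
    def test_out_of_range_viability_rejected(self, v):
        with pytest.raises(ValueError):
            viability_to_morphology(v, seed=0)

    def test_param_invariants_enforced(self):
        with pytest.raises(ValueError):
            MorphologyParams(radius=-1, irregularity_amplitude=0,
                             irregularity_harmonics=(), core_darkness=0,
                             fragment_count=0)
        with pytest.raises(ValueError):
            MorphologyParams(radius=10, irregularity_amplitude=0.6,
                             irregularity_harmonics=(), core_darkness=0,
                             fragment_count=0)


def _clean_disk(radius=20, **kw):
    return MorphologyParams(radius=radius, irregularity_amplitude=0.0,
                            irregularity_harmonics=(), core_darkness=0.0,
                            fragment_count=0, noise_sd=0.0, **kw)


class TestRendering:
    def test_disk_mask_area_matches_geometry(self):
        img, mask = render_spheroid(_clean_disk(20), 96, seed=0)
        assert mask.sum() == pytest.approx(np.pi * 20**2, rel=0.02)

    def test_rendering_is_bit_identical(self):
        p = viability_to_morphology(0.3, seed=12)
        img1, m1 = render_spheroid(p, 96, seed=4)
        img2, m2 = render_spheroid(p, 96, seed=4)
        assert np.array_equal(img1, img2) and np.array_equal(m1, m2)

    def test_irregular_boundary_lowers_circularity(self):
        harmonics = ((5, 0.3, 0.6), (7, 1.1, 0.4))
        smooth = _clean_disk(20)
        lobed = MorphologyParams(radius=20, irregularity_amplitude=0.3,
                                 irregularity_harmonics=harmonics,
                                 core_darkness=0.0, fragment_count=0,
                                 noise_sd=0.0)
        _, m0 = render_spheroid(smooth, 96, seed=0)
        _, m1 = render_spheroid(lobed, 96, seed=0)
        c0 = circularity(m0, extract_contour(m0))
        c1 = circularity(m1, extract_contour(m1))
        assert c1 < c0

    def test_frame_too_small_rejected(self):
        with pytest.raises(ValueError):
            render_spheroid(_clean_disk(30), 96, seed=0)

    def test_mean_circularity_decreases_with_viability(self):
        levels = [1.0, 0.7, 0.4, 0.1]
        means = []
        for v in levels:
            vals = []
            for i in range(20):
                p = viability_to_morphology(v, seed=300 + i)
                _, mask = render_spheroid(p, 96, seed=600 + i)
                vals.append(circularity(mask, extract_contour(mask)))
            means.append(np.mean(vals))
        assert all(a >= b for a, b in zip(means, means[1:]))


class TestStudyGeneration:
    def test_row_and_image_counts(self):
        spec = SyntheticStudySpec(n_plates=1, wells_per_plate=24,
                                  control_fraction=0.5, seed=1)
        study = generate_study(spec)
        assert len(study.manifest) == 24
        assert len(study.images) == 24
        assert list(study.manifest.columns) == MANIFEST_COLUMNS

    def test_generation_is_deterministic(self):
        spec = SyntheticStudySpec(wells_per_plate=24, control_fraction=0.5,
                                  seed=3)
        a, b = generate_study(spec), generate_study(spec)
        pd.testing.assert_frame_equal(a.manifest, b.manifest)
        assert all(np.array_equal(x, y) for x, y in zip(a.images, b.images))

    def test_all_controls_normalize_to_unit_median(self):
        spec = SyntheticStudySpec(wells_per_plate=24, control_fraction=1.0,
                                  seed=2)
        study = generate_study(spec)
        norm = normalize_manifest(study.manifest)
        assert np.median(norm["viability"]) == pytest.approx(1.0)

    def test_batch_scale_cancels_in_normalization(self):
        base = dict(wells_per_plate=48, control_fraction=0.25, seed=11, day=4)
        a = generate_study(SyntheticStudySpec(batch_scale=1.0, **base))
        b = generate_study(SyntheticStudySpec(batch_scale=7.3, **base))
        va = normalize_manifest(a.manifest)["viability"].to_numpy()
        vb = normalize_manifest(b.manifest)["viability"].to_numpy()
        np.testing.assert_allclose(va, vb, atol=1e-9)

    def test_atp_scale_is_realistic(self, small_study):
        controls = small_study.manifest.query("Treatment == 'control'")
        assert 0.2 * ATP_UNIT_NM < controls["Value"].median() < 5 * ATP_UNIT_NM

    def test_too_few_controls_warns(self):
        with pytest.warns(UserWarning, match="control wells"):
            SyntheticStudySpec(wells_per_plate=24, control_fraction=0.25)


class TestDoseResponse:
    def test_hill_midpoint_and_low_dose_limit(self):
        spec = DoseResponseSpec(drug="d", true_ic50=10.0, hill_slope=1.0,
                                concentrations=(0.01, 1.0, 10.0, 100.0),
                                cmax=1.0, dili_label=1, noise_cv=0.0,
                                days=(7,))
        panel = generate_dose_response(spec)
        at = panel.groupby("concentration_uM")["viability"].mean()
        assert at[10.0] == pytest.approx(0.5)
        assert at[0.01] == pytest.approx(1.0, abs=1e-3)

    def test_effect_onset_scales_with_day(self):
        spec = DoseResponseSpec(drug="d", true_ic50=5.0, hill_slope=1.5,
                                concentrations=(1.0, 3.0, 10.0, 30.0),
                                cmax=1.0, dili_label=1, noise_cv=0.0,
                                days=(3, 5, 7))
        panel = generate_dose_response(spec)
        v_by_day = panel.groupby("day")["viability"].mean()
        assert v_by_day[3] > v_by_day[5] > v_by_day[7]

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            DoseResponseSpec(drug="d", true_ic50=1.0, hill_slope=1.0,
                             concentrations=(3.0, 1.0, 10.0, 30.0), cmax=1.0,
                             dili_label=0)
        with pytest.raises(ValueError):
            DoseResponseSpec(drug="d", true_ic50=1.0, hill_slope=1.0,
                             concentrations=(-1.0, 1.0, 2.0, 3.0), cmax=1.0,
                             dili_label=0)

    def test_hill_curve_closed_form(self):
        assert hill_viability(10.0, 10.0, 2.0) == pytest.approx(0.5)
        assert hill_viability(1e-9, 10.0, 2.0) == pytest.approx(1.0)


class TestBiomarkers:
    def test_sample_correlation_matches_target(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0.0, 1.2, 500)
        bio = generate_biomarkers(v, seed=1, target_corr=(0.8, 0.8, 0.8))
        for ch in bio.columns:
            r = np.corrcoef(bio[ch], v)[0, 1]
            assert r == pytest.approx(0.8, abs=0.05)

    def test_noise_free_channels_are_perfectly_correlated(self):
        v = np.linspace(0.1, 1.1, 50)
        bio = generate_biomarkers(v, seed=0, target_corr=(1.0, 1.0, 1.0))
        for ch in bio.columns:
            assert np.corrcoef(bio[ch], v)[0, 1] == pytest.approx(1.0)

    def test_constant_viability_is_flagged(self):
        with pytest.raises(ValueError, match="zero variance"):
            generate_biomarkers(np.full(20, 0.8), seed=0)
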
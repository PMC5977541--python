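"""The seeded cohort generator: determinism, point-process calibration,
compartment consistency, and the architectural disorder dial."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import spearmanr

from nucmorph.architecture import nn_features
from nucmorph.errors import GenerationError, InvalidParameterError
from nucmorph.shape import length_width_ratio
from nucmorph.synthetic import (
    SyntheticCohortConfig,
    SyntheticPhenotype,
    generate_cohort,
    render_patch,
    sample_centroids,
    synthesize_nucleus_boundary,
    synthesize_patch,
)
from nucmorph.types import EPITHELIAL, STROMAL


class TestCentroids:
    def test_seeded_determinism(self):
        ph = SyntheticPhenotype()
        a, ma = sample_centroids(ph, 300, EPITHELIAL, seed=5)
        b, mb = sample_centroids(ph, 300, EPITHELIAL, seed=5)
        assert np.array_equal(a, b)
        assert np.array_equal(ma, mb)
        c, _ = sample_centroids(ph, 300, EPITHELIAL, seed=6)
        assert not (a.shape == c.shape and np.array_equal(a, c))

    def test_zero_intensities_give_empty_patch(self):
        ph = SyntheticPhenotype(cluster_intensity=0.0, stromal_intensity=0.0)
        ep, mask = sample_centroids(ph, 300, EPITHELIAL, seed=1)
        st, _ = sample_centroids(ph, 300, STROMAL, seed=1, epithelium_mask=mask)
        assert len(ep) == 0 and len(st) == 0

    def test_poisson_mean_over_free_area(self):
        # with no epithelium the whole patch is free area A; the stromal
        # count is Poisson(lambda * A)
        lam = 5000.0  # per mm^2
        size = 300
        area_mm2 = (size / 4000.0) ** 2
        expected = lam * area_mm2
        ph = SyntheticPhenotype(cluster_intensity=0.0, stromal_intensity=lam,
                                placement_jitter=0.0)
        counts = [
            len(sample_centroids(ph, size, STROMAL, seed=s)[0]) for s in range(500)
        ]
        assert abs(np.mean(counts) - expected) < 3 * np.sqrt(expected / 500) + 0.5

    def test_nonfinite_parameters_rejected(self):
        ph = SyntheticPhenotype(cluster_intensity=float("nan"))
        with pytest.raises(InvalidParameterError):
            sample_centroids(ph, 300, EPITHELIAL, seed=1)

    def test_epithelial_centroids_lie_inside_mask(self):
        ph = SyntheticPhenotype()
        pts, mask = sample_centroids(ph, 400, EPITHELIAL, seed=3)
        for x, y in pts:
            assert mask[int(y), int(x)] == 255


class TestNucleusBoundary:
    def test_circle_area(self):
        ph = SyntheticPhenotype(
            axis_ratio_mean=1.0, axis_ratio_sd=0.0, boundary_irregularity=0.0,
            mean_radius_px=10.0,
        )
        poly, _ = synthesize_nucleus_boundary((0, 0), ph, seed=1)
        import shapely.geometry as geom

        assert geom.Polygon(poly).area == pytest.approx(np.pi * 100, rel=0.01)

    def test_axis_ratio_recovered(self):
        ph = SyntheticPhenotype(
            axis_ratio_mean=2.0, axis_ratio_sd=0.0, boundary_irregularity=0.0
        )
        poly, _ = synthesize_nucleus_boundary((0, 0), ph, seed=2)
        assert length_width_ratio(poly) == pytest.approx(2.0, rel=0.02)

    def test_seeded_determinism(self):
        ph = SyntheticPhenotype()
        p1, o1 = synthesize_nucleus_boundary((5, 5), ph, seed=9)
        p2, o2 = synthesize_nucleus_boundary((5, 5), ph, seed=9)
        assert np.array_equal(p1, p2) and o1 == o2

    def test_degenerate_radius_rejected(self):
        ph = SyntheticPhenotype(mean_radius_px=0.0)
        with pytest.raises(InvalidParameterError):
            synthesize_nucleus_boundary((0, 0), ph, seed=1)

    def test_polygons_are_simple(self):
        import shapely.geometry as geom

        ph = SyntheticPhenotype(boundary_irregularity=0.5, axis_ratio_mean=2.5)
        for seed in range(50):
            poly, orientation = synthesize_nucleus_boundary((0, 0), ph, seed=seed)
            assert geom.Polygon(poly).is_valid
            assert 0.0 <= orientation < 180.0


class TestCohort:
    def test_counts(self):
        cfg = SyntheticCohortConfig(
            n_patients_per_class=3, patches_per_patient=2, patch_size_px=384, seed=2
        )
        cases = generate_cohort(cfg)
        assert len(cases) == 6
        assert sum(len(c.patches) for c in cases) == 12
        for case in cases:
            lo, hi = cfg.odx_score_ranges[case.phenotype_class]
            assert lo <= case.odx_score <= hi
            for patch in case.patches:
                assert len(patch.compartment_nuclei(EPITHELIAL)) >= cfg.min_nuclei
                assert len(patch.compartment_nuclei(STROMAL)) >= cfg.min_nuclei

    def test_full_determinism_and_seed_sensitivity(self):
        cfg = SyntheticCohortConfig(
            n_patients_per_class=2, patches_per_patient=1, patch_size_px=384, seed=4
        )
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        pa, pb = a[0].patches[0], b[0].patches[0]
        assert np.array_equal(pa.nuclei[0].boundary, pb.nuclei[0].boundary)
        assert [c.odx_score for c in a] == [c.odx_score for c in b]
        c = generate_cohort(replace_seed(cfg, 5))
        assert not np.array_equal(
            a[0].patches[0].centroids(), c[0].patches[0].centroids()
        )

    def test_unsatisfiable_min_nuclei_raises(self):
        barren = SyntheticPhenotype(cluster_intensity=0.0, stromal_intensity=0.0)
        cfg = SyntheticCohortConfig(
            n_patients_per_class=1, patches_per_patient=1, patch_size_px=256,
            low_phenotype=barren, high_phenotype=barren, seed=1,
        )
        with pytest.raises(GenerationError):
            generate_cohort(cfg)


class TestDisorderDial:
    def test_cluster_spread_increases_nn_disorder(self):
        # the architectural disorder dial must move the 40 px neighbor
        # disorder feature monotonically (rank correlation over patches)
        spreads, disorders = [], []
        for seed in range(200):
            s = float(np.random.default_rng(seed).uniform(10, 60))
            ph = SyntheticPhenotype(cluster_spread=s)
            patch, _ = synthesize_patch(ph, 448, "a", "p", np.random.default_rng(seed + 1))
            pts = patch.centroids(EPITHELIAL)
            if len(pts) < 8:
                continue
            spreads.append(s)
            disorders.append(nn_features(pts, (0, 0, 448, 448))[11])
        rho = spearmanr(spreads, disorders).statistic
        assert rho > 0.5


class TestRender:
    def test_empty_patch_is_uniform_background(self):
        from nucmorph.types import Patch

        rgb, labels = render_patch(Patch("p", "pt", 64, 64, []), noise_sd=0)
        assert len(np.unique(rgb.reshape(-1, 3), axis=0)) == 1
        assert labels.max() == 0

    def test_single_disc_gives_one_component(self):
        import scipy.ndimage as ndi
        from nucmorph.types import NucleusRecord, Patch

        t = np.linspace(0, 2 * np.pi, 48, endpoint=False)
        nuc = NucleusRecord(
            id=1, boundary=np.column_stack([60 + 10 * np.cos(t), 60 + 10 * np.sin(t)])
        )
        _, labels = render_patch(Patch("p", "pt", 120, 120, [nuc]), noise_sd=0)
        n_components = ndi.label(labels > 0)[1]
        assert n_components == 1


def replace_seed(cfg, seed):
    return replace(cfg, seed=seed)
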
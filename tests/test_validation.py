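import math

import numpy as np
import pytest

from manglar.geometry import EmptyInputError, PatchLayer, PatchPolygon
from manglar.validation import (
    ConfusionMatrix,
    GroundTruthSite,
    cohens_kappa,
    confusion,
    digitizer_qa,
    overall_accuracy,
    qa_error_rate,
    sample_validation_points,
    survey_sample_size,
    z_compare,
)


def _square(side=100.0, ox=0.0, oy=0.0):
    return PatchPolygon(exterior=[(ox, oy), (ox + side, oy),
                                  (ox + side, oy + side), (ox, oy + side)])


class TestPointSampling:
    def test_buffer_area_is_3p14_ha(self):
        site = GroundTruthSite(x=0, y=0, label="mangrove")
        assert round(site.buffer_area_ha, 2) == 3.14

    def test_deterministic_for_fixed_seed(self):
        site = GroundTruthSite(x=10, y=20, label="mangrove")
        a = sample_validation_points(site, 500, seed=9)
        b = sample_validation_points(site, 500, seed=9)
        assert np.array_equal(a, b)

    def test_all_points_inside_radius(self):
        site = GroundTruthSite(x=5, y=-3, label="non-mangrove", buffer_radius=40)
        pts = sample_validation_points(site, 2000, seed=1)
        r = np.hypot(pts[:, 0] - 5, pts[:, 1] + 3)
        assert (r <= 40.0 + 1e-9).all()

    def test_uniform_disc_mean_distance(self):
        """Uniform density on a disc gives E[r] = 2R/3."""
        site = GroundTruthSite(x=0, y=0, label="mangrove", buffer_radius=100)
        pts = sample_validation_points(site, 100_000, seed=2)
        mean_r = np.hypot(pts[:, 0], pts[:, 1]).mean()
        assert mean_r == pytest.approx(200.0 / 3.0, rel=0.01)

    def test_bad_radius(self):
        with pytest.raises(ValueError):
            sample_validation_points(
                GroundTruthSite(x=0, y=0, label="mangrove", buffer_radius=0), 10, 1)


class TestConfusion:
    def test_perfect_map_is_diagonal(self):
        layer = PatchLayer(patches=(_square(),))
        pts = np.array([[50.0, 50.0], [10.0, 10.0], [500.0, 500.0], [-50.0, 0.0]])
        truth = np.array([True, True, False, False])
        cm = confusion(layer, pts, truth)
        assert (cm.mm, cm.nn, cm.mn, cm.nm) == (2, 2, 0, 0)

    def test_planted_disagreement_recovered(self):
        rng = np.random.default_rng(0)
        layer = PatchLayer(patches=(_square(),))
        inside = rng.uniform(1, 99, size=(200, 2))
        truth = np.ones(200, dtype=bool)
        flip = rng.choice(200, size=10, replace=False)
        truth[flip] = False  # plant 5 % disagreement
        cm = confusion(layer, inside, truth)
        assert cm.mn == 10 and cm.nm == 0

    def test_boundary_point_counts_as_mangrove(self):
        layer = PatchLayer(patches=(_square(),))
        cm = confusion(layer, np.array([[0.0, 50.0]]), np.array([True]))
        assert cm.mm == 1

    def test_empty_points_raise(self):
        with pytest.raises(EmptyInputError):
            confusion(PatchLayer(patches=(_square(),)), np.empty((0, 2)), [])


class TestAccuracyAndKappa:
    def test_perfect(self):
        cm = ConfusionMatrix(mm=450, mn=0, nm=0, nn=50)
        assert overall_accuracy(cm) == pytest.approx(100.0)
        assert cohens_kappa(cm) == pytest.approx(1.0)

    def test_balanced_90pct(self):
        cm = ConfusionMatrix(mm=45, mn=5, nm=5, nn=45)
        assert overall_accuracy(cm) == pytest.approx(90.0)
        assert cohens_kappa(cm) == pytest.approx(0.8)

    def test_random_labels_accuracy_half_kappa_zero(self):
        rng = np.random.default_rng(4)
        a = rng.random(10_000) < 0.5
        b = rng.random(10_000) < 0.5
        cm = ConfusionMatrix(
            mm=int(np.sum(a & b)), mn=int(np.sum(a & ~b)),
            nm=int(np.sum(~a & b)), nn=int(np.sum(~a & ~b)))
        assert overall_accuracy(cm) == pytest.approx(50.0, abs=2.0)
        assert cohens_kappa(cm) == pytest.approx(0.0, abs=0.03)

    def test_kappa_one_iff_diagonal_with_both_classes(self):
        assert cohens_kappa(ConfusionMatrix(1, 0, 0, 1)) == pytest.approx(1.0)
        assert cohens_kappa(ConfusionMatrix(45, 5, 5, 45)) < 1.0
        with pytest.raises(ZeroDivisionError):
            cohens_kappa(ConfusionMatrix(10, 0, 0, 0))


class TestZTest:
    @pytest.mark.parametrize(
        "p2,expected",
        [(0.901, 6.3), (0.886, 6.9), (0.775, 10.7), (0.893, 6.7)],
    )
    def test_printed_map_comparisons(self, p2, expected):
        """Accuracy comparisons between the digitized map (99.1 %) and the
        four legacy maps at 500 points each."""
        zc = z_compare(0.991 * 500, 500, p2 * 500, 500)
        assert abs(zc.z) == pytest.approx(expected, abs=0.1)
        assert zc.significant

    def test_equal_proportions_z_zero(self):
        zc = z_compare(450, 500, 450, 500)
        assert zc.z == pytest.approx(0.0)
        assert not zc.significant

    def test_antisymmetry(self):
        a = z_compare(495, 500, 450, 500)
        b = z_compare(450, 500, 495, 500)
        assert a.z == pytest.approx(-b.z)

    def test_pooled_rho(self):
        zc = z_compare(400, 500, 300, 500)
        assert zc.rho == pytest.approx(0.7)

    def test_degenerate_proportions(self):
        with pytest.raises(ZeroDivisionError):
            z_compare(0, 500, 0, 500)

    def test_type_one_error_rate_at_alpha_05(self):
        """Two maps of equal true accuracy: |Z| >= 1.96 in ~5 % of trials."""
        rng = np.random.default_rng(12)
        n, p, sims = 500, 0.9, 2000
        x1 = rng.binomial(n, p, sims)
        x2 = rng.binomial(n, p, sims)
        rej = 0
        for a, b in zip(x1, x2):
            try:
                rej += abs(z_compare(int(a), n, int(b), n).z) >= 1.96
            except ZeroDivisionError:
                pass
        rate = 100.0 * rej / sims
        assert rate == pytest.approx(5.0, abs=1.5)


class TestDigitizerQA:
    def test_identical_polygon_fully_coincident(self, unit_square):
        r = digitizer_qa(unit_square, unit_square, tol=5.0)
        assert r.coincidence_fraction == pytest.approx(1.0)
        assert r.accurate

    def test_far_translation_zero(self, unit_square):
        far = unit_square.translate(1000.0, 0.0)
        r = digitizer_qa(far, unit_square, tol=5.0)
        assert r.coincidence_fraction == pytest.approx(0.0)
        assert not r.accurate

    def test_one_displaced_side_gives_three_quarters(self):
        """A 10 m square with one side pushed 15 m out (tol 5 m): the three
        matching sides are 30 of 40+ m of outline, fraction ~0.75 -> accurate."""
        ref = PatchPolygon(exterior=[(0, 0), (10, 0), (10, 10), (0, 10)])
        cand = PatchPolygon(exterior=[(0, 0), (10, 0), (10, 25), (0, 25)])
        r = digitizer_qa(cand, ref, tol=5.0)
        # candidate perimeter 70: bottom 10 + two 15 m flank stubs within tol
        assert r.coincidence_fraction == pytest.approx(40.0 / 70.0, abs=0.02)
        assert r.accurate


class TestQAErrorRateAndSurvey:
    @pytest.mark.parametrize("bad,n,expected", [(37, 82, 45.12), (8, 77, 10.39), (0, 3, 0.0)])
    def test_island_strata(self, bad, n, expected):
        assert qa_error_rate(bad, n) == pytest.approx(expected, abs=0.005)

    def test_eight_percent_stratified_sample(self):
        assert survey_sample_size(4099, fraction=0.08) == 328

    def test_cochran_with_fpc(self):
        assert survey_sample_size(4099, margin=0.05, z=2.58) == 573

    def test_margin_to_zero_saturates_at_population(self):
        assert survey_sample_size(50, margin=0.001, z=2.58) == 50
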
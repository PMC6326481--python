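import numpy as np
import pytest
from shapely.geometry import Polygon

from manglar.change import (
    STAMP_CATEGORIES,
    align_epochs,
    change_summary,
    ks_two_sample,
    stamp_events,
)
from manglar.geometry import CoastlineLayer, EmptyInputError, PatchLayer, PatchPolygon
from manglar import synth


def _square(side=100.0, ox=0.0, oy=0.0, id=""):
    return PatchPolygon(exterior=[(ox, oy), (ox + side, oy),
                                  (ox + side, oy + side), (ox, oy + side)], id=id)


def _layer(*patches, epoch=None):
    return PatchLayer(patches=tuple(patches), epoch=epoch)


def _totals(events):
    out = {c: 0.0 for c in STAMP_CATEGORIES}
    for ev in events:
        out[ev.category] += ev.area
    return out


COAST = CoastlineLayer(polylines=(((0.0, 0.0), (10_000.0, 0.0)),))


class TestStampEvents:
    def test_identical_layers_all_stable(self):
        a = _layer(_square(), _square(ox=500))
        ev = stamp_events(a, a)
        t = _totals(ev)
        assert t["STB"] == pytest.approx(20_000.0)
        assert t["EXP"] == t["CON"] == t["GEN"] == t["DIS"] == 0.0

    def test_buffered_square_expansion_algebra(self):
        """100 m square grown by 5 m on all sides: STB 10 000 m²,
        EXP = 105² − 100² = 1 025 m² (mitred corners), no contraction."""
        t0 = _layer(_square(100.0))
        grown = PatchPolygon.from_shapely(
            _square(100.0).shapely.buffer(2.5, join_style="mitre"))
        t1 = _layer(grown)
        t = _totals(stamp_events(t0, t1))
        assert t["STB"] == pytest.approx(10_000.0)
        assert t["EXP"] == pytest.approx(105.0**2 - 100.0**2)
        assert t["CON"] == pytest.approx(0.0)

    def test_threshold_semantics_dis_and_gen(self):
        """Nearest neighbour 20 m away with a 15 m threshold: separate
        groups, so the old patch disappears and the new one is generated."""
        t0 = _layer(_square(10.0, ox=0.0))
        t1 = _layer(_square(10.0, ox=30.0))  # 20 m gap
        t = _totals(stamp_events(t0, t1, dist_threshold=15.0))
        assert t["DIS"] == pytest.approx(100.0)
        assert t["GEN"] == pytest.approx(100.0)
        assert t["STB"] == 0.0

    def test_within_threshold_counts_as_same_group(self):
        t0 = _layer(_square(10.0, ox=0.0))
        t1 = _layer(_square(10.0, ox=20.0))  # 10 m gap < 15 m threshold
        t = _totals(stamp_events(t0, t1, dist_threshold=15.0))
        assert t["GEN"] == 0.0 and t["DIS"] == 0.0
        assert t["CON"] == pytest.approx(100.0)
        assert t["EXP"] == pytest.approx(100.0)

    def test_crs_mismatch(self):
        a = _layer(_square())
        b = PatchLayer(patches=(_square(),), crs="EPSG:32716")
        with pytest.raises(ValueError):
            stamp_events(a, b)

    def test_conservation_on_random_epoch_pairs(self):
        """area(t) = STB+CON+DIS and area(t+Δ) = STB+EXP+GEN on random
        overlapping epoch pairs."""
        rng = np.random.default_rng(8)
        for _ in range(200):
            def rand_layer():
                ps = []
                for k in range(rng.integers(1, 6)):
                    ox, oy = rng.uniform(0, 400, 2)
                    side = rng.uniform(5, 80)
                    ps.append(_square(side, ox, oy))
                return _layer(*ps)

            a, b = rand_layer(), rand_layer()
            t = _totals(stamp_events(a, b, rng.uniform(0, 30)))
            area_t = sum(p.shapely.area for p in a)
            area_t1 = sum(p.shapely.area for p in b)
            # layers may self-overlap; compare union areas
            from shapely.ops import unary_union
            area_t = unary_union([p.shapely for p in a]).area
            area_t1 = unary_union([p.shapely for p in b]).area
            assert t["STB"] + t["CON"] + t["DIS"] == pytest.approx(area_t, rel=1e-6)
            assert t["STB"] + t["EXP"] + t["GEN"] == pytest.approx(area_t1, rel=1e-6)

    def test_time_reversal_symmetry(self):
        rng = np.random.default_rng(5)
        a = _layer(*[_square(rng.uniform(10, 60), *rng.uniform(0, 300, 2)) for _ in range(4)])
        b = _layer(*[_square(rng.uniform(10, 60), *rng.uniform(0, 300, 2)) for _ in range(4)])
        fwd = _totals(stamp_events(a, b))
        rev = _totals(stamp_events(b, a))
        assert fwd["STB"] == pytest.approx(rev["STB"], rel=1e-9)
        assert fwd["EXP"] == pytest.approx(rev["CON"], rel=1e-9)
        assert fwd["GEN"] == pytest.approx(rev["DIS"], rel=1e-9)

    def test_scripted_generator_recovered_exactly(self, landscape):
        """Planted event areas match the recovered decomposition exactly when
        displacements are under and gaps over the grouping threshold."""
        ev = stamp_events(landscape.layer_t, landscape.layer_t1)
        rec = _totals(ev)
        for cat in STAMP_CATEGORIES:
            assert rec[cat] == pytest.approx(
                landscape.ledger.planted_area[cat], rel=1e-9, abs=1e-6)


class TestChangeSummary:
    def test_no_change(self):
        a = _layer(_square())
        s = change_summary(stamp_events(a, a), COAST)
        assert s.area_ha["EXP"] == s.area_ha["CON"] == 0.0
        assert s.area_ha["GEN"] == s.area_ha["DIS"] == 0.0
        assert s.percent_increase == pytest.approx(0.0)

    def test_per_km_normalization(self):
        a = _layer(_square(100.0))  # 1 ha stable on a 10 km coast
        s = change_summary(stamp_events(a, a), COAST)
        assert s.area_per_km["STB"] == pytest.approx(0.1)

    def test_percent_increase_matches_published_arithmetic(self):
        """203.7 ha -> 251.9 ha over the decade is a 23.7 % increase."""
        assert 100 * (251.9 - 203.7) / 203.7 == pytest.approx(23.7, abs=0.05)
        assert 100 * (130.4 - 118.8) / 118.8 == pytest.approx(9.8, abs=0.05)

    def test_summary_equals_ledger(self, landscape):
        ev = stamp_events(landscape.layer_t, landscape.layer_t1)
        s = change_summary(ev, landscape.coastline)
        assert s.total_t * 1e4 == pytest.approx(landscape.ledger.total_t, rel=1e-9)
        assert s.total_t1 * 1e4 == pytest.approx(landscape.ledger.total_t1, rel=1e-9)


class TestKS:
    def test_identical_samples(self):
        d, p = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == pytest.approx(0.0)

    def test_disjoint_supports(self):
        d, _ = ks_two_sample([1.0, 2.0], [10.0, 20.0])
        assert d == pytest.approx(1.0)

    def test_empty_sample(self):
        with pytest.raises(EmptyInputError):
            ks_two_sample([], [1.0])

    def test_null_rejection_rate(self):
        """Same-distribution samples: 5 % rejections at alpha = 0.05."""
        rng = np.random.default_rng(3)
        rej = 0
        sims = 2000
        for _ in range(sims):
            a, b = rng.random(100), rng.random(100)
            _, p = ks_two_sample(a, b)
            rej += p < 0.05
        assert 100.0 * rej / sims == pytest.approx(5.0, abs=2.0)


class TestAlignEpochs:
    def test_zero_shift_identity(self):
        a = _layer(_square())
        assert align_epochs(a, (0.0, 0.0)).patches == a.patches

    def test_round_trip(self):
        a = _layer(_square(), _square(ox=300))
        back = align_epochs(align_epochs(a, (12.5, -7.0)), (-12.5, 7.0))
        for p, q in zip(a, back):
            assert np.allclose(p.exterior, q.exterior)

    def test_three_four_five_displacement(self):
        a = _layer(_square())
        moved = align_epochs(a, (3.0, 4.0))
        for (x0, y0), (x1, y1) in zip(a.patches[0].exterior, moved.patches[0].exterior):
            assert np.hypot(x1 - x0, y1 - y0) == pytest.approx(5.0)

    def test_areas_preserved(self, landscape):
        moved = align_epochs(landscape.layer_t, (250.0, -31.0))
        assert moved.total_area == pytest.approx(landscape.layer_t.total_area, rel=1e-12)
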
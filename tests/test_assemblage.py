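"""ZNISP tabulation, broad-category mapping, morphology comparison, grids."""

import numpy as np
import pandas as pd
import pytest

from zoomsid.assemblage import (
    FAIL,
    ZNISPTable,
    compare_with_morph,
    expand_fixture,
    load_broad_map,
    load_morph_fixture,
    load_znisp_fixture,
    map_broad,
    round_half_up,
    spatial_success,
    success_rate,
    tabulate_znisp,
)
from zoomsid.identification import Identification
from zoomsid.spectral_io import SampleRecord


@pytest.fixture(scope="module")
def znisp():
    return load_znisp_fixture()


def test_round_half_up():
    assert round_half_up(8.55, 1) == 8.6
    assert round_half_up(12.85, 1) == 12.9
    assert round_half_up(87.14) == 87
    assert round_half_up(91.43) == 91
    assert round_half_up(0.5) == 1


class TestFixtureArithmetic:
    """Published assemblage counts reproduce the reported headline numbers."""

    def test_stratum_totals(self, znisp):
        totals = znisp.totals()
        assert totals["Mousterian"] == 210
        assert totals["Uluzzian"] == 840
        assert totals["Protoaurignacian"] == 213
        assert totals.sum() == 1263

    def test_identified_total(self, znisp):
        assert znisp.identified().sum() == 1263 - 149 == 1114

    def test_key_percentages(self, znisp):
        pct = znisp.percentages()
        assert pct.loc["Equus", "Uluzzian"] == 40.2
        assert pct.loc["Equus", "Protoaurignacian"] == 50.2
        assert pct.loc[FAIL, "Uluzzian"] == 12.9
        assert pct.loc[FAIL, "Mousterian"] == 8.6
        assert pct.loc["Cervid", "Mousterian"] == 56.2

    def test_percentages_sum_to_100(self, znisp):
        for stratum, total in znisp.percentages().sum().items():
            assert total == pytest.approx(100.0, abs=0.3), stratum

    def test_success_rates(self, znisp):
        assert success_rate(znisp, "Mousterian") == 91
        assert success_rate(znisp, "Uluzzian") == 87
        assert success_rate(znisp) == 88

    def test_broad_totals(self, znisp):
        broad = map_broad(znisp, load_broad_map())
        by_cat = broad.counts.sum(axis=1)
        assert by_cat["Equid"] == 448
        assert by_cat["Cervidae"] == 367
        # conservation across the mapping
        assert broad.counts.to_numpy().sum() == znisp.counts.to_numpy().sum() == 1114

    def test_expand_fixture_round_trip(self, znisp):
        ids, records = expand_fixture(znisp)
        again = tabulate_znisp(ids, records, stratum="complex")
        pd.testing.assert_frame_equal(
            again.counts.sort_index(), znisp.counts.sort_index(), check_names=False
        )
        pd.testing.assert_series_equal(again.fails, znisp.fails, check_names=False)


class TestTabulate:
    def make(self, spec):
        """spec: list of (category_or_None, complex)"""
        ids, recs = [], []
        for k, (cat, cx) in enumerate(spec):
            sid = f"S{k}"
            layer = {"Mousterian": "gar", "Uluzzian": "pie", "Protoaurignacian": "rsa'"}[cx]
            recs.append(SampleRecord(sid, layer=layer, complex=cx))
            if cat is None:
                ids.append(Identification(sid, "fail", None, 1, "single"))
            else:
                ids.append(Identification(sid, "identified", cat, 9, "full"))
        return ids, recs

    def test_empty_input(self):
        t = tabulate_znisp([], [], stratum="complex")
        assert t.counts.empty

    def test_single_sample_hundred_percent(self):
        ids, recs = self.make([("Equus", "Uluzzian")])
        t = tabulate_znisp(ids, recs)
        assert t.percentages().loc["Equus", "Uluzzian"] == 100.0

    def test_fail_counts_in_total(self):
        ids, recs = self.make([("Equus", "Uluzzian"), (None, "Uluzzian")])
        t = tabulate_znisp(ids, recs)
        assert t.totals()["Uluzzian"] == 2
        assert success_rate(t, "Uluzzian") == 50

    def test_by_layer(self):
        ids, recs = self.make([("Equus", "Uluzzian"), ("Cervid", "Mousterian")])
        t = tabulate_znisp(ids, recs, stratum="layer")
        assert set(t.strata) == {"pie", "gar"}

    def test_missing_record_raises(self):
        ids, _ = self.make([("Equus", "Uluzzian")])
        with pytest.raises(ValueError, match="S0"):
            tabulate_znisp(ids, [])

    def test_unknown_stratum_rejected(self, znisp):
        with pytest.raises(KeyError):
            success_rate(znisp, "Aurignacian")
        with pytest.raises(ValueError):
            tabulate_znisp([], [], stratum="square")


class TestBroadMapping:
    def test_identity_map_unchanged(self, znisp):
        ident = {c: c for c in znisp.counts.index}
        out = map_broad(znisp, ident)
        pd.testing.assert_frame_equal(
            out.counts.sort_index(), znisp.counts.sort_index(), check_names=False
        )

    def test_unmapped_category_named(self, znisp):
        partial = load_broad_map().copy()
        partial.pop("Equus")
        with pytest.raises(KeyError, match="Equus"):
            map_broad(znisp, partial)


class TestCompareWithMorph:
    def test_proportional_morph_perfect_correlation(self, znisp):
        broad = map_broad(znisp, load_broad_map())
        morph = broad.counts * 3
        cmp = compare_with_morph(broad, morph, n_permutations=200, seed=1)
        assert np.allclose(cmp.stats["spearman_rho"], 1.0)

    def test_zero_morph_totals_equal_znisp(self, znisp):
        broad = map_broad(znisp, load_broad_map())
        morph = broad.counts * 0
        cmp = compare_with_morph(broad, morph, n_permutations=50, seed=1)
        assert (cmp.table["total"] == cmp.table["znisp"]).all()

    def test_transcribed_morph_positive_in_all_complexes(self, znisp):
        """ZooMS and morphological abundances rank-agree in every complex."""
        broad = map_broad(znisp, load_broad_map())
        cmp = compare_with_morph(broad, load_morph_fixture(), n_permutations=2000, seed=7)
        assert (cmp.stats["spearman_rho"] > 0).all()

    def test_category_mismatch_rejected(self, znisp):
        broad = map_broad(znisp, load_broad_map())
        with pytest.raises(ValueError):
            compare_with_morph(broad, broad.counts.iloc[:3], n_permutations=10)


class TestSpatialSuccess:
    def make(self, per_square):
        """per_square: {square: (n_ok, n_fail)}"""
        ids, recs = [], []
        k = 0
        for sq, (ok, fail) in per_square.items():
            for flag in [True] * ok + [False] * fail:
                sid = f"S{k}"; k += 1
                recs.append(SampleRecord(sid, layer="pie", complex="Uluzzian", square=sq))
                status = "identified" if flag else "fail"
                ids.append(Identification(sid, status, "Equus" if flag else None, 9, "single"))
        return ids, recs

    def test_all_identified_square(self):
        ids, recs = self.make({"G12": (5, 0)})
        grid = spatial_success(ids, recs)
        assert grid.percent("G12") == 100.0

    def test_unsampled_square_absent_not_zero(self):
        ids, recs = self.make({"G12": (1, 1)})
        grid = spatial_success(ids, recs)
        assert "H13" not in grid.grid.index
        assert grid.percent("G12") == 50.0

    def test_no_square_records_excluded(self):
        ids, recs = self.make({"G12": (2, 0)})
        recs.append(SampleRecord("X1", layer="pie", complex="Uluzzian"))
        ids.append(Identification("X1", "identified", "Equus", 9, "single"))
        grid = spatial_success(ids, recs)
        assert grid.grid["n_sampled"].sum() == 2
        assert grid.grid.attrs["n_no_square"] == 1

    def test_binomial_preservation_band(self):
        """p=0.8 per sample, n=200 per square: nearly every square in [70, 90]."""
        rng = np.random.default_rng(42)
        hits = 0
        squares = [f"G{i}" for i in range(20)]
        per_square = {}
        for sq in squares:
            ok = int(rng.binomial(200, 0.8))
            per_square[sq] = (ok, 200 - ok)
        ids, recs = self.make(per_square)
        grid = spatial_success(ids, recs)
        inside = [(70 <= grid.percent(sq) <= 90) for sq in squares]
        assert np.mean(inside) >= 0.95

    def test_by_layer_index(self):
        ids, recs = self.make({"G12": (3, 1)})
        grid = spatial_success(ids, recs, by_layer=True)
        assert grid.percent(("G12", "pie")) == 75.0


class TestZNISPTableInvariants:
    def test_negative_counts_rejected(self):
        counts = pd.DataFrame({"Uluzzian": [-1]}, index=["Equus"])
        with pytest.raises(ValueError):
            ZNISPTable(counts, pd.Series({"Uluzzian": 0}))

    def test_totals_are_counts_plus_fails(self, znisp):
        assert (znisp.totals() == znisp.counts.sum() + znisp.fails).all()
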
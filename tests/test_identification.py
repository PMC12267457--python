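"""Marker matching, category resolution, replicate consensus, full chain."""

import numpy as np
import pytest

from zoomsid.identification import (
    Identification,
    MatchConfig,
    classify_sample,
    combine_replicates,
    match_markers,
    resolve_taxon,
)
from zoomsid.spectral_io import Peak, PeakList
from zoomsid.synthetic_data import SimulationConfig, render_spectrum

CERVIDS = {"Cervus elaphus", "Dama dama", "Megaloceros giganteus"}


def peaklist(*mzs, sample_id="S1", rep=1, intensity=50.0):
    return PeakList(sample_id, rep, peaks=[Peak(m, intensity, 10.0) for m in mzs])


def matches_for(lib, *mzs, cfg=MatchConfig()):
    return match_markers(peaklist(*mzs), lib, cfg)


class TestMatchMarkers:
    def test_cervid_anchor_peak(self, lib):
        ms = matches_for(lib, 3033.1)
        assert len(ms) == 1
        m = ms[0]
        assert m.marker_id == "COL1a2 757-789"
        assert m.leaves == CERVIDS
        assert m.best_delta == pytest.approx(0.4)

    def test_empty_peaklist(self, lib):
        assert match_markers(peaklist(), lib) == []

    def test_at_most_one_match_per_marker(self, lib):
        # two in-window peaks: the smaller-delta one must win
        pl = peaklist(3033.4, 3035.2)
        ms = match_markers(pl, lib)
        assert len(ms) == 1
        assert ms[0].observed_mz == pytest.approx(3033.4)

    def test_equidistant_values_both_carried(self, lib):
        """A peak within tolerance of two variant groups keeps both leaf sets."""
        cfg = MatchConfig(mz_tolerance=2.0)
        ms = matches_for(lib, 3034.8, cfg=cfg)  # 1.3 Da from 3033.5, within 2.0
        (m,) = [m for m in ms if m.marker_id == "COL1a2 757-789"]
        assert m.leaves >= CERVIDS

    def test_out_of_window_peak_ignored(self, lib):
        assert matches_for(lib, 999.0) == []


class TestResolveTaxon:
    def test_broadens_without_marker_c(self, lib):
        """No COL1a2 502-519 peak: 1580/1550 cannot separate cervids from
        chamois, so the call stays at Cervid/Rupicapra."""
        leaf = lib.leaves["Cervus elaphus"]
        skip = {"COL1a2 502-519", "COL1a2 757-789"}
        mzs = [v for mid, vs in leaf.marker_mz.items() if mid not in skip for v in vs[:1]]
        ident = resolve_taxon(matches_for(lib, *mzs), lib, sample_id="S1")
        assert ident.identified
        assert ident.category == "Cervid/Rupicapra"

    def test_marker_c_without_g_gives_unidentified_cervid(self, lib):
        """1580 on marker C pins the cervids, but without COL1a2 757-789 the
        roe/red-fallow split is impossible: all cervid species remain."""
        leaf = lib.leaves["Cervus elaphus"]
        skip = {"COL1a2 757-789"}
        mzs = [v for mid, vs in leaf.marker_mz.items() if mid not in skip for v in vs[:1]]
        ident = resolve_taxon(matches_for(lib, *mzs), lib)
        assert ident.category == "Unidentified Cervid"

    def test_three_markers_fail(self, lib):
        leaf = lib.leaves["Equus"]
        mzs = [leaf.marker_mz[mid][0] for mid in list(leaf.marker_mz)[:3]]
        ident = resolve_taxon(matches_for(lib, *mzs), lib)
        assert ident.status == "fail"
        assert ident.n_markers == 3

    def test_nine_markers_equus(self, lib):
        leaf = lib.leaves["Equus"]
        mzs = [v for vs in leaf.marker_mz.values() for v in vs[:1]]
        ident = resolve_taxon(matches_for(lib, *mzs), lib)
        assert ident.identified
        assert ident.category == "Equus"
        assert ident.n_markers == 9

    def test_conflicting_intersection_fails(self, lib):
        # mix Equus-only and Capreolus-only diagnostic masses
        eq, cap = lib.leaves["Equus"], lib.leaves["Capreolus capreolus"]
        mzs = [eq.marker_mz["COL1a2 484-498"][0], eq.marker_mz["COL1a2 502-519"][0],
               cap.marker_mz["COL1a2 757-789"][0], eq.marker_mz["COL1a1 934-963"][0]]
        ident = resolve_taxon(matches_for(lib, *mzs), lib)
        assert ident.status == "fail"
        assert ident.conflict

    def test_intersection_monotone(self, lib):
        """Each added marker can only shrink the candidate set."""
        leaf = lib.leaves["Rupicapra rupicapra"]
        mzs = [v for vs in leaf.marker_mz.values() for v in vs[:1]]
        previous = set(lib.leaves)
        for k in range(1, len(mzs) + 1):
            ident = resolve_taxon(matches_for(lib, *mzs[:k]), lib)
            assert ident.candidates <= previous
            previous = set(ident.candidates)
        assert previous == {"Rupicapra rupicapra"}


class TestCombineReplicates:
    def equus_ident(self, lib, n_markers=9, sample_id="S1"):
        leaf = lib.leaves["Equus"]
        mzs = [v for vs in leaf.marker_mz.values() for v in vs[:1]][:n_markers]
        return resolve_taxon(matches_for(lib, *mzs), lib, sample_id=sample_id)

    def capreolus_ident(self, lib, sample_id="S1"):
        leaf = lib.leaves["Capreolus capreolus"]
        mzs = [v for vs in leaf.marker_mz.values() for v in vs[:1]]
        return resolve_taxon(matches_for(lib, *mzs), lib, sample_id=sample_id)

    def test_three_identical_full_agreement(self, lib):
        ids = [self.equus_ident(lib) for _ in range(3)]
        out = combine_replicates(ids, lib)
        assert out.category == "Equus"
        assert out.replicate_agreement == "full"

    def test_two_good_one_fail_partial(self, lib):
        ids = [self.equus_ident(lib), self.equus_ident(lib),
               resolve_taxon(matches_for(lib, *[]), lib, sample_id="S1")]
        out = combine_replicates(ids, lib)
        assert out.identified
        assert out.category == "Equus"
        assert out.replicate_agreement == "partial"

    def test_disjoint_replicates_conflict(self, lib):
        out = combine_replicates([self.equus_ident(lib), self.capreolus_ident(lib)], lib)
        assert out.replicate_agreement == "conflict"
        assert out.conflict
        assert out.status == "fail"

    def test_union_pools_markers(self, lib):
        # 3 markers + 3 different markers -> combined 6 markers, identified
        leaf = lib.leaves["Equus"]
        mzs = [v for vs in leaf.marker_mz.values() for v in vs[:1]]
        a = resolve_taxon(matches_for(lib, *mzs[:3]), lib, sample_id="S1")
        b = resolve_taxon(matches_for(lib, *mzs[3:6]), lib, sample_id="S1")
        assert a.status == b.status == "fail"
        out = combine_replicates([a, b], lib)
        assert out.n_markers == 6
        assert out.identified
        assert out.category == "Equus"

    def test_mismatched_sample_ids_rejected(self, lib):
        with pytest.raises(ValueError, match="different samples"):
            combine_replicates(
                [self.equus_ident(lib, sample_id="A"), self.equus_ident(lib, sample_id="B")],
                lib,
            )

    def test_single_replicate_marked_single(self, lib):
        out = combine_replicates([self.equus_ident(lib)], lib)
        assert out.replicate_agreement == "single"


class TestClassifySample:
    def triplicate(self, lib, taxon, survival, seed=11):
        cfg = SimulationConfig(seed=seed)
        rng = np.random.default_rng(seed)
        return [
            render_spectrum(taxon, survival, cfg, lib, rng, sample_id="SYN1", replicate_index=r)
            for r in (1, 2, 3)
        ]

    def test_full_survival_equus(self, lib):
        surv = {m: True for m in lib.leaves["Equus"].marker_mz}
        out = classify_sample(self.triplicate(lib, "Equus", surv), lib)
        assert out.identified
        assert out.category == "Equus"
        assert out.n_markers == 9

    def test_all_markers_dropped_fails(self, lib):
        surv = {m: False for m in lib.leaves["Equus"].marker_mz}
        out = classify_sample(self.triplicate(lib, "Equus", surv), lib)
        assert out.status == "fail"
        assert out.n_markers == 0

    def test_capreolus_excludes_cervid_group(self, lib):
        surv = {m: True for m in lib.leaves["Capreolus capreolus"].marker_mz}
        out = classify_sample(self.triplicate(lib, "Capreolus capreolus", surv), lib)
        assert out.identified
        members = lib.categories[out.category].members
        assert "Capreolus capreolus" in members
        assert not (members & CERVIDS)

    def test_deterministic(self, lib):
        surv = {m: True for m in lib.leaves["Bos"].marker_mz}
        spectra = self.triplicate(lib, "Bos", surv)
        a = classify_sample(spectra, lib)
        b = classify_sample(spectra, lib)
        assert a == b


class TestMatchConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [{"mz_tolerance": 0.0}, {"mz_tolerance": 3.0}, {"min_markers": 0},
         {"min_markers": 10}, {"consensus_rule": "majority"}],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MatchConfig(**kwargs)
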
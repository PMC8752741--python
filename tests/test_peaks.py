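import numpy as np
import pandas as pd
import pytest

from uprnet import peaks as pk
from uprnet.exceptions import ConsistencyError, ParameterError
from uprnet.io import PeakSet


def _peakset(rows, **prov):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score",
                                     "strand", "signal", "pfloat", "qvalue",
                                     "summit_offset", "summit"])
    return PeakSet(df, **prov)


def _row(chrom, start, end, name, pfloat, summit=None):
    summit = summit if summit is not None else (start + end) // 2
    return (chrom, start, end, name, 0, ".", pfloat / 2, pfloat, -1.0,
            summit - start, summit)


class TestUprSpecificFilter:
    def test_low_overlap_retained(self):
        tm = _peakset([_row("c1", 1000, 1400, "t1", 10)])
        mock = _peakset([_row("c1", 1300, 1700, "m1", 9)])   # 100/400 = 25%
        ret, elim = pk.upr_specific_filter(tm, mock)
        assert ret.ids == {"t1"} and len(elim) == 0
        assert not ret.peaks["rescued"].iloc[0]

    def test_high_overlap_rescued_by_pfloat_ratio(self):
        tm = _peakset([_row("c1", 1000, 1400, "t1", 10)])
        mock = _peakset([_row("c1", 1200, 1700, "m1", 2)])   # 200/400 = 50%, ratio 5
        ret, elim = pk.upr_specific_filter(tm, mock)
        assert ret.ids == {"t1"} and ret.peaks["rescued"].iloc[0]

    def test_high_overlap_insufficient_ratio_eliminated(self):
        tm = _peakset([_row("c1", 1000, 1400, "t1", 5)])
        mock = _peakset([_row("c1", 1200, 1700, "m1", 2)])   # ratio 2.5
        ret, elim = pk.upr_specific_filter(tm, mock)
        assert len(ret) == 0 and elim.ids == {"t1"}

    def test_boundary_overlap_exactly_30pct_retained(self):
        tm = _peakset([_row("c1", 1000, 1400, "t1", 1)])
        mock = _peakset([_row("c1", 1280, 1700, "m1", 100)])  # 120/400 = 30.0%
        ret, _ = pk.upr_specific_filter(tm, mock)
        assert ret.ids == {"t1"}   # elimination requires strictly > 30%

    def test_boundary_ratio_exactly_3_eliminated(self):
        tm = _peakset([_row("c1", 1000, 1400, "t1", 6)])
        mock = _peakset([_row("c1", 1200, 1700, "m1", 2)])   # ratio 3.0, not > 3
        ret, elim = pk.upr_specific_filter(tm, mock)
        assert elim.ids == {"t1"}

    def test_zero_mock_pfloat_rescues(self):
        tm = _peakset([_row("c1", 1000, 1400, "t1", 5)])
        mock = _peakset([_row("c1", 1000, 1400, "m1", 0.0)])
        ret, _ = pk.upr_specific_filter(tm, mock)
        assert ret.ids == {"t1"}

    def test_union_coverage_across_multiple_mock_peaks(self):
        tm = _peakset([_row("c1", 1000, 1400, "t1", 5)])
        # two mock peaks covering 80 bp each, disjoint: union 160/400 = 40%
        mock = _peakset([_row("c1", 1000, 1080, "m1", 4),
                         _row("c1", 1200, 1280, "m2", 4)])
        ret, elim = pk.upr_specific_filter(tm, mock)
        assert elim.ids == {"t1"}

    @staticmethod
    def _random_fixture(rng):
        def peaks(prefix, n):
            rows = []
            for i in range(n):
                start = int(rng.integers(0, 3000))
                width = int(rng.integers(50, 400))
                rows.append(_row("c1", start, start + width, f"{prefix}{i}",
                                 float(rng.uniform(0.5, 20))))
            return _peakset(rows)
        return peaks("t", int(rng.integers(1, 10))), peaks("m", int(rng.integers(0, 10)))

    def test_partition_idempotence_monotonicity_on_random_fixtures(self):
        rng = np.random.default_rng(42)
        params = pk.PeakFilterParams()
        tighter = pk.PeakFilterParams(rescue_ratio=6.0)
        looser_frac = pk.PeakFilterParams(overlap_frac=0.15)
        for _ in range(200):
            tm, mock = self._random_fixture(rng)
            ret, elim = pk.upr_specific_filter(tm, mock, params)
            # partition
            assert ret.ids | elim.ids == tm.ids
            assert not ret.ids & elim.ids
            assert len(ret) + len(elim) == len(tm)
            # idempotence
            ret2, elim2 = pk.upr_specific_filter(ret, mock, params)
            assert ret2.ids == ret.ids and len(elim2) == 0
            # monotonicity: higher rescue bar or lower overlap tolerance never grows
            ret_hi, _ = pk.upr_specific_filter(tm, mock, tighter)
            assert ret_hi.ids <= ret.ids
            ret_lo, _ = pk.upr_specific_filter(tm, mock, looser_frac)
            assert ret_lo.ids <= ret.ids


class TestReproduciblePeaks:
    def test_identical_replicates_pass_through(self):
        rows = [_row("c1", 100, 500, "p1", 5), _row("c1", 900, 1300, "p2", 7)]
        r1 = _peakset(rows, tf="A", condition="Tm", timepoint=0)
        r2 = _peakset(rows, tf="A", condition="Tm", timepoint=0)
        out = pk.reproducible_peaks(r1, r2)
        assert out.ids == {"p1", "p2"}

    def test_disjoint_replicates_empty(self):
        r1 = _peakset([_row("c1", 100, 500, "p1", 5)], tf="A", condition="Tm")
        r2 = _peakset([_row("c1", 900, 1300, "q1", 5)], tf="A", condition="Tm")
        assert len(pk.reproducible_peaks(r1, r2)) == 0

    def test_higher_pfloat_partner_wins(self):
        r1 = _peakset([_row("c1", 100, 500, "p1", 5)], tf="A", condition="Tm")
        r2 = _peakset([_row("c1", 120, 520, "q1", 9, summit=300)], tf="A", condition="Tm")
        out = pk.reproducible_peaks(r1, r2)
        assert out.ids == {"q1"}
        assert out.peaks["pfloat"].iloc[0] == 9

    def test_mismatched_provenance_rejected(self):
        r1 = _peakset([], tf="A", condition="Tm")
        r2 = _peakset([], tf="B", condition="Tm")
        with pytest.raises(ConsistencyError):
            pk.reproducible_peaks(r1, r2)

    def test_jittered_planted_replicates_fully_retained(self, sim_config, sim_peaks):
        peaksets, truth = sim_peaks
        for tf, sets in peaksets.items():
            tm_sets = [ps for ps in sets if ps.condition == "Tm" and ps.timepoint == 0]
            out = pk.reproducible_peaks(*tm_sets)
            assert truth.specific_peaks[tf] <= out.ids


class TestMergeAcrossTimepoints:
    def _ps(self, rows):
        return _peakset(rows, tf="A", condition="Tm")

    def test_identical_sets_collapse_once(self):
        rows = [_row("c1", 100, 500, "p1", 5)]
        merged = pk.merge_across_timepoints([self._ps(rows)] * 3)
        assert len(merged) == 1

    def test_disjoint_sets_concatenate_sorted(self):
        a = self._ps([_row("c1", 900, 1300, "p2", 5)])
        b = self._ps([_row("c1", 100, 500, "p1", 5)])
        merged = pk.merge_across_timepoints([a, b])
        assert list(merged.peaks["name"]) == ["p1", "p2"]

    def test_chained_overlaps_span_and_keep_best_summit(self):
        a = self._ps([_row("c1", 100, 500, "A", 5)])
        b = self._ps([_row("c1", 400, 900, "B", 9, summit=600)])
        c = self._ps([_row("c1", 800, 1200, "C", 3)])
        merged = pk.merge_across_timepoints([a, b, c])
        assert len(merged) == 1
        r = merged.peaks.iloc[0]
        assert (r.start, r.end) == (100, 1200)
        assert r["name"] == "B" and r.summit == 600 and r.pfloat == 9
        assert r.summit_offset == 500

    def test_interval_union_matches_oracle_on_random_sets(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            sets = []
            intervals = []
            for s in range(3):
                rows = []
                for i in range(int(rng.integers(1, 8))):
                    start = int(rng.integers(0, 2000))
                    end = start + int(rng.integers(50, 300))
                    rows.append(_row("c1", start, end, f"s{s}i{i}", float(rng.uniform(1, 9))))
                    intervals.append((start, end))
                sets.append(self._ps(rows))
            merged = pk.merge_across_timepoints(sets)
            # oracle: sweep-line union of intervals
            intervals.sort()
            blocks = []
            for s, e in intervals:
                if blocks and s < blocks[-1][1]:
                    blocks[-1][1] = max(blocks[-1][1], e)
                else:
                    blocks.append([s, e])
            got = sorted((r.start, r.end) for r in merged.peaks.itertuples())
            assert got == [tuple(b) for b in blocks]

    def test_mixed_tf_rejected(self):
        a = _peakset([_row("c1", 0, 100, "x", 1)], tf="A")
        b = _peakset([_row("c1", 0, 100, "y", 1)], tf="B")
        with pytest.raises(ConsistencyError):
            pk.merge_across_timepoints([a, b])


class TestAssignAndClassify:
    ANN = pd.DataFrame({
        "gene_id": ["gplus", "gminus"],
        "chrom": ["c1", "c1"],
        "start": [1600, 20000],
        "end": [3600, 22000],
        "strand": ["+", "-"],
        "tss": [1600, 21999],
    })

    def test_tss_within_window_assigned(self):
        ps = _peakset([_row("c1", 1000, 1400, "p", 5)])
        _, _, bound, _ = pk.assign_peaks_to_genes(ps, self.ANN)
        assert bound == {"gplus"}   # distance 200

    def test_tss_one_bp_beyond_window_not_assigned(self):
        ps = _peakset([_row("c1", 100, 600, "p", 5)])
        # gene at TSS 1600: distance = 1600 - 600 = 1000 -> assigned
        _, _, bound, _ = pk.assign_peaks_to_genes(ps, self.ANN)
        assert bound == {"gplus"}
        ps2 = _peakset([_row("c1", 99, 599, "p", 5)])  # distance 1001
        _, _, bound2, inter = pk.assign_peaks_to_genes(ps2, self.ANN)
        assert bound2 == set() and inter == ["p"]

    def test_unknown_chromosome_is_intergenic(self):
        ps = _peakset([_row("cX", 100, 400, "p", 5)])
        _, _, bound, inter = pk.assign_peaks_to_genes(ps, self.ANN)
        assert not bound and inter == ["p"]

    def test_planted_promoter_peaks_recover_target_genes(self, sim_config, sim_genome, sim_peaks):
        annotation = sim_genome[0]
        peaksets, truth = sim_peaks
        for tf, sets in peaksets.items():
            tm0 = [ps for ps in sets if ps.condition == "Tm" and ps.timepoint == 0
                   and ps.replicate == 1][0]
            spec_names = truth.specific_peaks[tf]
            only_spec = tm0.with_peaks(tm0.peaks[tm0.peaks["name"].isin(spec_names)])
            _, _, bound, _ = pk.assign_peaks_to_genes(only_spec, annotation)
            assert truth.peak_target_genes[tf] <= bound

    @pytest.mark.parametrize("summit,expect", [
        (1100, "promoter"),           # 500 bp upstream of + strand TSS
        (2000, "gene body"),
        (3700, "downstream"),
        (9000, "distal intergenic"),
        (22500, "promoter"),          # 501 bp upstream of - strand TSS
        (19500, "downstream"),        # past the 3' end of the - strand gene
    ])
    def test_location_categories(self, summit, expect):
        row = _peakset([_row("c1", summit - 50, summit + 50, "p", 5,
                             summit=summit)]).peaks.iloc[0]
        assert pk.classify_peak_location(row, self.ANN) == expect


class TestPlantedScenario:
    def test_filter_recovers_exactly_the_planted_specific_peaks(self, sim_config, sim_peaks):
        peaksets, truth = sim_peaks
        params = pk.PeakFilterParams()
        for tf, sets in peaksets.items():
            by_key = {}
            for ps in sets:
                by_key.setdefault((ps.condition, ps.timepoint), []).append(ps)
            retained_all = set()
            for tp in sim_config.timepoints:
                tm = pk.reproducible_peaks(*by_key[("Tm", tp)], params)
                mock = pk.reproducible_peaks(*by_key[("mock", tp)], params)
                ret, _ = pk.upr_specific_filter(tm, mock, params)
                retained_all |= ret.ids
            assert retained_all == truth.specific_peaks[tf]
            assert not retained_all & truth.constitutive_peaks[tf]
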
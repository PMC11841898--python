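"""Peak clustering, intensity ranking and the allele caller."""

import numpy as np
import pytest

from msatcall.calling import (
    Genotype,
    PeakCluster,
    batch_adenylation_check,
    call_genotype,
    cluster_peaks,
    exported_alleles,
    manual_edit,
    peak_intensity,
)
from msatcall.panels import Bin, Marker, make_bin_set

from conftest import make_peak


def sized_peak(size, height, scan=None, **kw):
    return make_peak(int(scan if scan is not None else size * 18),
                     height=height, size=float(size), **kw)


def dinuc_marker(**kw):
    defaults = dict(name="Ma", channel=0, ploidy=2, motif_length=2,
                    range_start=248.0, range_end=272.0)
    defaults.update(kw)
    m = Marker(**defaults)
    m.bins = make_bin_set(m, 1.0, float(m.motif_length), m.range_start + 2)
    return m


class TestClusterPeaks:
    def test_stutter_series_forms_one_cluster(self):
        peaks = [sized_peak(254, 300), sized_peak(256, 800), sized_peak(258, 2000)]
        clusters = cluster_peaks(peaks, motif_length=2)
        assert len(clusters) == 1
        assert clusters[0].principal.size == 258

    def test_adenylation_pair_forms_one_cluster(self):
        peaks = [sized_peak(257, 900), sized_peak(258, 1100)]
        clusters = cluster_peaks(peaks, motif_length=2)
        assert len(clusters) == 1
        assert clusters[0].principal.size == 258

    def test_unrelated_spacing_stays_separate(self):
        peaks = [sized_peak(258, 2000), sized_peak(263, 1800)]
        clusters = cluster_peaks(peaks, motif_length=2, stutter_tol=0.5)
        assert len(clusters) == 2

    def test_heterozygote_alleles_not_merged(self):
        # alleles differ by two repeats; near-equal heights mean they
        # cannot both be stutter of one another
        peaks = [
            sized_peak(258, 2000), sized_peak(257, 1300),
            sized_peak(256, 560),  # stutter of 258
            sized_peak(262, 1900), sized_peak(261, 1250),
            sized_peak(260, 530),  # stutter of 262
        ]
        clusters = cluster_peaks(peaks, motif_length=2)
        principals = sorted(c.principal.size for c in clusters)
        assert principals == [258.0, 262.0]

    def test_clusters_are_disjoint_and_sorted(self, rng):
        for _ in range(20):
            sizes = np.sort(rng.uniform(100, 140, size=8))
            peaks = [sized_peak(round(s, 2), float(rng.uniform(100, 3000)))
                     for s in sizes]
            clusters = cluster_peaks(peaks, motif_length=3)
            seen = [id(p) for c in clusters for p in c.peaks]
            assert len(seen) == len(set(seen)) == len(peaks)
            assert [c.size for c in clusters] == sorted(c.size for c in clusters)

    def test_equal_intensity_tie_prefers_longer_fragment(self):
        peaks = [sized_peak(257, 1000), sized_peak(258, 1000)]
        clusters = cluster_peaks(peaks, motif_length=2)
        assert clusters[0].principal.size == 258


class TestPeakIntensity:
    def test_height_orders_unsaturated_peaks(self):
        assert peak_intensity(sized_peak(258, 2000)) > peak_intensity(
            sized_peak(258, 800)
        )

    def test_saturated_outranks_any_height(self):
        sat = sized_peak(258, 20000, saturated=True, saturated_width=12)
        tall = sized_peak(260, 30000)
        assert peak_intensity(sat) > peak_intensity(tall)

    def test_saturated_peaks_order_by_clip_width(self):
        a = sized_peak(258, 31000, saturated=True, saturated_width=8)
        b = sized_peak(260, 31000, saturated=True, saturated_width=20)
        assert peak_intensity(b) > peak_intensity(a)


class TestCallGenotype:
    def test_heterozygote_two_clusters(self):
        clusters = [
            PeakCluster([sized_peak(258, 2000)]),
            PeakCluster([sized_peak(262, 1800)]),
        ]
        gt = call_genotype(clusters, dinuc_marker())
        assert [(round(s), n) for s, n in gt.alleles] == [(258, "258"), (262, "262")]
        assert gt.status == "called"

    def test_single_cluster_reported_homozygous_on_export(self):
        clusters = [PeakCluster([sized_peak(258, 2000)])]
        m = dinuc_marker()
        gt = call_genotype(clusters, m)
        assert len(gt.alleles) == 1
        assert [n for _, n in exported_alleles(gt, m.ploidy)] == ["258", "258"]

    def test_third_cluster_becomes_additional_fragment(self):
        clusters = [
            PeakCluster([sized_peak(250, 2000)]),
            PeakCluster([sized_peak(258, 1900)]),
            PeakCluster([sized_peak(266, 600)]),
        ]
        gt = call_genotype(clusters, dinuc_marker(), secondary_ratio=0.2)
        assert sorted(round(s) for s, _ in gt.alleles) == [250, 258]
        assert [round(s) for s, _ in gt.additional_fragments] == [266]

    def test_additional_detection_can_be_disabled(self):
        clusters = [
            PeakCluster([sized_peak(250, 2000)]),
            PeakCluster([sized_peak(258, 1900)]),
            PeakCluster([sized_peak(266, 600)]),
        ]
        gt = call_genotype(clusters, dinuc_marker(), additional_detection=False)
        assert gt.additional_fragments == []

    def test_weak_second_cluster_demoted_to_additional(self):
        # 22% of the first: below the heterozygote threshold (25%) but
        # above the additional-fragment threshold (20%)
        clusters = [
            PeakCluster([sized_peak(258, 4000)]),
            PeakCluster([sized_peak(266, 880)]),
        ]
        gt = call_genotype(clusters, dinuc_marker(), het_min_ratio=0.25)
        assert len(gt.alleles) == 1
        assert [round(s) for s, _ in gt.additional_fragments] == [266]

    def test_fragment_below_secondary_ratio_discarded(self):
        clusters = [
            PeakCluster([sized_peak(258, 4000)]),
            PeakCluster([sized_peak(266, 400)]),  # 10% of first
        ]
        gt = call_genotype(clusters, dinuc_marker(), secondary_ratio=0.2)
        assert len(gt.alleles) == 1 and gt.additional_fragments == []

    def test_out_of_bin_allele_named_question_mark(self):
        clusters = [PeakCluster([sized_peak(258.9, 2000)])]
        gt = call_genotype(clusters, dinuc_marker())
        assert gt.alleles[0][1] == "?"

    def test_no_clusters_is_no_peak(self):
        gt = call_genotype([], dinuc_marker())
        assert gt.status == "no-peak" and gt.alleles == []

    def test_any_peak_yields_at_least_one_allele(self, rng):
        # absolute height is irrelevant to the first allele
        clusters = [PeakCluster([sized_peak(258, 25.0)])]
        gt = call_genotype(clusters, dinuc_marker())
        assert len(gt.alleles) == 1

    def test_haploid_marker_caps_at_one_allele(self):
        m = dinuc_marker(ploidy=1)
        clusters = [
            PeakCluster([sized_peak(258, 2000)]),
            PeakCluster([sized_peak(262, 1900)]),
        ]
        gt = call_genotype(clusters, m)
        assert len(gt.alleles) == 1
        assert round(gt.alleles[0][0]) == 258

    def test_ploidy_cap_on_random_batches(self, rng):
        m = dinuc_marker()
        for _ in range(300):
            n = int(rng.integers(1, 9))
            sizes = np.sort(rng.uniform(m.range_start, m.range_end, size=n))
            clusters = cluster_peaks(
                [sized_peak(round(s, 2), float(rng.uniform(50, 5000)))
                 for s in sizes],
                motif_length=m.motif_length,
            )
            gt = call_genotype(clusters, m)
            assert len(gt.alleles) <= m.ploidy


class TestBatchAdenylationCheck:
    def _merged_genotype(self):
        # true 257/258 heterozygote with near-equal peaks merged as one
        # adenylation cluster
        p257 = sized_peak(257, 1900)
        p258 = sized_peak(258, 2000)
        cluster = PeakCluster([p257, p258])
        m = dinuc_marker()
        gt = call_genotype([cluster], m, sample="suspect")
        assert len(gt.alleles) == 1  # merged: looks homozygous
        return gt, m

    def _clean(self, sample, size, marker):
        return call_genotype(
            [PeakCluster([sized_peak(size, 2000)])], marker, sample=sample
        )

    def test_merge_split_when_batch_has_both_alleles(self):
        suspect, m = self._merged_genotype()
        batch = (
            [self._clean(f"a{i}", 257, m) for i in range(5)]
            + [self._clean(f"b{i}", 258, m) for i in range(5)]
            + [suspect]
        )
        revised = batch_adenylation_check(batch, m)
        fixed = revised[-1]
        assert sorted(round(s) for s, _ in fixed.alleles) == [257, 258]
        assert "split" in fixed.notes

    def test_no_one_bp_alleles_is_a_noop(self):
        m = dinuc_marker()
        batch = [self._clean(f"s{i}", 258, m) for i in range(4)]
        revised = batch_adenylation_check(batch, m)
        assert [g.alleles for g in revised] == [g.alleles for g in batch]

    def test_single_genotype_batch_unchanged(self):
        suspect, m = self._merged_genotype()
        assert batch_adenylation_check([suspect], m) == [suspect]

    def test_unbalanced_pair_not_split(self):
        # a 60/40-ish pair is ordinary partial adenylation; leave it
        p257 = sized_peak(257, 800)
        p258 = sized_peak(258, 2000)
        m = dinuc_marker()
        gt = call_genotype([PeakCluster([p257, p258])], m, sample="ok")
        batch = (
            [self._clean(f"a{i}", 257, m) for i in range(3)]
            + [self._clean(f"b{i}", 258, m) for i in range(3)]
            + [gt]
        )
        revised = batch_adenylation_check(batch, m)
        assert len(revised[-1].alleles) == 1


class TestManualEdit:
    def test_assign_peak_to_bin_replaces_question_mark(self):
        m = dinuc_marker()
        gt = call_genotype([PeakCluster([sized_peak(258.9, 2000)])], m)
        assert gt.alleles[0][1] == "?"
        target = next(b for b in m.bins if b.name == "258")
        manual_edit(gt, m, "assign-peak-to-bin",
                    peak=sized_peak(258.9, 2000), bin=target)
        assert gt.alleles[0][1] == "258"
        assert gt.status == "manual"

    def test_move_allele_to_other_peak(self):
        m = dinuc_marker()
        gt = call_genotype([PeakCluster([sized_peak(258, 2000)])], m)
        manual_edit(gt, m, "move-allele-to-peak", from_size=gt.alleles[0][0],
                    peak=sized_peak(262, 900))
        assert [round(s) for s, _ in gt.alleles] == [262]

    def test_toggle_peak_is_an_involution(self):
        m = dinuc_marker()
        gt = call_genotype([PeakCluster([sized_peak(258, 2000)])], m)
        peak = gt.clusters[0].principal
        before = list(gt.alleles)
        manual_edit(gt, m, "toggle-peak", peak=peak)
        assert gt.alleles == []
        manual_edit(gt, m, "toggle-peak", peak=peak)
        assert gt.alleles == before

    def test_rename_allele_accepts_arbitrary_text(self):
        m = dinuc_marker()
        gt = call_genotype([PeakCluster([sized_peak(258, 2000)])], m)
        manual_edit(gt, m, "rename-allele", size=gt.alleles[0][0], name="258.3*")
        assert gt.alleles[0][1] == "258.3*"

    def test_out_of_range_peak_rejected(self):
        m = dinuc_marker()
        gt = call_genotype([PeakCluster([sized_peak(258, 2000)])], m)
        with pytest.raises(ValueError, match="outside range"):
            manual_edit(gt, m, "toggle-peak", peak=sized_peak(300, 500))

    def test_ploidy_cap_preserved_on_assignment(self):
        m = dinuc_marker()
        gt = call_genotype(
            [PeakCluster([sized_peak(252, 2000)]),
             PeakCluster([sized_peak(262, 1800)])], m
        )
        target = next(b for b in m.bins if b.name == "258")
        manual_edit(gt, m, "assign-peak-to-bin",
                    peak=sized_peak(258, 900), bin=target)
        assert len(gt.alleles) == 2
        # the nearer-sized allele (262) was replaced
        assert sorted(round(s) for s, _ in gt.alleles) == [252, 258]
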
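from __future__ import annotations

import math

import numpy as np
import pytest

from chipdeg.peaks import (
    DifferentialPeak,
    Peak,
    assign_peaks_to_genes,
    call_differential_peaks,
    differential_peak_gene_features,
    m_value,
    merge_condition_peaks,
    normalize_densities,
    peak_gene_features,
)
from chipdeg.io import ReadTrack


def peak(start, end, chrom="chr1", fe=1.0, da=None, dc=None, name="."):
    return Peak(
        chromosome=chrom,
        start=start,
        end=end,
        name=name,
        fold_enrichment=fe,
        density_air=da,
        density_eth=dc,
    )


class TestAssignment:
    GENES = {"a": ("chr1", 10_000, 12_000), "b": ("chr1", 20_000, 22_000)}

    def test_overlapping_peak_distance_zero(self):
        assignment = assign_peaks_to_genes([peak(11_000, 11_400)], self.GENES)
        assert assignment == {"a": [(peak(11_000, 11_400), 0)]}

    def test_beyond_5kb_unassigned(self):
        genes = {"a": ("chr1", 10_000, 12_000)}
        assignment = assign_peaks_to_genes([peak(18_001, 18_400)], genes)
        assert assignment == {}

    def test_exactly_5kb_assigned(self):
        genes = {"a": ("chr1", 10_000, 12_000)}
        assignment = assign_peaks_to_genes([peak(17_000, 17_400)], genes)
        assert list(assignment) == ["a"]
        assert assignment["a"][0][1] == 5000

    def test_nearest_gene_wins(self):
        # peak at 1000 bp from a, 3000 bp from b
        genes = {"a": ("chr1", 10_000, 12_000), "b": ("chr1", 16_400, 18_000)}
        assignment = assign_peaks_to_genes([peak(13_000, 13_400)], genes)
        assert list(assignment) == ["a"]

    def test_tie_broken_by_smallest_gene_id(self):
        genes = {"zz": ("chr1", 0, 1000), "aa": ("chr1", 3000, 4000)}
        assignment = assign_peaks_to_genes([peak(1500, 2500)], genes)
        assert list(assignment) == ["aa"]

    def test_chromosome_mismatch_unassigned(self):
        assignment = assign_peaks_to_genes([peak(11_000, 11_400, chrom="chr2")], self.GENES)
        assert assignment == {}

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        genes = {}
        for i in range(30):
            s = int(rng.integers(0, 500_000))
            genes[f"g{i:03d}"] = ("chr1", s, s + int(rng.integers(500, 3000)))
        peaks = []
        for i in range(60):
            s = int(rng.integers(0, 500_000))
            peaks.append(peak(s, s + int(rng.integers(100, 800)), name=f"p{i}"))
        assignment = assign_peaks_to_genes(peaks, genes, max_distance=5000)
        # brute force: nearest gene per peak
        expected: dict[str, list] = {}
        for p in peaks:
            best = None
            for gid in sorted(genes):
                _, gs, ge = genes[gid]
                d = max(0, gs - p.end, p.start - ge)
                if best is None or d < best[1]:
                    best = (gid, d)
            if best and best[1] <= 5000:
                expected.setdefault(best[0], []).append((p, best[1]))
        assert assignment == expected


class TestPeakGeneFeatures:
    def test_single_peak(self):
        assignment = {"a": [(peak(0, 400, fe=5.0), 0)]}
        df = peak_gene_features(assignment, "CK9A")
        row = df.loc["a"]
        assert row["numberpeaks_CK9A"] == 1
        assert row["avg_peaksize_CK9A"] == 400.0
        assert row["avg_FE_CK9A"] == 5.0
        assert row["avg_distance_CK9A"] == 0.0

    def test_means_over_two_peaks(self):
        assignment = {
            "a": [(peak(0, 200, fe=4.0), 0), (peak(1000, 1600, fe=8.0), 1000)]
        }
        df = peak_gene_features(assignment, "CK9A")
        row = df.loc["a"]
        assert row["numberpeaks_CK9A"] == 2
        assert row["avg_peaksize_CK9A"] == 400.0
        assert row["avg_FE_CK9A"] == 6.0
        assert row["avg_distance_CK9A"] == 500.0

    def test_column_names_carry_track_label(self):
        df = peak_gene_features({"a": [(peak(0, 100), 0)]}, "CK9A")
        assert list(df.columns) == [
            "numberpeaks_CK9A",
            "avg_peaksize_CK9A",
            "avg_FE_CK9A",
            "avg_distance_CK9A",
        ]


class TestMValue:
    def test_examples(self):
        assert m_value(4, 1) == pytest.approx(2.0)
        assert m_value(3.7, 3.7) == 0.0
        assert m_value(1, 2) == pytest.approx(-1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            m_value(0, 1)


class TestNormalizeDensities:
    def test_balanced_gives_factor_one(self):
        peaks = [peak(0, 100, da=10.0, dc=10.0), peak(200, 300, da=4.0, dc=4.0)]
        _, factor = normalize_densities(peaks)
        assert factor == pytest.approx(1.0)

    def test_uniform_doubling_gives_half(self):
        peaks = [peak(0, 100, da=10.0, dc=20.0), peak(200, 300, da=4.0, dc=8.0)]
        rescaled, factor = normalize_densities(peaks)
        assert factor == pytest.approx(0.5)
        assert rescaled[0].density_eth == pytest.approx(10.0)

    def test_mixed_factor_is_closed_form(self):
        peaks = [
            peak(0, 100, da=10.0, dc=5.0),
            peak(200, 300, da=8.0, dc=16.0),
            peak(400, 500, da=4.0, dc=8.0),
        ]
        ms = [math.log2(5 / 10), math.log2(16 / 8), math.log2(8 / 4)]
        _, factor = normalize_densities(peaks)
        assert factor == pytest.approx(2.0 ** (-float(np.median(ms))))

    @pytest.mark.parametrize("seed", range(6))
    def test_median_m_zero_after_normalization(self, seed):
        rng = np.random.default_rng(seed)
        peaks = [
            peak(i * 1000, i * 1000 + 100, da=float(rng.uniform(1, 50)), dc=float(rng.uniform(1, 50)))
            for i in range(11)
        ]
        rescaled, _ = normalize_densities(peaks)
        ms = [m_value(p.density_eth, p.density_air) for p in rescaled]
        assert float(np.median(ms)) == pytest.approx(0.0, abs=1e-12)

    def test_no_common_peaks_factor_one(self):
        peaks = [peak(0, 100, da=10.0, dc=0.0)]
        _, factor = normalize_densities(peaks)
        assert factor == 1.0


class TestDifferentialCalling:
    def test_equal_counts_rejected(self):
        peaks = [peak(0, 100, da=100.0, dc=100.0)]
        assert call_differential_peaks(peaks) == []

    def test_two_to_one_retained(self):
        peaks = [peak(0, 100, da=100.0, dc=200.0)]
        out = call_differential_peaks(peaks)
        assert len(out) == 1
        assert out[0].m == pytest.approx(1.0)
        assert out[0].p_value < 0.05

    def test_small_m_rejected_regardless_of_p(self):
        # M = log2(5/4) ~ 0.32 < 0.4
        peaks = [peak(0, 100, da=4.0, dc=5.0)]
        assert call_differential_peaks(peaks) == []

    def test_monotone_in_m_threshold(self):
        rng = np.random.default_rng(0)
        peaks = [
            peak(i * 1000, i * 1000 + 100, da=float(rng.integers(20, 400)), dc=float(rng.integers(20, 400)))
            for i in range(40)
        ]
        kept = [
            {dp.peak.name for dp in call_differential_peaks(peaks, m_threshold=t)}
            for t in (0.0, 0.4, 0.8, 1.6)
        ]
        for wider, narrower in zip(kept, kept[1:]):
            assert narrower <= wider


class TestDifferentialGeneFeatures:
    GENES = {"a": ("chr1", 0, 2000)}

    def test_avg_fe_is_mean_of_two_to_the_m(self):
        dps = [
            DifferentialPeak(peak(100, 300, name="p1"), m=1.0, p_value=0.01),
            DifferentialPeak(peak(500, 700, name="p2"), m=2.0, p_value=0.01),
        ]
        df = differential_peak_gene_features(dps, self.GENES, "CK9diff")
        assert df.loc["a", "avg_FE_CK9diff"] == pytest.approx(3.0)
        assert df.loc["a", "numberpeaks_CK9diff"] == 2

    def test_single_peak_m1_gives_fe_2(self):
        dps = [DifferentialPeak(peak(100, 300), m=1.0, p_value=0.01)]
        df = differential_peak_gene_features(dps, self.GENES, "CK9diff")
        assert df.loc["a", "avg_FE_CK9diff"] == pytest.approx(2.0)

    def test_no_differential_peaks_gene_absent(self):
        df = differential_peak_gene_features([], self.GENES, "CK9diff")
        assert "a" not in df.index


def test_merge_condition_peaks_counts_reads():
    air = [peak(100, 200), peak(500, 600)]
    eth = [peak(150, 300)]
    reads_air = ReadTrack.from_intervals(["chr1"] * 3, [110, 210, 510], [160, 260, 560])
    reads_eth = ReadTrack.from_intervals(["chr1"] * 2, [120, 180], [170, 230])
    merged = merge_condition_peaks(air, eth, reads_air, reads_eth)
    assert [(p.start, p.end) for p in merged] == [(100, 300), (500, 600)]
    assert merged[0].density_air == 2.0
    assert merged[0].density_eth == 2.0
    assert merged[1].density_air == 1.0
    assert merged[1].density_eth == 0.0
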
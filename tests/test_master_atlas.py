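import numpy as np
import pytest

from tfclust import master_atlas as ma
from tfclust.genomic_io import GenomicInterval, merge_intervals, read_gene_annotation
from tfclust.region_calling import ClusteredRegion, categorize


def region(cell, start, end, c, chrom="chr1"):
    label, band = categorize(c)
    return ClusteredRegion(
        cell, chrom, (start + end) // 2, GenomicInterval(chrom, start, end), c,
        category=label, band=band, n_sites=1, n_distinct_tfs=1,
    )


class TestBuildMasterList:
    def test_highest_complexity_wins(self):
        m = ma.build_master_list({
            "A": [region("A", 100, 700, 5)],
            "B": [region("B", 400, 900, 9)],
        })
        assert [(e.window.start, e.window.end) for e in m] == [(400, 900)]
        assert m.entries[0].region.cell_type == "B"

    def test_identical_region_in_three_cells(self):
        per = {c: [region(c, 100, 700, 5)] for c in "XYZ"}
        m = ma.build_master_list(per)
        assert len(m) == 1
        assert ma.cell_ubiquity(m, per) == [3]

    def test_chain_keeps_only_middle(self):
        m = ma.build_master_list({
            "A": [region("A", 0, 100, 3)],
            "B": [region("B", 90, 200, 9)],
            "C": [region("C", 190, 300, 5)],
        })
        assert [(e.window.start, e.window.end) for e in m] == [(90, 200)]

    def test_windows_pairwise_disjoint(self, rng):
        per = {}
        for ci in range(5):
            regions = []
            for _ in range(40):
                s = int(rng.integers(0, 20_000))
                regions.append(region(f"c{ci}", s, s + int(rng.integers(50, 800)),
                                      float(rng.uniform(1, 40))))
            per[f"c{ci}"] = regions
        m = ma.build_master_list(per)
        ws = m.windows()
        for a, b in zip(ws, ws[1:]):
            assert a.end <= b.start

    def test_order_invariance(self, rng):
        regions = []
        for i in range(60):
            s = int(rng.integers(0, 10_000))
            regions.append(region(f"c{i % 3}", s, s + int(rng.integers(50, 500)),
                                  float(rng.uniform(1, 30))))
        per1 = {"c0": [], "c1": [], "c2": []}
        for r in regions:
            per1[r.cell_type].append(r)
        per2 = {c: list(reversed(v)) for c, v in reversed(list(per1.items()))}
        m1 = ma.build_master_list(per1)
        m2 = ma.build_master_list(per2)
        assert [(e.window.start, e.window.end, e.region.cell_type) for e in m1] == \
               [(e.window.start, e.window.end, e.region.cell_type) for e in m2]


class TestCellUbiquity:
    def test_private_region(self):
        per = {"A": [region("A", 0, 100, 2)], "B": [region("B", 5000, 5100, 2)]}
        m = ma.build_master_list(per)
        assert ma.cell_ubiquity(m, per) == [1, 1]

    def test_abutting_window_not_counted(self):
        per = {"A": [region("A", 0, 100, 2)], "B": [region("B", 100, 200, 9)]}
        m = ma.build_master_list(per)
        counts = ma.cell_ubiquity(m, per)
        assert len(m) == 2 and counts == [1, 1]


class TestSaturationCurve:
    def test_shared_identical_sets_constant(self):
        per = {c: [region(c, i * 10_000, i * 10_000 + 500, 2) for i in range(7)]
               for c in "ABC"}
        curve = ma.saturation_curve(per, n_samples=50, seed=0)
        assert np.allclose(curve.mean_elements, 7)

    def test_disjoint_private_sets_additive(self):
        per = {
            c: [region(c, (ci * 10 + i) * 10_000, (ci * 10 + i) * 10_000 + 500, 2)
                for i in range(5)]
            for ci, c in enumerate("ABCD")
        }
        curve = ma.saturation_curve(per, n_samples=200, seed=0)
        assert np.allclose(curve.mean_elements, 5 * curve.x)

    def test_long_run_chunking(self):
        # one merged 12 kb run -> 3 elements of max 5 kb
        per = {
            "A": [region("A", 0, 12_000, 2)],
            "B": [region("B", 0, 12_000, 3)],
        }
        curve = ma.saturation_curve(per, n_samples=10, seed=0)
        assert curve.mean_elements[-1] == 3
        assert curve.mean_bp[-1] == 12_000

    def test_monotone_and_exact_at_full_union(self, small_landscape):
        from tfclust.region_calling import call_regions

        per_cell, _ = small_landscape
        per = {c: call_regions(v) for c, v in per_cell.items()}
        curve = ma.saturation_curve(per, n_samples=30, seed=1)
        assert np.all(np.diff(curve.mean_elements) >= 0)
        assert np.all(np.diff(curve.mean_bp) >= 0)
        pooled = [r.window for regions in per.values() for r in regions]
        n_full, bp_full = ma._count_elements(pooled, curve.max_element_len)
        assert curve.mean_elements[-1] == n_full
        assert curve.mean_bp[-1] == bp_full


class TestWeibullFit:
    def test_exact_recovery(self):
        x = np.arange(1, 25, dtype=float)
        y = ma.weibull_saturation(x, 1000, 10, 1)
        fit = ma.fit_weibull_saturation(x, y)
        assert fit.asymptote == pytest.approx(1000, rel=0.01)

    def test_constant_curve(self):
        x = np.arange(1, 10, dtype=float)
        fit = ma.fit_weibull_saturation(x, np.full_like(x, 55.0))
        assert fit.asymptote == pytest.approx(55.0, rel=0.01)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            ma.fit_weibull_saturation([1, 2, 3], [1, 2, 3])


def _write_gtf(tmp_path):
    p = tmp_path / "genes.gtf"
    p.write_text(
        'chr1\ts\tgene\t1201\t3000\t.\t+\t.\tgene_id "G1";\n'
        'chr1\ts\tCDS\t1201\t1500\t.\t+\t.\tgene_id "G1";\n'
        'chr1\ts\tUTR\t2001\t2200\t.\t+\t.\tgene_id "G1";\n'
        'chr1\ts\tgene\t6001\t8000\t.\t+\t.\tgene_id "G2";\n'
        'chr1\ts\tCDS\t6001\t6500\t.\t+\t.\tgene_id "G2";\n'
        'chr1\ts\tCDS\t7501\t8000\t.\t+\t.\tgene_id "G2";\n'
    )
    return read_gene_annotation(p)


class TestAnnotateClasses:
    def test_promoter_by_peak_distance(self, tmp_path):
        ann = _write_gtf(tmp_path)
        # peak 500, TSS 1200 -> |500-1200| <= 1000 -> promoter
        r = region("A", 400, 600, 2)
        r.peak = 500
        m = ma.MasterList([ma.MasterEntry(r)])
        assert ma.annotate_region_classes(m, ann) == ["promoter"]

    def test_utr_when_cds_overlap_short(self, tmp_path):
        ann = _write_gtf(tmp_path)
        # CDS [1200,1500), UTR [2000,2200); window overlaps CDS by 74 bp only
        r = region("A", 1426, 2010, 2)
        r.peak = 3000  # force non-promoter path
        m = ma.MasterList([ma.MasterEntry(r)])
        assert ma.annotate_region_classes(m, ann) == ["UTR"]

    def test_intron(self, tmp_path):
        ann = _write_gtf(tmp_path)
        r = region("A", 6600, 6700, 2)
        r.peak = 4000
        m = ma.MasterList([ma.MasterEntry(r)])
        assert ma.annotate_region_classes(m, ann) == ["intron"]

    def test_intergenic(self, tmp_path):
        ann = _write_gtf(tmp_path)
        r = region("A", 20_000, 20_100, 2)
        r.peak = 20_050
        m = ma.MasterList([ma.MasterEntry(r)])
        assert ma.annotate_region_classes(m, ann) == ["intergenic"]


class TestNearestGene:
    def test_nearest_tss(self, tmp_path):
        ann = _write_gtf(tmp_path)  # TSS at 1200 and 6000
        m = ma.MasterList([ma.MasterEntry(region("A", 4900, 5100, 2))])  # centre 5000
        assert ma.assign_nearest_gene(m, ann) == ["G2"]
        m2 = ma.MasterList([ma.MasterEntry(region("A", 2900, 3100, 2))])
        assert ma.assign_nearest_gene(m2, ann) == ["G1"]

    def test_tie_breaks_lexicographically(self, tmp_path):
        p = tmp_path / "g.gtf"
        p.write_text(
            'chr1\ts\tgene\t1001\t2000\t.\t+\t.\tgene_id "GB";\n'
            'chr1\ts\tgene\t3001\t4000\t.\t+\t.\tgene_id "GA";\n'
        )
        ann = read_gene_annotation(p)
        # centre 2000: TSS at 1000 and 3000, both 1000 away
        m = ma.MasterList([ma.MasterEntry(region("A", 1900, 2100, 2))])
        assert ma.assign_nearest_gene(m, ann) == ["GA"]

    def test_empty_annotation_error(self, tmp_path):
        from tfclust.genomic_io import GeneAnnotation

        m = ma.MasterList([ma.MasterEntry(region("A", 0, 100, 2))])
        with pytest.raises(ValueError):
            ma.assign_nearest_gene(m, GeneAnnotation([]))
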
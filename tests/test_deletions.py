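"""Deletion tables, burden metrics and impact annotation."""

import io

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_overlaps

from mtaging.deletions import (COMMON_DELETION, DeletionCall,
                               DeletionTableError, annotate_impact,
                               cohort_summary, deletion_size, deleted_span,
                               default_top30_catalog, impact_long_table,
                               metrics_table, read_deletion_table,
                               sample_metrics, write_deletion_table)

HEADER = "sample_id\tbp5\tbp3\tsupporting_reads\tread_pct\tbenchmark_coverage\n"


def table(rows: str) -> io.StringIO:
    return io.StringIO(HEADER + rows)


def make_call(bp5, bp3, pct=0.05, sid="s1", bench=5000.0, reads=3):
    return DeletionCall(sid, bp5, bp3, reads, pct, bench)


class TestReader:
    def test_valid_rows(self):
        calls = read_deletion_table(table(
            "s1\t8471\t13449\t10\t0.2\t5000\n"
            "s1\t7816\t14807\t5\t0.1\t5000\n"
            "s2\t12369\t14004\t2\t0.04\t5000\n"))
        assert len(calls) == 3
        assert calls[0].junction == COMMON_DELETION

    def test_invalid_breakpoints_rejected_with_diagnostic(self):
        with pytest.warns(UserWarning, match="row 3"):
            calls = read_deletion_table(table(
                "s1\t8471\t13449\t10\t0.2\t5000\n"
                "s1\t9000\t9001\t5\t0.1\t5000\n"))
        assert len(calls) == 1

    def test_strict_mode_raises(self):
        with pytest.raises(DeletionTableError, match="row 2"):
            read_deletion_table(table("s1\t9000\t8000\t5\t-1\t5000\n"),
                                on_invalid="raise")

    def test_empty_table(self):
        assert read_deletion_table(table("")) == []

    def test_missing_columns(self):
        with pytest.raises(DeletionTableError, match="missing"):
            read_deletion_table(io.StringIO("sample_id\tbp5\n"))

    def test_wrap_junction_flagged_but_kept(self):
        with pytest.warns(UserWarning, match="wraps"):
            calls = read_deletion_table(table("s1\t16000\t300\t4\t0.1\t5000\n"))
        assert calls[0].wraps_origin

    def test_roundtrip(self, tmp_path):
        calls = [make_call(8471, 13449), make_call(7816, 14807, sid="s1")]
        p = tmp_path / "dels.tsv"
        write_deletion_table(calls, p)
        assert read_deletion_table(p) == calls


class TestDeletionSize:
    @pytest.mark.parametrize("bp5,bp3,size", [
        (8471, 13449, 4977),   # the canonical common deletion
        (12369, 14004, 1634),
        (100, 102, 1),
    ])
    def test_retained_base_convention(self, bp5, bp3, size):
        assert deletion_size(make_call(bp5, bp3)) == size

    def test_wrap_size_is_circular(self):
        call = make_call(16000, 300)
        # removes 16001..16569 and 1..299
        assert deletion_size(call) == 16569 - 16000 + 299

    def test_invariant_rejects_empty_deletion(self):
        with pytest.raises(DeletionTableError):
            make_call(100, 101)


class TestAnnotateImpact:
    def test_common_deletion_complexes(self, catalog):
        ann = annotate_impact(make_call(8471, 13449), catalog)
        assert ann.complexes == frozenset({"I", "IV", "V"})
        assert "III" not in ann.complexes

    def test_common_deletion_microproteins(self, catalog):
        ann = annotate_impact(make_call(8471, 13449), catalog)
        assert set(ann.MDPs) == {"mtALTND4", "SHMOOSE"}

    def test_control_region_deletion_hits_nothing_coding(self, catalog):
        ann = annotate_impact(make_call(16100, 16400), catalog)
        assert ann.complexes == frozenset()
        assert ann.MDPs == () and ann.tRNAs == ()

    def test_ol_removal_flag(self, catalog):
        assert annotate_impact(make_call(5700, 5810), catalog).removes_OL
        assert not annotate_impact(make_call(8471, 13449), catalog).removes_OL

    def test_matches_per_base_oracle_on_random_junctions(self, catalog, rng):
        for _ in range(300):
            bp5 = int(rng.integers(1, 16560))
            bp3 = int(rng.integers(bp5 + 2, min(bp5 + 12000, 16569) + 1))
            call = make_call(bp5, bp3)
            ann = annotate_impact(call, catalog)
            start, end = deleted_span(call, catalog.genome_length)
            oracle = brute_force_overlaps(catalog, start, end)
            assert dict(ann.genes) == {
                k: v for k, v in oracle.items() if k.startswith("MT-") and
                catalog.by_name(k).category == "protein"
            }
            assert set(ann.tRNAs) == {
                k for k in oracle if catalog.by_name(k).category == "tRNA"}
            assert set(ann.MDPs) == {
                k for k in oracle if catalog.by_name(k).category == "MDP"}

    def test_long_table_shape(self, catalog):
        df = impact_long_table([make_call(8471, 13449)], catalog)
        assert set(df.columns) == {"sample_id", "bp5", "bp3", "feature",
                                   "category", "impact"}
        assert (df.feature == "MT-CO3").any()


class TestSampleMetrics:
    def test_deletions_per_10k_formula(self, catalog):
        calls = [make_call(6000 + i * 100, 14000 + i, pct=0.01, bench=5000)
                 for i in range(5)]
        m = sample_metrics(calls, catalog)
        assert m.deletions_per_10k == pytest.approx(10.0)

    def test_single_common_deletion_sums(self, catalog):
        m = sample_metrics([make_call(*COMMON_DELETION, pct=0.05)], catalog)
        assert m.cumulative_read_pct == pytest.approx(0.05)
        assert m.top30_read_pct == pytest.approx(0.05)
        assert m.common_del_read_pct == pytest.approx(0.05)
        assert m.read_pct_lt1000 == 0.0
        assert m.read_pct_ge1000 == pytest.approx(0.05)

    def test_no_calls_all_zero(self, catalog):
        m = sample_metrics([], catalog, sample_id="s9", benchmark_coverage=4000)
        assert m.cumulative_read_pct == 0 and m.deletions_per_10k == 0
        assert m.n_unique_deletions == 0

    def test_inconsistent_benchmark_rejected(self, catalog):
        calls = [make_call(8471, 13449, bench=5000),
                 make_call(7816, 14807, bench=6000)]
        with pytest.raises(DeletionTableError, match="benchmark"):
            sample_metrics(calls, catalog)

    def test_mixed_samples_rejected(self, catalog):
        calls = [make_call(8471, 13449, sid="a"), make_call(7816, 14807, sid="b")]
        with pytest.raises(DeletionTableError, match="samples"):
            sample_metrics(calls, catalog)

    def test_size_split_partitions_cumulative(self, catalog, rng):
        calls = []
        for _ in range(30):
            bp5 = int(rng.integers(600, 15000))
            bp3 = int(rng.integers(bp5 + 2, min(bp5 + 9000, 16569) + 1))
            calls.append(make_call(bp5, bp3, pct=float(rng.uniform(0, 0.2))))
        m = sample_metrics(calls, catalog)
        assert m.read_pct_lt1000 + m.read_pct_ge1000 == pytest.approx(
            m.cumulative_read_pct)
        assert m.top30_read_pct <= m.cumulative_read_pct + 1e-12
        # complex I burden aggregates over the ND genes, so it dominates the
        # burden attributable to any single ND gene
        from mtaging.deletions import annotate_impact as ann_fn
        nd_genes = [f"MT-ND{k}" for k in ("1", "2", "3", "4", "4L", "5", "6")]
        per_gene = {g: 0.0 for g in nd_genes}
        for c in calls:
            impacted = dict(ann_fn(c, catalog).genes)
            for g in nd_genes:
                if g in impacted:
                    per_gene[g] += c.read_pct
        assert m.complex_read_pct["I"] >= max(per_gene.values()) - 1e-12

    def test_complex_totals_bounded_by_cumulative(self, catalog, rng):
        calls = [make_call(int(b5), int(b3), pct=0.02)
                 for b5, b3 in [(3310, 4200), (5950, 9500), (10100, 14100)]]
        m = sample_metrics(calls, catalog)
        for cx in "I", "III", "IV", "V":
            assert m.complex_read_pct[cx] <= m.cumulative_read_pct + 1e-12

    def test_row_order_invariance(self, catalog, rng):
        calls = [make_call(6000, 7500, pct=0.01),
                 make_call(8471, 13449, pct=0.05),
                 make_call(9000, 9400, pct=0.02)]
        a = sample_metrics(calls, catalog)
        b = sample_metrics(calls[::-1], catalog)
        assert a == b

    def test_explicit_top30_catalog(self, catalog):
        top = frozenset({(6000, 7500)})
        m = sample_metrics([make_call(6000, 7500, pct=0.03),
                            make_call(*COMMON_DELETION, pct=0.05)],
                           catalog, top30_catalog=top)
        assert m.top30_read_pct == pytest.approx(0.03)
        assert m.common_del_read_pct == pytest.approx(0.05)


class TestCohortSummary:
    def _metrics(self, catalog, values):
        rows = []
        for sid, pct in values:
            rows.append(sample_metrics([make_call(*COMMON_DELETION, pct=pct,
                                                  sid=sid)], catalog).to_row())
        return pd.DataFrame(rows)

    def test_identical_regions_fold_one(self, catalog):
        metrics = self._metrics(catalog, [("a", 0.1), ("b", 0.1),
                                          ("c", 0.1), ("d", 0.1)])
        meta = pd.DataFrame({"sample_id": list("abcd"),
                             "region": ["FC", "FC", "CER", "CER"]})
        summary = cohort_summary(metrics, meta,
                                 metric_columns=["cumulative_read_pct"])
        assert summary["fold_FC_over_CER"].iloc[0] == pytest.approx(1.0)

    def test_doubled_region_fold_two(self, catalog):
        metrics = self._metrics(catalog, [("a", 0.2), ("b", 0.4),
                                          ("c", 0.1), ("d", 0.2)])
        meta = pd.DataFrame({"sample_id": list("abcd"),
                             "region": ["FC", "FC", "CER", "CER"]})
        summary = cohort_summary(metrics, meta,
                                 metric_columns=["cumulative_read_pct"])
        assert summary["fold_FC_over_CER"].iloc[0] == pytest.approx(2.0)

    def test_missing_region_metadata(self, catalog):
        metrics = self._metrics(catalog, [("a", 0.2)])
        meta = pd.DataFrame({"sample_id": ["zzz"], "region": ["FC"]})
        with pytest.raises(DeletionTableError, match="without region"):
            cohort_summary(metrics, meta)


def test_metrics_table_includes_deletion_free_samples(catalog):
    calls = [make_call(8471, 13449, sid="a")]
    df = metrics_table(calls, catalog, all_samples=[("a", 5000.0), ("b", 4000.0)])
    assert set(df.sample_id) == {"a", "b"}
    assert df.loc[df.sample_id == "b", "cumulative_read_pct"].iloc[0] == 0.0
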
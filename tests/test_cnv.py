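import numpy as np
import pandas as pd
import pytest

from portrait.cnv import (
    FgaParams,
    alteration_frequency,
    call_cnv,
    cnv_similarity,
    compute_fga,
    map_segments_to_genes,
    select_top_variable,
)
from portrait.errors import UndefinedResultError
from portrait.io import GeneModelTable, LabeledMatrix, SegmentTable


def segments(rows, sample="S1"):
    return SegmentTable(pd.DataFrame(
        [(sample, str(c), s, e, m) for c, s, e, m in rows],
        columns=["sample_id", "chromosome", "start", "end", "segment_mean"],
    ))


def genes(rows):
    return GeneModelTable(pd.DataFrame(
        [(g, str(c), s, e) for g, c, s, e in rows],
        columns=["gene_id", "chromosome", "start", "end"],
    ))


def per_base_fga(table: SegmentTable, threshold: float) -> float:
    """Per-base oracle: expand every segment and count altered bases."""
    values = np.concatenate([
        np.full(int(r.end - r.start + 1), r.segment_mean)
        for r in table.df.itertuples(index=False)
    ])
    return float((np.abs(values) > threshold).mean())


def per_base_gene_values(seg: SegmentTable, models: GeneModelTable):
    """Per-base oracle for segment-to-gene mapping (single sample)."""
    out = {}
    for g in models.df.itertuples(index=False):
        acc = []
        sub = seg.df[seg.df["chromosome"] == g.chromosome]
        for pos in range(g.start, g.end + 1):
            hit = sub[(sub["start"] <= pos) & (sub["end"] >= pos)]
            if len(hit):
                acc.append(float(hit["segment_mean"].iloc[0]))
        out[g.gene_id] = float(np.mean(acc)) if acc else np.nan
    return out


class TestFga:
    def test_no_segment_clears_threshold(self):
        table = segments([(1, 1, 100, 0.05), (2, 1, 50, -0.1)])
        assert compute_fga(table, FgaParams(0.2)) == 0.0

    def test_all_segments_clear_threshold(self):
        table = segments([(1, 1, 100, 0.9), (2, 1, 50, -0.8)])
        assert compute_fga(table, FgaParams(0.2)) == 1.0

    def test_hand_case(self):
        # lengths 100 and 300; only the first exceeds |mean| > 0.2
        table = segments([(1, 1, 100, 0.5), (1, 101, 400, 0.1)])
        assert compute_fga(table, FgaParams(0.2)) == pytest.approx(0.25)

    def test_empty_sample_is_undefined(self):
        table = segments([(1, 1, 10, 0.5)])
        with pytest.raises(UndefinedResultError):
            compute_fga(table.for_sample("nope"), FgaParams(0.2))

    def test_matches_per_base_oracle_randomized(self, rng):
        for _ in range(100):
            rows, pos = [], 1
            for _ in range(int(rng.integers(1, 11))):
                length = int(rng.integers(1, 10_001))
                rows.append((1, pos, pos + length - 1, float(rng.normal(0, 0.4))))
                pos += length
            table = segments(rows)
            t = float(rng.uniform(0.05, 0.6))
            assert compute_fga(table, FgaParams(t)) == pytest.approx(per_base_fga(table, t))

    def test_monotone_non_increasing_in_threshold(self, rng):
        rows, pos = [], 1
        for _ in range(10):
            length = int(rng.integers(1, 5000))
            rows.append((1, pos, pos + length - 1, float(rng.normal(0, 0.4))))
            pos += length
        table = segments(rows)
        values = [compute_fga(table, FgaParams(t)) for t in (0.05, 0.1, 0.2, 0.3, 0.5)]
        assert all(a >= b for a, b in zip(values, values[1:]))
        assert all(0 <= v <= 1 for v in values)

    def test_splitting_a_segment_changes_nothing(self):
        whole = segments([(1, 1, 1000, 0.45)])
        split = segments([(1, 1, 400, 0.45), (1, 401, 1000, 0.45)])
        assert compute_fga(whole, FgaParams(0.3)) == compute_fga(split, FgaParams(0.3))


class TestSegmentToGeneMapping:
    def test_gene_inside_one_segment(self):
        m = map_segments_to_genes(segments([(1, 1, 1000, 0.7)]), genes([("g1", 1, 100, 200)]))
        assert m.data.at["g1", "S1"] == pytest.approx(0.7)

    def test_equal_overlap_of_two_segments_averages(self):
        seg = segments([(1, 1, 100, 0.2), (1, 101, 200, 0.6)])
        m = map_segments_to_genes(seg, genes([("g1", 1, 51, 150)]))
        assert m.data.at["g1", "S1"] == pytest.approx(0.4)

    def test_gene_on_absent_chromosome_is_missing(self):
        m = map_segments_to_genes(segments([(1, 1, 100, 0.2)]), genes([("g1", 9, 10, 20)]))
        assert np.isnan(m.data.at["g1", "S1"])

    def test_matches_per_base_oracle_randomized(self, rng):
        for _ in range(40):
            rows, pos = [], 1
            for _ in range(int(rng.integers(1, 11))):
                length = int(rng.integers(1, 400))
                rows.append((1, pos, pos + length - 1, float(rng.normal(0, 0.5))))
                pos += length + int(rng.integers(0, 50))  # allow gaps
            seg = segments(rows)
            gene_rows = []
            for gi in range(int(rng.integers(1, 6))):
                s = int(rng.integers(1, pos))
                gene_rows.append((f"g{gi}", 1, s, s + int(rng.integers(0, 300))))
            models = genes(gene_rows)
            mapped = map_segments_to_genes(seg, models)
            oracle = per_base_gene_values(seg, models)
            for gid, expected in oracle.items():
                got = mapped.data.at[gid, "S1"]
                if np.isnan(expected):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expected, abs=1e-9)

    def test_splitting_a_segment_preserves_gene_values(self):
        whole = segments([(1, 1, 1000, 0.42)])
        split = segments([(1, 1, 250, 0.42), (1, 251, 1000, 0.42)])
        models = genes([("g1", 1, 100, 600)])
        a = map_segments_to_genes(whole, models).data
        b = map_segments_to_genes(split, models).data
        pd.testing.assert_frame_equal(a, b)


class TestCallsAndSelection:
    def test_amplification_and_deletion_cutoffs(self):
        m = LabeledMatrix(pd.DataFrame(
            {"S1": [0.31, -0.31, 0.0, 0.3, np.nan]},
            index=["g1", "g2", "g3", "g4", "g5"],
        ))
        calls = call_cnv(m)
        assert list(calls["S1"][:4]) == ["amplified", "deleted", "neutral", "neutral"]
        assert pd.isna(calls.at["g5", "S1"])

    def test_alteration_frequency_counts(self):
        m = LabeledMatrix(pd.DataFrame(
            [[0.5, 0.5, 0.1, 0.1], [0.0, 0.0, 0.0, 0.0], [np.nan] * 4],
            index=["g1", "g2", "g3"], columns=["S1", "S2", "S3", "S4"],
        ))
        freq = alteration_frequency(call_cnv(m))
        assert freq.at["g1", "amp_fraction"] == pytest.approx(0.5)
        assert freq.at["g2", "amp_fraction"] == 0.0
        assert np.isnan(freq.at["g3", "amp_fraction"])

    def test_fraction_one_returns_all_eligible(self):
        m = LabeledMatrix(pd.DataFrame(np.random.default_rng(0).normal(size=(5, 4)),
                                       index=list("abcde"), columns=list("WXYZ")))
        assert sorted(select_top_variable(m, 1.0)) == list("abcde")

    def test_constant_gene_ranks_last(self):
        m = LabeledMatrix(pd.DataFrame(
            [[1.0, 1.0, 1.0], [0.1, 5.0, -3.0]], index=["flat", "var"],
            columns=["S1", "S2", "S3"],
        ))
        assert select_top_variable(m, 0.5) == ["var"]

    def test_top_fraction_matches_brute_force_variance_ranking(self):
        values = np.array([
            [0.0, 0.1, 0.0, 0.1],
            [5.0, -5.0, 5.0, -5.0],
            [1.0, 2.0, 3.0, 4.0],
            [0.0, 0.0, 0.0, 0.0],
            [2.0, -2.0, 0.0, 0.0],
        ])
        m = LabeledMatrix(pd.DataFrame(values, index=list("abcde"), columns=list("WXYZ")))
        variances = {g: float(np.var(values[i], ddof=1)) for i, g in enumerate("abcde")}
        expected = sorted(variances, key=lambda g: (-variances[g], g))[:2]
        assert select_top_variable(m, 0.4) == expected

    def test_bad_fraction_rejected(self):
        m = LabeledMatrix(pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["S1", "S2"]))
        with pytest.raises(ValueError):
            select_top_variable(m, 0.0)


class TestCnvSimilarity:
    def test_constant_offset_gives_perfect_correlation(self, rng):
        gene_ids = [f"g{i}" for i in range(6)]
        base = rng.normal(size=(6, 1))
        cells = LabeledMatrix(pd.DataFrame(base, index=gene_ids, columns=["C1"]))
        tumors = LabeledMatrix(pd.DataFrame(base + 0.25, index=gene_ids, columns=["T1"]))
        table = cnv_similarity(cells, tumors, genes=gene_ids)
        assert table.df.at["C1", "T1"] == pytest.approx(1.0)
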
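import numpy as np
import pandas as pd
import pytest

from conftest import brute_pearson
from portrait.errors import UndefinedResultError
from portrait.io import CoverageTable, LabeledMatrix, MutationTable
from portrait.mutation import (
    SPECTRUM_CATEGORIES,
    binarize,
    context_profile,
    filter_somatic_functional,
    mutation_frequency,
    mutation_rate_per_mb,
    mutation_similarity,
    reverse_complement,
    spectrum,
    spectrum_correlation,
)

COLS = ["sample_id", "gene_id", "chromosome", "position", "ref_allele",
        "alt_allele", "variant_classification", "somatic", "context"]


def muts(rows):
    return MutationTable(pd.DataFrame(rows, columns=COLS))


def record(sample="S1", gene="TP53", chrom="17", pos=100, ref="C", alt="T",
           cls="Missense_Mutation", somatic=True, context=None):
    return (sample, gene, chrom, pos, ref, alt, cls, somatic, context)


class TestFiltering:
    def test_silent_and_germline_records_dropped(self):
        table = muts([
            record(cls="Silent"),
            record(pos=101, somatic=False),
            record(pos=102),
            record(pos=103, cls="Intron"),
            record(pos=104, cls="Nonsense_Mutation"),
        ])
        kept = filter_somatic_functional(table)
        assert list(kept.df["position"]) == [102, 104]

    def test_blacklisted_site_dropped(self):
        table = muts([record(pos=500), record(pos=501)])
        kept = filter_somatic_functional(table, germline_sites={("17", 500)})
        assert list(kept.df["position"]) == [501]


class TestBinarization:
    def test_multiple_hits_stay_one(self):
        table = muts([record(pos=p) for p in (1, 2, 3)])
        b = binarize(table, ["TP53"], ["S1"])
        assert b.data.at["TP53", "S1"] == 1.0

    def test_empty_input_all_zero(self):
        b = binarize(muts([]), ["TP53", "PIK3CA"], ["S1", "S2"])
        assert (b.data.to_numpy() == 0).all()

    def test_manual_tally(self):
        table = muts([
            record("S1", "TP53"), record("S1", "GATA3", pos=2),
            record("S2", "PIK3CA", pos=3),
        ])
        b = binarize(table, ["TP53", "PIK3CA", "GATA3"], ["S1", "S2"])
        expected = pd.DataFrame(
            [[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]],
            index=["TP53", "PIK3CA", "GATA3"], columns=["S1", "S2"],
        )
        pd.testing.assert_frame_equal(b.data, expected)

    def test_frequency_is_row_mean(self):
        b = LabeledMatrix(pd.DataFrame(
            [[1.0] * 31 + [0.0] * 69], index=["TP53"],
            columns=[f"S{i}" for i in range(100)],
        ))
        assert mutation_frequency(b)["TP53"] == pytest.approx(0.31)


class TestMutationRate:
    def coverage(self, rows):
        return CoverageTable(pd.DataFrame(rows, columns=["sample_id", "chromosome", "start", "end"]))

    def test_rate_arithmetic(self):
        cov = self.coverage([("S1", "1", 0, 2_000_000)])
        table = muts([record(pos=p) for p in range(4)])
        assert mutation_rate_per_mb(table, cov, "S1") == pytest.approx(2.0)

    def test_zero_mutations(self):
        cov = self.coverage([("S1", "1", 0, 1_000_000)])
        assert mutation_rate_per_mb(muts([]), cov, "S1") == 0.0

    def test_double_listed_intervals_not_double_counted(self):
        once = self.coverage([("S1", "1", 0, 1_000_000)])
        doubled = self.coverage([("S1", "1", 0, 1_000_000), ("S1", "1", 0, 1_000_000)])
        table = muts([record()])
        assert mutation_rate_per_mb(table, once, "S1") == mutation_rate_per_mb(table, doubled, "S1")

    def test_split_coverage_intervals_same_rate(self):
        whole = self.coverage([("S1", "1", 0, 1_000_000)])
        split = self.coverage([("S1", "1", 0, 400_000), ("S1", "1", 400_000, 1_000_000)])
        table = muts([record()])
        assert mutation_rate_per_mb(table, whole, "S1") == mutation_rate_per_mb(table, split, "S1")

    def test_absent_sample_is_undefined(self):
        with pytest.raises(UndefinedResultError):
            mutation_rate_per_mb(muts([]), self.coverage([("S1", "1", 0, 10)]), "S2")


class TestSpectrum:
    def test_single_record_concentrates_category(self):
        v = spectrum(muts([record(ref="C", alt="T")]))
        assert v.proportions["C>T"] == 1.0 and v.proportions.sum() == 1.0

    def test_complement_collapse_of_g_to_a(self):
        v = spectrum(muts([record(ref="G", alt="A")]))
        assert v.proportions["C>T"] == 1.0

    def test_hand_tally(self):
        v = spectrum(muts([
            record(ref="C", alt="T"), record(pos=2, ref="C", alt="T"),
            record(pos=3, ref="G", alt="C"), record(pos=4, ref="A", alt="G"),
        ]))
        expected = pd.Series([0.0, 0.25, 0.0, 0.0, 0.25, 0.5], index=SPECTRUM_CATEGORIES)
        pd.testing.assert_series_equal(v.proportions, expected, check_names=False)

    def test_indel_only_input_undefined(self):
        with pytest.raises(UndefinedResultError):
            spectrum(muts([record(ref="C", alt="CT", cls="Frame_Shift_Ins")]))

    def test_reverse_complement_invariance(self, rng):
        bases = "ACGT"
        for _ in range(50):
            rows = []
            for i in range(int(rng.integers(1, 20))):
                ref = bases[rng.integers(4)]
                alt = bases[rng.integers(4)]
                if alt == ref:
                    alt = bases[(bases.index(ref) + 1) % 4]
                rows.append(record(pos=i, ref=ref, alt=alt))
            fwd = spectrum(muts(rows))
            comp = str.maketrans("ACGT", "TGCA")
            flipped = [
                record(pos=i, ref=r[4].translate(comp), alt=r[5].translate(comp))
                for i, r in enumerate(rows)
            ]
            rev = spectrum(muts(flipped))
            assert (fwd.proportions == rev.proportions).all()
            assert fwd.proportions.sum() == pytest.approx(1.0)


class TestContextProfile:
    def test_direct_read_off(self):
        p = context_profile(muts([record(context="AACTG")]))
        grid = p.grids["C>T"]
        assert grid.at["A", -2] == 1.0
        assert grid.at["A", -1] == 1.0
        assert grid.at["T", 1] == 1.0
        assert grid.at["G", 2] == 1.0

    def test_strand_collapse_reverse_complements_context(self):
        # G>A at the middle of CAGTT contributes to C>T with context AACTG
        p = context_profile(muts([record(ref="G", alt="A", context="CAGTT")]))
        grid = p.grids["C>T"]
        assert grid.at["A", -2] == 1.0 and grid.at["G", 2] == 1.0

    def test_position_proportions_sum_to_one(self, rng):
        bases = "ACGT"
        rows = []
        for i in range(30):
            ref = bases[rng.integers(4)]
            alt = bases[(bases.index(ref) + 1 + rng.integers(3)) % 4]
            ctx = "".join(bases[j] for j in rng.integers(0, 4, 5))
            ctx = ctx[:2] + ref + ctx[3:]
            rows.append(record(pos=i, ref=ref, alt=alt, context=ctx))
        p = context_profile(muts(rows))
        for grid in p.grids.values():
            sums = grid.sum(axis=0, min_count=1)
            for v in sums:
                assert np.isnan(v) or v == pytest.approx(1.0)

    def test_missing_context_counted(self):
        p = context_profile(muts([record(context="AACTG"), record(pos=2, context=None)]))
        assert p.n_missing_context == 1


class TestSpectrumCorrelation:
    def test_identical_vectors(self):
        r = spectrum_correlation(np.array([0.1, 0.2, 0.7]), np.array([0.1, 0.2, 0.7]))
        assert r == pytest.approx(1.0)

    def test_hand_vectors_match_brute_force(self):
        a = [0.05, 0.15, 0.05, 0.10, 0.20, 0.45]
        b = [0.10, 0.10, 0.05, 0.15, 0.25, 0.35]
        assert spectrum_correlation(np.array(a), np.array(b)) == pytest.approx(brute_pearson(a, b))

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedResultError):
            spectrum_correlation(np.ones(6), np.arange(6.0))


def phi_from_contingency(x, y) -> float:
    """Closed-form phi coefficient of two binary vectors via the 2x2 table."""
    x, y = np.asarray(x), np.asarray(y)
    n11 = int(((x == 1) & (y == 1)).sum())
    n10 = int(((x == 1) & (y == 0)).sum())
    n01 = int(((x == 0) & (y == 1)).sum())
    n00 = int(((x == 0) & (y == 0)).sum())
    denom = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    return (n11 * n00 - n10 * n01) / np.sqrt(denom)


class TestMutationSimilarity:
    def binmat(self, columns, genes):
        return LabeledMatrix(pd.DataFrame(columns, index=genes))

    def test_identical_and_complementary_columns(self):
        genes = [f"g{i}" for i in range(6)]
        x = np.array([1.0, 0, 1, 0, 0, 1])
        cells = self.binmat({"C1": x}, genes)
        assert mutation_similarity(cells, self.binmat({"T1": x}, genes)).df.at["C1", "T1"] == pytest.approx(1.0)
        assert mutation_similarity(cells, self.binmat({"T2": 1 - x}, genes)).df.at["C1", "T2"] == pytest.approx(-1.0)

    def test_equals_phi_coefficient(self, rng):
        genes = [f"g{i}" for i in range(12)]
        for _ in range(25):
            x = (rng.random(12) < 0.4).astype(float)
            y = (rng.random(12) < 0.4).astype(float)
            if x.std() == 0 or y.std() == 0:
                continue
            r = mutation_similarity(self.binmat({"C1": x}, genes),
                                    self.binmat({"T1": y}, genes)).df.at["C1", "T1"]
            assert r == pytest.approx(phi_from_contingency(x, y), abs=1e-12)

    def test_constant_column_yields_missing(self):
        genes = [f"g{i}" for i in range(6)]
        cells = self.binmat({"C1": np.zeros(6)}, genes)
        tumors = self.binmat({"T1": np.array([1.0, 0, 1, 0, 1, 0])}, genes)
        assert np.isnan(mutation_similarity(cells, tumors).df.at["C1", "T1"])


def test_reverse_complement_involution():
    assert reverse_complement("AACTG") == "CAGTT"
    assert reverse_complement(reverse_complement("GATTACA")) == "GATTACA"
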
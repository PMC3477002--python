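"""Tests for nearest-neighbor search, the two separability scores, and the grid."""

import numpy as np
import pytest

from taxosep import (
    LabeledDataset,
    SequenceRecord,
    TaxonLevel,
    conventional_score,
    hierarchical_score,
    nearest_neighbor,
    run_grid,
)
from taxosep.scoring import InsufficientPoolError

from conftest import make_lineage, random_pool
from naive_oracle import naive_conventional, naive_dense, naive_hierarchical


def rec(rid, seq, **lineage_kwargs):
    return SequenceRecord(rid, seq, make_lineage(**lineage_kwargs))


def oracle_scores(pool, level, n, measure, smoothed):
    records = [(r.id, r.lineage) for r in pool]
    vectors = {r.id: naive_dense(r.sequence, n, smoothed) for r in pool}
    conv = naive_conventional(records, vectors, level, measure)
    hier = naive_hierarchical(records, vectors, level, measure)
    return conv, hier


class TestNearestNeighbor:
    def test_exact_duplicate_is_neighbor(self):
        pool = LabeledDataset(
            [rec("a", "AAAATTTT"), rec("b", "AAAATTTT"), rec("c", "GGGGCCCC")]
        )
        assert nearest_neighbor(pool["a"], pool, 2, "1") == "b"

    def test_argmin_matches_brute_force(self):
        pool = LabeledDataset(
            [rec("a", "AAAAAAAA"), rec("b", "AAAAAATT"), rec("c", "TTTTTTTT")]
        )
        vectors = {r.id: naive_dense(r.sequence, 1) for r in pool}
        from naive_oracle import naive_measure
        for q in "abc":
            dists = {
                o: naive_measure("1", vectors[q], vectors[o]) for o in "abc" if o != q
            }
            expected = min(dists, key=lambda k: (dists[k], k))
            assert nearest_neighbor(pool[q], pool, 1, "1") == expected

    def test_tie_broken_by_smallest_id(self):
        # b and z are bit-identical, both at the same distance from a
        pool = LabeledDataset(
            [rec("a", "AAAAAAAA"), rec("z", "AAAATTTT"), rec("b", "AAAATTTT")]
        )
        assert nearest_neighbor(pool["a"], pool, 1, "2") == "b"

    def test_singleton_pool_rejected(self):
        pool = LabeledDataset([rec("a", "ACGTACGT")])
        with pytest.raises(InsufficientPoolError):
            nearest_neighbor(pool["a"], pool, 1, "1")


class TestConventionalScore:
    def test_perfect_separation(self):
        pool = LabeledDataset(
            [
                rec("x1", "AAAAAAAAAA", species="spX"),
                rec("x2", "AAAAAAAAAT", species="spX"),
                rec("y1", "GGGGGGGGGG", species="spY"),
                rec("y2", "GGGGGGGGGC", species="spY"),
            ]
        )
        r = conventional_score(pool, "species", 1, "1")
        assert r.score == 1.0 and r.m == 4

    def test_every_neighbor_cross_class(self):
        # each record's closest other record belongs to the other species
        pool = LabeledDataset(
            [
                rec("x1", "AAAAAAAA", species="spX"),
                rec("x2", "TTTTTTTT", species="spX"),
                rec("y1", "AAAAAAAT", species="spY"),
                rec("y2", "TTTTTTTA", species="spY"),
            ]
        )
        (conv, m), _ = oracle_scores(pool, 7, 1, "1", False)
        assert conv == 0.0  # fixture really is antipodal per the oracle
        r = conventional_score(pool, "species", 1, "1")
        assert r.score == 0.0 and r.m == 4

    def test_unique_representative_skipped(self):
        pool = LabeledDataset(
            [
                rec("x1", "AAAAAAAA", species="spX"),
                rec("x2", "AAAAAATT", species="spX"),
                rec("y1", "GGGGGGGG", species="spY"),
            ]
        )
        r = conventional_score(pool, "species", 1, "1")
        assert r.m == 2  # y1 not scored
        assert r.score == 1.0

    def test_undefined_when_all_singletons(self):
        pool = LabeledDataset(
            [rec("a", "AAAAAAAA", species="s1"), rec("b", "GGGGGGGG", species="s2")]
        )
        r = conventional_score(pool, "species", 1, "1")
        assert not r.defined and r.m == 0
        assert r.undefined_level is TaxonLevel.SPECIES


# 10 random records over a 2-domain planted tree where pruning visibly helps:
# the conventional species score is 0 but per-level match fractions are not.
_PRUNING_FIXTURE = [
    ("r00", "AAATGTGGTGGGGTCTGACTGATGTAATAGA", ("do1", "ph1.1", "cl1.1.0", "or1.1.0.0", "fa1.1.0.0.0", "ge1.1.0.0.0.0", "sp1.1.0.0.0.0.0")),
    ("r01", "AAAGGGCGTCCTTTCGTGTGGCTAGGTGCC", ("do0", "ph0.0", "cl0.0.0", "or0.0.0.0", "fa0.0.0.0.0", "ge0.0.0.0.0.0", "sp0.0.0.0.0.0.0")),
    ("r02", "TGCGGCCGGGCTCCTCAGGAACTCTCATTAAG", ("do0", "ph0.0", "cl0.0.0", "or0.0.0.0", "fa0.0.0.0.0", "ge0.0.0.0.0.1", "sp0.0.0.0.0.1.1")),
    ("r03", "TTGATAGCTATAGGTCTGTATTACGAGGTTCCCTACACTGCTG", ("do0", "ph0.1", "cl0.1.0", "or0.1.0.0", "fa0.1.0.0.0", "ge0.1.0.0.0.0", "sp0.1.0.0.0.0.1")),
    ("r04", "CCCGATACCGGGTTAAAGTTGTTAATATTTCAGTCTCTACCATTATTCCGGCA", ("do1", "ph1.0", "cl1.0.0", "or1.0.0.0", "fa1.0.0.0.0", "ge1.0.0.0.0.0", "sp1.0.0.0.0.0.1")),
    ("r05", "AGGATGCAATAGTTCACTGAGCACTTAGTCCAATAAAATCTGTGTTAGCCCC", ("do1", "ph1.1", "cl1.1.0", "or1.1.0.0", "fa1.1.0.0.0", "ge1.1.0.0.0.0", "sp1.1.0.0.0.0.1")),
    ("r06", "TGCAGAGATTATCATTAGTTCTTAAACAACGGCTGGTTAATCACCCCCCCTG", ("do0", "ph0.1", "cl0.1.0", "or0.1.0.0", "fa0.1.0.0.0", "ge0.1.0.0.0.1", "sp0.1.0.0.0.1.1")),
    ("r07", "GTGTAGGCGTGCAACTCTCGGTGTTGGTTAGAAGAGTA", ("do1", "ph1.0", "cl1.0.0", "or1.0.0.0", "fa1.0.0.0.0", "ge1.0.0.0.0.0", "sp1.0.0.0.0.0.1")),
    ("r08", "GGGGATGTGCAGTAGCAGTGTGGTCTACGGAGGTGTTAAGCGGCAGC", ("do1", "ph1.0", "cl1.0.0", "or1.0.0.0", "fa1.0.0.0.0", "ge1.0.0.0.0.1", "sp1.0.0.0.0.1.1")),
    ("r09", "ACCTTACGTATTTCAGAAAATGGTCAACGCCAGACGGG", ("do1", "ph1.0", "cl1.0.0", "or1.0.0.0", "fa1.0.0.0.0", "ge1.0.0.0.0.1", "sp1.0.0.0.0.1.1")),
]


def pruning_pool():
    return LabeledDataset(
        [SequenceRecord(i, s, lin) for i, s, lin in _PRUNING_FIXTURE]
    )


class TestHierarchicalScore:
    def test_domain_equals_conventional(self, rng):
        for _ in range(5):
            pool = random_pool(rng)
            c = conventional_score(pool, "domain", 2, "1")
            h = hierarchical_score(pool, "domain", 2, "1")
            assert h.score == c.score and h.m == c.m
            assert h.level_factors == (c.score,)

    def test_pruning_recovers_species_signal(self):
        """Restricting each query's pool to its clade one level above can turn
        a hopeless flat species classification into a partly correct one."""
        pool = pruning_pool()
        c = conventional_score(pool, "species", 2, "1")
        h = hierarchical_score(pool, "species", 2, "1")
        assert c.defined and h.defined
        assert h.score > c.score
        # cross-check both against the direct transcription oracle
        (oc, _), (oh, _) = oracle_scores(pool, 7, 2, "1", False)
        assert c.score == oc
        assert h.score == pytest.approx(oh, abs=1e-12)

    def test_score_is_product_of_level_factors(self):
        h = hierarchical_score(pruning_pool(), "species", 2, "1")
        assert h.score == pytest.approx(float(np.prod(h.level_factors)), abs=1e-12)

    def test_all_factors_one_gives_one(self):
        pool = LabeledDataset(
            [
                rec("x1", "AAAAAAAAAA", species="spX"),
                rec("x2", "AAAAAAAAAT", species="spX"),
                rec("y1", "GGGGGGGGGG", species="spY"),
                rec("y2", "GGGGGGGGGC", species="spY"),
            ]
        )
        h = hierarchical_score(pool, "species", 1, "1")
        assert h.score == 1.0
        assert all(f == 1.0 for f in h.level_factors)

    def test_undefined_reports_offending_level(self):
        # two domains with one record each: domain level has m == 0
        pool = LabeledDataset(
            [
                rec("a", "AAAAAAAA", domain="doA", species="s1"),
                rec("b", "GGGGGGGG", domain="doB", species="s2"),
            ]
        )
        h = hierarchical_score(pool, "species", 1, "1")
        assert not h.defined
        assert h.undefined_level is TaxonLevel.DOMAIN


class TestOracleEquivalence:
    """Both scores on random small pools match the naive transcription exactly."""

    @pytest.mark.parametrize("measure", ["1", "2", "inf", "kl"])
    def test_random_pools(self, measure):
        rng = np.random.default_rng({"1": 11, "2": 22, "inf": 33, "kl": 44}[measure])
        for _ in range(15):
            pool = random_pool(rng)
            n = int(rng.integers(1, 3))
            level = int(rng.integers(1, 8))
            smoothed = measure == "kl"
            (oc, ocm), (oh, ohm) = oracle_scores(pool, level, n, measure, smoothed)
            c = conventional_score(pool, level, n, measure)
            h = hierarchical_score(pool, level, n, measure)
            assert c.m == ocm and c.score == oc
            assert h.m == ohm
            if oh is None:
                assert not h.defined
            else:
                assert h.score == pytest.approx(oh, abs=1e-12)


class TestStructuralInvariants:
    def test_scores_within_unit_interval(self, rng):
        for _ in range(10):
            pool = random_pool(rng)
            for level in (1, 4, 7):
                for fn in (conventional_score, hierarchical_score):
                    r = fn(pool, level, 2, "2")
                    if r.defined:
                        assert 0.0 <= r.score <= 1.0

    def test_depth_monotonicity_without_singletons(self, rng):
        """With ≥ 2 members per class everywhere, a correct match at level t
        implies one at t-1, so the conventional score cannot increase with
        depth; the hierarchical score is a product of factors ≤ 1."""
        bases = np.array(list("ACGT"))
        prefixes = ("do", "ph", "cl", "or", "fa", "ge", "sp")
        branching = (2, 2, 1, 1, 1, 2, 2)
        for _ in range(5):
            # ≥ 2 records per species guarantees ≥ 2 per class at every level
            records = []
            paths = {
                tuple(int(rng.integers(0, b)) for b in branching) for _ in range(4)
            }
            i = 0
            for path in sorted(paths):
                lineage = tuple(
                    prefixes[t] + ".".join(map(str, path[: t + 1])) for t in range(7)
                )
                for _ in range(int(rng.integers(2, 4))):
                    L = int(rng.integers(30, 60))
                    seq = "".join(bases[rng.integers(0, 4, L)])
                    records.append(SequenceRecord(f"r{i:02d}", seq, lineage))
                    i += 1
            pool = LabeledDataset(records)
            conv = [conventional_score(pool, t, 2, "1").score for t in range(1, 8)]
            hier = hierarchical_score(pool, "species", 2, "1")
            for a, b in zip(conv, conv[1:]):
                assert b <= a + 1e-12
            prods = np.cumprod(hier.level_factors)
            for a, b in zip(prods, prods[1:]):
                assert b <= a + 1e-12
            assert hier.score <= hier.level_factors[-1] + 1e-12


class TestRunGrid:
    def test_genomic_axes_produce_80_cells(self, rng):
        pool = random_pool(rng, min_records=6, max_records=8, seq_len=(40, 60))
        df = run_grid(pool, ["species"], range(1, 11), ["1", "2", "inf", "kl"])
        assert len(df) == 80
        assert df["n"].nunique() == 10 and df["measure"].nunique() == 4

    def test_fragment_axes_produce_64_cells(self, rng):
        pool = random_pool(rng, min_records=6, max_records=8, seq_len=(40, 60))
        df = run_grid(pool, ["species"], range(1, 9), ["1", "2", "inf", "kl"])
        assert len(df) == 64

    def test_restricted_measure_axis(self, rng):
        pool = random_pool(rng, min_records=6, max_records=8)
        df = run_grid(pool, ["species"], range(1, 11), ["kl"])
        assert len(df) == 20

    def test_empty_axis_rejected(self, rng):
        pool = random_pool(rng)
        with pytest.raises(ValueError):
            run_grid(pool, ["species"], range(1, 5), [])

    def test_grid_matches_single_runs(self, rng):
        pool = random_pool(rng, min_records=8, max_records=10)
        df = run_grid(pool, ["phylum", "species"], [2, 3], ["1", "kl"])
        for row in df.itertuples():
            fn = conventional_score if row.score_measure == "conventional" else hierarchical_score
            ref = fn(pool, row.level, row.n, row.measure)
            if ref.defined:
                assert row.score == pytest.approx(ref.score, abs=1e-12)
            else:
                assert not row.defined

    def test_undefined_cells_do_not_abort(self):
        pool = LabeledDataset(
            [rec("a", "AAAAAAAA", species="s1"), rec("b", "GGGGGGGG", species="s2")]
        )
        df = run_grid(pool, ["species"], [1], ["1"])
        assert len(df) == 2
        assert not df["defined"].any()


class TestExcludeSameSource:
    def test_sibling_fragments_excluded_from_neighbors(self):
        lin = make_lineage()
        recs = [
            SequenceRecord("f1", "AAAAAAAAAA", lin, source_id="g1"),
            SequenceRecord("f2", "AAAAAAAAAT", lin, source_id="g1"),
            SequenceRecord("f3", "GGGGGGGGGG", lin, source_id="g2"),
        ]
        pool = LabeledDataset(recs)
        assert nearest_neighbor(pool["f1"], pool, 1, "1") == "f2"
        assert (
            nearest_neighbor(pool["f1"], pool, 1, "1", exclude_same_source=True)
            == "f3"
        )
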
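import math

import numpy as np
import pytest

from ascabc.coalsim import HaplotypeMatrix, SimulationConfig, simulate_locus
from ascabc.demography import DemographicModel
from ascabc.sumstats import (
    StatSchema,
    aggregate,
    assemble_vector,
    compute_locus_stats,
    haplotype_counts,
    pairwise_fst,
    per_pop_sfs_stats,
    shared_private_haplotypes,
    tajimas_d,
)
from oracles import (
    oracle_haplotype_counts,
    oracle_hudson_fst,
    oracle_sfs_counts,
    oracle_shared_private,
    oracle_tajimas_d,
)


def random_matrix(rng, n, sites):
    return (rng.uniform(size=(n, sites)) < rng.uniform(0.1, 0.9, sites)).astype(np.uint8)


class TestBruteForceOracles:
    def test_all_statistics_match_oracles_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n1 = int(rng.integers(4, 11))
            n2 = int(rng.integers(4, 11))
            sites = int(rng.integers(1, 13))
            m1 = random_matrix(rng, n1, sites)
            m2 = random_matrix(rng, n2, sites)
            assert per_pop_sfs_stats(m1) == oracle_sfs_counts(m1)
            d, od = tajimas_d(m1), oracle_tajimas_d(m1)
            assert (math.isnan(d) and math.isnan(od)) or d == pytest.approx(od)
            assert haplotype_counts(m1) == oracle_haplotype_counts(m1)
            assert shared_private_haplotypes(m1, m2) == oracle_shared_private(m1, m2)
            f, of = pairwise_fst(m1, m2), oracle_hudson_fst(m1, m2)
            if math.isnan(of):
                assert math.isnan(f)
            else:
                assert f == pytest.approx(min(max(of, -1 + 1e-12), 1.0))


class TestSfsCounts:
    def test_singleton_counted(self):
        m = np.array([[1, 0], [0, 0], [0, 1], [0, 1]], dtype=np.uint8)
        assert per_pop_sfs_stats(m) == (2, 1, 1)

    def test_monomorphic_not_counted(self):
        m = np.ones((4, 3), dtype=np.uint8)
        assert per_pop_sfs_stats(m) == (0, 0, 0)

    def test_doubleton_on_minor_allele(self):
        m = np.array([[1, 1], [1, 1], [0, 1], [0, 1]], dtype=np.uint8)
        # first site 2/2 -> doubleton; second monomorphic
        assert per_pop_sfs_stats(m) == (1, 0, 1)


class TestTajimasD:
    def test_undefined_without_segregating_sites(self):
        assert math.isnan(tajimas_d(np.zeros((6, 4), dtype=np.uint8)))

    def test_excess_singletons_negative(self):
        m = np.zeros((10, 8), dtype=np.uint8)
        for j in range(8):
            m[j % 10, j] = 1
        assert tajimas_d(m) < 0


class TestHaplotypeCounts:
    def test_all_identical(self):
        m = np.tile([1, 0, 1], (8, 1)).astype(np.uint8)
        assert haplotype_counts(m) == (1, 8)

    def test_all_distinct(self):
        m = np.array([[int(b) for b in f"{i:03b}"] for i in range(8)], dtype=np.uint8)
        assert haplotype_counts(m) == (8, 1)

    def test_zero_sites_convention(self):
        assert haplotype_counts(np.zeros((5, 0), dtype=np.uint8)) == (1, 5)


class TestFst:
    def test_fixed_difference_is_one(self):
        a = np.zeros((4, 1), dtype=np.uint8)
        b = np.ones((4, 1), dtype=np.uint8)
        assert pairwise_fst(a, b) == pytest.approx(1.0)

    def test_identical_frequencies_near_zero(self):
        # Hudson's unbiased within-het gives exactly -1/(n-1) for two
        # identical samples; with large n this vanishes.
        n = 400
        block = np.array([[1, 0]] * (n // 2) + [[0, 1]] * (n // 2), dtype=np.uint8)
        assert abs(pairwise_fst(block, block)) < 1.5 / (n - 1)

    def test_no_between_diversity_undefined(self):
        a = np.zeros((4, 2), dtype=np.uint8)
        assert math.isnan(pairwise_fst(a, a))

    def test_panmictic_mean_near_zero(self):
        model = DemographicModel(populations={"P": 10_000.0}, samples={"P": 16})
        cfg = SimulationConfig(locus_length=5_000)
        rng = np.random.default_rng(77)
        vals = []
        for _ in range(500):
            H = simulate_locus(model, cfg, rng)
            if H.n_sites == 0:
                continue
            f = pairwise_fst(H.alleles[:8], H.alleles[8:])
            if not math.isnan(f):
                vals.append(f)
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean()) < 3 * se

    def test_weir_cockerham_available(self):
        a = np.zeros((6, 1), dtype=np.uint8)
        b = np.ones((6, 1), dtype=np.uint8)
        assert pairwise_fst(a, b, estimator="weir_cockerham") == pytest.approx(1.0)


class TestSharedPrivate:
    def test_set_arithmetic(self):
        p1 = np.array([[0, 0], [0, 1]], dtype=np.uint8)
        p2 = np.array([[0, 1], [1, 1]], dtype=np.uint8)
        assert shared_private_haplotypes(p1, p2) == (1, 1, 1)

    def test_disjoint_and_identical(self):
        p1 = np.array([[0, 0], [0, 1]], dtype=np.uint8)
        p2 = np.array([[1, 0], [1, 1]], dtype=np.uint8)
        assert shared_private_haplotypes(p1, p2) == (0, 2, 2)
        assert shared_private_haplotypes(p1, p1) == (2, 0, 0)


class TestAggregation:
    def _stats(self, values, name="genomic.A.segsites"):
        schema = StatSchema((("A", ("genomic",)),), ())
        rows = [{e: v for e in schema.locus_entries} for v in values]
        return schema, rows

    def test_two_point_mean_and_sd(self):
        schema, rows = self._stats([10.0, 20.0])
        vec = aggregate(rows, schema)
        d = vec.as_dict()
        assert d["genomic.A.segsites.mean"] == pytest.approx(15.0)
        assert d["genomic.A.segsites.sd"] == pytest.approx(7.0710678, rel=1e-6)

    def test_identical_loci_zero_sd(self):
        schema, rows = self._stats([5.0, 5.0, 5.0])
        assert aggregate(rows, schema).as_dict()["genomic.A.segsites.sd"] == 0.0

    def test_nan_excluded_and_logged(self):
        schema, rows = self._stats([1.0, float("nan"), 3.0])
        vec = aggregate(rows, schema)
        assert vec.as_dict()["genomic.A.tajimas_d.mean"] == pytest.approx(2.0)
        assert vec.exclusions["genomic.A.tajimas_d"] == 1


class TestSchema:
    def test_ooa_vector_size(self):
        schema = StatSchema.for_model("ooa")
        # 3 pops x 6 stats x 2 layers x 2 moments + 3 pairs x 4 x 2 x 2
        assert len(schema.vector_entries) == 3 * 6 * 2 * 2 + 3 * 4 * 2 * 2

    def test_wollstein_subset(self):
        full = set(StatSchema.for_model("ooa").vector_entries)
        reduced = set(StatSchema.for_model("ooa", wollstein=True).vector_entries)
        assert reduced < full

    def test_admixture_new_pops_ascertained_only(self):
        names = StatSchema.for_model("admixture").vector_entries
        assert not any(n.startswith("genomic.IBS") or "genomic.IBS-" in n
                       or "genomic.MXL" in n or "genomic.NXP" in n for n in names)
        assert any(n.startswith("ascertained.MXL.") for n in names)

    def test_layer_provenance(self, rng):
        # Ascertained-layer stats must be computed on the selected sites only.
        alleles = (rng.uniform(size=(8, 12)) < 0.5).astype(np.uint8)
        H = HaplotypeMatrix(alleles, np.sort(rng.uniform(0, 1000, 12)),
                            np.repeat(["A", "B"], 4), 1000)
        schema = StatSchema.two_population()
        sites = [0, 3, 7]
        stats = compute_locus_stats(H, sites, schema)
        seg_a, _, _ = per_pop_sfs_stats(alleles[:4][:, sites])
        assert stats["ascertained.A.segsites"] == seg_a
        seg_full, _, _ = per_pop_sfs_stats(alleles[:4])
        assert stats["genomic.A.segsites"] == seg_full


def test_assemble_vector_matches_schema_order(toy_spec, rng):
    schema = toy_spec.schema
    rows = []
    for _ in range(3):
        row = {}
        for name in schema.locus_entries:
            row[name] = float(rng.integers(0, 10))
        rows.append(row)
    vec = assemble_vector(schema, rows)
    assert vec.names == schema.vector_entries
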
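import numpy as np
import pandas as pd
import pytest

from saltwise import classify_interactions, core_response, top_genes, unique_de_partition

from conftest import make_stagewise

STRAINS = list("ABDF")
PAIRS = ["8-16", "8-24", "16-24"]
SAL_COLS = [f"{s}:{p}" for s in STRAINS for p in PAIRS] + [
    f"average:{p}" for p in PAIRS
]
INT_COLS = ["A-vs-B:8-24", "A-vs-D:8-24"]


def sal_result(call_rows, logfc_rows, genes):
    calls = pd.DataFrame(call_rows, index=genes, columns=SAL_COLS, dtype=bool)
    logfc = pd.DataFrame(logfc_rows, index=genes, columns=SAL_COLS, dtype=float)
    return make_stagewise(calls, logfc)


def int_result(de_genes, genes):
    calls = pd.DataFrame(False, index=genes, columns=INT_COLS)
    calls.loc[de_genes, INT_COLS[0]] = True
    logfc = pd.DataFrame(1.0, index=genes, columns=INT_COLS)
    return make_stagewise(calls, logfc, family="interaction-set")


class TestClassification:
    def test_opposite_sign_calls_is_direction(self):
        genes = ["g1"]
        calls = np.zeros((1, len(SAL_COLS)), bool)
        logfc = np.zeros((1, len(SAL_COLS)))
        # strain A up, strain B down in the same 8-24 contrast, both called
        calls[0, SAL_COLS.index("A:8-24")] = True
        calls[0, SAL_COLS.index("B:8-24")] = True
        logfc[0, SAL_COLS.index("A:8-24")] = 2.0
        logfc[0, SAL_COLS.index("B:8-24")] = -2.0
        cls = classify_interactions(
            int_result(genes, genes), sal_result(calls, logfc, genes)
        )
        assert cls.table.loc["g1", "category"] == "direction"
        assert cls.table.loc["g1", "evidence_contrast"] == "8-24"

    def test_single_strain_response_is_magnitude(self):
        genes = ["g1"]
        calls = np.zeros((1, len(SAL_COLS)), bool)
        logfc = np.full((1, len(SAL_COLS)), 0.1)
        calls[0, SAL_COLS.index("A:8-24")] = True
        logfc[0, SAL_COLS.index("A:8-24")] = 2.0
        cls = classify_interactions(
            int_result(genes, genes), sal_result(calls, logfc, genes)
        )
        assert cls.table.loc["g1", "category"] == "magnitude"

    def test_opposite_signs_in_different_contrasts_is_magnitude(self):
        # up in A for 8-16, down in B for 16-24: never the same pair
        genes = ["g1"]
        calls = np.zeros((1, len(SAL_COLS)), bool)
        logfc = np.zeros((1, len(SAL_COLS)))
        calls[0, SAL_COLS.index("A:8-16")] = True
        logfc[0, SAL_COLS.index("A:8-16")] = 2.0
        calls[0, SAL_COLS.index("B:16-24")] = True
        logfc[0, SAL_COLS.index("B:16-24")] = -2.0
        cls = classify_interactions(
            int_result(genes, genes), sal_result(calls, logfc, genes)
        )
        assert cls.table.loc["g1", "category"] == "magnitude"

    def test_categories_partition_interaction_de_set(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(40)]
        calls = rng.random((40, len(SAL_COLS))) < 0.3
        logfc = rng.normal(0, 2, (40, len(SAL_COLS)))
        de = [g for g in genes[::2]]
        cls = classify_interactions(
            int_result(de, genes), sal_result(calls, logfc, genes)
        )
        assert set(cls.table.index) == set(de)
        assert set(cls.direction_genes) | set(cls.magnitude_genes) == set(de)
        assert not set(cls.direction_genes) & set(cls.magnitude_genes)

    def test_gene_missing_salinity_info_flagged_magnitude(self):
        genes = ["g1"]
        sal = sal_result(
            np.zeros((1, len(SAL_COLS)), bool), np.zeros((1, len(SAL_COLS))), ["gX"]
        )
        cls = classify_interactions(int_result(genes, genes), sal)
        assert cls.table.loc["g1", "category"] == "magnitude"
        assert bool(cls.table.loc["g1", "flagged"])


class TestCoreResponse:
    def test_called_in_all_strains_is_core(self):
        genes = ["g1", "g2"]
        calls = np.zeros((2, len(SAL_COLS)), bool)
        for s in STRAINS:
            calls[0, SAL_COLS.index(f"{s}:8-24")] = True
        for s in STRAINS[:-1]:  # g2 misses one strain
            calls[1, SAL_COLS.index(f"{s}:8-24")] = True
        res = sal_result(calls, np.ones((2, len(SAL_COLS))), genes)
        core = core_response(res, STRAINS)
        assert list(core) == ["g1"]

    def test_average_calls_do_not_count(self):
        genes = ["g1"]
        calls = np.zeros((1, len(SAL_COLS)), bool)
        for p in PAIRS:
            calls[0, SAL_COLS.index(f"average:{p}")] = True
        res = sal_result(calls, np.ones((1, len(SAL_COLS))), genes)
        assert len(core_response(res, STRAINS)) == 0

    def test_matches_brute_force_on_random_calls(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(20)]
        calls = rng.random((20, len(SAL_COLS))) < 0.5
        res = sal_result(calls, np.ones((20, len(SAL_COLS))), genes)
        expected = []
        for gi, g in enumerate(genes):
            ok = all(
                any(calls[gi, SAL_COLS.index(f"{s}:{p}")] for p in PAIRS)
                for s in STRAINS
            )
            if ok:
                expected.append(g)
        assert list(core_response(res, STRAINS)) == expected

    def test_monotone_in_strains(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(30)]
        calls = rng.random((30, len(SAL_COLS))) < 0.4
        res = sal_result(calls, np.ones((30, len(SAL_COLS))), genes)
        full = set(core_response(res, STRAINS))
        fewer = set(core_response(res, STRAINS[:-1]))
        assert full <= fewer


class TestPartition:
    def test_buckets(self):
        genes = ["only_D", "d_and_avg", "avg_only", "multi", "none"]
        calls = np.zeros((5, len(SAL_COLS)), bool)
        calls[0, SAL_COLS.index("D:8-24")] = True
        calls[1, SAL_COLS.index("D:8-16")] = True
        calls[1, SAL_COLS.index("average:8-16")] = True
        calls[2, SAL_COLS.index("average:8-24")] = True
        calls[3, SAL_COLS.index("A:8-24")] = True
        calls[3, SAL_COLS.index("B:8-24")] = True
        res = sal_result(calls, np.ones((5, len(SAL_COLS))), genes)
        part = unique_de_partition(res)
        assert list(part.unique_strain["D"]) == ["only_D"]
        assert list(part.unique_strain_and_average["D"]) == ["d_and_avg"]
        assert list(part.average_only) == ["avg_only"]
        assert list(part.multi_strain) == ["multi"]

    def test_sizes_match_brute_force_recount(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(500)]
        calls = rng.random((500, len(SAL_COLS))) < 0.15
        res = sal_result(calls, np.ones((500, len(SAL_COLS))), genes)
        part = unique_de_partition(res)
        n_unique = n_unique_avg = n_avg_only = n_multi = 0
        for gi in range(500):
            strains_de = {
                s
                for s in STRAINS
                if any(calls[gi, SAL_COLS.index(f"{s}:{p}")] for p in PAIRS)
            }
            avg_de = any(calls[gi, SAL_COLS.index(f"average:{p}")] for p in PAIRS)
            if not strains_de and not avg_de:
                continue
            if len(strains_de) == 1 and not avg_de:
                n_unique += 1
            elif len(strains_de) == 1 and avg_de:
                n_unique_avg += 1
            elif not strains_de and avg_de:
                n_avg_only += 1
            else:
                n_multi += 1
        sizes = part.sizes()
        assert sizes["unique_strain"] == n_unique
        assert sizes["unique_strain_and_average"] == n_unique_avg
        assert sizes["average_only"] == n_avg_only
        assert sizes["multi_strain"] == n_multi
        # buckets are disjoint
        buckets = (
            [g for v in part.unique_strain.values() for g in v]
            + [g for v in part.unique_strain_and_average.values() for g in v]
            + list(part.average_only)
            + list(part.multi_strain)
        )
        assert len(buckets) == len(set(buckets))


class TestTopGenes:
    def test_unique_smallest_padjscreen_is_first(self, small_results):
        sal_res, _ = small_results
        top, _ = top_genes(sal_res, n=1, ranking="padjscreen")
        best = sal_res.padj_screen.sort_values(kind="stable").index[0]
        assert top[0] == best

    def test_direction_counts_conserve_calls(self, small_results):
        sal_res, _ = small_results
        top, summary = top_genes(sal_res, n=50, ranking="padjscreen")
        n_called = sal_res.calls.loc[top].sum().sum()
        assert summary["n_up"].sum() + summary["n_down"].sum() == n_called

    def test_confect_ranks_by_lower_bound(self):
        genes = [f"g{i}" for i in range(10)]
        cols = SAL_COLS
        rng = np.random.default_rng(1)
        # one dominant contrast per gene with decreasing effect and equal p
        logfc = pd.DataFrame(0.0, index=genes, columns=cols)
        raw_p = pd.DataFrame(0.5, index=genes, columns=cols)
        effects = np.linspace(5, 0.5, 10)
        for i, g in enumerate(genes):
            logfc.loc[g, "A:8-24"] = effects[i]
            raw_p.loc[g, "A:8-24"] = 1e-6  # same precision for all
        calls = raw_p < 1e-3
        res = make_stagewise(calls, logfc)
        res.raw_p = raw_p
        top, _ = top_genes(res, n=10, ranking="confect")
        assert list(top) == genes  # ordering follows the lower CI bound

    def test_truncation_warns(self, small_results):
        sal_res, _ = small_results
        with pytest.warns(UserWarning, match="truncating"):
            top, _ = top_genes(sal_res, n=10**6)
        assert len(top) == len(sal_res.gene_ids)


class TestPartitionPerContrast:
    def test_restricting_to_one_pair(self):
        genes = ["gA", "gB"]
        calls = np.zeros((2, len(SAL_COLS)), bool)
        calls[0, SAL_COLS.index("A:8-24")] = True      # in 8-24 only
        calls[1, SAL_COLS.index("A:8-16")] = True      # in 8-16 only
        res = sal_result(calls, np.ones((2, len(SAL_COLS))), genes)
        part = unique_de_partition(res, salinity_pair="8-24")
        assert list(part.unique_strain["A"]) == ["gA"]
        assert part.sizes()["unique_strain"] == 1
        assert sum(part.sizes().values()) == 1  # gB invisible in this pair

    def test_unknown_pair_rejected(self):
        genes = ["g"]
        calls = np.zeros((1, len(SAL_COLS)), bool)
        res = sal_result(calls, np.ones((1, len(SAL_COLS))), genes)
        with pytest.raises(ValueError, match="salinity pair"):
            unique_de_partition(res, salinity_pair="1-2")
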
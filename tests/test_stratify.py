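"""Clustering, co-occurrence testing, the step-wise classifier and crosstabs."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from enoc_strat.io_model import (
    GeneMutationMatrix,
    MmrStatus,
    MutatorClass,
    SampleProfile,
)
from enoc_strat.stratify import (
    PristineSubtype,
    association_test,
    build_mutation_matrix,
    classify_pristine,
    cluster_samples,
    cohort_crosstab,
    pairwise_scan,
)
from enoc_strat.stratify import test_cooccurrence as cooccurrence_test


def _profile(sid, genes):
    return SampleProfile(
        sample_id=sid, tmb=len(genes), msi_score=0, spectrum=(0.0,) * 6,
        math_score=None, n_vaf_peaks=None, mutated_genes=frozenset(genes),
        mutator_class=MutatorClass.NORMAL, mmr_status=MmrStatus.WT,
    )


class TestBuildMutationMatrix:
    def test_column_sums_match_frequencies(self):
        profiles = [_profile("s1", {"A", "B"}), _profile("s2", {"A"}), _profile("s3", {"A"})]
        m = build_mutation_matrix(profiles, top_n=2)
        assert m.genes == ["A", "B"]
        assert list(m.values.sum(axis=0)) == [3, 1]

    def test_sample_with_no_mutations_zero_row(self):
        profiles = [_profile("s1", {"A"}), _profile("s2", set())]
        m = build_mutation_matrix(profiles, top_n=1)
        assert list(m.values[1]) == [0]

    def test_ranking_matches_brute_force_tally(self, rng):
        genes = [f"G{i}" for i in range(20)]
        profiles = [
            _profile(f"s{j}", {g for g in genes if rng.random() < 0.3})
            for j in range(30)
        ]
        m = build_mutation_matrix(profiles, top_n=10)
        tally = {
            g: sum(g in p.mutated_genes for p in profiles) for g in genes
        }
        expected = sorted(
            [g for g in genes if tally[g] > 0], key=lambda g: (-tally[g], g)
        )[:10]
        assert m.genes == expected

    def test_top_n_capped_with_warning(self):
        profiles = [_profile("s1", {"A"})]
        m = build_mutation_matrix(profiles, top_n=50)
        assert m.genes == ["A"]


class TestClusterSamples:
    def _planted(self, rng, n_per_block=10, n_genes=8):
        rows, names = [], []
        for block in (0, 1):
            for i in range(n_per_block):
                row = np.zeros(2 * n_genes, dtype=int)
                sl = slice(block * n_genes, (block + 1) * n_genes)
                row[sl] = rng.random(n_genes) < 0.7
                if row.sum() == 0:
                    row[block * n_genes] = 1
                rows.append(row)
                names.append(f"b{block}_{i}")
        genes = [f"G{i}" for i in range(2 * n_genes)]
        return GeneMutationMatrix(samples=names, genes=genes, values=np.array(rows))

    def test_disjoint_blocks_separate_exactly_at_k2(self, rng):
        m = self._planted(rng)
        res = cluster_samples(m)
        labels = res.labels[2]
        block = np.array([s.startswith("b1") for s in m.samples])
        assert len(set(labels)) == 2
        # labels agree with the planted partition (up to label swap)
        agree = (labels == labels[0]) == ~block
        assert agree.all() or (~agree).all()

    def test_duplicate_samples_merge_at_height_zero(self):
        vals = np.array([[1, 0, 1], [1, 0, 1], [0, 1, 0], [0, 1, 1]])
        m = GeneMutationMatrix(
            samples=["a", "b", "c", "d"], genes=["g1", "g2", "g3"], values=vals
        )
        res = cluster_samples(m)
        assert res.linkage[0, 2] == pytest.approx(0.0)
        assert set(res.linkage[0, :2].astype(int)) == {0, 1}

    def test_deterministic(self, rng):
        m = self._planted(rng)
        a, b = cluster_samples(m), cluster_samples(m)
        assert np.array_equal(a.linkage, b.linkage)
        assert np.array_equal(a.labels[3], b.labels[3])

    def test_zero_variance_row_handled(self):
        vals = np.array([[0, 0, 0], [1, 0, 1], [0, 1, 0], [1, 1, 0]])
        m = GeneMutationMatrix(
            samples=list("abcd"), genes=["g1", "g2", "g3"], values=vals
        )
        res = cluster_samples(m)
        assert np.isfinite(res.correlation).all()
        assert res.correlation[0, 0] == 1.0
        assert res.correlation[0, 1] == 0.0

    def test_newick_contains_all_samples(self, rng):
        m = self._planted(rng, n_per_block=4)
        nwk = cluster_samples(m).newick()
        assert nwk.endswith(";")
        for s in m.samples:
            assert s in nwk


class TestAssociation:
    def test_fisher_on_sparse_table(self):
        res = association_test([[5, 2], [15, 90]])
        assert res.test_used == "fisher"
        assert res.p_value == pytest.approx(0.00189, abs=5e-4)
        assert res.direction == "co-occurring"

    def test_degenerate_margin(self):
        res = association_test([[0, 0], [10, 20]])
        assert res.p_value == 1.0 and res.odds_ratio is None
        assert res.test_used == "degenerate"

    def test_symmetric_in_gene_order(self, rng):
        n = 60
        values = (rng.random((n, 2)) < 0.3).astype(int)
        m = GeneMutationMatrix(
            samples=[f"s{i}" for i in range(n)], genes=["A", "B"], values=values
        )
        ab = cooccurrence_test(m, "A", "B")
        ba = cooccurrence_test(m, "B", "A")
        # swapping genes transposes the table: p identical, OR = ad/bc unchanged
        assert ab.p_value == pytest.approx(ba.p_value)
        if ab.odds_ratio is not None and ba.odds_ratio is not None:
            assert ab.odds_ratio == pytest.approx(ba.odds_ratio, rel=1e-6)

    def test_type_i_error_near_nominal_under_null(self, rng):
        """Independent genes: rejection rate at alpha=0.05 is ~5%."""
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            a = rng.random(50) < 0.4
            b = rng.random(50) < 0.4
            table = [
                [int((a & b).sum()), int((a & ~b).sum())],
                [int((~a & b).sum()), int((~a & ~b).sum())],
            ]
            if association_test(table).p_value < 0.05:
                rejections += 1
        assert rejections / n_rep < 0.09  # Fisher is conservative; chi2 ~ nominal

    def test_pairwise_scan_bonferroni(self, rng):
        values = (rng.random((40, 4)) < 0.3).astype(int)
        m = GeneMutationMatrix(
            samples=[f"s{i}" for i in range(40)],
            genes=list("ABCD"), values=values,
        )
        scan = pairwise_scan(m)
        assert len(scan) == 6
        assert (scan["p_bonferroni"] >= scan["p_value"]).all()
        assert (scan["p_bonferroni"] <= 1.0).all()


class TestClassifyPristine:
    @pytest.mark.parametrize(
        "tp53,ctnnb1,math,thr,expected",
        [
            (True, True, None, None, PristineSubtype.TP53M),
            (True, False, None, None, PristineSubtype.TP53M),
            (False, True, None, None, PristineSubtype.TP53WT_CTNNB1M),
            (False, False, 30.0, 30.0, PristineSubtype.LOW_COMPLEXITY),
            (False, False, 25.0, 30.0, PristineSubtype.LOW_COMPLEXITY),
            (False, False, 30.1, 30.0, PristineSubtype.HIGH_COMPLEXITY),
            (False, False, None, 30.0, PristineSubtype.UNRESOLVED),
            (False, False, 30.0, None, PristineSubtype.UNRESOLVED),
        ],
    )
    def test_rule_table(self, tp53, ctnnb1, math, thr, expected):
        assert classify_pristine(tp53, ctnnb1, math, thr).subtype is expected

    def test_total_partition(self):
        """Every input combination yields exactly one subtype."""
        for tp53 in (True, False):
            for ctnnb1 in (True, False):
                for math in (None, 10.0, 50.0):
                    call = classify_pristine(tp53, ctnnb1, math, 30.0)
                    assert isinstance(call.subtype, PristineSubtype)
                    assert call.rules_fired

    def test_tp53_count_independent_of_ctnnb1(self):
        with_c = classify_pristine(True, True).subtype
        without_c = classify_pristine(True, False).subtype
        assert with_c is without_c is PristineSubtype.TP53M


class TestCohortCrosstab:
    def test_missing_excluded_from_denominators(self):
        df = pd.DataFrame(
            {
                "group": ["A"] * 4 + ["B"] * 4,
                "stage": ["III_IV", "I_II", "missing", "III_IV",
                          "I_II", "I_II", "I_II", "missing"],
            }
        )
        ct = cohort_crosstab(df, "group", "stage")
        assert ct.n_evaluable == 6
        count, pct = ct.cell("A", "III_IV")
        assert (count, pct) == (2, 66.7)

    def test_percentages_equal_brute_force(self, rng):
        df = pd.DataFrame(
            {
                "g": rng.choice(["x", "y"], 200),
                "v": rng.choice(["p", "q", "r"], 200),
            }
        )
        ct = cohort_crosstab(df, "g", "v")
        for g in ("x", "y"):
            total = (df["g"] == g).sum()
            for v in ("p", "q", "r"):
                n = ((df["g"] == g) & (df["v"] == v)).sum()
                assert ct.cell(g, v) == (n, round(100 * n / total, 1))

    def test_all_missing_errors(self):
        df = pd.DataFrame({"a": ["missing", "missing"], "b": ["x", "y"]})
        with pytest.raises(ValueError):
            cohort_crosstab(df, "a", "b")
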
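"""Mutation-profile clustering, co-occurrence testing and PRISTINE subtyping.

Samples are clustered on their profiles of pairwise product-moment
correlation computed from the binary mutation matrix (Euclidean distance,
Ward linkage).  Pairwise gene co-occurrence / mutual exclusivity is tested
with Fisher's exact test or the chi-square test as appropriate, with
Bonferroni adjustment available for scans.  The PRISTINE classifier
assigns each tumour a step-wise molecular subtype: TP53-mutant first;
otherwise CTNNB1-mutant; otherwise split by genomic complexity (MATH score
at or below the cohort's single-VAF-peak median is low complexity).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .io_model import GeneMutationMatrix, SampleProfile

logger = logging.getLogger(__name__)

__all__ = [
    "PristineSubtype",
    "PristineCall",
    "ClusterResult",
    "AssociationResult",
    "CrossTab",
    "build_mutation_matrix",
    "cluster_samples",
    "association_test",
    "test_cooccurrence",
    "pairwise_scan",
    "classify_pristine",
    "cohort_crosstab",
]


class PristineSubtype(str, enum.Enum):
    TP53M = "TP53m"
    TP53WT_CTNNB1M = "TP53wt_CTNNB1m"
    LOW_COMPLEXITY = "TP53wt_CTNNB1wt_low_complexity"
    HIGH_COMPLEXITY = "TP53wt_CTNNB1wt_high_complexity"
    UNRESOLVED = "TP53wt_CTNNB1wt_unresolved"


@dataclass(frozen=True)
class PristineCall:
    """Step-wise subtype label with the rules that fired, in order."""

    sample_id: str
    subtype: PristineSubtype
    rules_fired: tuple[str, ...]


def classify_pristine(
    tp53_mut: bool,
    ctnnb1_mut: bool,
    math: float | None = None,
    threshold: float | None = None,
    sample_id: str = "",
) -> PristineCall:
    """Assign the step-wise molecular subtype.

    Rule order: (1) TP53-mutant wins regardless of CTNNB1 status (the rare
    co-mutant is grouped with TP53m); (2) else CTNNB1-mutant; (3) else,
    when both a MATH score and a threshold are available, MATH <= threshold
    is low complexity and MATH > threshold high complexity; (4) else
    unresolved.  Total: every input receives exactly one subtype.
    """
    rules = []
    rules.append("tp53_checked")
    if tp53_mut:
        rules.append("tp53_mutant")
        return PristineCall(sample_id, PristineSubtype.TP53M, tuple(rules))
    rules.append("ctnnb1_checked")
    if ctnnb1_mut:
        rules.append("ctnnb1_mutant")
        return PristineCall(sample_id, PristineSubtype.TP53WT_CTNNB1M, tuple(rules))
    if math is not None and threshold is not None:
        if math <= threshold:
            rules.append("math_le_threshold")
            return PristineCall(sample_id, PristineSubtype.LOW_COMPLEXITY, tuple(rules))
        rules.append("math_gt_threshold")
        return PristineCall(sample_id, PristineSubtype.HIGH_COMPLEXITY, tuple(rules))
    rules.append("complexity_unavailable")
    return PristineCall(sample_id, PristineSubtype.UNRESOLVED, tuple(rules))


# ---------------------------------------------------------------------------
# Binary matrix construction and clustering


def build_mutation_matrix(
    profiles: list[SampleProfile], top_n: int = 50
) -> GeneMutationMatrix:
    """Binary matrix over the ``top_n`` most frequently mutated genes.

    Genes are ranked by cohort mutation frequency, ties broken
    alphabetically.  When fewer than ``top_n`` distinct genes are mutated,
    all are used with a warning.
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    freq: dict[str, int] = {}
    for p in profiles:
        for g in p.mutated_genes:
            freq[g] = freq.get(g, 0) + 1
    ranked = sorted(freq, key=lambda g: (-freq[g], g))
    if top_n > len(ranked):
        logger.warning(
            "top_n=%d exceeds the %d distinct mutated genes; using all",
            top_n, len(ranked),
        )
    genes = ranked[:top_n]
    samples = [p.sample_id for p in profiles]
    values = np.array(
        [[1 if g in p.mutated_genes else 0 for g in genes] for p in profiles],
        dtype=int,
    )
    return GeneMutationMatrix(samples=samples, genes=genes, values=values)


@dataclass
class ClusterResult:
    """Hierarchical clustering output: linkage plus labels at k = 2 and 3."""

    samples: list[str]
    linkage: np.ndarray
    correlation: np.ndarray
    labels: dict[int, np.ndarray]  # k -> cluster labels (1-based)

    def newick(self) -> str:
        """Dendrogram as a Newick string (leaf = sample id, branch lengths)."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.samples[node.id]
            ld = max(node.dist - node.left.dist, 0.0)
            rd = max(node.dist - node.right.dist, 0.0)
            return f"({walk(node.left)}:{ld:.6g},{walk(node.right)}:{rd:.6g})"

        return walk(tree) + ";"


def _binary_correlation(values: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation between sample rows.

    Zero-variance rows (all-0 or all-1 mutation vectors) have undefined
    correlation; they are assigned correlation 0 with every other sample
    (and 1 with themselves) with a warning.
    """
    x = values.astype(float)
    sd = x.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "%d sample(s) have zero-variance mutation vectors; "
            "their correlations are set to 0", int(degenerate.sum()),
        )
    corr = np.zeros((x.shape[0], x.shape[0]))
    ok = ~degenerate
    if ok.sum() >= 2:
        corr[np.ix_(ok, ok)] = np.corrcoef(x[ok])
    elif ok.sum() == 1:
        corr[np.ix_(ok, ok)] = 1.0
    np.fill_diagonal(corr, 1.0)
    return corr


def cluster_samples(
    matrix: GeneMutationMatrix, on_correlation: bool = True
) -> ClusterResult:
    """Hierarchically cluster samples by mutation-profile correlation.

    Step 1: the n x n product-moment correlation matrix between sample
    binary vectors.  Step 2: each sample's feature vector is its row of
    that correlation matrix; agglomerative clustering with Euclidean
    distance and Ward linkage.  ``on_correlation=False`` clusters the raw
    binary matrix directly instead.  Deterministic; labels are reported
    for k = 2 and k = 3.
    """
    n = len(matrix.samples)
    if n < 3:
        raise ValueError("clustering requires at least 3 samples")
    corr = _binary_correlation(matrix.values)
    features = corr if on_correlation else matrix.values.astype(float)
    linkage = hierarchy.linkage(features, method="ward", metric="euclidean")
    labels = {
        k: hierarchy.fcluster(linkage, t=k, criterion="maxclust")
        for k in (2, 3)
    }
    return ClusterResult(
        samples=list(matrix.samples), linkage=linkage,
        correlation=corr, labels=labels,
    )


# ---------------------------------------------------------------------------
# Co-occurrence / exclusivity testing


@dataclass
class AssociationResult:
    """2x2 association test between two genes' mutation status."""

    table: np.ndarray  # [[both, a_only], [b_only, neither]]
    odds_ratio: float | None
    p_value: float
    fisher_p: float
    direction: str  # "co-occurring" | "exclusive" | "undefined"
    test_used: str  # "fisher" | "chi2" | "degenerate"
    p_bonferroni: float | None = None


def association_test(table) -> AssociationResult:
    """Two-sided association test on a 2x2 contingency table.

    Fisher's exact test when any expected cell count is below 5, otherwise
    the chi-square test (the Fisher p-value is always reported alongside).
    Degenerate margins (an all-zero row or column) yield p = 1 with the
    odds ratio flagged undefined.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be a non-negative 2x2 matrix")
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        return AssociationResult(
            table=t.astype(int), odds_ratio=None, p_value=1.0, fisher_p=1.0,
            direction="undefined", test_used="degenerate",
        )
    odds, fisher_p = stats.fisher_exact(t, alternative="two-sided")
    expected = np.outer(rows, cols) / t.sum()
    if (expected < 5).any():
        p, used = float(fisher_p), "fisher"
    else:
        p = float(stats.chi2_contingency(t, correction=False).pvalue)
        used = "chi2"
    direction = "co-occurring" if odds > 1 else "exclusive"
    return AssociationResult(
        table=t.astype(int),
        odds_ratio=float(odds) if np.isfinite(odds) else None,
        p_value=p, fisher_p=float(fisher_p),
        direction=direction, test_used=used,
    )


def test_cooccurrence(
    matrix: GeneMutationMatrix, gene_a: str, gene_b: str
) -> AssociationResult:
    """Test mutual exclusivity / co-occurrence of two genes in the cohort."""
    a = matrix.column(gene_a).astype(bool)
    b = matrix.column(gene_b).astype(bool)
    table = [
        [int((a & b).sum()), int((a & ~b).sum())],
        [int((~a & b).sum()), int((~a & ~b).sum())],
    ]
    return association_test(table)


def pairwise_scan(
    matrix: GeneMutationMatrix, genes: list[str] | None = None
) -> pd.DataFrame:
    """All-pairs co-occurrence scan with Bonferroni adjustment.

    The Bonferroni family is the number of gene pairs tested.
    """
    genes = genes if genes is not None else list(matrix.genes)
    rows = []
    pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1:]]
    family = len(pairs)
    for a, b in pairs:
        res = test_cooccurrence(matrix, a, b)
        rows.append(
            {
                "gene_a": a, "gene_b": b,
                "odds_ratio": res.odds_ratio,
                "p_value": res.p_value,
                "p_bonferroni": min(res.p_value * family, 1.0),
                "direction": res.direction,
                "test_used": res.test_used,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cross-tabulation


@dataclass
class CrossTab:
    """Contingency table with row-wise percentages over evaluable cases."""

    counts: pd.DataFrame
    percent: pd.DataFrame  # row percentages, 1 d.p., over evaluable cases
    n_evaluable: int

    def cell(self, row, col) -> tuple[int, float]:
        """(count, percentage of the row's evaluable cases) for one cell."""
        return int(self.counts.loc[row, col]), float(self.percent.loc[row, col])


_MISSING_TOKENS = {"missing", "", "nan", "none"}


def cohort_crosstab(
    data: pd.DataFrame, row_var: str, col_var: str
) -> CrossTab:
    """Cross-tabulate two categorical variables over evaluable cases.

    Rows with a missing value in either variable are excluded from the
    denominators, reproducing the "x of n evaluable cases" convention.
    Percentages are row-wise at 1 decimal place.
    """
    sub = data[[row_var, col_var]].astype(object).copy()
    for c in (row_var, col_var):
        col = sub[c].astype(str).str.strip().str.lower()
        sub.loc[col.isin(_MISSING_TOKENS) | sub[c].isna(), c] = np.nan
    sub = sub.dropna()
    if sub.empty:
        raise ValueError(
            f"no evaluable cases for {row_var} x {col_var} "
            "(all values missing)"
        )
    counts = pd.crosstab(sub[row_var], sub[col_var])
    percent = (counts.div(counts.sum(axis=1), axis=0) * 100).round(1)
    return CrossTab(counts=counts, percent=percent, n_evaluable=len(sub))
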
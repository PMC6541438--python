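"""Genotype-group statistics and presentation-layer orderings.

Allelic-ratio comparisons between genotype groups use Welch's
two-sample t-test (unequal variances and group sizes); imaging / FISH
proportion and normalized-expression comparisons use the two-tailed
Student's t-test.  Both are two-tailed throughout.  Heat-map rows are
ordered by allelic expression in a reference genotype group.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    statistic: float
    degrees_of_freedom: float
    p_value: float
    test_name: str
    group_labels: tuple = ("a", "b")


def _check_groups(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("groups must contain finite values")
    return a, b


def _ttest(a, b, equal_var: bool, name: str, labels) -> TestResult:
    a, b = _check_groups(a, b)
    # degenerate zero-variance case: identical constant groups carry no
    # evidence of a difference
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        df = a.size + b.size - 2 if equal_var else float(a.size + b.size - 2)
        return TestResult(0.0, float(df), 1.0, name, tuple(labels))
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return TestResult(
        float(res.statistic), float(res.df), float(res.pvalue), name, tuple(labels)
    )


def welch_test(a, b, labels=("a", "b")) -> TestResult:
    """Welch's two-sample two-tailed t-test (Welch–Satterthwaite df)."""
    return _ttest(a, b, equal_var=False, name="welch_two_sample", labels=labels)


def student_test_two_tailed(a, b, labels=("a", "b")) -> TestResult:
    """Two-tailed Student's t-test with pooled variance, df = n_a + n_b - 2."""
    return _ttest(a, b, equal_var=True, name="student_two_tailed", labels=labels)


def embryo_mean_paternal(gene_table: pd.DataFrame, gene_subset) -> float:
    """Per-embryo summary: unweighted mean paternal % over a gene subset.

    ``gene_table`` is a ``quantify_embryo`` DataFrame; ``gene_subset``
    is typically the informative-in-all-samples X-linked gene list.
    """
    genes = list(gene_subset)
    if not genes:
        raise ValueError("gene subset is empty")
    vals = gene_table.loc[genes, "mean_paternal_pct"]
    if vals.isna().any():
        missing = vals.index[vals.isna()].tolist()
        raise ValueError(f"genes without allelic ratio in this sample: {missing}")
    return float(vals.mean())


def pairwise_tests(groups: dict, method: str = "welch",
                   bonferroni: bool = True) -> pd.DataFrame:
    """All pairwise group comparisons as a tidy table.

    ``groups`` maps genotype label to per-embryo values.  The raw
    two-tailed p-values mirror the study's supplementary comparison
    tables; a Bonferroni-adjusted column is appended as an extra
    convenience (not part of the original analysis) unless disabled.
    """
    test = welch_test if method == "welch" else student_test_two_tailed
    rows = []
    pairs = list(combinations(groups.keys(), 2))
    for ga, gb in pairs:
        r = test(groups[ga], groups[gb], labels=(ga, gb))
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "mean_a": float(np.mean(groups[ga])),
                "mean_b": float(np.mean(groups[gb])),
                "test": r.test_name,
                "statistic": r.statistic,
                "df": r.degrees_of_freedom,
                "p_value": r.p_value,
            }
        )
    out = pd.DataFrame(rows)
    if bonferroni and not out.empty:
        out["p_bonferroni"] = np.minimum(out["p_value"] * len(pairs), 1.0)
    return out


def order_genes_by_reference_group(matrix: pd.DataFrame, sample_groups: dict,
                                   reference_label: str) -> list:
    """Heat-map row order: genes sorted by reference-group allelic ratio.

    ``matrix`` is genes x samples of mean paternal %, ``sample_groups``
    maps sample id to genotype label.  Genes are sorted ascending by the
    mean over the reference group's samples, ties broken by gene id, so
    the order is deterministic and invariant to input row order.
    """
    ref_samples = [s for s in matrix.columns if sample_groups.get(s) == reference_label]
    if not ref_samples:
        raise ValueError(f"no samples with reference group {reference_label!r}")
    ref_mean = matrix[ref_samples].mean(axis=1)
    key = sorted(matrix.index, key=lambda g: (ref_mean.loc[g], g))
    return key
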
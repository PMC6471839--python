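"""Cross-method and cross-subject abundance comparisons.

Proteomic genus profiles (spectral counts) are compared with 16S read
counts over a shared taxon x subject grid; subjects are compared with each
other by Pearson correlation of their metacluster spectral-count vectors.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import CorrelationResult


def merge_family(matrix: pd.DataFrame, family_name: str,
                 member_genera: Sequence[str]) -> pd.DataFrame:
    """Collapse several genus rows into a single family row.

    Member genera absent from the matrix count as zero; the family row is
    the element-wise sum and replaces the member rows. Raises when
    ``family_name`` collides with an existing row that is not itself a
    member (the merge would silently absorb unrelated counts).
    """
    if family_name in matrix.index and family_name not in member_genera:
        raise ValueError(
            f"row {family_name!r} already exists and is not a member")
    present = [g for g in member_genera if g in matrix.index]
    family_row = (matrix.loc[present].sum(axis=0) if present
                  else pd.Series(0, index=matrix.columns))
    out = matrix.drop(index=present)
    out.loc[family_name] = family_row
    return out.sort_index()


def cross_method_correlation(proteomics: pd.DataFrame,
                             sixteen_s: pd.DataFrame,
                             taxa: Optional[Sequence[str]] = None
                             ) -> CorrelationResult:
    """Spearman and Pearson agreement between two taxon x subject tables.

    Rows are aligned on the union of taxa (or an explicit ``taxa`` list),
    filling zeros where one method misses a taxon; both matrices must
    share subject columns. The aligned cells are flattened into paired
    vectors; rank ties take average ranks (scipy default).
    """
    subjects = list(proteomics.columns)
    if list(sixteen_s.columns) != subjects:
        common = [s for s in subjects if s in sixteen_s.columns]
        if len(common) != len(subjects) or not common:
            raise ValueError("matrices must share subject columns")
        sixteen_s = sixteen_s[common]
    if taxa is None:
        taxa = sorted(set(proteomics.index) | set(sixteen_s.index))
    a = proteomics.reindex(taxa).fillna(0).to_numpy(dtype=float).ravel()
    b = sixteen_s.reindex(taxa).fillna(0).to_numpy(dtype=float).ravel()
    if a.size < 3:
        raise ValueError("need at least 3 paired cells")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant input: correlation undefined")
    rho = stats.spearmanr(a, b).statistic
    r = stats.pearsonr(a, b).statistic
    return CorrelationResult(pair=("proteomics", "16S"),
                             spearman_rho=float(rho), pearson_r=float(r),
                             r_squared=float(r) ** 2, n=int(a.size))


def pairwise_metacluster_correlation(counts: pd.DataFrame,
                                     subject_a: str, subject_b: str
                                     ) -> CorrelationResult:
    """Pearson correlation of two subjects' metacluster count vectors.

    Restricted to metaclusters detected in at least one of the two
    subjects (union support); fewer than 3 such features is an error.
    """
    for s in (subject_a, subject_b):
        if s not in counts.columns:
            raise ValueError(f"subject {s!r} not in count matrix")
    a = counts[subject_a].to_numpy(dtype=float)
    b = counts[subject_b].to_numpy(dtype=float)
    support = (a > 0) | (b > 0)
    if support.sum() < 3:
        raise ValueError("fewer than 3 metaclusters in union support")
    a, b = a[support], b[support]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant counts: correlation undefined")
    r = stats.pearsonr(a, b).statistic
    rho = stats.spearmanr(a, b).statistic
    return CorrelationResult(pair=(subject_a, subject_b),
                             spearman_rho=float(rho), pearson_r=float(r),
                             r_squared=float(r) ** 2, n=int(support.sum()))


def all_pairwise_correlations(counts: pd.DataFrame) -> pd.DataFrame:
    """Pearson r/r^2 for every unordered subject pair."""
    subjects = list(counts.columns)
    rows = []
    for i, a in enumerate(subjects):
        for b in subjects[i + 1:]:
            res = pairwise_metacluster_correlation(counts, a, b)
            rows.append((a, b, res.pearson_r, res.r_squared,
                         res.spearman_rho, res.n))
    return pd.DataFrame(rows, columns=["subject_a", "subject_b",
                                       "pearson_r", "r_squared",
                                       "spearman_rho", "n"])


def heatmap_matrix(matrix: pd.DataFrame, top_k: int
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Order features for a heat-map display and bin values into tertiles.

    Keeps the ``top_k`` features by total count, aggregates the remainder
    into an ``unknown/others`` row, and labels each positive cell low /
    medium / high by tertiles computed over the positive cells; zero
    cells stay unlabelled. Returns (ordered matrix, label matrix).
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    order = matrix.sum(axis=1).sort_values(ascending=False).index
    top = list(order[:top_k])
    rest = list(order[top_k:])
    out = matrix.loc[top].copy()
    out.loc["unknown/others"] = (matrix.loc[rest].sum(axis=0) if rest
                                 else 0)
    values = out.to_numpy(dtype=float)
    positive = values[values > 0]
    labels = pd.DataFrame("", index=out.index, columns=out.columns)
    if positive.size:
        lo, hi = np.quantile(positive, [1 / 3, 2 / 3])
        for i in range(out.shape[0]):
            for j in range(out.shape[1]):
                v = values[i, j]
                if v <= 0:
                    continue
                labels.iat[i, j] = ("low" if v <= lo
                                    else "medium" if v <= hi else "high")
    return out, labels
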
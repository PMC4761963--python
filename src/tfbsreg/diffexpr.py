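"""Up-regulated gene calling, DUG partitioning, and set statistics.

Genes are called up-regulated against control with a fold-change and FDR
double threshold (>2 FC, q < 0.05 by default). Fold change uses a
pseudocount on FPKM-scale condition means, the per-gene test is Welch's t
on log2(x+1) replicate values, and multiplicity is handled with
Benjamini-Hochberg. Differentially up-regulated genes (DUGs) are the
up-regulated genes additionally >2-fold different between the two
treatment conditions, assigned to whichever condition is the higher.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "DEResult",
    "GenePartition",
    "call_upregulated",
    "detect_expressed",
    "partition_upregulated",
    "overlap_test",
    "correlate",
    "enrich_categories",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance table plus a sample -> condition design.

    ``values``: nonnegative FPKM-like abundances, one row per gene.
    ``design``: sample id -> (condition, replicate index). Every condition
    must carry at least two replicates.
    """

    values: pd.DataFrame
    design: Mapping[str, tuple[str, int]]

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if (self.values.values < 0).any():
            raise ValueError("expression values must be nonnegative")
        missing = set(self.values.columns) - set(self.design)
        if missing:
            raise ValueError(f"samples without design entry: {sorted(missing)}")
        counts: dict[str, int] = {}
        for s in self.values.columns:
            cond, _ = self.design[s]
            counts[cond] = counts.get(cond, 0) + 1
        thin = [c for c, n in counts.items() if n < 2]
        if thin:
            raise ValueError(f"conditions with <2 replicates: {thin}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.design[s][0])
        return list(seen)

    def samples_of(self, condition: str) -> list[str]:
        out = [s for s in self.values.columns if self.design[s][0] == condition]
        if not out:
            raise KeyError(f"unknown condition {condition!r}")
        return out

    def condition_means(self) -> pd.DataFrame:
        """Per-gene mean abundance per condition."""
        return pd.DataFrame(
            {c: self.values[self.samples_of(c)].mean(axis=1) for c in self.conditions}
        )

    def to_tsv(self, path: str) -> None:
        """Write tab-delimited with columns named <condition>_<replicate>."""
        out = self.values.copy()
        out.columns = [f"{self.design[s][0]}_{self.design[s][1]}" for s in out.columns]
        out.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str) -> "ExpressionMatrix":
        """Read the tab-delimited format; design parsed from column names."""
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        design = {}
        for col in df.columns:
            cond, _, rep = col.rpartition("_")
            if not cond or not rep.isdigit():
                raise ValueError(
                    f"sample column {col!r} not of the form <condition>_<replicate>"
                )
            design[col] = (cond, int(rep))
        return cls(df, design)


@dataclass
class DEResult:
    """Per-gene differential-expression summary vs control."""

    table: pd.DataFrame  # mean_control, mean_treated, fc, p, q, up_regulated
    control: str
    treated: str
    fc_threshold: float
    fdr_threshold: float

    @property
    def upregulated(self) -> set[str]:
        return set(self.table.index[self.table["up_regulated"]])

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class GenePartition:
    """Fig-style partition of up-regulated genes across two treatments."""

    shared: set[str]
    unique_to_A: set[str]
    unique_to_B: set[str]
    dug_A: set[str]
    dug_B: set[str]

    @property
    def all_upregulated(self) -> set[str]:
        return self.shared | self.unique_to_A | self.unique_to_B

    @property
    def dugs(self) -> set[str]:
        return self.dug_A | self.dug_B

    def counts(self) -> dict[str, int]:
        return {
            "shared": len(self.shared),
            "unique_to_A": len(self.unique_to_A),
            "unique_to_B": len(self.unique_to_B),
            "total_upregulated": len(self.all_upregulated),
            "dug_A": len(self.dug_A),
            "dug_B": len(self.dug_B),
            "dug_total": len(self.dugs),
        }


def _log2p1(x: np.ndarray) -> np.ndarray:
    return np.log2(np.asarray(x, dtype=float) + 1.0)


def mean_log2_response(expr: ExpressionMatrix, condition: str) -> pd.Series:
    """Per-gene mean log2(x+1) over a condition's replicates.

    This is the response variable of the promoter regression model.
    """
    cols = expr.samples_of(condition)
    return pd.Series(
        _log2p1(expr.values[cols].to_numpy(float)).mean(axis=1),
        index=expr.values.index,
        name=condition,
    )


def call_upregulated(
    expr: ExpressionMatrix,
    control: str,
    treated: str,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    epsilon: float = 1.0,
) -> DEResult:
    """Call genes up-regulated in ``treated`` vs ``control``.

    FC = (mean_treated + eps) / (mean_control + eps); Welch's t-test on
    log2(x+1) replicate values; BH q-values over all tested genes. A gene
    is up-regulated iff FC > fc_threshold and q < fdr_threshold. Genes
    with zero variance in both groups get p = 1 by convention.
    """
    ctrl = expr.values[expr.samples_of(control)].to_numpy(float)
    trt = expr.values[expr.samples_of(treated)].to_numpy(float)
    mean_c, mean_t = ctrl.mean(axis=1), trt.mean(axis=1)
    fc = (mean_t + epsilon) / (mean_c + epsilon)

    lc, lt = _log2p1(ctrl), _log2p1(trt)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(lt, lc, axis=1, equal_var=False)
    flat = (lc.std(axis=1) == 0) & (lt.std(axis=1) == 0)
    if flat.any():
        logger.info("%d gene(s) with zero variance in both groups: p set to 1",
                    int(flat.sum()))
    p = np.where(flat | ~np.isfinite(p), 1.0, p)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    up = (fc > fc_threshold) & (q < fdr_threshold)

    table = pd.DataFrame(
        {
            "mean_control": mean_c,
            "mean_treated": mean_t,
            "fc": fc,
            "p": p,
            "q": q,
            "up_regulated": up,
        },
        index=expr.values.index,
    )
    return DEResult(table, control, treated, fc_threshold, fdr_threshold)


def detect_expressed(expr: ExpressionMatrix, min_abundance: float = 1.0) -> set[str]:
    """Genes whose mean abundance exceeds the floor in >=1 condition."""
    means = expr.condition_means()
    keep = (means > min_abundance).any(axis=1)
    return set(means.index[keep])


def partition_upregulated(
    deA: DEResult,
    deB: DEResult,
    dug_fc_threshold: float = 2.0,
    epsilon: float = 1.0,
) -> GenePartition:
    """Partition up-regulated genes into shared/unique sets and call DUGs.

    DUGs are up-regulated genes whose condition-mean ratio between the
    two treatments exceeds ``dug_fc_threshold``; the gene must be
    up-regulated vs control in the favored condition.
    """
    if not deA.table.index.equals(deB.table.index):
        raise ValueError("DE results cover different gene universes")
    upA, upB = deA.upregulated, deB.upregulated
    shared = upA & upB
    uniq_a, uniq_b = upA - upB, upB - upA

    ma = deA.table["mean_treated"]
    mb = deB.table["mean_treated"]
    ab = (ma + epsilon) / (mb + epsilon)
    genes = deA.table.index
    dug_a = set(genes[(ab > dug_fc_threshold)]) & upA
    dug_b = set(genes[(1.0 / ab > dug_fc_threshold)]) & upB
    return GenePartition(shared, uniq_a, uniq_b, dug_a, dug_b)


def overlap_test(
    setA: set[str], setB: set[str], universe: set[str], n_tests: int = 1
) -> tuple[float, float]:
    """Upper-tail hypergeometric probability of the observed overlap.

    Returns (raw p, Bonferroni-adjusted p = min(1, p * n_tests)).
    """
    if not universe:
        raise ValueError("empty universe")
    if not (setA <= universe and setB <= universe):
        raise ValueError("sets must be subsets of the universe")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    n, a, b = len(universe), len(setA), len(setB)
    k = len(setA & setB)
    # P(X >= k) for X ~ Hypergeom(N=n, K=a, draws=b)
    p = float(stats.hypergeom.sf(k - 1, n, a, b))
    p = min(1.0, max(0.0, p))
    return p, min(1.0, p * n_tests)


def correlate(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-d arrays of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def enrich_categories(
    query: set[str],
    universe: set[str],
    categories: Mapping[str, set[str]],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Hypergeometric category enrichment with Bonferroni correction.

    Returns a table with overlap, raw and adjusted p per category, and a
    ``significant`` flag (adjusted p < alpha). An empty query gives p = 1
    everywhere.
    """
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    rows = []
    m = max(1, len(categories))
    for name, members in categories.items():
        if not members <= universe:
            raise ValueError(f"category {name!r} not a subset of the universe")
        k = len(query & members)
        if not query:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(
                k - 1, len(universe), len(members), len(query)
            ))
            p = min(1.0, max(0.0, p))
        adj = min(1.0, p * m)
        rows.append((name, len(members), k, p, adj, adj < alpha))
    return pd.DataFrame(
        rows,
        columns=["category", "size", "overlap", "p", "p_bonferroni", "significant"],
    ).set_index("category")
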
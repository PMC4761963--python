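"""Promoter regression modelling of TFBS importance.

The response (per-gene mean log2 abundance in the modelled condition) is
regressed on TFBS hit-count features. A model search picks the best
feature subset under an information criterion (BIC by default, which
penalizes model size and makes "best combination" well defined);
exhaustive enumeration is used when the subset count fits a budget, with
greedy forward selection as the scalable fallback.

Coefficient uncertainty is captured by repeating the search on B
gene-level bootstrap resamples: each TFBS accrues one regression
coefficient (RC) per replicate, contributing 0 when it is not selected,
so every RC distribution has exactly B entries. Significance of a
distribution is a one-sample two-sided t-test of the B RCs against zero
with a Bonferroni correction over the TFBSs tested (alpha 0.01).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scan import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ModelFit",
    "RCDistribution",
    "TFBSClassification",
    "CollinearityError",
    "BudgetExceededError",
    "fit_linear",
    "search_models",
    "bootstrap_rcs",
    "test_rcs",
    "classify_tfbs",
    "refit_excluding",
]

DEFAULT_BUDGET = 1_000_000
_RSS_FLOOR = 1e-12


class CollinearityError(ValueError):
    """Raised when a design submatrix is rank deficient."""


class BudgetExceededError(ValueError):
    """Raised when exhaustive enumeration would exceed the subset budget."""


@dataclass
class ModelFit:
    """One fitted subset model: selected TFBSs, OLS coefficients, criterion."""

    selected_tfbs: tuple[str, ...]
    coefficients: dict[str, float]  # includes "intercept"
    fit_criterion: float
    n_genes: int


@dataclass
class RCDistribution:
    """The B-member regression-coefficient distribution of one TFBS."""

    tfbs_id: str
    rcs: np.ndarray
    p_bonferroni: float = field(init=False)
    mean_rc: float = field(init=False)
    t_statistic: float = field(init=False)
    p_raw: float = field(init=False)
    selection_frequency: float = field(init=False)
    n_tested: int = 1

    def __post_init__(self) -> None:
        rcs = np.asarray(self.rcs, dtype=float)
        object.__setattr__(self, "rcs", rcs)
        self.mean_rc = float(rcs.mean())
        t, p = _one_sample_t(rcs)
        self.t_statistic = t
        self.p_raw = p
        self.p_bonferroni = min(1.0, p * self.n_tested)
        self.selection_frequency = float(np.mean(rcs != 0.0))


@dataclass
class TFBSClassification:
    """Per-TFBS concordance of significant mean RCs between two conditions."""

    status: dict[str, str]  # identical | opposite | unique_to_A | unique_to_B | not_significant
    sign_A: dict[str, int]
    sign_B: dict[str, int]

    def counts(self) -> dict[str, int]:
        out = {
            "identical": 0,
            "opposite": 0,
            "unique_to_A": 0,
            "unique_to_B": 0,
            "not_significant": 0,
        }
        for s in self.status.values():
            out[s] += 1
        return out


def _one_sample_t(x: np.ndarray) -> tuple[float, float]:
    """Two-sided one-sample t against 0 with degenerate-case conventions.

    Zero variance: nonzero mean -> (inf-signed t, p=0); zero mean -> (0, 1).
    """
    if len(x) < 2:
        raise ValueError("need at least 2 values for a t-test")
    if np.ptp(x) == 0.0:
        if x[0] == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, x[0]), 0.0
    t, p = stats.ttest_1samp(x, 0.0)
    return float(t), float(p)


def _design(features: FeatureMatrix, subset: Sequence[str]):
    if features.response is None:
        raise ValueError("feature matrix has no response vector")
    X = features.values[list(subset)].to_numpy(float)
    y = features.response.to_numpy(float)
    return X, y


def _bic(n: int, rss: float, k: int) -> float:
    return n * math.log(max(rss, _RSS_FLOOR) / n) + k * math.log(n)


def _adj_r2_criterion(n: int, rss: float, k: int, tss: float) -> float:
    # negated so that "lower is better" holds for every criterion
    if n - k <= 0 or tss <= 0:
        return math.inf
    return -(1.0 - (rss / (n - k)) / (tss / (n - 1)))


def _ols(X: np.ndarray, y: np.ndarray):
    """OLS with intercept; returns (beta, rss) or raises on rank loss."""
    n = len(y)
    Z = np.column_stack([np.ones(n), X]) if X.shape[1] else np.ones((n, 1))
    beta, _, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    if rank < Z.shape[1]:
        raise CollinearityError("design submatrix is rank deficient")
    resid = y - Z @ beta
    return beta, float(resid @ resid)


def _criterion(name, n: int, rss: float, k: int, tss: float) -> float:
    """Model-selection criterion, lower is better.

    ``name`` is "bic", "adj_r2", or a float: a generalized information
    criterion n*log(RSS/n) + penalty*k with an explicit per-parameter
    penalty (BIC is the special case penalty = log n).
    """
    if isinstance(name, (int, float)):
        return n * math.log(max(rss, _RSS_FLOOR) / n) + float(name) * k
    if name == "bic":
        return _bic(n, rss, k)
    if name == "adj_r2":
        return _adj_r2_criterion(n, rss, k, tss)
    raise ValueError(f"unknown criterion {name!r}")


def calibrated_penalty(n_tfbs: int, B: int, alpha: float = 0.01) -> float:
    """Per-parameter selection penalty for bootstrap model searches.

    A feature enters a model when its partial t-statistic exceeds
    sqrt(penalty). BIC's threshold (sqrt(log n) ~ 2.4) admits the best
    chance-correlated null feature in a sizeable fraction of replicates;
    because the downstream one-sample t-test over B replicate RCs has
    power growing like sqrt(B * selection frequency), that makes null
    TFBSs wildly anticonservative. This penalty Bonferroni-controls
    false inclusion over the ~n_tfbs * B candidate entry tests of the
    whole resampling scheme at level ``alpha``, so null RC distributions
    stay essentially all-zero.
    """
    z = float(stats.norm.ppf(1.0 - alpha / (2.0 * n_tfbs * B)))
    return z * z


def fit_linear(features: FeatureMatrix, subset: Sequence[str],
               criterion: str = "bic") -> ModelFit:
    """OLS of the response on a TFBS subset's columns plus an intercept."""
    subset = list(subset)
    X, y = _design(features, subset)
    n = len(y)
    if n <= len(subset) + 1:
        raise ValueError(
            f"need more genes ({n}) than parameters ({len(subset) + 1})"
        )
    beta, rss = _ols(X, y)
    tss = float(np.sum((y - y.mean()) ** 2))
    crit = _criterion(criterion, n, rss, len(beta), tss)
    coefs = {"intercept": float(beta[0])}
    coefs.update({t: float(b) for t, b in zip(subset, beta[1:])})
    return ModelFit(tuple(subset), coefs, crit, n)


def _subset_count(p: int, max_size: int) -> int:
    return sum(math.comb(p, k) for k in range(0, max_size + 1))


def _search_exhaustive(X: np.ndarray, y: np.ndarray, max_size: int,
                       criterion: str) -> tuple[tuple[int, ...], np.ndarray]:
    n, p = X.shape
    tss = float(np.sum((y - y.mean()) ** 2))
    best: tuple[int, ...] | None = None
    best_crit = math.inf
    best_beta: np.ndarray | None = None
    # sizes ascending + lexicographic combinations + strict improvement
    # implement the tie-break: smaller subset first, then lexicographic order
    for k in range(0, max_size + 1):
        for subset in combinations(range(p), k):
            try:
                beta, rss = _ols(X[:, subset], y)
            except CollinearityError:
                continue
            crit = _criterion(criterion, n, rss, len(beta), tss)
            if crit < best_crit - 1e-12:
                best, best_crit, best_beta = subset, crit, beta
    if best is None:
        raise CollinearityError("no valid subset model could be fitted")
    return best, best_beta


def _search_forward(X: np.ndarray, y: np.ndarray, max_size: int,
                    criterion: str) -> tuple[tuple[int, ...], np.ndarray]:
    n, p = X.shape
    tss = float(np.sum((y - y.mean()) ** 2))
    selected: list[int] = []
    beta, rss = _ols(X[:, []], y)
    best_crit = _criterion(criterion, n, rss, 1, tss)
    best_beta = beta
    while len(selected) < max_size:
        best_add = None
        for j in range(p):
            if j in selected:
                continue
            cols = selected + [j]
            try:
                beta, rss = _ols(X[:, cols], y)
            except CollinearityError:
                continue
            crit = _criterion(criterion, n, rss, len(beta), tss)
            if crit < best_crit - 1e-12:
                best_crit, best_add, best_beta = crit, j, beta
        if best_add is None:
            break
        selected.append(best_add)
    return tuple(selected), best_beta


def search_models(
    features: FeatureMatrix,
    max_model_size: int = 10,
    mode: str = "exhaustive",
    criterion: str = "bic",
    budget: int = DEFAULT_BUDGET,
) -> ModelFit:
    """Find the best TFBS subset (size <= max_model_size) by the criterion.

    ``mode='exhaustive'`` enumerates every subset (errors if the count
    exceeds ``budget``); ``mode='forward'`` is greedy stepwise selection
    with the same criterion. Ties favor smaller subsets, then the
    lexicographically earlier one in the feature order.
    """
    X, y = _design(features, features.tfbs_ids)
    names = features.tfbs_ids
    if mode == "exhaustive":
        count = _subset_count(len(names), max_model_size)
        if count > budget:
            raise BudgetExceededError(
                f"exhaustive search over {count} subsets exceeds the budget "
                f"of {budget}; use mode='forward'"
            )
        idx, beta = _search_exhaustive(X, y, max_model_size, criterion)
    elif mode == "forward":
        idx, beta = _search_forward(X, y, max_model_size, criterion)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    subset = [names[j] for j in idx]
    return fit_linear(features, subset, criterion=criterion)


def _auto_mode(p: int, max_size: int, budget: int) -> str:
    return "exhaustive" if _subset_count(p, max_size) <= budget else "forward"


def bootstrap_rcs(
    features: FeatureMatrix,
    max_model_size: int = 10,
    B: int = 1000,
    seed: int = 0,
    mode: str = "auto",
    criterion="calibrated",
    budget: int = DEFAULT_BUDGET,
    scheme: str = "bootstrap",
    selection_alpha: float = 0.01,
) -> dict[str, RCDistribution]:
    """Build B-member RC distributions per TFBS.

    ``scheme='bootstrap'`` (default): resample genes with replacement and
    rerun the model search per replicate. ``scheme='subset'``: fit B
    random feature subsets (size <= max_model_size) on the full gene set.
    A TFBS absent from a replicate's model contributes RC 0, so every
    distribution has exactly B entries. Degenerate resamples (constant
    response) are redrawn, up to 10*B attempts in total.

    ``criterion='calibrated'`` (default) uses a generalized information
    criterion whose per-parameter penalty controls false inclusion over
    the whole resampling scheme (see :func:`calibrated_penalty`);
    ``'bic'`` and ``'adj_r2'`` are available for single-search parity.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    X, y = _design(features, features.tfbs_ids)
    names = features.tfbs_ids
    p = len(names)
    if criterion == "calibrated":
        criterion = calibrated_penalty(p, B, selection_alpha)
    if mode == "auto":
        mode = _auto_mode(p, max_model_size, budget)
    elif mode == "exhaustive" and _subset_count(p, max_model_size) > budget:
        raise BudgetExceededError(
            "exhaustive bootstrap exceeds the subset budget; use mode='forward'"
        )
    search = _search_exhaustive if mode == "exhaustive" else _search_forward

    rng = np.random.default_rng(seed)
    n = len(y)
    rcs = np.zeros((B, p))
    redraws = 0
    max_attempts = 10 * B
    attempts = 0
    b = 0
    while b < B:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"exceeded {max_attempts} resampling attempts "
                f"({redraws} degenerate resamples)"
            )
        attempts += 1
        if scheme == "bootstrap":
            idx = rng.integers(0, n, n)
            yb = y[idx]
            if np.ptp(yb) == 0.0:
                redraws += 1
                continue
            sel, beta = search(X[idx], yb, max_model_size, criterion)
        elif scheme == "subset":
            k = int(rng.integers(1, max_model_size + 1))
            cols = sorted(rng.choice(p, size=min(k, p), replace=False).tolist())
            try:
                beta, _ = _ols(X[:, cols], y)
            except CollinearityError:
                redraws += 1
                continue
            sel = tuple(cols)
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        for j, col in enumerate(sel):
            rcs[b, col] = beta[j + 1]
        b += 1
    if redraws:
        logger.info("redrew %d degenerate replicate(s)", redraws)

    return {
        name: RCDistribution(name, rcs[:, j].copy(), n_tested=p)
        for j, name in sorted(enumerate(names), key=lambda t: t[1])
    }


def test_rcs(
    dist: RCDistribution, n_tfbs_tested: int | None = None, alpha: float = 0.01
) -> tuple[bool, int]:
    """Significance flag and sign of one RC distribution.

    One-sample two-sided t-test of the RCs against 0, Bonferroni-corrected
    over ``n_tfbs_tested`` (defaults to the count recorded at construction).
    Sign is sign(mean RC) when significant, else 0.
    """
    n_tests = dist.n_tested if n_tfbs_tested is None else n_tfbs_tested
    p_adj = min(1.0, dist.p_raw * n_tests)
    significant = p_adj < alpha
    sign = int(np.sign(dist.mean_rc)) if significant else 0
    if significant and sign == 0:  # zero mean cannot be significant
        significant = False
    return significant, sign


def classify_tfbs(
    resA: Mapping[str, RCDistribution],
    resB: Mapping[str, RCDistribution],
    alpha: float = 0.01,
) -> TFBSClassification:
    """Concordance classes of TFBS mean RCs between two conditions.

    identical: significant in both with equal signs; opposite: significant
    in both with unequal signs; unique: significant in exactly one.
    """
    if set(resA) != set(resB):
        raise ValueError("TFBS universes differ between conditions")
    status: dict[str, str] = {}
    sign_a: dict[str, int] = {}
    sign_b: dict[str, int] = {}
    for tfbs in sorted(resA):
        sa_flag, sa = test_rcs(resA[tfbs], alpha=alpha)
        sb_flag, sb = test_rcs(resB[tfbs], alpha=alpha)
        sign_a[tfbs], sign_b[tfbs] = sa, sb
        if sa_flag and sb_flag:
            status[tfbs] = "identical" if sa == sb else "opposite"
        elif sa_flag:
            status[tfbs] = "unique_to_A"
        elif sb_flag:
            status[tfbs] = "unique_to_B"
        else:
            status[tfbs] = "not_significant"
    return TFBSClassification(status, sign_a, sign_b)


def refit_excluding(
    features: FeatureMatrix,
    excluded_genes: Iterable[str],
    max_model_size: int = 10,
    B: int = 1000,
    seed: int = 0,
    baseline: Mapping[str, RCDistribution] | None = None,
    **kwargs,
) -> tuple[dict[str, RCDistribution], dict[str, float]]:
    """Rerun the bootstrap pipeline with a gene subset removed.

    Returns the new distributions and the per-TFBS mean-RC shift
    (after - before); ``baseline`` defaults to a same-seed run on the
    full gene set.
    """
    excluded = set(excluded_genes)
    unknown = excluded - set(features.gene_ids)
    if unknown:
        raise ValueError(f"excluded genes not in feature matrix: {sorted(unknown)}")
    kept = [g for g in features.gene_ids if g not in excluded]
    if len(kept) < max_model_size + 2:
        raise ValueError(
            f"only {len(kept)} genes remain; need >= {max_model_size + 2}"
        )
    if baseline is None:
        baseline = bootstrap_rcs(
            features, max_model_size=max_model_size, B=B, seed=seed, **kwargs
        )
    reduced = features.subset_genes(kept)
    after = bootstrap_rcs(
        reduced, max_model_size=max_model_size, B=B, seed=seed, **kwargs
    )
    shifts = {t: after[t].mean_rc - baseline[t].mean_rc for t in after}
    return after, shifts


def rc_table(dists: Mapping[str, RCDistribution], alpha: float = 0.01) -> pd.DataFrame:
    """Summary table: mean RC, t, p, Bonferroni p, selection frequency, status."""
    rows = []
    for tfbs in sorted(dists):
        d = dists[tfbs]
        sig, sign = test_rcs(d, alpha=alpha)
        rows.append((tfbs, d.mean_rc, d.t_statistic, d.p_raw, d.p_bonferroni,
                     d.selection_frequency, "significant" if sig else "ns", sign))
    return pd.DataFrame(
        rows,
        columns=["tfbs_id", "mean_rc", "t", "p_raw", "p_bonferroni",
                 "selection_frequency", "status", "sign"],
    ).set_index("tfbs_id")


def rc_quantiles(
    dists: Mapping[str, RCDistribution],
    quantiles: Sequence[float] = (0.05, 0.25, 0.5, 0.75, 0.95),
) -> pd.DataFrame:
    """Per-TFBS RC quantile summary (for quantile plots of the distributions)."""
    rows = {
        t: np.quantile(d.rcs, quantiles) for t, d in sorted(dists.items())
    }
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"q{int(100 * q)}" for q in quantiles]
    )
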
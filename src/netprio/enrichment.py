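"""Enrichment of prioritized genes for drug targets, and AUCs.

Prioritized genes (top fraction of a ranked score table, 1% by default,
5% for the sparse pQTL-GWAS background) are crossed with drug-target
genes over a declared background in a 2x2 table.  Two conventions
accompany the Fisher exact test:

* if no prioritized gene is a target (``a = 0``) the odds ratio is
  reported as 1;
* if a main-diagonal cell (``a`` or ``d``) is zero it is set to 1
  before the cross-product odds ratio (and its Woolf standard error)
  is formed.

The Fisher p-value is always computed on the unadjusted table.
Threshold-free performance is measured by the ROC AUC (midrank tie
handling) with DeLong standard errors, and between-method concordance
by Fisher ORs across a grid of top-percentile cutoffs on the methods'
common gene background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "AucResult",
    "top_genes",
    "tied_rank_ranges",
    "fisher_enrichment",
    "roc_auc",
    "concordance",
    "CONCORDANCE_GRID",
]

#: Top-percentile grid used in between-method concordance analyses.
CONCORDANCE_GRID = (0.001, 0.002, 0.005, 0.01, 0.02, 0.03, 0.05, 0.075, 0.10)


@dataclass(frozen=True)
class EnrichmentResult:
    or_value: float
    log_or: float
    se_log_or: float
    p: float
    table: tuple[int, int, int, int]
    adjusted: bool = False


@dataclass(frozen=True)
class AucResult:
    auc: float
    se_auc: float
    n_pos: int
    n_neg: int


def _priority(scores: pd.Series, higher_is_better: bool) -> pd.Series:
    """Orient scores so that larger means more prioritized."""
    return scores if higher_is_better else -scores


def top_genes(
    scores: pd.Series,
    q: float,
    background: Iterable[str] | None = None,
    higher_is_better: bool = False,
) -> frozenset[str]:
    """The top ``floor(q * n_scored)`` genes of a score vector.

    ``scores`` is indexed by gene id; by default lower values (p-values)
    rank first, set ``higher_is_better`` for diffusion scores.  Ties at
    the boundary are broken deterministically by lexicographic gene id.
    ``background``, when given, restricts the scored genes first.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("top fraction q must lie in (0, 1)")
    if background is not None:
        scores = scores.loc[scores.index.isin(set(background))]
    k = math.floor(q * len(scores))
    if k == 0:
        raise ValueError(f"top fraction {q} of {len(scores)} scored genes is empty")
    pri = _priority(scores, higher_is_better)
    order = sorted(zip(-pri.to_numpy(float), pri.index.astype(str)))
    return frozenset(g for _, g in order[:k])


def tied_rank_ranges(scores: pd.Series, higher_is_better: bool = False) -> pd.DataFrame:
    """Min--max rank range per gene (ties share a range, e.g. 1-52)."""
    pri = _priority(scores, higher_is_better).to_numpy(float)
    lo = stats.rankdata(-pri, method="min").astype(int)
    hi = stats.rankdata(-pri, method="max").astype(int)
    return pd.DataFrame({"gene_id": scores.index, "rank_min": lo, "rank_max": hi})


def fisher_enrichment(
    prioritized: Iterable[str],
    targets: Iterable[str],
    background: Iterable[str],
) -> EnrichmentResult:
    """Fisher exact test of prioritized genes against drug targets.

    Targets are restricted to the background first (only targets
    testable by the method count).  The two-sided hypergeometric p is
    computed on the raw table; the cross-product odds ratio then applies
    the fallback conventions described in the module docstring, and the
    Woolf standard error ``sqrt(1/a + 1/b + 1/c + 1/d)`` is taken on the
    post-rule table.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    prioritized = set(prioritized) & background
    targets = set(targets) & background
    a = len(prioritized & targets)
    b = len(prioritized - targets)
    c = len(targets - prioritized)
    d = len(background) - a - b - c

    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])

    adjusted = False
    if a == 0:
        or_value, log_or = 1.0, 0.0
        se = float("nan")
        adjusted = True
    else:
        aa, dd = a, d
        if dd == 0:
            dd = 1
            adjusted = True
        if b == 0 or c == 0:
            or_value = float("inf")
            log_or = float("inf")
            se = float("inf")
        else:
            or_value = (aa * dd) / (b * c)
            log_or = math.log(or_value)
            se = math.sqrt(1 / aa + 1 / b + 1 / c + 1 / dd)
    return EnrichmentResult(
        or_value=or_value, log_or=log_or, se_log_or=se, p=p,
        table=(a, b, c, d), adjusted=adjusted,
    )


def _delong_se(pos: np.ndarray, neg: np.ndarray) -> float:
    # DeLong et al. (1988) with midrank tie handling.
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    rk_all = stats.rankdata(all_scores)
    rk_pos = stats.rankdata(pos)
    rk_neg = stats.rankdata(neg)
    v10 = (rk_all[:m] - rk_pos) / n          # placement of positives
    v01 = 1.0 - (rk_all[m:] - rk_neg) / m    # placement of negatives
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(np.sqrt(s10 / m + s01 / n))


def roc_auc(
    scores: pd.Series,
    labels: pd.Series | Iterable[str],
    higher_is_better: bool = False,
) -> AucResult:
    """ROC AUC of gene scores against target membership, with DeLong SE.

    ``labels`` is either a boolean Series aligned to ``scores`` or an
    iterable of positive gene ids.  The AUC is the probability that a
    random positive outranks a random negative, ties counting one half
    (midrank formula).  Requires at least one positive and one negative.
    """
    if isinstance(labels, pd.Series):
        y = labels.reindex(scores.index).fillna(False).astype(bool)
    else:
        pos_set = set(labels)
        y = pd.Series([g in pos_set for g in scores.index], index=scores.index)
    pri = _priority(scores, higher_is_better).to_numpy(float)
    y = y.to_numpy()
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires at least one positive and one negative")
    ranks = stats.rankdata(pri)
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    se = _delong_se(pri[y], pri[~y])
    return AucResult(auc=float(auc), se_auc=se, n_pos=n_pos, n_neg=n_neg)


def concordance(
    scores_a: pd.Series,
    scores_b: pd.Series,
    grid: Sequence[float] = CONCORDANCE_GRID,
    higher_is_better: bool = False,
) -> pd.DataFrame:
    """Between-method concordance: Fisher OR of top sets per percentile.

    Only genes scored by both methods form the background.  At each
    percentile the two top sets are crossed in a Fisher test; when the
    sets do not overlap the OR falls back to 1 (flagged through
    ``adjusted``).  Returns a tidy frame with columns ``percentile, or,
    log_or, se, p, n_overlap, adjusted``.
    """
    if any(not (0.0 < g < 1.0) for g in grid):
        raise ValueError("percentile grid must lie in (0, 1)")
    common = scores_a.index.intersection(scores_b.index)
    if len(common) == 0:
        raise ValueError("no common genes between the two methods")
    sa, sb = scores_a.loc[common], scores_b.loc[common]
    rows = []
    for qq in grid:
        if math.floor(qq * len(common)) == 0:
            continue
        ta = top_genes(sa, qq, higher_is_better=higher_is_better)
        tb = top_genes(sb, qq, higher_is_better=higher_is_better)
        res = fisher_enrichment(ta, tb, common)
        rows.append({
            "percentile": qq, "or": res.or_value, "log_or": res.log_or,
            "se": res.se_log_or, "p": res.p,
            "n_overlap": res.table[0], "adjusted": res.adjusted,
        })
    return pd.DataFrame(rows)
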
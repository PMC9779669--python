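"""TF regulation classification and TF–TF co-expression from expression panels.

Across a panel of conditions, a TF with a significant positive Pearson
correlation (p < alpha) to a target gene is classified as an activator and a
significant negative correlation as a repressor; the OLS slope of the gene
on the TF is the strength of regulation. A TF is "co-expressing" when it
shows significant positive (or negative) correlation with at least
`min_partners` other TFs of the same gene. Raw p-values are used by default,
matching the protocol; an optional Benjamini–Hochberg flag is provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["RegulationEstimate", "CoexpressionSummary", "gene_tf_regulation", "tf_tf_coexpression"]


@dataclass(frozen=True)
class RegulationEstimate:
    gene_id: str
    tf_id: str
    correlation: float
    p_value: float
    slope: float | None
    role: str  # activator / repressor / none


@dataclass
class CoexpressionSummary:
    per_tf: pd.DataFrame  # n_positive_partners, n_negative_partners, flags
    correlations: pd.DataFrame
    p_values: pd.DataFrame
    min_partners: int
    alpha: float

    @property
    def n_positively_coexpressing(self) -> int:
        return int(self.per_tf["positively_coexpressing"].sum())

    @property
    def n_negatively_coexpressing(self) -> int:
        return int(self.per_tf["negatively_coexpressing"].sum())


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def gene_tf_regulation(
    panel: pd.DataFrame,
    gene_id: str,
    tf_ids: list[str],
    alpha: float = 0.05,
    log_scale: bool = False,
    bh_correct: bool = False,
) -> list[RegulationEstimate]:
    """Classify each regulating TF of a gene as activator/repressor/none.

    `panel` is samples × genes. The regulation strength (slope) is reported
    only for significant TFs. With `log_scale` both gene and TF expression
    are log1p-transformed before the fit.
    """
    if len(panel) < 3:
        raise ValueError("need at least 3 samples")
    y = panel[gene_id].to_numpy(dtype=float)
    if log_scale:
        y = np.log1p(y)
    results = []
    raw = []
    for tf in tf_ids:
        x = panel[tf].to_numpy(dtype=float)
        if log_scale:
            x = np.log1p(x)
        r, p = _pearson(x, y)
        raw.append((tf, x, r, p))
    pvals = np.array([p for *_, p in raw])
    if bh_correct:
        finite = np.isfinite(pvals)
        adj = pvals.copy()
        if finite.any():
            adj[finite] = multipletests(pvals[finite], method="fdr_bh")[1]
        pvals = adj
    for (tf, x, r, _), p in zip(raw, pvals):
        if not np.isfinite(p) or p >= alpha:
            role, slope = "none", None
        else:
            role = "activator" if r > 0 else "repressor"
            slope = float(np.polyfit(x, y, 1)[0])
        results.append(RegulationEstimate(gene_id, tf, r, float(p), slope, role))
    return results


def tf_tf_coexpression(
    panel: pd.DataFrame,
    tf_ids: list[str],
    alpha: float = 0.05,
    min_partners: int = 3,
    bh_correct: bool = False,
) -> CoexpressionSummary:
    """All pairwise TF–TF correlations and the ≥ min_partners co-expression rule."""
    k = len(tf_ids)
    corr = pd.DataFrame(np.eye(k), index=tf_ids, columns=tf_ids)
    pvals = pd.DataFrame(np.zeros((k, k)), index=tf_ids, columns=tf_ids)
    flat = []
    for a, b in combinations(tf_ids, 2):
        r, p = _pearson(panel[a].to_numpy(float), panel[b].to_numpy(float))
        corr.loc[a, b] = corr.loc[b, a] = r
        pvals.loc[a, b] = pvals.loc[b, a] = p
        flat.append(((a, b), p))
    if bh_correct and flat:
        ps = np.array([p for _, p in flat])
        finite = np.isfinite(ps)
        if finite.any():
            ps[finite] = multipletests(ps[finite], method="fdr_bh")[1]
        for ((a, b), _), p in zip(flat, ps):
            pvals.loc[a, b] = pvals.loc[b, a] = p
    rows = []
    for tf in tf_ids:
        others = [o for o in tf_ids if o != tf]
        sig = [o for o in others if np.isfinite(pvals.loc[tf, o]) and pvals.loc[tf, o] < alpha]
        n_pos = sum(corr.loc[tf, o] > 0 for o in sig)
        n_neg = sum(corr.loc[tf, o] < 0 for o in sig)
        rows.append(
            {
                "tf_id": tf,
                "n_positive_partners": n_pos,
                "n_negative_partners": n_neg,
                "positively_coexpressing": n_pos >= min_partners,
                "negatively_coexpressing": n_neg >= min_partners,
            }
        )
    return CoexpressionSummary(
        per_tf=pd.DataFrame(rows).set_index("tf_id"),
        correlations=corr,
        p_values=pvals,
        min_partners=min_partners,
        alpha=alpha,
    )
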
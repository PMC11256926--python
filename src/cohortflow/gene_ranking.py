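"""Per-gene scoring between two sample groups for enrichment prerank export.

Each gene is scored as ``-log10(adjusted p) * log2(fold change)`` where the
p-value comes from a two-sided two-sample Kolmogorov-Smirnov test between
the groups' expression distributions, adjusted across genes by
Benjamini-Hochberg, and the fold change is the ratio of pseudocounted group
means on the normalized linear scale. The ranked list feeds standard
prerank-based enrichment tools; running the enrichment itself is out of
scope here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp
from statsmodels.stats.multitest import multipletests

from cohortflow.data_io import ExpressionMatrix

P_FLOOR = 1e-300


def gene_score(adj_p: float, log2_fc: float) -> float:
    """The ranking score ``-log10(adj_p) * log2(FC)``; adj_p is floored at
    1e-300 to avoid infinities."""
    return -np.log10(max(adj_p, P_FLOOR)) * log2_fc


@dataclass
class GeneScore:
    gene_id: str
    statistic: float
    p_value: float
    adj_p: float
    log2_fc: float
    score: float


def score_genes(
    m: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fc_pseudocount: float = 1.0,
) -> list[GeneScore]:
    """Score every gene between two disjoint sample groups.

    FC = (mean_a + pseudocount) / (mean_b + pseudocount) on the values as
    given; score = -log10(adj_p) * log2(FC). Genes constant and equal in
    both groups get p = 1 and score 0. Returned sorted by score descending
    (ties by gene_id).
    """
    a_set, b_set = set(group_a), set(group_b)
    if a_set & b_set:
        raise ValueError("groups must be disjoint")
    if len(a_set) < 3 or len(b_set) < 3:
        raise ValueError("each group needs at least 3 samples")
    col = {s: j for j, s in enumerate(m.sample_ids)}
    ia = [col[s] for s in group_a]
    ib = [col[s] for s in group_b]
    xa, xb = m.values[:, ia], m.values[:, ib]

    stats = np.empty(m.n_genes)
    pvals = np.empty(m.n_genes)
    for g in range(m.n_genes):
        va, vb = xa[g], xb[g]
        if np.all(va == va[0]) and np.all(vb == vb[0]) and va[0] == vb[0]:
            stats[g], pvals[g] = 0.0, 1.0
        else:
            res = ks_2samp(va, vb, alternative="two-sided", method="auto")
            stats[g], pvals[g] = res.statistic, res.pvalue
    adj = multipletests(pvals, method="fdr_bh")[1]
    log2_fc = np.log2(
        (xa.mean(axis=1) + fc_pseudocount) / (xb.mean(axis=1) + fc_pseudocount)
    )
    scores = np.array([gene_score(a, f) for a, f in zip(adj, log2_fc)])
    out = [
        GeneScore(
            gene_id=m.gene_ids[g],
            statistic=float(stats[g]),
            p_value=float(pvals[g]),
            adj_p=float(adj[g]),
            log2_fc=float(log2_fc[g]),
            score=float(scores[g]),
        )
        for g in range(m.n_genes)
    ]
    out.sort(key=lambda s: (-s.score, s.gene_id))
    return out


def export_prerank(scores: list[GeneScore], path: str | Path) -> None:
    """Write a header-less two-column tab-separated (gene, score) file,
    sorted by score descending, for prerank-style enrichment consumers."""
    if not scores:
        raise ValueError("no scores to export")
    ids = [s.gene_id for s in scores]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene_id in scores")
    ordered = sorted(scores, key=lambda s: (-s.score, s.gene_id))
    with open(path, "w") as fh:
        for s in ordered:
            fh.write(f"{s.gene_id}\t{s.score:.10g}\n")


def write_scores_csv(scores: list[GeneScore], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": s.gene_id,
                "statistic": s.statistic,
                "p_value": s.p_value,
                "adj_p": s.adj_p,
                "log2_fc": s.log2_fc,
                "score": s.score,
            }
            for s in scores
        ]
    ).to_csv(path, index=False)
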
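"""Hypergeometric over-representation of functional annotations.

Given a result gene set and the background of all analyzed genes, each
annotation category is tested with the upper-tail hypergeometric
probability P(X >= k) of drawing at least k category members in a sample
of the result-set size; p-values are corrected with Benjamini–Hochberg.
Categories with fewer than ``min_copies`` members in the background
(default 4) carry no power and are excluded before testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError


@dataclass
class EnrichmentRecord:
    """One category's over-representation test."""

    category: str
    k: int  # category hits in the gene set
    n: int  # gene set size
    K: int  # category size in the background
    N: int  # background size
    p_value: float
    q_value: float
    significant: bool


def hypergeom_enrichment(
    gene_set,
    annotations: dict[str, set[str]],
    background,
    min_copies: int = 4,
    fdr: float = 0.05,
) -> list[EnrichmentRecord]:
    """Test every annotation category for over-representation in ``gene_set``.

    ``annotations`` maps character id -> set of category labels; characters
    without an entry are simply unannotated. ``gene_set`` must be a subset
    of ``background``. Returns records sorted by p-value (ties by category
    label); ``significant`` flags BH q-value <= ``fdr``.
    """
    background = set(background)
    gene_set = set(gene_set)
    if not background:
        raise ValidationError("background set is empty")
    if not gene_set <= background:
        extra = sorted(gene_set - background)[:5]
        raise ValidationError(f"gene set is not inside the background: {extra}")
    N = len(background)
    n = len(gene_set)
    category_members: dict[str, set[str]] = {}
    for gene in background:
        for cat in annotations.get(gene, ()):
            category_members.setdefault(cat, set()).add(gene)
    records = []
    for cat in sorted(category_members):
        members = category_members[cat]
        K = len(members)
        if K < min_copies:
            continue
        k = len(members & gene_set)
        p = float(hypergeom.sf(k - 1, N, K, n))
        records.append(
            EnrichmentRecord(cat, k, n, K, N, p_value=min(p, 1.0), q_value=np.nan,
                             significant=False)
        )
    if not records:
        return []
    pvals = [r.p_value for r in records]
    reject, qvals, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    for r, q, rej in zip(records, qvals, reject):
        r.q_value = float(q)
        r.significant = bool(rej)
    records.sort(key=lambda r: (r.p_value, r.category))
    return records
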
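"""Chromosomal representation of gene sets: ratios, exact tests, adjustment.

The representation ratio of a gene set on an arm is the set's arm
frequency divided by the genome's arm frequency (1.0 = genome average).
Departures are tested with the hypergeometric distribution (both tails
reported), Fisher's exact test for 2×2 contrasts, and Pearson's χ² for
bias-category tables; families of tests are adjusted with Bonferroni,
and differential-expression contrasts use Benjamini–Hochberg q-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import UsageError
from .io import ARMS, AUTOSOMES, GeneCatalog

logger = logging.getLogger("xbias")


@dataclass
class EnrichmentResult:
    """Representation of one gene set on one chromosome compartment."""

    arm: str
    n_set_on_arm: int
    n_set: int
    n_arm: int
    n_genome: int
    representation_ratio: float
    p_under: float
    p_over: float
    p_adjusted: float
    method: str

    def as_dict(self) -> dict:
        return asdict(self)


def representation_ratio(gene_set: Iterable[str], catalog: GeneCatalog, arm: str) -> float:
    """(set fraction on arm) / (genome fraction on arm); 1.0 = average."""
    k, n_set, n_arm, n_genome = _arm_counts(gene_set, catalog, arm)
    if n_set == 0:
        raise UsageError("gene set is empty (after joining the catalog)")
    if n_arm == 0:
        raise UsageError(f"no catalog genes on arm {arm!r}")
    return (k / n_set) / (n_arm / n_genome)


def _arm_counts(gene_set, catalog: GeneCatalog, arm: str) -> tuple[int, int, int, int]:
    genes = pd.Index(sorted(set(gene_set))).intersection(catalog.gene_ids)
    on_arm = pd.Index(catalog.genes_on(arm))
    k = len(genes.intersection(on_arm))
    return k, len(genes), len(on_arm), len(catalog)


def hypergeom_test(
    n_set_on_arm: int, n_set: int, n_arm: int, n_genome: int
) -> tuple[float, float]:
    """Exact lower/upper tail probabilities of the arm count.

    ``K ~ Hypergeometric(n_genome, n_arm, n_set)``; returns
    ``(P(K <= k), P(K >= k))``.  Computed in log space by scipy, stable
    for genome sizes well beyond 2e4.
    """
    k, N, n, M = n_set_on_arm, n_set, n_arm, n_genome
    if not (0 <= k <= min(N, n) and n <= M and N <= M and k >= max(0, N + n - M)):
        raise UsageError(
            f"inconsistent counts: k={k}, n_set={N}, n_arm={n}, n_genome={M}"
        )
    dist = stats.hypergeom(M, n, N)
    p_under = float(min(1.0, dist.cdf(k)))
    p_over = float(min(1.0, dist.sf(k - 1)))
    return p_under, p_over


def fisher_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Two-sidedness by the point-probability rule: sum the probabilities of
    all tables with the observed margins whose probability does not
    exceed that of the observed table.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise UsageError("fisher_2x2 requires nonnegative integers")
    if (a + b == 0 or c + d == 0) and (a + c == 0 or b + d == 0):
        raise UsageError("fisher_2x2: degenerate all-zero margins")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(min(1.0, p))


def chisq_category_table(
    counts_x: Sequence[int], counts_autosome: Sequence[int]
) -> tuple[float, int, float]:
    """Pearson χ² comparing bias-category counts between X and autosomes.

    Zero-margin categories are dropped with a warning; a warning is also
    logged when any expected count falls below 5.
    Returns ``(statistic, df, p)``.
    """
    cx = np.asarray(counts_x, dtype=float)
    ca = np.asarray(counts_autosome, dtype=float)
    if cx.shape != ca.shape:
        raise UsageError("category vectors must have equal length")
    keep = (cx + ca) > 0
    if not keep.all():
        logger.warning(
            "chisq_category_table: dropping %d zero-margin category(ies)",
            int((~keep).sum()),
        )
    cx, ca = cx[keep], ca[keep]
    if cx.size < 2:
        raise UsageError("need at least two non-empty categories")
    table = np.vstack([cx, ca])
    stat, p, df, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 5).any():
        logger.warning("chisq_category_table: expected count below 5")
    return float(stat), int(df), float(p)


def bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment: min(1, m·p), order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise UsageError("p-values must lie in [0,1]")
    m = len(p) if m is None else int(m)
    return list(np.minimum(1.0, m * p))


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values (monotone)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise UsageError("p-values must lie in [0,1]")
    return list(multipletests(p, method="fdr_bh")[1])


# ---------------------------------------------------------------------------
# table-level drivers
# ---------------------------------------------------------------------------

def arm_representation(
    gene_set: Iterable[str],
    catalog: GeneCatalog,
    arms: Sequence[str] | None = None,
) -> list[EnrichmentResult]:
    """Hypergeometric representation of a gene set on each arm.

    One Bonferroni family per call (``p_adjusted`` adjusts
    ``min(p_under, p_over)`` across the arms of this table).
    """
    arms = list(arms if arms is not None else ARMS)
    gene_set = set(gene_set)
    rows = []
    for arm in arms:
        k, n_set, n_arm, n_genome = _arm_counts(gene_set, catalog, arm)
        if n_set == 0 or n_arm == 0:
            raise UsageError(f"empty set or arm {arm!r} for representation analysis")
        p_under, p_over = hypergeom_test(k, n_set, n_arm, n_genome)
        rows.append(
            EnrichmentResult(
                arm=arm,
                n_set_on_arm=k,
                n_set=n_set,
                n_arm=n_arm,
                n_genome=n_genome,
                representation_ratio=(k / n_set) / (n_arm / n_genome),
                p_under=p_under,
                p_over=p_over,
                p_adjusted=np.nan,
                method="hypergeometric",
            )
        )
    adj = bonferroni([min(r.p_under, r.p_over) for r in rows])
    for r, a in zip(rows, adj):
        r.p_adjusted = float(a)
    return rows


def x_vs_autosomes(gene_set: Iterable[str], catalog: GeneCatalog) -> EnrichmentResult:
    """Hypergeometric representation of a gene set on X vs all autosomes."""
    k, n_set, n_arm, n_genome = _arm_counts(gene_set, catalog, "X")
    if n_set == 0 or n_arm == 0 or n_arm == n_genome:
        raise UsageError("need non-empty set plus X and autosomal genes")
    p_under, p_over = hypergeom_test(k, n_set, n_arm, n_genome)
    return EnrichmentResult(
        arm="X",
        n_set_on_arm=k,
        n_set=n_set,
        n_arm=n_arm,
        n_genome=n_genome,
        representation_ratio=(k / n_set) / (n_arm / n_genome),
        p_under=p_under,
        p_over=p_over,
        p_adjusted=min(p_under, p_over),
        method="hypergeometric",
    )
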
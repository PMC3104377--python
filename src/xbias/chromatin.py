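"""Chromatin-protein association of tissue-biased / up-regulated genes.

Two treatments mirror the two views of the data:

* thresholded: per protein, genes are called bound when their score
  reaches the protein's threshold; the frequency of bound genes inside a
  gene set (split into X-linked and autosomal compartments) is
  normalized to the bound frequency in the whole assessed genome
  (relative frequency 1.0 = genome average);
* continuous: the per-timepoint Pearson correlation between
  developmental log2 fold change and the raw binding score, two-sided p
  from the t transform, Bonferroni within the protein × timepoint
  series.

Each protein carries a role tag (``silencing`` or ``activation``); the
"inverse" pattern — up-regulation in testis development positively
correlated with silencer binding and negatively with activator binding
— is summarized by :func:`inverse_correlation_report`.

Universes are per-protein, pairwise-complete: the source binding data
assess different gene subsets per protein, so genes missing a score are
excluded from both numerator and denominator for that protein only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bonferroni
from .errors import UsageError
from .io import BindingProfile, GeneCatalog
from .timecourse import FoldChangeMatrix

logger = logging.getLogger("xbias")


@dataclass
class BindingEnrichment:
    """Bound-gene frequency of a set, one compartment, one protein."""

    protein: str
    role: str
    set_label: str
    compartment: str  # "X" or "autosomes"
    n_genes: int
    f_set: float
    f_genome: float
    relative_frequency: float
    assessable: bool

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class CorrelationResult:
    """Pearson correlation of one protein's binding with one contrast."""

    protein: str
    role: str
    timepoint: str
    r: float
    n: int
    p: float
    p_adj: float

    def as_dict(self) -> dict:
        return asdict(self)


def binarize_binding(bp: BindingProfile, protein: str) -> set[str]:
    """Genes whose score reaches the protein's threshold (missing excluded)."""
    assessed = bp.assessed(protein)
    scores = bp.scores.loc[assessed, protein]
    return set(scores.index[scores >= bp.thresholds[protein]])


def binding_enrichment(
    bp: BindingProfile,
    protein: str,
    gene_set: Iterable[str],
    catalog: GeneCatalog,
    set_label: str = "set",
) -> list[BindingEnrichment]:
    """Relative bound-gene frequency of a set on X and autosomes.

    The genome baseline is the bound fraction over all genes assessed
    for this protein (and present in the catalog); each compartment's
    set frequency is normalized to that baseline.  An empty compartment
    yields a result flagged not-assessable instead of aborting.
    """
    universe = pd.Index(bp.assessed(protein)).intersection(catalog.gene_ids)
    if len(universe) == 0:
        raise UsageError(f"no assessed genes for {protein!r} in the catalog")
    bound = binarize_binding(bp, protein) & set(universe)
    f_genome = len(bound) / len(universe)
    arms = catalog.arms.loc[universe]
    gene_set = set(gene_set) & set(universe)
    out = []
    for compartment, mask in (("X", arms == "X"), ("autosomes", arms != "X")):
        comp_genes = set(universe[mask.to_numpy()])
        members = gene_set & comp_genes
        if not members or f_genome == 0:
            out.append(
                BindingEnrichment(
                    protein, bp.roles[protein], set_label, compartment,
                    len(members), float("nan"), f_genome, float("nan"), False,
                )
            )
            continue
        f_set = len(members & bound) / len(members)
        out.append(
            BindingEnrichment(
                protein, bp.roles[protein], set_label, compartment,
                len(members), f_set, f_genome, f_set / f_genome, True,
            )
        )
    return out


def expression_binding_correlation(
    fc: FoldChangeMatrix,
    bp: BindingProfile,
    min_pairs: int = 3,
) -> list[CorrelationResult]:
    """Pearson r between each contrast's log2 FC and each protein's score.

    Pairwise-complete join per (protein, timepoint); cells with fewer
    than ``min_pairs`` shared genes are omitted with a log entry.
    Bonferroni is applied across all reported cells of the run.
    """
    results: list[CorrelationResult] = []
    shared = fc.log2fc.index.intersection(bp.gene_ids)
    for protein in bp.proteins:
        scores = bp.scores.loc[shared, protein]
        ok = scores.notna()
        for timepoint in fc.contrasts:
            x = fc.log2fc.loc[shared, timepoint][ok]
            y = scores[ok]
            n = len(x)
            if n < min_pairs:
                logger.info(
                    "correlation omitted: %s × %s has %d shared gene(s)",
                    protein, timepoint, n,
                )
                continue
            if np.std(x) == 0 or np.std(y) == 0:
                r, p = 0.0, 1.0
            else:
                r, p = stats.pearsonr(x, y)
            results.append(
                CorrelationResult(
                    protein=protein,
                    role=str(bp.roles[protein]),
                    timepoint=str(timepoint),
                    r=float(r),
                    n=n,
                    p=float(p),
                    p_adj=float("nan"),
                )
            )
    adj = bonferroni([r.p for r in results])
    for res, a in zip(results, adj):
        res.p_adj = float(a)
    return results


def inverse_correlation_report(
    results: Sequence[CorrelationResult], alpha: float = 0.05
) -> dict:
    """Summarize the silencing-positive / activation-negative pattern.

    Per role: counts and fraction of (protein, timepoint) cells with
    significant (``p_adj < alpha``) positive vs negative r.  The
    ``inverse_pattern`` flag is true when significant silencing-role
    correlations are predominantly positive *and* significant
    activation-role correlations predominantly negative.
    """
    summary: dict = {"alpha": alpha, "roles": {}}
    predominant: dict[str, str | None] = {}
    for role in ("silencing", "activation"):
        cells = [r for r in results if r.role == role]
        sig = [r for r in cells if r.p_adj < alpha]
        pos = sum(1 for r in sig if r.r > 0)
        neg = sum(1 for r in sig if r.r < 0)
        summary["roles"][role] = {
            "n_cells": len(cells),
            "n_significant": len(sig),
            "n_positive": pos,
            "n_negative": neg,
            "frac_significant": len(sig) / len(cells) if cells else 0.0,
        }
        if pos > neg:
            predominant[role] = "positive"
        elif neg > pos:
            predominant[role] = "negative"
        else:
            predominant[role] = None
    summary["inverse_pattern"] = (
        predominant["silencing"] == "positive"
        and predominant["activation"] == "negative"
    )
    return summary
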
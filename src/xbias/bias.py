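"""Tissue-bias scoring: the minimal target-to-panel signal ratio.

A gene's bias toward a target tissue (testis, midgut, ...) is measured
conservatively as the *minimum*, over every other tissue in the atlas,
of the target::tissue signal ratio.  A gene only scores high when its
target signal exceeds *all* panel signals, so the statistic is robust to
a single permissive tissue.  Genes are binned with inclusive lower
edges: <2, >=2, >=5, >=10; "highly biased" means a minimal ratio of at
least ten.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import UsageError
from .io import ExpressionAtlas

#: Default category edges (inclusive lower bounds).
DEFAULT_THRESHOLDS: tuple[float, ...] = (2.0, 5.0, 10.0)

#: Category labels for the default edges, low to high.
CATEGORIES: tuple[str, ...] = ("<2", ">=2", ">=5", ">=10")


def minimal_ratio(
    target_signal: float,
    panel_signals: Sequence[float],
    epsilon: float = 0.0,
) -> float:
    """Minimal (target + eps) / (panel + eps) ratio over a tissue panel.

    ``epsilon`` is a pseudocount guarding division by zero; with
    ``epsilon=0`` the statistic is scale-invariant.
    """
    panel = np.asarray(panel_signals, dtype=float)
    if panel.size == 0:
        raise UsageError("panel must be non-empty")
    return float(np.min((target_signal + epsilon) / (panel + epsilon)))


def classify_bias(
    min_ratio: float, thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> str:
    """Bin a minimal ratio into its bias category (inclusive lower edges)."""
    thresholds = list(thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise UsageError("thresholds must be strictly increasing")
    labels = [f"<{_fmt(thresholds[0])}"] + [f">={_fmt(t)}" for t in thresholds]
    i = int(np.searchsorted(thresholds, min_ratio, side="right"))
    return labels[i]


def _fmt(x: float) -> str:
    return f"{int(x)}" if float(x).is_integer() else f"{x}"


def resolve_epsilon(atlas: ExpressionAtlas, epsilon: float | str = "auto") -> float:
    """Pseudocount: half the smallest positive intensity when ``auto``."""
    if epsilon == "auto":
        values = atlas.frame.to_numpy()
        positive = values[values > 0]
        return float(positive.min() / 2.0) if positive.size else 1.0
    return float(epsilon)


def min_ratio_profile(
    atlas: ExpressionAtlas,
    target_tissue: str,
    epsilon: float | str = "auto",
) -> pd.Series:
    """Minimal ratio of every gene against the designated target tissue.

    The panel is every atlas tissue except the target (no germline
    exclusion: ovary stays in the panel when testis is the target).
    """
    if target_tissue not in atlas.tissues:
        raise UsageError(f"tissue {target_tissue!r} not in atlas")
    eps = resolve_epsilon(atlas, epsilon)
    values = atlas.frame.to_numpy(dtype=float)
    j = atlas.frame.columns.get_loc(target_tissue)
    panel = np.delete(values, j, axis=1)
    if panel.shape[1] == 0:
        raise UsageError("atlas has no panel tissues besides the target")
    ratios = (values[:, [j]] + eps) / (panel + eps)
    return pd.Series(ratios.min(axis=1), index=atlas.gene_ids, name="min_ratio")


def bias_table(
    atlas: ExpressionAtlas,
    target_tissue: str,
    epsilon: float | str = "auto",
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per-gene minimal ratio and bias category for one target tissue."""
    ratios = min_ratio_profile(atlas, target_tissue, epsilon)
    categories = [classify_bias(r, thresholds) for r in ratios]
    return pd.DataFrame(
        {
            "gene_id": ratios.index,
            "target_tissue": target_tissue,
            "min_ratio": ratios.to_numpy(),
            "category": categories,
        }
    )


def biased_gene_set(
    atlas: ExpressionAtlas,
    target_tissue: str,
    threshold: float = 10.0,
    epsilon: float | str = "auto",
) -> set[str]:
    """Genes whose minimal ratio toward the target is >= threshold."""
    ratios = min_ratio_profile(atlas, target_tissue, epsilon)
    return set(ratios.index[ratios >= threshold])


def overlap_fraction(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """|A ∩ B| / |A| — e.g. the share of a biased set that is gonad-dependent."""
    set_a, set_b = set(set_a), set(set_b)
    if not set_a:
        raise UsageError("set_a must be non-empty")
    return len(set_a & set_b) / len(set_a)
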
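"""Testis-development time-course analysis.

Pipeline: log2 + quantile normalization across arrays, per-gene linear
model over developmental conditions, empirical-Bayes moderated t for
each later condition against the earliest one (four-day larvae in the
study design this emulates), Benjamini–Hochberg q-values per contrast,
and the q<0.1 up-regulated gene set used downstream.  Also provides the
per-timepoint X-vs-autosome global expression comparison and ΔΔCt
relative quantification for qRT-PCR validation data.

Moderated t
-----------
Per gene the residual variance ``s²`` around condition means has
``d = n − c`` degrees of freedom.  The gene-wise variances are modelled
as scaled-F around a prior ``s0²`` with ``d0`` prior degrees of freedom;
``(d0, s0²)`` are estimated from the marginal distribution of
``log s²`` by moment matching (digamma mean, trigamma variance — the
classical estimator for this hierarchy).  The posterior variance
``s̃² = (d0·s0² + d·s²)/(d0 + d)`` replaces ``s²`` in the t statistic,
which then has ``d0 + d`` degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import UsageError, ValidationError
from .enrichment import bh_fdr, bonferroni
from .io import GeneCatalog, QpcrTable, TimeCourse


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def quantile_normalize(frame: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common (mean) empirical distribution.

    Ties within a column receive the mean of the reference values they
    span (standard mean-of-sorted-rows scheme).
    """
    values = frame.to_numpy(dtype=float)
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    reference = sorted_vals.mean(axis=1)
    out = np.empty_like(values)
    ranks = np.empty_like(order)
    rows = np.arange(values.shape[0])[:, None]
    np.put_along_axis(ranks, order, rows, axis=0)
    out = reference[ranks]
    # average reference values over tied entries, per column
    for j in range(values.shape[1]):
        col = values[:, j]
        uniq, inv = np.unique(col, return_inverse=True)
        if uniq.size < col.size:
            sums = np.bincount(inv, weights=out[:, j])
            counts = np.bincount(inv)
            out[:, j] = (sums / counts)[inv]
    return pd.DataFrame(out, index=frame.index, columns=frame.columns)


def normalize_arrays(tc: TimeCourse) -> TimeCourse:
    """log2-transform then quantile-normalize the sample columns."""
    if (tc.frame.to_numpy() <= 0).any():
        raise ValidationError("normalize_arrays requires strictly positive intensities")
    logged = np.log2(tc.frame)
    return TimeCourse(quantile_normalize(logged), tc.samples.copy(), log_scale=True)


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------

def _invert_trigamma(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on a log-safe start)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y  # asymptotic trigamma(x) ~ 1/x + 1/(2x^2)
    for _ in range(60):
        f = special.polygamma(1, x) - y
        step = f / special.polygamma(2, x)
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < 1e-12 * max(1.0, x):
            return float(x_new)
        x = x_new
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match ``(d0, s0²)`` from gene-wise sample variances.

    Uses the log-variance hierarchy: if ``s² | σ² ~ σ² χ²_d / d`` and
    ``1/σ² ~ χ²_{d0}/(d0 s0²)``, then ``Var[log s²] = ψ'(d/2) + ψ'(d0/2)``
    and ``E[log s²] = log s0² + ψ(d/2) − ψ(d0/2) + log(d0/d)``.
    Returns ``(inf, geometric-mean-variance)`` when the observed spread
    is no larger than the sampling spread (complete shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size < 2:
        return np.inf, float(positive.mean()) if positive.size else 0.0
    z = np.log(positive)
    excess = z.var(ddof=1) - special.polygamma(1, df / 2.0)
    if excess <= 0:
        d0 = np.inf
        s02 = float(np.exp(z.mean() - special.polygamma(0, df / 2.0) + np.log(df / 2.0)))
    else:
        d0 = 2.0 * _invert_trigamma(float(excess))
        s02 = float(
            np.exp(
                z.mean()
                - special.polygamma(0, df / 2.0)
                + special.polygamma(0, d0 / 2.0)
                - np.log(d0 / df)
            )
        )
    return float(d0), s02


def squeeze_variances(
    s2: np.ndarray, df: int, d0: float, s02: float
) -> np.ndarray:
    """Posterior variances ``(d0 s0² + d s²)/(d0 + d)``."""
    if np.isinf(d0):
        return np.full_like(np.asarray(s2, dtype=float), s02)
    return (d0 * s02 + df * np.asarray(s2, dtype=float)) / (d0 + df)


@dataclass
class FoldChangeMatrix:
    """log2 fold changes vs the earliest condition, with companion stats.

    All frames are genes × later-condition labels; ``q`` is BH-adjusted
    within each contrast column.  ``d0``/``s02`` record the fitted
    variance prior; ``df_total = d0 + df_resid`` is the t df.
    """

    log2fc: pd.DataFrame
    t: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    reference: str
    d0: float
    s02: float
    df_resid: int

    @property
    def contrasts(self) -> pd.Index:
        return self.log2fc.columns


def _condition_label(condition: tuple[int, str]) -> str:
    day, stage = condition
    return f"d{day}{stage[:1]}"


def fold_change_vs_earliest(
    tc_norm: TimeCourse, moderated: bool = True
) -> FoldChangeMatrix:
    """Differential expression of each later condition vs the earliest.

    Expects log2-scale (normalized) data.  Residual variance is pooled
    per gene across all conditions (linear model on condition means);
    with ``moderated=False`` the empirical-Bayes squeeze is disabled and
    the statistic is the ordinary pooled t.
    """
    conditions = tc_norm.conditions
    groups = {c: tc_norm.frame[tc_norm.samples_of(c)].to_numpy() for c in conditions}
    sizes = {c: g.shape[1] for c, g in groups.items()}
    if min(sizes.values()) < 2:
        raise UsageError("every condition needs at least 2 replicates for inference")
    n_total = sum(sizes.values())
    df_resid = n_total - len(conditions)

    means = {c: g.mean(axis=1) for c, g in groups.items()}
    rss = np.zeros(len(tc_norm.frame))
    for c, g in groups.items():
        rss += ((g - means[c][:, None]) ** 2).sum(axis=1)
    s2 = rss / df_resid

    if moderated:
        d0, s02 = estimate_variance_prior(s2, df_resid)
    else:
        d0, s02 = 0.0, float("nan")
    s2_post = s2 if d0 == 0.0 else squeeze_variances(s2, df_resid, d0, s02)
    df_total = df_resid if np.isinf(d0) else df_resid + d0

    ref = conditions[0]
    fc, tstat, pval, qval = {}, {}, {}, {}
    for c in conditions[1:]:
        label = _condition_label(c)
        delta = means[c] - means[ref]
        se = np.sqrt(s2_post * (1.0 / sizes[c] + 1.0 / sizes[ref]))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, delta / se, 0.0)
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
        fc[label], tstat[label], pval[label] = delta, t, p
        qval[label] = bh_fdr(p)
    index = tc_norm.frame.index
    return FoldChangeMatrix(
        log2fc=pd.DataFrame(fc, index=index),
        t=pd.DataFrame(tstat, index=index),
        p=pd.DataFrame(pval, index=index),
        q=pd.DataFrame(qval, index=index),
        reference=_condition_label(ref),
        d0=float(d0),
        s02=float(s02),
        df_resid=int(df_resid),
    )


def upregulated_set(fc: FoldChangeMatrix, q_threshold: float = 0.1) -> set[str]:
    """Genes with q below threshold and positive log2 FC at >=1 contrast."""
    hit = ((fc.q.to_numpy() < q_threshold) & (fc.log2fc.to_numpy() > 0)).any(axis=1)
    return set(fc.log2fc.index[hit])


# ---------------------------------------------------------------------------
# global X vs autosome profile
# ---------------------------------------------------------------------------

def x_vs_autosome_profile(tc_norm: TimeCourse, catalog: GeneCatalog) -> pd.DataFrame:
    """Per-condition X vs autosome comparison of global expression.

    For each condition: median and quartiles of the per-gene mean
    normalized signal in the X-linked and autosomal groups, the
    X − autosome median difference, a two-sided rank-sum
    (Mann–Whitney) p, and Bonferroni adjustment across the conditions
    of this profile.
    """
    genes = tc_norm.frame.index.intersection(catalog.gene_ids)
    arms = catalog.arms.loc[genes]
    x_genes = genes[(arms == "X").to_numpy()]
    a_genes = genes[(arms != "X").to_numpy()]
    if len(x_genes) == 0 or len(a_genes) == 0:
        raise UsageError("need both X-linked and autosomal genes in the time course")
    rows = []
    for cond in tc_norm.conditions:
        cols = tc_norm.samples_of(cond)
        per_gene = tc_norm.frame[cols].mean(axis=1)
        x_vals = per_gene.loc[x_genes].to_numpy()
        a_vals = per_gene.loc[a_genes].to_numpy()
        p = float(stats.mannwhitneyu(x_vals, a_vals, alternative="two-sided").pvalue)
        rows.append(
            {
                "condition": _condition_label(cond),
                "day": cond[0],
                "stage": cond[1],
                "x_q1": float(np.percentile(x_vals, 25)),
                "x_median": float(np.median(x_vals)),
                "x_q3": float(np.percentile(x_vals, 75)),
                "auto_q1": float(np.percentile(a_vals, 25)),
                "auto_median": float(np.median(a_vals)),
                "auto_q3": float(np.percentile(a_vals, 75)),
                "median_diff": float(np.median(x_vals) - np.median(a_vals)),
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bonferroni(out["p"])
    return out


# ---------------------------------------------------------------------------
# qRT-PCR relative quantification
# ---------------------------------------------------------------------------

def qpcr_relative(qt: QpcrTable, reference_sample: str) -> pd.DataFrame:
    """2^(−ΔΔCt) relative expression against a loading control and a
    designated reference sample (whose value is 1 by construction).

    ΔCt = Ct_target − Ct_reference per (gene, sample); ΔΔCt subtracts the
    gene's ΔCt in the reference sample.
    """
    df = qt.frame.copy()
    df["delta_ct"] = df["ct_target"] - df["ct_reference"]
    ref = df[df["sample_id"] == reference_sample].set_index("gene_id")["delta_ct"]
    missing = set(df["gene_id"]) - set(ref.index)
    if missing:
        raise ValidationError(
            f"gene(s) missing the reference sample {reference_sample!r}: {sorted(missing)}"
        )
    df["ddct"] = df["delta_ct"] - df["gene_id"].map(ref)
    df["relative_expression"] = 2.0 ** (-df["ddct"])
    return df[["gene_id", "sample_id", "delta_ct", "ddct", "relative_expression"]]
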
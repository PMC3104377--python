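"""Tabular data model and TSV I/O for the analysis pipeline.

All interchange happens through TSV tables (gzip accepted transparently).
The in-memory containers are thin, validated wrappers around pandas
objects:

* :class:`GeneCatalog` — gene → chromosome-arm assignment, the universe
  for every enrichment test.  Only the five major euchromatic arms plus
  chromosome 4 are retained; genes mapped to Y or unplaced scaffolds are
  dropped at load time with a logged count.
* :class:`ExpressionAtlas` — genes × tissues nonnegative intensities
  (FlyAtlas-style panel).
* :class:`TimeCourse` — genes × samples intensities with per-sample
  metadata (day, developmental stage, replicate).
* :class:`BindingProfile` — genes × chromatin proteins continuous scores
  (ChIP/DamID fold enrichments; may be negative log-ratios and may carry
  missing values, which mark a gene as unassessed for that protein),
  plus per-protein thresholds and role tags.
* :class:`QpcrTable` — paired target/loading-control Ct values.

Matrices keep their input row order: loaders never reorder genes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, UsageError, ValidationError

logger = logging.getLogger("xbias")

#: Closed chromosome-arm vocabulary (Release-5 major arms + chromosome 4).
ARMS: tuple[str, ...] = ("X", "2L", "2R", "3L", "3R", "4")

#: Arms pooled as "autosomes" in X-vs-autosome contrasts (chromosome 4 kept).
AUTOSOMES: tuple[str, ...] = ("2L", "2R", "3L", "3R", "4")

#: Closed vocabulary of chromatin-protein roles.
ROLES: tuple[str, ...] = ("silencing", "activation")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GeneCatalog:
    """Mapping of gene ids to chromosome arms.

    Parameters
    ----------
    frame
        DataFrame indexed by gene id with a single column ``arm``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if "arm" not in self.frame.columns:
            raise ValidationError("catalog frame must have an 'arm' column")
        if self.frame.empty:
            raise ValidationError("gene catalog is empty")
        dup = self.frame.index[self.frame.index.duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate gene_id in catalog: {dup[0]!r}")
        bad = set(self.frame["arm"]) - set(ARMS)
        if bad:
            raise ValidationError(f"arm outside vocabulary {ARMS}: {sorted(bad)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def arms(self) -> pd.Series:
        return self.frame["arm"]

    def genes_on(self, arm: str) -> pd.Index:
        if arm == "autosomes":
            return self.frame.index[self.frame["arm"].isin(AUTOSOMES)]
        return self.frame.index[self.frame["arm"] == arm]

    def arm_counts(self) -> pd.Series:
        return self.frame["arm"].value_counts().reindex(ARMS, fill_value=0)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class ExpressionAtlas:
    """Genes × tissues intensity matrix, arbitrary nonnegative units."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.frame.index, "gene_id")
        _check_unique(self.frame.columns, "tissue label")
        if self.frame.isna().any().any():
            raise ValidationError("atlas contains missing values")
        if (self.frame.to_numpy() < 0).any():
            raise ValidationError("atlas intensities must be nonnegative")

    @property
    def tissues(self) -> pd.Index:
        return self.frame.columns

    @property
    def gene_ids(self) -> pd.Index:
        return self.frame.index


@dataclass
class TimeCourse:
    """Genes × samples intensity matrix with per-sample metadata.

    ``samples`` is indexed by sample name with columns ``day`` (int),
    ``stage`` (free text, e.g. feeding/wandering) and ``replicate`` (int).
    The earliest condition — minimal ``(day, stage)`` in stage order
    feeding < wandering < other — is the reference for fold changes.
    """

    frame: pd.DataFrame
    samples: pd.DataFrame
    #: post-normalization data live on the log2 scale, where negative
    #: values are legitimate; raw intensities must be nonnegative.
    log_scale: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.frame.index, "gene_id")
        _check_unique(self.frame.columns, "sample")
        if self.frame.isna().any().any():
            raise ValidationError("time course contains missing values")
        if not self.log_scale and (self.frame.to_numpy() < 0).any():
            raise ValidationError("time-course intensities must be nonnegative")
        missing = set(self.frame.columns) - set(self.samples.index)
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)}")
        self.samples = self.samples.loc[self.frame.columns]
        if self.n_conditions < 2:
            raise ValidationError("time course needs at least two conditions")
        low = self.replicate_counts()
        if (low < 3).any():
            logger.warning(
                "conditions with fewer than 3 replicates: %s",
                dict(low[low < 3]),
            )

    @property
    def conditions(self) -> list[tuple[int, str]]:
        """Distinct (day, stage) conditions in temporal order."""
        order = {"feeding": 0, "wandering": 1}
        conds = {
            (int(d), str(s))
            for d, s in zip(self.samples["day"], self.samples["stage"])
        }
        return sorted(conds, key=lambda c: (c[0], order.get(c[1], 2), c[1]))

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def earliest(self) -> tuple[int, str]:
        return self.conditions[0]

    def samples_of(self, condition: tuple[int, str]) -> list[str]:
        day, stage = condition
        mask = (self.samples["day"] == day) & (self.samples["stage"] == stage)
        return list(self.samples.index[mask])

    def replicate_counts(self) -> pd.Series:
        return pd.Series(
            {f"d{d}{s[:1]}": len(self.samples_of((d, s))) for d, s in self.conditions}
        )

    @property
    def gene_ids(self) -> pd.Index:
        return self.frame.index


@dataclass
class BindingProfile:
    """Genes × chromatin proteins continuous binding scores.

    Missing scores mean the gene was not assessed for that protein and is
    excluded pairwise from downstream analyses.
    """

    scores: pd.DataFrame
    thresholds: pd.Series
    roles: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.scores.index, "gene_id")
        _check_unique(self.scores.columns, "protein")
        for protein in self.scores.columns:
            if protein not in self.thresholds.index:
                raise ValidationError(f"no threshold for protein {protein!r}")
            if not np.isfinite(self.thresholds[protein]):
                raise ValidationError(f"non-finite threshold for {protein!r}")
            if protein not in self.roles.index:
                raise ValidationError(f"no role for protein {protein!r}")
            if self.roles[protein] not in ROLES:
                raise ValidationError(
                    f"role for {protein!r} must be one of {ROLES}, "
                    f"got {self.roles[protein]!r}"
                )

    @property
    def proteins(self) -> pd.Index:
        return self.scores.columns

    @property
    def gene_ids(self) -> pd.Index:
        return self.scores.index

    def assessed(self, protein: str) -> pd.Index:
        """Genes with a (non-missing) score for *protein*."""
        if protein not in self.scores.columns:
            raise UsageError(f"unknown protein {protein!r}")
        col = self.scores[protein]
        return col.index[col.notna()]


@dataclass
class QpcrTable:
    """Paired target / loading-control Ct values per (gene, sample)."""

    frame: pd.DataFrame  # columns: gene_id, sample_id, ct_target, ct_reference

    REQUIRED = ("gene_id", "sample_id", "ct_target", "ct_reference")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.frame.columns)
        if missing:
            raise FormatError(f"qPCR table missing columns: {sorted(missing)}")
        vals = self.frame[["ct_target", "ct_reference"]].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValidationError("Ct values must be finite")
        dup = self.frame.duplicated(subset=["gene_id", "sample_id"])
        if dup.any():
            row = self.frame[dup].iloc[0]
            raise ValidationError(
                f"duplicate (gene, sample) pair: ({row['gene_id']}, {row['sample_id']})"
            )


def _check_unique(index: pd.Index, what: str) -> None:
    dup = index[index.duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate {what}: {dup[0]!r}")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_catalog(path: str | Path) -> GeneCatalog:
    """Read a gene catalog TSV with header columns ``gene_id``, ``arm``.

    Rows whose arm is outside the closed vocabulary (Y, scaffolds, ...)
    are dropped and counted in the log.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "arm"):
        if col not in df.columns:
            raise FormatError(f"catalog {path}: missing column {col!r}")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"catalog {path}: duplicate gene_id {dup.iloc[0]!r}")
    keep = df["arm"].isin(ARMS)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("read_catalog: dropped %d gene(s) outside arm vocabulary", n_dropped)
    df = df[keep]
    if df.empty:
        raise ValidationError(f"catalog {path}: no genes on recognized arms")
    return GeneCatalog(df.set_index("gene_id")[["arm"]])


def _read_numeric_matrix(path: str | Path, allow_na: bool) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: expected gene_id column plus data columns")
    gene_col = raw.columns[0]
    genes = raw[gene_col]
    data = raw.drop(columns=[gene_col])
    out = {}
    for col in data.columns:
        converted = pd.to_numeric(data[col].replace("", np.nan), errors="coerce")
        bad = converted.isna() & ~(allow_na & data[col].isin(("", "NA", "NaN", "nan")))
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise FormatError(
                f"{path}: non-numeric cell {data[col].iloc[i]!r} "
                f"at row {genes.iloc[i]!r}, column {col!r}"
            )
        out[col] = converted
    frame = pd.DataFrame(out)
    frame.index = pd.Index(genes, name="gene_id")
    return frame


def read_matrix(
    path: str | Path,
    kind: str,
    meta: str | Path | Mapping | None = None,
) -> ExpressionAtlas | TimeCourse | BindingProfile:
    """Read a genes × samples TSV as one of the typed matrices.

    Parameters
    ----------
    path
        TSV file, first column gene ids, remaining columns samples.
    kind
        One of ``atlas``, ``timecourse``, ``binding``.
    meta
        Sidecar metadata (mapping, or path to JSON/YAML).  Required for
        ``timecourse`` (per-sample ``day``/``stage``/``replicate``) and
        ``binding`` (per-protein ``threshold`` and ``role``).
    """
    if kind == "atlas":
        return ExpressionAtlas(_read_numeric_matrix(path, allow_na=False))
    if kind == "timecourse":
        frame = _read_numeric_matrix(path, allow_na=False)
        meta_map = _load_sidecar(meta, "timecourse")
        samples = pd.DataFrame.from_dict(meta_map, orient="index")
        samples.index.name = "sample"
        return TimeCourse(frame, samples)
    if kind == "binding":
        frame = _read_numeric_matrix(path, allow_na=True)
        meta_map = _load_sidecar(meta, "binding")
        thresholds = pd.Series(
            {p: float(m["threshold"]) for p, m in meta_map.items()}, name="threshold"
        )
        roles = pd.Series({p: m["role"] for p, m in meta_map.items()}, name="role")
        return BindingProfile(frame, thresholds, roles)
    raise UsageError(f"unknown matrix kind {kind!r}")


def read_qpcr(path: str | Path) -> QpcrTable:
    """Read a qPCR Ct table (gene_id, sample_id, ct_target, ct_reference)."""
    df = pd.read_csv(path, sep="\t")
    return QpcrTable(df)


def _load_sidecar(meta, kind: str) -> Mapping:
    if meta is None:
        raise UsageError(f"kind={kind!r} requires sidecar metadata")
    if isinstance(meta, Mapping):
        return meta
    text = Path(meta).read_text()
    if str(meta).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


# ---------------------------------------------------------------------------
# writers & helpers
# ---------------------------------------------------------------------------

def write_result_table(records, path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write records (DataFrame or iterable of dicts) as a deterministic TSV.

    Column order is the given/declared order; floats use 6 significant
    digits so re-running on identical input is byte-identical.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        df = pd.DataFrame(records, columns=columns)
        if columns is None and records:
            df = df[list(records[0].keys())]
    if columns is not None:
        df = df.reindex(columns=list(columns))
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def write_json_summary(summary: Mapping, path: str | Path) -> None:
    """Mirror headline statistics as sorted, indented JSON."""
    Path(path).write_text(json.dumps(_jsonable(summary), indent=2, sort_keys=True) + "\n")


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj)] if isinstance(obj, set) else [
            _jsonable(v) for v in obj
        ]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def collapse_probes(frame: pd.DataFrame, gene_ids: Iterable[str]) -> pd.DataFrame:
    """Collapse a probe-level matrix to gene level by per-gene median.

    ``gene_ids`` gives the gene of each row (probes with ambiguous mapping
    are expected to be excluded upstream).  The number of collapsed groups
    is logged.  Output keeps first-appearance gene order.
    """
    gene_ids = pd.Index(list(gene_ids), name="gene_id")
    if len(gene_ids) != len(frame):
        raise UsageError("gene_ids must have one entry per probe row")
    grouped = frame.groupby(gene_ids, sort=False).median()
    n_multi = int((pd.Series(gene_ids).value_counts() > 1).sum())
    if n_multi:
        logger.info("collapse_probes: %d gene(s) collapsed from multiple probes", n_multi)
    return grouped


def write_catalog(catalog: GeneCatalog, path: str | Path) -> None:
    catalog.frame.reset_index().to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_matrix(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g", lineterminator="\n")
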
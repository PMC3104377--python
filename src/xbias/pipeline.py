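"""End-to-end orchestration: simulate → bias → represent → timecourse → chromatin.

A single config (YAML/JSON mapping) drives the run; every stage writes
its tables under the output directory and the headline numbers are
collected into ``report.json`` / ``report.tsv``.  Runs are idempotent
for a fixed seed, a MANIFEST records stage completion, and every number
in the report is recomputable from the referenced stage outputs.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .bias import DEFAULT_THRESHOLDS, bias_table, biased_gene_set
from .chromatin import (
    binding_enrichment,
    expression_binding_correlation,
    inverse_correlation_report,
)
from .enrichment import chisq_category_table, x_vs_autosomes
from .errors import ConfigError, UsageError, XbiasError
from .io import (
    read_catalog,
    read_matrix,
    write_catalog,
    write_json_summary,
    write_matrix,
    write_result_table,
)
from .simulate import SimConfig, generate_all
from .timecourse import (
    fold_change_vs_earliest,
    normalize_arrays,
    upregulated_set,
    x_vs_autosome_profile,
)

logger = logging.getLogger("xbias")


class StageError(XbiasError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def induced_fraction(n_induced: int, n_assayed: int) -> int:
    """Integer percentage of assayed genes scored as induced.

    The percentage is truncated to the integer part (474 of 501 assayed
    genes = 94.61% is reported as 94), matching how such headline
    percentages are conventionally printed.
    """
    if n_assayed <= 0:
        raise UsageError("n_assayed must be positive")
    if not 0 <= n_induced <= n_assayed:
        raise UsageError("need 0 <= n_induced <= n_assayed")
    return int(math.floor(100.0 * n_induced / n_assayed))


def load_config(source: str | Path | Mapping | None) -> dict:
    """Load a run config from a mapping or a YAML/JSON path."""
    if source is None:
        return {}
    if isinstance(source, Mapping):
        return dict(source)
    path = Path(source)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    loaded = yaml.safe_load(path.read_text())
    if loaded is None:
        return {}
    if not isinstance(loaded, Mapping):
        raise ConfigError("config must be a mapping")
    return dict(loaded)


def _load_inputs(cfg: dict, out: Path, seed: int | None) -> dict:
    if "inputs" in cfg:
        paths = cfg["inputs"]
        for key in ("catalog", "atlas", "timecourse", "binding"):
            if key in paths and not Path(paths[key]).exists():
                raise ConfigError(f"input file for {key!r} not found: {paths[key]}")
        data = {"catalog": read_catalog(paths["catalog"])}
        data["atlas"] = read_matrix(paths["atlas"], "atlas")
        data["timecourse"] = read_matrix(
            paths["timecourse"], "timecourse", paths.get("timecourse_meta")
        )
        data["binding"] = read_matrix(paths["binding"], "binding", paths.get("binding_meta"))
        data["truth"] = None
        data["sim_config"] = None
        return data
    sim_kwargs = dict(cfg.get("synthetic", {}))
    if seed is not None:
        sim_kwargs["seed"] = seed
    sim_config = SimConfig(**sim_kwargs)
    data = generate_all(sim_config)
    data["sim_config"] = sim_config
    write_catalog(data["catalog"], out / "catalog.tsv")
    write_matrix(data["atlas"].frame, out / "atlas.tsv")
    write_matrix(data["timecourse"].frame, out / "timecourse.tsv")
    write_matrix(data["binding"].scores, out / "binding.tsv")
    data["truth"].reset_index().to_csv(
        out / "truth.tsv", sep="\t", index=False, float_format="%.6g", lineterminator="\n"
    )
    return data


def run_all(
    config: str | Path | Mapping | None = None,
    out_dir: str | Path = "xbias_out",
    seed: int | None = None,
) -> dict:
    """Run every stage in dependency order and return the report dict."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = seed if seed is not None else int(cfg.get("seed", 0))
    manifest: list[str] = []
    report: dict = {"software_version": __version__, "seed": seed}
    stage = "config"
    try:
        stage = "inputs"
        data = _load_inputs(cfg, out, seed)
        catalog, atlas = data["catalog"], data["atlas"]
        if data["sim_config"] is not None:
            report["resolved_config"] = data["sim_config"].to_dict()
        else:
            report["resolved_config"] = cfg
        _done(manifest, out, stage)

        stage = "bias"
        targets = list(cfg.get("bias", {}).get("targets", ["testis"]))
        epsilon = cfg.get("bias", {}).get("epsilon", "auto")
        sets: dict[tuple[str, float], set] = {}
        for tissue in targets:
            table = bias_table(atlas, tissue, epsilon)
            write_result_table(table, out / f"bias_{tissue}.tsv")
            for thr in DEFAULT_THRESHOLDS:
                sets[(tissue, thr)] = biased_gene_set(atlas, tissue, thr, epsilon)
        _done(manifest, out, stage)

        stage = "represent"
        rows = []
        headline_repr: dict = {}
        for (tissue, thr), genes in sorted(sets.items()):
            if not genes:
                continue
            res = x_vs_autosomes(genes, catalog)
            d = res.as_dict()
            d.update({"tissue": tissue, "bias_threshold": thr})
            rows.append(d)
            headline_repr.setdefault(tissue, {})[f">={int(thr)}"] = {
                "representation_ratio": res.representation_ratio,
                "p_under": res.p_under,
                "p_over": res.p_over,
            }
        write_result_table(pd.DataFrame(rows), out / "representation.tsv")
        report["x_representation"] = headline_repr
        _done(manifest, out, stage)

        stage = "timecourse"
        tc_norm = normalize_arrays(data["timecourse"])
        fc = fold_change_vs_earliest(tc_norm)
        up = upregulated_set(fc, float(cfg.get("timecourse", {}).get("q_threshold", 0.1)))
        profile = x_vs_autosome_profile(tc_norm, catalog)
        fc_out = fc.log2fc.copy()
        write_matrix(fc_out, out / "foldchange.tsv")
        (out / "upregulated.txt").write_text("\n".join(sorted(up)) + "\n")
        write_result_table(profile, out / "x_vs_autosome.tsv")
        report["n_upregulated"] = len(up)
        report["x_vs_autosome_min_p_adjusted"] = (
            float(profile["p_adjusted"].min()) if len(profile) else float("nan")
        )
        _done(manifest, out, stage)

        stage = "chisq"
        # bias-category composition (testis target) of the up-regulated set,
        # X vs autosomes: the headline category-table test
        if up and targets:
            tissue = targets[0]
            table = bias_table(atlas, tissue, epsilon).set_index("gene_id")
            members = table.loc[table.index.intersection(pd.Index(sorted(up)))]
            arms = catalog.arms.loc[members.index]
            order = ["<2", ">=2", ">=5", ">=10"]
            cx = members[arms == "X"]["category"].value_counts().reindex(order, fill_value=0)
            ca = members[arms != "X"]["category"].value_counts().reindex(order, fill_value=0)
            try:
                stat, df, p = chisq_category_table(cx.to_numpy(), ca.to_numpy())
                report["category_chisq"] = {"statistic": stat, "df": df, "p": p}
            except UsageError:
                report["category_chisq"] = None
            high = float(
                (members[arms != "X"]["category"] == ">=10").mean()
            ) if (arms != "X").any() else float("nan")
            high_x = float(
                (members[arms == "X"]["category"] == ">=10").mean()
            ) if (arms == "X").any() else float("nan")
            report["highbias_fraction_upregulated"] = {"X": high_x, "autosomes": high}
        _done(manifest, out, stage)

        stage = "chromatin"
        bp = data["binding"]
        correlations = expression_binding_correlation(fc, bp)
        write_result_table(
            pd.DataFrame([c.as_dict() for c in correlations]), out / "correlations.tsv"
        )
        inverse = inverse_correlation_report(correlations)
        enrich_rows = []
        for (tissue, thr), genes in sorted(sets.items()):
            if thr != 2.0 or not genes:
                continue
            for protein in bp.proteins:
                for res in binding_enrichment(bp, protein, genes, catalog, f"{tissue}>=2"):
                    enrich_rows.append(res.as_dict())
        write_result_table(pd.DataFrame(enrich_rows), out / "binding_enrichment.tsv")
        report["inverse_correlation"] = inverse
        _done(manifest, out, stage)

        stage = "report"
        in_situ = cfg.get("in_situ")
        if in_situ:
            report["induced_gene_percentage"] = induced_fraction(
                int(in_situ["n_induced"]), int(in_situ["n_assayed"])
            )
        write_json_summary(report, out / "report.json")
        flat = _flatten(report)
        write_result_table(
            pd.DataFrame({"key": list(flat), "value": [flat[k] for k in flat]}),
            out / "report.tsv",
        )
        _done(manifest, out, stage)
    except XbiasError:
        _write_manifest(manifest, out, complete=False)
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        _write_manifest(manifest, out, complete=False)
        raise StageError(stage, exc) from exc
    _write_manifest(manifest, out, complete=True)
    return report


def _done(manifest: list[str], out: Path, stage: str) -> None:
    logger.info("stage %s complete", stage)
    manifest.append(stage)
    _write_manifest(manifest, out, complete=False)


def _write_manifest(manifest: list[str], out: Path, complete: bool) -> None:
    lines = [f"complete: {str(complete).lower()}", "stages:"]
    lines += [f"  - {s}" for s in manifest]
    (out / "MANIFEST").write_text("\n".join(lines) + "\n")


def _flatten(obj, prefix: str = "") -> dict:
    flat: dict = {}
    if isinstance(obj, Mapping):
        for k, v in obj.items():
            key = f"{prefix}.{k}" if prefix else str(k)
            flat.update(_flatten(v, key))
        return flat
    if isinstance(obj, (list, tuple)):
        return {prefix: ";".join(map(str, obj))}
    return {prefix: obj}
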
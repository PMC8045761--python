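"""End-to-end orchestration: contrasts -> gene sets -> sequence features -> clustering.

A run is driven by a :class:`PipelineConfig` (loadable from a flat TOML file,
every key overridable from the CLI) and writes a deterministic artifact tree:
contrast tables, one TSV per gene-set label plus a count summary, per-gene
sequence features with two frequency tables (cold and normal-temperature
translational sets against the transcriptome background), cluster leaf orders
for the cold transcriptional and translational set unions, a human-readable
markdown report, and a manifest listing every artifact with its SHA-256 hash.
Identical config + inputs produce identical hashes.

Stage failures abort with a stage-named :class:`PipelineError`; whatever was
already written is moved into a ``quarantine/`` subdirectory so a partial run
is never mistaken for a complete one.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import tomllib
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Any

import pandas as pd

from . import cluster as _cluster
from .contrasts import Thresholds, write_contrast_tsv
from .gene_sets import GeneSetLabel, assemble_gene_sets, write_gene_sets
from .io import read_signal_matrix, read_transcripts, read_transcripts_table
from .seq_features import UorfMode, feature_frequency, feature_table, kozak_call, find_uorfs

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "load_config", "run_pipeline", "render_report"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    signals: str = ""
    samples: str = ""
    transcripts: str = ""  # flat TSV; or "<fasta>:<gff3>" for genome + annotation
    out: str = "polysel_out"
    fold_min: float = 1.5
    expr_sum_min: float = 10.0
    alpha: float = 0.05
    sig_metric: str = "q"
    expr_basis: str = "mean_sum"
    test: str = "pooled"
    uorf_mode: str = "CONTAINED"
    isoform_rule: str = "first"
    distance: str = "PEARSON"
    linkage: str = "AVERAGE"
    pseudocount: float = 1.0
    seed: int = 0

    def thresholds(self) -> Thresholds:
        return Thresholds(
            fold_min=self.fold_min,
            expr_sum_min=self.expr_sum_min,
            alpha=self.alpha,
            sig_metric=self.sig_metric,
        )


def load_config(path: str | Path, **overrides: Any) -> PipelineConfig:
    """Load a flat TOML config; keyword overrides win over file values."""
    data = tomllib.loads(Path(path).read_text())
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**data)
    overrides = {k: v for k, v in overrides.items() if v is not None}
    return replace(cfg, **overrides)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_transcripts(config: PipelineConfig):
    source = config.transcripts
    if ":" in source and not Path(source).exists():
        fasta, gff = source.split(":", 1)
        return read_transcripts(fasta, gff, config.isoform_rule)
    return read_transcripts_table(source, config.isoform_rule)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage; return the artifact manifest (also written to disk)."""
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def fail(stage: str, exc: Exception):
        quarantine = out / "quarantine"
        quarantine.mkdir(exist_ok=True)
        for p in written:
            if p.exists():
                shutil.move(str(p), quarantine / p.name)
        raise PipelineError(stage, str(exc)) from exc

    # --- load -------------------------------------------------------------
    try:
        for name, p in (("signals", config.signals), ("samples", config.samples)):
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"{name} path missing or not found: {p!r}")
        matrix = read_signal_matrix(config.signals, config.samples)
    except Exception as exc:
        fail("load", exc)

    thresholds = config.thresholds()

    # --- contrasts + gene sets -------------------------------------------
    try:
        sets, contrasts = assemble_gene_sets(
            matrix, thresholds,
            pseudocount=config.pseudocount, expr_basis=config.expr_basis,
            test=config.test,
        )
        for name, results in contrasts.items():
            p = out / f"contrast_{name}.tsv"
            write_contrast_tsv(results, p)
            written.append(p)
        written.extend(write_gene_sets(sets, contrasts, out))
    except Exception as exc:
        fail("contrasts", exc)

    # --- sequence features ------------------------------------------------
    freq_rows: dict[str, Any] = {}
    if config.transcripts:
        try:
            models = _load_transcripts(config)
            mode = UorfMode(config.uorf_mode)
            features = feature_table(models, mode)
            p = out / "features.tsv"
            features.to_csv(p, sep="\t", index=False)
            written.append(p)
            calls = {m.gene_id: kozak_call(m) for m in models}
            uorfs = {
                m.gene_id: len(find_uorfs(m.utr5, m.cds, mode)) for m in models
            }
            universe = set(matrix.genes)
            tables = {
                "frequency_cold": {
                    "COLD_DOWN_TL": sets[GeneSetLabel.COLD_DOWN_TL],
                    "COLD_UP_TL": sets[GeneSetLabel.COLD_UP_TL],
                },
                "frequency_nt": {
                    "NT_UP_TL": sets[GeneSetLabel.NT_UP_TL],
                    "NT_DOWN_TL": sets[GeneSetLabel.NT_DOWN_TL],
                },
            }
            for name, group in tables.items():
                table = feature_frequency(group, calls, uorfs, universe)
                tsv, js = out / f"{name}.tsv", out / f"{name}.json"
                table.to_tsv(tsv)
                table.to_json(js)
                written.extend([tsv, js])
                freq_rows[name] = table.rows
        except Exception as exc:
            fail("features", exc)

    # --- clustering -------------------------------------------------------
    cluster_orders: dict[str, list[str]] = {}
    try:
        groups = {
            "cluster_cold_tx": sorted(
                sets[GeneSetLabel.COLD_DOWN_TX] | sets[GeneSetLabel.COLD_UP_TX]
            ),
            "cluster_cold_tl": sorted(
                sets[GeneSetLabel.COLD_DOWN_TL] | sets[GeneSetLabel.COLD_UP_TL]
            ),
        }
        gene_index = {g: i for i, g in enumerate(matrix.genes)}
        for name, members in groups.items():
            if len(members) < 2:
                logger.info("%s: fewer than 2 genes, skipping clustering", name)
                continue
            rows = [gene_index[g] for g in members]
            standardized = _cluster.log_zscore(
                matrix.values[rows, :], config.pseudocount
            )
            result = _cluster.hcluster(
                standardized,
                distance=_cluster.DistanceMetric(config.distance),
                linkage=_cluster.Linkage(config.linkage),
                labels=members,
            )
            order_path = out / f"{name}_leaf_order.tsv"
            pd.DataFrame({"gene_id": result.leaf_labels}).to_csv(
                order_path, sep="\t", index=False
            )
            tree_path = out / f"{name}_tree.json"
            result.to_json(tree_path)
            written.extend([order_path, tree_path])
            cluster_orders[name] = result.leaf_labels
    except Exception as exc:
        fail("cluster", exc)

    # --- report + manifest ------------------------------------------------
    try:
        report = {
            "set_counts": {lbl.value: len(s) for lbl, s in sets.items()},
            "frequency_tables": freq_rows,
            "cluster_orders": cluster_orders,
        }
        report_json = out / "report.json"
        report_json.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        written.append(report_json)
        report_md = out / "report.md"
        report_md.write_text(render_report(report))
        written.append(report_md)
    except Exception as exc:
        fail("report", exc)

    manifest = {
        "artifacts": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(set(written))
        }
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def render_report(report: dict[str, Any]) -> str:
    lines = ["# polysel run report", "", "## Regulated gene-set sizes", ""]
    lines += [
        f"- {label}: {count}" for label, count in sorted(report["set_counts"].items())
    ]
    for name, rows in report.get("frequency_tables", {}).items():
        lines += ["", f"## {name}", "",
                  "| gene set | strong % | adequate % | weak % | no 5'-UTR % | uORF % | n |",
                  "|---|---|---|---|---|---|---|"]
        for label, row in rows.items():
            cells = [
                row["strong_pct"], row["adequate_pct"], row["weak_pct"],
                row["no_utr_pct"], row["uorf_pct"], row["n"],
            ]
            rendered = " | ".join("NA" if c is None else str(c) for c in cells)
            lines.append(f"| {label} | {rendered} |")
    for name, order in report.get("cluster_orders", {}).items():
        lines += ["", f"## {name}", "", f"{len(order)} genes; leaf order starts: "
                  + ", ".join(order[:8]) + ("..." if len(order) > 8 else "")]
    return "\n".join(lines) + "\n"
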
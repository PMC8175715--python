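"""End-to-end pipeline driver.

Ties the stages together from a :class:`RunConfig` (paths + stage
parameters), writes every stage output as TSV with reproducibility
headers, and emits a JSON run report with counts, parameters, the seed
and SHA-256 hashes of the inputs.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import dataclass, field, fields
from pathlib import Path

from . import __version__
from .containers import MicrodissectionSet
from .exceptions import ConfigError
from .io import (
    read_expression_tsv,
    read_survival_tsv,
    read_table_tsv,
    write_table_tsv,
)
from .score import mesenchymal_score_all, stroma_epithelium_logfc
from .screen import SelectionThresholds, prognostic_z_all, select_candidates
from .cluster import cut_and_label_emt, hierarchical_cluster


@dataclass
class RunConfig:
    """Paths and stage parameters for a full pipeline run."""

    bulk: str
    epithelium: str
    stroma: str
    survival: str | None = None
    cellline_panel: str | None = None
    marker_genes: list[str] = field(default_factory=list)
    outdir: str = "emtscreen_out"
    bulk_log2: bool = True
    pseudocount: float = 1.0
    aggregation: str = "ratio_of_means"
    exclude_self: bool = True
    transform: str = "raw"
    ms_min: float = 0.3
    log_ratio_max: float = 0.0
    z_min: float = 1.96
    distance: str = "one_minus_pearson"
    linkage: str = "average"
    k: int = 2
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as handle:
            raw = json.load(handle)
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown run-config fields: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        required = {"bulk": self.bulk, "epithelium": self.epithelium, "stroma": self.stroma}
        for name, path in required.items():
            if path is None or not Path(path).exists():
                raise ConfigError(f"input path for {name!r} does not exist: {path}")
        for name, path in (("survival", self.survival), ("cellline_panel", self.cellline_panel)):
            if path is not None and not Path(path).exists():
                raise ConfigError(f"input path for {name!r} does not exist: {path}")
        SelectionThresholds(self.ms_min, self.log_ratio_max, self.z_min)


def _sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(config: RunConfig, quiet: bool = True) -> dict:
    """Run logfc -> score -> coxz -> select (-> cluster), write outputs,
    return the run report.

    A survival table is required for z-scores and selection; a cell-line
    panel triggers the clustering stage.  Any stage failure aborts with
    the stage name attached.
    """
    import sys

    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = _time.time()
    report: dict = {
        "tool": f"emtscreen {__version__}",
        "seed": config.seed,
        "parameters": {
            f.name: getattr(config, f.name)
            for f in fields(config)
            if f.name not in ("bulk", "epithelium", "stroma", "survival", "cellline_panel")
        },
        "input_hashes": {},
        "counts": {},
        "stages": [],
    }
    for name in ("bulk", "epithelium", "stroma", "survival", "cellline_panel"):
        path = getattr(config, name)
        if path is not None:
            report["input_hashes"][name] = _sha256(path)

    def log(stage, message=""):
        if not quiet:
            print(f"[emtscreen +{_time.time() - started:6.1f}s] {stage} {message}",
                  file=sys.stderr)

    def run_stage(name, fn):
        log(name, "...")
        try:
            result = fn()
        except Exception as exc:
            raise type(exc)(f"stage {name!r} failed: {exc}") from exc
        report["stages"].append(name)
        return result

    meta = {"seed": config.seed, "parameters": report["parameters"]}

    def load_inputs():
        epithelium = read_expression_tsv(config.epithelium)
        stroma = read_expression_tsv(config.stroma)
        micro = MicrodissectionSet(
            epithelium=epithelium,
            stroma=stroma,
            pairing=list(zip(epithelium.columns, stroma.columns)),
            log2=config.bulk_log2,
        )
        return read_expression_tsv(config.bulk), micro

    bulk, micro = run_stage("load", load_inputs)

    log_ratio = run_stage(
        "logfc",
        lambda: stroma_epithelium_logfc(micro, config.pseudocount, config.aggregation),
    )
    write_table_tsv(log_ratio.to_frame(), outdir / "log_ratio.tsv", meta)

    scores = run_stage(
        "score",
        lambda: mesenchymal_score_all(bulk, log_ratio, exclude_self=config.exclude_self),
    )
    write_table_tsv(scores, outdir / "score_table.tsv", meta)
    report["counts"]["genes"] = int(len(scores))
    report["counts"]["genes_scored"] = int(scores["mesenchymal_score"].notna().sum())

    if config.survival is not None:
        survival = read_survival_tsv(config.survival)
        z_table = run_stage(
            "coxz", lambda: prognostic_z_all(bulk, survival, transform=config.transform)
        )
        write_table_tsv(z_table, outdir / "z_table.tsv", meta)
        thresholds = SelectionThresholds(config.ms_min, config.log_ratio_max, config.z_min)
        candidates = run_stage(
            "select", lambda: select_candidates(scores, z_table, thresholds)
        )
        out = scores.join(z_table[["z"]]).rename(columns={"z": "cox_z"})
        out["selected"] = out.index.isin(candidates.table.index)
        write_table_tsv(out, outdir / "candidates.tsv", meta)
        report["counts"]["candidates"] = len(candidates)
        report["counts"]["genes_with_z"] = int(z_table["z"].notna().sum())

    if config.cellline_panel is not None:
        panel = read_expression_tsv(config.cellline_panel)
        markers = config.marker_genes or None

        def cluster_stage():
            tree = hierarchical_cluster(
                panel, gene_subset=markers, distance=config.distance,
                linkage=config.linkage,
            )
            labels = cut_and_label_emt(
                tree, panel, marker_set=markers or list(panel.index), k=config.k
            )
            return tree, labels

        tree, labels = run_stage("cluster", cluster_stage)
        write_table_tsv(
            labels.is_emt_prone().to_frame().join(labels.labels),
            outdir / "cellline_clusters.tsv",
            meta,
        )
        (outdir / "cellline_tree.nwk").write_text(tree.to_newick() + "\n")
        report["counts"]["emt_prone_lines"] = int(labels.is_emt_prone().sum())

    report["runtime_s"] = round(_time.time() - started, 2)
    with open(outdir / "run_report.json", "w") as handle:
        json.dump(report, handle, indent=2, default=str)
    log("done", f"report at {outdir / 'run_report.json'}")
    return report
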
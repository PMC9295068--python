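"""End-to-end orchestration: quant -> stats -> gene aggregation -> hit
calling -> QC, from either FASTQ or a precomputed count matrix.

Every stage output is a pure function of (inputs, config, seed); result
files (TSV/JSON) are byte-identical across reruns on the same inputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .countmatrix import CONDITIONS, CountMatrix, assemble_count_matrix
from .diffabund import guide_stats
from .geneagg import aggregate_genes
from .hitcall import HitCallConfig, hit_report
from .library import SgRNALibrary, build_spacer_index, load_library
from .qc import qc_report, write_qc_report
from .quant import QuantConfig, quantify_sample

DEFAULT_COMPARISONS = [
    ("lenvatinib_cell", "control_cell"),
    ("primary_tumor", "control_cell"),
    ("lung_metastasis", "control_cell"),
]


class PipelineConfigError(ValueError):
    """Invalid pipeline configuration, caught before any compute."""


@dataclass
class PipelineConfig:
    """Inputs, comparisons and stage options for one pipeline run.

    Exactly one of ``counts_path`` (with ``samples_path``) or
    ``fastq_paths`` (sample_id -> FASTQ file, with ``samples_path``)
    must be provided alongside ``library_path``.
    """

    library_path: str | Path
    out_dir: str | Path
    samples_path: str | Path | None = None
    counts_path: str | Path | None = None
    fastq_paths: dict[str, str] = field(default_factory=dict)
    spacer_length: int = 20
    quant: QuantConfig | None = None
    hitcall: HitCallConfig | None = None
    comparisons: list[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_COMPARISONS)
    )
    one_sided: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        quant = QuantConfig(**raw["quant"]) if "quant" in raw else None
        hc = HitCallConfig(**raw["hitcall"]) if "hitcall" in raw else None
        comparisons = [tuple(c) for c in raw.get("comparisons", DEFAULT_COMPARISONS)]
        return cls(
            library_path=raw["library"],
            out_dir=raw.get("out_dir", "screenforge_out"),
            samples_path=raw.get("samples"),
            counts_path=raw.get("counts"),
            fastq_paths=raw.get("fastq", {}),
            spacer_length=raw.get("spacer_length", 20),
            quant=quant,
            hitcall=hc,
            comparisons=comparisons,
            one_sided=raw.get("one_sided", False),
            seed=raw.get("seed", 0),
        )

    def resolved(self) -> dict:
        return {
            "version": __version__,
            "library": str(self.library_path),
            "samples": str(self.samples_path),
            "counts": str(self.counts_path) if self.counts_path else None,
            "fastq": {k: str(v) for k, v in self.fastq_paths.items()},
            "spacer_length": self.spacer_length,
            "quant": vars(self.quant) if self.quant else None,
            "hitcall": vars(self.hitcall) if self.hitcall else None,
            "comparisons": [list(c) for c in self.comparisons],
            "one_sided": self.one_sided,
            "seed": self.seed,
        }


def _validate(cfg: PipelineConfig, meta: pd.DataFrame) -> None:
    declared = set(meta["condition"])
    for treated, control in cfg.comparisons:
        for cond in (treated, control):
            if cond not in declared:
                raise PipelineConfigError(
                    f"comparison references undeclared condition {cond!r}; "
                    f"declared: {sorted(declared)}"
                )
    unknown = declared - set(CONDITIONS) - {"unknown"}
    if unknown:
        raise PipelineConfigError(
            f"sample sheet conditions {sorted(unknown)} are not recognized "
            f"(expected among {CONDITIONS})"
        )


def _load_counts(cfg: PipelineConfig, library: SgRNALibrary, log: list) -> CountMatrix:
    meta = pd.read_csv(cfg.samples_path, sep="\t", index_col="sample_id", dtype=str)
    _validate(cfg, meta)
    if cfg.counts_path:
        cm = CountMatrix.from_tsv(cfg.counts_path, cfg.samples_path)
        extra = set(cm.sgrna_ids) - set(library.sgrna_ids)
        if extra:
            raise PipelineConfigError(
                f"count matrix rows not in library: {sorted(extra)[:5]}"
            )
        # keep library row order
        cm = CountMatrix(
            cm.counts.reindex([g for g in library.sgrna_ids if g in cm.counts.index]),
            cm.sample_meta,
        )
        log.append({"stage": "load_counts", "n_guides": len(cm.sgrna_ids),
                    "n_samples": len(cm.sample_ids)})
        return cm
    if not cfg.fastq_paths:
        raise PipelineConfigError("config needs counts or fastq inputs")
    index = build_spacer_index(library)
    qcfg = cfg.quant or QuantConfig(spacer_length=library.spacer_length)
    per_sample, tallies = {}, {}
    for sample_id in meta.index:
        if sample_id not in cfg.fastq_paths:
            raise PipelineConfigError(f"no FASTQ declared for sample {sample_id!r}")
        counts, tally = quantify_sample(cfg.fastq_paths[sample_id], index, qcfg)
        per_sample[sample_id] = counts
        tallies[sample_id] = tally
    log.append({"stage": "quant", "tallies": tallies})
    return assemble_count_matrix(per_sample, meta, library.sgrna_ids)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages and write results under ``cfg.out_dir``.

    Layout: out/{counts.tsv,qc/qc_report.json,guides/<cmp>.tsv,
    genes/<cmp>.tsv,hits/hit_report.json,run_log.json,
    resolved_config.json}.  Any stage error aborts with the stage name;
    an INCOMPLETE marker is left in the run directory until the run
    finishes.
    """
    out = Path(cfg.out_dir)
    for sub in ("qc", "guides", "genes", "hits"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    marker = out / "INCOMPLETE"
    marker.write_text("run in progress or aborted\n")
    log: list = []
    t0 = time.perf_counter()
    stage = "load_library"
    try:
        library = load_library(cfg.library_path, spacer_length=cfg.spacer_length)
        log.append({"stage": stage, "n_guides": len(library), "seed": cfg.seed})

        stage = "counts"
        cm = _load_counts(cfg, library, log)
        cm.to_tsv(out / "counts.tsv")

        stage = "qc"
        report = qc_report(cm)
        write_qc_report(report, out / "qc" / "qc_report.json")

        stage = "diffabund"
        per_comparison: dict[str, pd.DataFrame] = {}
        for treated, control in cfg.comparisons:
            stats = guide_stats(cm, treated, control, sf_method="auto")
            per_comparison[treated] = stats
            name = f"{treated}_vs_{control}"
            stats.drop(columns=["all_zero"]).to_csv(
                out / "guides" / f"{name}.tsv", sep="\t", float_format="%.6g"
            )
            log.append({"stage": "diffabund", "comparison": name,
                        "n_guides": len(stats)})

        stage = "gene_agg"
        for (treated, control), stats in zip(cfg.comparisons, per_comparison.values()):
            genes = aggregate_genes(stats, library, one_sided=cfg.one_sided)
            genes.to_csv(
                out / "genes" / f"{treated}_vs_{control}.tsv",
                sep="\t",
                float_format="%.6g",
            )
            log.append({"stage": "gene_agg", "comparison": f"{treated}_vs_{control}",
                        "n_targets": len(genes)})

        stage = "hitcall"
        hits = hit_report(per_comparison, cm, library, cfg.hitcall)
        (out / "hits" / "hit_report.json").write_text(
            json.dumps(hits, indent=2, default=str)
        )
        log.append({"stage": "hitcall", "n_core_guides": len(hits["core_guides"]),
                    "n_core_genes": len(hits["core_genes"]),
                    "n_trend_guides": len(hits["trend_guides"])})
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    (out / "resolved_config.json").write_text(
        json.dumps(cfg.resolved(), indent=2)
    )
    elapsed = time.perf_counter() - t0
    (out / "run_log.json").write_text(
        json.dumps({"stages": log, "elapsed_s": round(elapsed, 3)}, indent=2)
    )
    marker.unlink()
    return {"out_dir": str(out), "hits": hits, "qc": report, "log": log}
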
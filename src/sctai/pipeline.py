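"""End-to-end orchestration: gene ages -> QC -> normalization -> DEGs ->
TAI/pTAI -> phylostratum profiles -> enrichment, from one config file.

Stages communicate through files (TSV / MatrixMarket) so any stage can be
re-run or audited in isolation; a JSON manifest records parameters, seeds,
and the cell/gene counts at every stage.  Re-running with the same config
produces identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .degs import select_upregulated_degs, shared_unique_partition
from .enrichment import ps_enrichment
from .io import attach_annotation, read_annotation, read_mtx_dir, write_mtx_dir
from .phylostrata import (
    GeneAgeMap,
    assign_gene_ages,
    build_phylostratum_index,
    read_hit_table,
    read_node_table,
    read_taxon_table,
)
from .profiles import compare_ps_expression, mean_expression_by_ps, relative_expression
from .qc import downsample_cells, filter_cells, filter_genes, normalize_total
from .tai import compute_partial_tai, compute_tai, compare_tai

__all__ = ["RunConfig", "ConfigError", "StageError", "run_pipeline"]

log = logging.getLogger("sctai.pipeline")


class ConfigError(ValueError):
    """Invalid run configuration (raised before any stage executes)."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run."""

    counts_dir: str
    annotation: str
    outdir: str
    nodes: str | None = None
    taxa: str | None = None
    hits: str | None = None
    focal_taxon: str | None = None
    ages: str | None = None  # precomputed gene-age TSV, alternative to hits
    seed: int = 0
    evalue: float = 1e-3
    min_genes: int = 200
    max_genes: int = 5000
    max_mito: float = 0.20
    min_cells: int = 10
    scale_factor: float = 1e6
    logfc_min: float = 0.25
    min_diff_pct: float = 0.25
    alpha: float = 0.05
    detect_frac: float = 0.10
    downsample: Sequence[int] = (50, 100)
    background_types: Sequence[str] | None = None
    venn_types: Sequence[str] | None = None
    mito_prefix: str = "mt-"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat: dict = {}
        for section in ("inputs", "params"):
            flat.update(raw.pop(section, {}) or {})
        flat.update(raw)
        unknown = set(flat) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)

    def validate(self) -> None:
        if self.evalue <= 0:
            raise ConfigError("evalue must be > 0")
        if not (0 <= self.min_genes < self.max_genes):
            raise ConfigError("need 0 <= min_genes < max_genes")
        if not (0 <= self.max_mito <= 1):
            raise ConfigError("max_mito must lie in [0, 1]")
        if self.min_cells < 1:
            raise ConfigError("min_cells must be >= 1")
        if self.scale_factor <= 0:
            raise ConfigError("scale_factor must be > 0")
        if not (0 <= self.min_diff_pct <= 1):
            raise ConfigError("min_diff_pct must lie in [0, 1]")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must lie in (0, 1)")
        if not (0 <= self.detect_frac <= 1):
            raise ConfigError("detect_frac must lie in [0, 1]")
        if any(int(n) < 1 for n in self.downsample):
            raise ConfigError("downsample sizes must be >= 1")
        if self.ages is None and not (self.nodes and self.taxa and self.hits and self.focal_taxon):
            raise ConfigError("provide either 'ages' or all of nodes/taxa/hits/focal_taxon")
        for name in ("counts_dir", "annotation", "nodes", "taxa", "hits", "ages"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} path does not exist: {p}")


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    Raises :class:`ConfigError` before any stage runs if the config is
    invalid, and :class:`StageError` naming the failing stage otherwise.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    manifest: dict = {
        "sctai_version": __version__,
        "seed": int(config.seed),
        "parameters": {
            k: (list(v) if isinstance(v, (tuple, list)) else v)
            for k, v in asdict(config).items()
        },
        "counts": {},
    }
    counts = manifest["counts"]
    stage = "init"
    try:
        stage = "gene_ages"
        if config.ages is not None:
            ages = GeneAgeMap.from_tsv(config.ages, evalue_threshold=config.evalue)
        else:
            index = build_phylostratum_index(
                read_node_table(config.nodes), read_taxon_table(config.taxa)
            )
            ages = assign_gene_ages(
                read_hit_table(config.hits), index,
                evalue_threshold=config.evalue, focal_taxon=config.focal_taxon,
            )
            counts["n_strata"] = index.n_strata
        ages.to_tsv(outdir / "ages.tsv")
        counts["n_genes_age_mapped"] = len(ages)
        counts["n_queries_discarded"] = int(ages.n_discarded)
        log.info("gene ages: %d mapped, %d discarded", len(ages), ages.n_discarded)

        stage = "load_counts"
        adata = read_mtx_dir(config.counts_dir)
        adata = attach_annotation(adata, read_annotation(config.annotation))
        counts["n_cells_input"] = int(adata.n_obs)
        counts["n_genes_input"] = int(adata.n_vars)

        stage = "qc"
        adata = filter_cells(
            adata, min_genes=config.min_genes, max_genes=config.max_genes,
            max_mito=config.max_mito, mito_prefix=config.mito_prefix,
        )
        adata = filter_genes(adata, min_cells=config.min_cells)
        counts["n_cells_qc"] = int(adata.n_obs)
        counts["n_genes_qc"] = int(adata.n_vars)
        log.info("QC: %d cells, %d genes retained", adata.n_obs, adata.n_vars)
        qc_dir = outdir / "qc"
        write_mtx_dir(adata, qc_dir)
        _write_tsv(
            adata.obs[["cell_type", "n_genes_detected", "mito_fraction"]]
            .rename_axis("cell_id").reset_index(),
            qc_dir / "annotation_qc.tsv",
        )

        stage = "normalize"
        norm = normalize_total(adata, scale_factor=config.scale_factor)

        stage = "degs"
        degs_all = select_upregulated_degs(
            norm, mode="all", logfc_min=config.logfc_min,
            min_diff_pct=config.min_diff_pct, alpha=config.alpha,
        )
        degs_specific = select_upregulated_degs(
            norm, mode="specific", logfc_min=config.logfc_min,
            min_diff_pct=config.min_diff_pct, alpha=config.alpha,
        )
        degs_all.to_tsv(outdir / "degs_all.tsv")
        degs_specific.to_tsv(outdir / "degs_specific.tsv")
        counts["n_degs_per_type"] = {t: len(g) for t, g in sorted(degs_all.sets.items())}
        counts["n_degs_specific_per_type"] = {
            t: len(g) for t, g in sorted(degs_specific.sets.items())
        }

        stage = "tai"
        tai = compute_tai(norm, ages)
        tai_df = pd.DataFrame(
            {"cell_id": norm.obs_names, "cell_type": norm.obs["cell_type"].values,
             "tai": tai.values}
        )
        _write_tsv(tai_df, outdir / "tai.tsv")
        ptai = compute_partial_tai(norm, ages)
        _write_tsv(ptai.rename_axis("cell_id").reset_index(), outdir / "ptai.tsv")
        comp = compare_tai(tai, norm.obs["cell_type"])
        _write_tsv(comp["pairwise"], outdir / "tai_compare.tsv")
        counts["kruskal_p"] = comp["kruskal_p"]

        spec_union = set().union(*degs_specific.sets.values()) if degs_specific.sets else set()
        if spec_union:
            tai_spec = compute_tai(norm, ages, gene_subset=spec_union)
            _write_tsv(
                pd.DataFrame({"cell_id": norm.obs_names, "tai": tai_spec.values}),
                outdir / "tai_specific.tsv",
            )
            comp_s = compare_tai(tai_spec, norm.obs["cell_type"])
            _write_tsv(comp_s["pairwise"], outdir / "tai_compare_specific.tsv")

        rng = np.random.default_rng(config.seed)
        for n_down in config.downsample:
            sub = downsample_cells(norm.obs["cell_type"], int(n_down), rng)
            comp_d = compare_tai(tai.iloc[sub], norm.obs["cell_type"].iloc[sub])
            _write_tsv(comp_d["pairwise"], outdir / f"tai_compare_down{int(n_down)}.tsv")

        stage = "profiles"
        mean_mat = mean_expression_by_ps(norm, ages)
        _write_tsv(mean_mat, outdir / "ps_mean.tsv", index=True)
        if mean_mat.shape[1] >= 2:
            _write_tsv(relative_expression(mean_mat), outdir / "ps_re.tsv", index=True)
        _write_tsv(compare_ps_expression(norm, ages), outdir / "ps_compare.tsv")

        stage = "venn"
        types = list(config.venn_types or sorted(norm.obs["cell_type"].unique())[:3])
        if len(types) >= 2:
            venn = shared_unique_partition(
                norm, ages.ages, types, detect_frac=config.detect_frac
            )
            _write_tsv(venn, outdir / "venn.tsv", index=True)

        stage = "enrichment"
        background = list(config.background_types or sorted(degs_all.sets))
        enr = ps_enrichment(degs_all, background, ages, alpha=config.alpha)
        _write_tsv(enr, outdir / "enrichment.tsv")
        counts["n_enrichment_significant"] = int(enr["significant"].sum())

        stage = "manifest"
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except ConfigError:
        raise
    except BaseException as exc:  # noqa: BLE001 - re-raise with stage context
        log.error("stage %s failed: %s", stage, exc)
        raise StageError(stage, exc) from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    return outdir
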
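"""Config-driven end-to-end orchestration.

Runs the stages in analysis order — (optional) simulation, normalization,
per-replicate sgRNA fits, gene scoring and hit calling, optional rank
comparison and gene-set enrichment — and writes every artifact plus a
manifest (config echo, seed, version, per-file sha256) sufficient to
reproduce the run bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .genescore import AnalysisConfig
from .io import ScreenFormatError, read_gene_results, read_gmt
from .model import PooledScreenModel
from .simulate import SimConfig, write_simulation

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass(frozen=True)
class RunConfig:
    """Full description of one pipeline run.

    Exactly one of ``inputs`` (paths to counts/library/samples TSVs) or
    ``simulate`` (an embedded :class:`SimConfig`) must be given.
    """

    outdir: str
    inputs: dict | None = None
    simulate: SimConfig | None = None
    analysis: AnalysisConfig = AnalysisConfig()
    gene_sets: str | None = None  # GMT path for enrichment
    compare_with: str | None = None  # gene-results TSV of another screen
    log_level: str = "INFO"
    seed: int | None = None

    def __post_init__(self):
        if (self.inputs is None) == (self.simulate is None):
            raise ScreenFormatError(
                ["exactly one of 'inputs' and 'simulate' must be configured"]
            )
        if self.inputs is not None:
            missing = {"counts", "library", "samples"} - set(self.inputs)
            if missing:
                raise ScreenFormatError([f"inputs missing keys: {sorted(missing)}"])

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.get("simulate")
        if sim is not None:
            sim = dict(sim)
            if "seed" not in sim and d.get("seed") is not None:
                sim["seed"] = d["seed"]
            for key in ("resistant_fitness", "efficiency_beta", "survival_range",
                        "concentrations_uM"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            d["simulate"] = SimConfig(**sim)
        if "analysis" in d and d["analysis"] is not None:
            d["analysis"] = AnalysisConfig(**d["analysis"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ScreenFormatError([f"unknown run-config keys: {sorted(unknown)}"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def from_manifest(cls, manifest_path) -> "RunConfig":
        with open(manifest_path, encoding="utf-8") as fh:
            manifest = json.load(fh)
        return cls.from_dict(manifest["config"])

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = dataclasses.asdict(self.simulate)
        d["analysis"] = dataclasses.asdict(self.analysis)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineStageError(name, exc) from exc

        return wrapped

    return deco


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all configured stages; return (and write) the run manifest."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    @_stage("load")
    def _load():
        if cfg.simulate is not None:
            model = PooledScreenModel.from_simulation(cfg.simulate, cfg.analysis)
            paths = write_simulation(
                model.counts, model.samples, model.library, model.truth, outdir / "inputs"
            )
            files.update({f"input_{k}": v for k, v in paths.items()})
            return model
        return PooledScreenModel.from_tables(
            cfg.inputs["counts"], cfg.inputs["library"], cfg.inputs["samples"], cfg.analysis
        )

    model = _load()

    @_stage("fit")
    def _fit():
        return model.fit()

    results = _fit()
    fun = results.funnel()
    logger.info(
        "funnel: %d genes -> %d tested (>=%d guides) -> %d FDR<%g -> %d CS>%g",
        fun["genes_total"],
        fun["genes_tested"],
        cfg.analysis.min_guides,
        fun["fdr_significant"],
        cfg.analysis.fdr_threshold,
        fun["strong_enriched"],
        cfg.analysis.cs_threshold,
    )

    @_stage("write_results")
    def _write():
        gene_path = outdir / "gene_results.tsv"
        results.save(gene_path)
        files["gene_results"] = str(gene_path)
        sg_path = outdir / "sgrna_results.tsv"
        results.sgrna_table.to_csv(sg_path, sep="\t", index=False, float_format="%.8g")
        files["sgrna_results"] = str(sg_path)
        v_path = outdir / "volcano.tsv"
        results.volcano_table().to_csv(v_path, sep="\t", index=False, float_format="%.8g")
        files["volcano"] = str(v_path)
        nf_path = outdir / "norm_factors.tsv"
        with open(nf_path, "w", encoding="utf-8") as fh:
            fh.write("replicate\tsample\tlibrary_size\ttmm_factor\n")
            for rep_id, nf in results.norm_factors.items():
                for s, ls, f in zip(nf.sample_ids, nf.library_size, nf.tmm_factor):
                    fh.write(f"{rep_id}\t{s}\t{ls:.8g}\t{f:.8g}\n")
        files["norm_factors"] = str(nf_path)

    _write()

    if cfg.compare_with is not None:

        @_stage("compare")
        def _cmp():
            other = read_gene_results(cfg.compare_with).set_index("gene")
            comp = results.compare_ranks(other)
            path = outdir / "rank_comparison.tsv"
            comp.to_csv(path, sep="\t", float_format="%.8g")
            files["rank_comparison"] = str(path)

        _cmp()

    if cfg.gene_sets is not None:

        @_stage("enrich")
        def _enr():
            coll = read_gmt(cfg.gene_sets)
            table = results.enrich(coll)
            path = outdir / "enrichment.tsv"
            table.to_csv(path, sep="\t", index=False, float_format="%.8g")
            files["enrichment"] = str(path)

        _enr()

    manifest = {
        "version": __version__,
        "seed": cfg.seed if cfg.seed is not None else (
            cfg.simulate.seed if cfg.simulate else None
        ),
        "config": cfg.to_dict(),
        "funnel": fun,
        "files": {k: {"path": v, "sha256": _sha256(Path(v))} for k, v in files.items()},
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
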
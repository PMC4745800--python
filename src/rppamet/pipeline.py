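"""End-to-end pipeline: derive -> validate -> network -> screen.

Given a derivation dataset (expression + RPPA), an optional independent
validation dataset, a clinical table and optional gene-set collections,
``run_pipeline`` executes the stages in order and writes one directory of
plain-text results plus a machine-readable manifest (input hashes,
thresholds, versions, seed).  Re-running with identical inputs and seed
reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .derivation import derive_all_metagenes, Metagene
from .exceptions import RppametError
from .io import (
    GeneSetCollection,
    quantile_align,
    read_clinical_table,
    read_expression_matrix,
    read_gmt,
    read_rppa_matrix,
)
from .network import build_network, enrich, enrichment_report
from .scoring import sigscore, validate_metagenes, validation_report
from .survival import forest_table, km_logrank, screen, screen_report, dichotomize_at_median

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All file paths and thresholds of one pipeline run."""

    expr: str
    rppa: str
    clinical: str | None = None
    expr_validation: str | None = None
    rppa_validation: str | None = None
    genesets: str | None = None
    out: str = "rppamet_run"
    fdr_derive: float = 0.05
    r_threshold: float = 0.5
    fdr_validate: float = 0.05
    min_overlap: int = 5
    fdr_network: float = 0.05
    fdr_screen: float = 0.05
    align_quantile: float = 0.95
    covariates: list[str] = field(default_factory=list)
    subgroup: str | None = None  # "column=value"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fdr_derive", "fdr_validate", "fdr_network", "fdr_screen"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise RppametError(f"{name} must be in (0, 1], got {v}")
        if not 0 <= self.r_threshold <= 1:
            raise RppametError(f"r_threshold must be in [0, 1], got {self.r_threshold}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineError(RppametError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory."""
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("rppamet")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run_stages(config, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_stages(config: PipelineConfig, out: Path) -> Path:
    stage = "load"
    try:
        expr = read_expression_matrix(config.expr)
        rppa = read_rppa_matrix(config.rppa)
        expr_val = rppa_val = None
        if config.expr_validation:
            expr_val = read_expression_matrix(config.expr_validation)
            expr, expr_val = quantile_align([expr, expr_val], q=config.align_quantile)
        if config.rppa_validation:
            rppa_val = read_rppa_matrix(config.rppa_validation)
        clinical = read_clinical_table(config.clinical) if config.clinical else None
        genesets = read_gmt(config.genesets) if config.genesets else None

        stage = "derive"
        logger.info("deriving metagenes from %d proteins", rppa.shape[0])
        metagenes = derive_all_metagenes(expr, rppa, fdr_threshold=config.fdr_derive)
        mg_dir = out / "metagenes"
        mg_dir.mkdir(exist_ok=True)
        for name, mg in sorted(metagenes.items()):
            mg.to_tsv(mg_dir / f"{name}.tsv")
        summary = pd.DataFrame(
            [
                {"metagene": name, "n_members": len(mg), "n_up": len(mg.up_genes),
                 "n_down": len(mg.down_genes), "n_low": mg.n_low, "n_high": mg.n_high}
                for name, mg in sorted(metagenes.items())
            ],
            columns=["metagene", "n_members", "n_up", "n_down", "n_low", "n_high"],
        )
        summary.to_csv(out / "metagenes.tsv", sep="\t", index=False)
        gmt_entries: dict[str, list[str]] = {}
        for mg in metagenes.values():
            gmt_entries.update(mg.gmt_entries())
        if gmt_entries:
            GeneSetCollection(gmt_entries).to_gmt(out / "metagenes.gmt")
        logger.info("%d/%d proteins delivered metagenes", len(metagenes), rppa.shape[0])

        stage = "validate"
        screened: list[Metagene] = list(metagenes.values())
        if metagenes and expr_val is not None and rppa_val is not None:
            results = validate_metagenes(
                list(metagenes.values()), expr_val, rppa_val,
                r_threshold=config.r_threshold, fdr_threshold=config.fdr_validate,
            )
            report = validation_report(results)
            report.to_csv(out / "validation.tsv", sep="\t")
            passed = {r.metagene_name for r in results if r.passed}
            screened = [metagenes[n] for n in sorted(passed)]
            logger.info("%d/%d metagenes passed validation", len(passed), len(metagenes))

        stage = "network"
        if metagenes:
            net = build_network(
                list(metagenes.values()), universe=expr.gene_ids,
                min_overlap=config.min_overlap, fdr_threshold=config.fdr_network,
            )
            net.tests_frame().to_csv(out / "network_tests.tsv", sep="\t", index=False)
            net.to_graphml(out / "network.graphml")
            net.to_sif(out / "network.sif")
            if genesets is not None:
                frames = [
                    enrichment_report(enrich(mg, genesets, expr.gene_ids,
                                             fdr_threshold=config.fdr_network))
                    for mg in sorted(metagenes.values(), key=lambda m: m.name)
                ]
                pd.concat(frames, ignore_index=True).to_csv(
                    out / "enrichment.tsv", sep="\t", index=False
                )

        stage = "screen"
        if clinical is not None:
            subgroup = None
            if config.subgroup:
                col, _, val = config.subgroup.partition("=")
                subgroup = (col, val)
            results = screen(
                screened, expr, clinical, covariates=config.covariates,
                fdr_threshold=config.fdr_screen, subgroup=subgroup,
            )
            screen_report(results).to_csv(out / "screen.tsv", sep="\t")
            ft = forest_table(results)
            ft.to_csv(out / "forest.tsv", sep="\t", index=False)
            _write_km_curves(screened, expr, clinical, out)

        stage = "manifest"
        inputs = {
            k: {"path": str(p), "sha256": _sha256(p)}
            for k, p in (
                ("expr", config.expr), ("rppa", config.rppa),
                ("clinical", config.clinical),
                ("expr_validation", config.expr_validation),
                ("rppa_validation", config.rppa_validation),
                ("genesets", config.genesets),
            )
            if p
        }
        manifest = {
            "rppamet_version": __version__,
            "config": config.to_dict(),
            "inputs": inputs,
            "n_metagenes_derived": len(metagenes),
            "n_metagenes_screened": len(screened),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    except PipelineError:
        raise
    except Exception as exc:
        logger.error("stage %r failed: %s", stage, exc)
        raise PipelineError(stage, exc) from exc
    return out


def _write_km_curves(metagenes, expr, clinical, out: Path) -> None:
    """Plot-ready Kaplan-Meier coordinates per metagene stratum."""
    rows = []
    shared = [s for s in clinical.sample_ids if s in set(expr.sample_ids)]
    if not shared:
        return
    sub = clinical.subset(shared)
    for mg in metagenes:
        try:
            part = dichotomize_at_median(sigscore(mg, expr).scores.loc[shared])
            curves, chi2, p = km_logrank(part, sub)
        except RppametError:
            continue
        for grp, coords in curves.items():
            for _, r in coords.iterrows():
                rows.append({"metagene": mg.name, "stratum": grp,
                             "time": r["time"], "survival": r["survival"],
                             "logrank_chi2": chi2, "logrank_p": p})
    if rows:
        pd.DataFrame(rows).to_csv(out / "km_curves.tsv", sep="\t", index=False)
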
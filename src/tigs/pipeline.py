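"""Reproducible score -> evaluate -> report runs.

A run is described by a single config (YAML on disk, :class:`RunConfig`
in memory); every run directory contains the per-sample score table, the
biomarker AUC ladder, median-split survival summaries, the fully
resolved config, and a JSON run log with the package version, a config
hash, the seed, and per-stage sample counts — enough to reproduce the
run exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .enrichment import GsvaParams
from .evaluation import compare_biomarkers, km_logrank, median_split
from .immunogenicity import NormalizationReference, score_biomarker_panel
from .io_formats import (
    read_clinical,
    read_expression_matrix,
    read_gmt,
    read_maf,
    write_scores,
)
from .signatures import apm_gene_set

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything a pipeline run depends on."""

    expr_path: str
    maf_path: str
    out_dir: str
    clinical_path: str | None = None
    apm_gmt: str | None = None
    cell_sets_gmt: str | None = None
    signature_gmt: str | None = None
    tide_path: str | None = None
    ref_min: float | None = None
    ref_max: float | None = None
    exome_size_mb: float = 38.0
    n_random_repeats: int = 100
    seed: int = 0
    gsva: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        for attr in ("expr_path", "maf_path", "clinical_path", "apm_gmt",
                     "cell_sets_gmt", "signature_gmt", "tide_path"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise PipelineError("validate", f"{attr}: no such file: {p}")
        if (self.ref_min is None) != (self.ref_max is None):
            raise PipelineError(
                "validate", "ref_min and ref_max must be given together"
            )

    def resolved(self) -> dict:
        return asdict(self)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.resolved(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute score -> evaluate -> report; returns the run directory.

    Deterministic for a fixed config (the seed is part of the config).
    Any stage failure aborts with the stage name attached.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }

    try:
        expr = read_expression_matrix(config.expr_path)
        muts = read_maf(config.maf_path)
        clinical = read_clinical(config.clinical_path) if config.clinical_path else None
        apm = read_gmt(config.apm_gmt)[0] if config.apm_gmt else apm_gene_set()
        cells = read_gmt(config.cell_sets_gmt) if config.cell_sets_gmt else None
        sigs = None
        if config.signature_gmt:
            sigs = {
                s.name.lower().replace(".", "_"): s
                for s in read_gmt(config.signature_gmt)
            }
        tide = None
        if config.tide_path:
            tide = pd.read_csv(config.tide_path, sep="\t", index_col=0).iloc[:, 0]
        log["stages"]["load"] = {
            "n_genes": expr.shape[0],
            "n_expr_samples": expr.shape[1],
            "n_mutation_records": len(muts),
        }
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001 - rewrap with the stage name
        raise PipelineError("load", str(e)) from e

    try:
        ref = None
        if config.ref_min is not None:
            ref = NormalizationReference(config.ref_min, config.ref_max)
        result, apsr = score_biomarker_panel(
            expr,
            muts,
            apm_set=apm,
            cell_type_sets=cells,
            signature_sets=sigs,
            params=GsvaParams(**config.gsva),
            ref=ref,
            exome_size_mb=config.exome_size_mb,
            seed=config.seed,
            n_random_repeats=config.n_random_repeats,
            tide=tide,
        )
        write_scores(out / "scores.tsv", result)
        apsr.to_csv(out / "apsr_scores.tsv", sep="\t", float_format="%.17g")
        log["stages"]["score"] = {"n_samples_scored": len(result)}
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("score", str(e)) from e

    if clinical is not None:
        try:
            labels = pd.Series(
                clinical.response, index=clinical.sample_ids, name="response"
            ).reindex(result.index)
            ladder = compare_biomarkers(result, labels, apsr)
            ladder.to_csv(out / "auc.tsv", sep="\t", index=False)

            km_rows = []
            for biom in ("tigs", "tmb"):
                groups = median_split(result[biom])
                km = km_logrank(groups, clinical)
                km_rows.append(
                    {
                        "biomarker": biom,
                        "logrank_statistic": km.statistic,
                        "logrank_p": km.p_value,
                        **{f"n_{g.lower()}": n for g, n in km.group_sizes.items()},
                    }
                )
            pd.DataFrame(km_rows).to_csv(out / "km_summary.tsv", sep="\t", index=False)
            log["stages"]["evaluate"] = {
                "n_labeled": int(labels.notna().sum()),
                "n_biomarkers": len(ladder),
            }
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError("evaluate", str(e)) from e

    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(config.resolved(), fh, sort_keys=True)
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    logger.info("run complete: %s", out)
    return out
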
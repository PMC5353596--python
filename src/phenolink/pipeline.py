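"""End-to-end pipeline orchestration.

Runs the three analysis stages in order — OCR extraction, heterogeneity
(clustering + TES/RV), combined-phenotype embedding — writing each stage's
outputs plus provenance sidecars and a run log.  Inputs are never mutated;
re-running with the same config and inputs reproduces every numeric output
byte for byte (timestamps live only in the run log).
"""

from __future__ import annotations

import datetime
import logging
from pathlib import Path

import pandas as pd

from . import io as _io
from .config import PipelineConfig
from .exceptions import ConfigurationError, PhenolinkError
from .heterogeneity import HeterogeneityModel
from .integrate import CombinedPhenotypeModel
from .ocr import extract_ocr

logger = logging.getLogger(__name__)


def extract_ocr_stage(
    traces, manifest: pd.DataFrame, calibration, *, smooth=True, window=5,
    detection_floor=0.1,
) -> tuple[pd.DataFrame, list[dict]]:
    """Run OCR extraction over a batch of traces; failures go to QC."""
    meta = manifest.set_index("cell_id")
    rows, qc = [], []
    for trace in traces:
        try:
            res = extract_ocr(
                trace, calibration, smooth=smooth, window=window,
                detection_floor=detection_floor,
            )
        except PhenolinkError as exc:
            qc.append({"cell_id": trace.cell_id, "error": str(exc)})
            continue
        info = meta.loc[trace.cell_id]
        rows.append(
            {
                "cell_id": trace.cell_id,
                "cell_type": info.get("cell_type", ""),
                "strain": info.get("strain", ""),
                "ocr_fmol_min": res.ocr_fmol_min,
                "slope_uM_min": res.slope_um_min,
                "r_squared": res.r_squared,
                "respirer_class": res.respirer_class,
                "sealed": res.sealed,
            }
        )
    return pd.DataFrame(rows, columns=list(_io.OCR_TABLE_COLUMNS)), qc


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute extract-ocr -> heterogeneity -> integrate; return out_dir."""
    out = Path(config.paths.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.to_dict()

    # load + validate everything before any stage runs
    manifest = _io.read_manifest(config.paths.manifest)
    n_cells = len(manifest)
    if config.clustering.k > n_cells:
        raise ConfigurationError(
            f"clustering k={config.clustering.k} exceeds the {n_cells} manifest cells"
        )
    if config.embedding.perplexity >= (n_cells - 1) / 3:
        raise ConfigurationError(
            f"perplexity {config.embedding.perplexity} too large for {n_cells} cells"
        )
    matrix, _ = _io.read_expression_matrix(config.paths.matrix)
    traces, trace_qc = _io.read_traces(
        config.paths.traces_dir, manifest, well=config.well_geometry()
    )

    stage = "extract-ocr"
    try:
        logger.info("stage %s: %d traces", stage, len(traces))
        ocr_table, ocr_qc = extract_ocr_stage(
            traces,
            manifest,
            config.calibration_model(),
            smooth=config.smoothing.enabled,
            window=config.smoothing.window,
            detection_floor=config.thresholds.detection_floor,
        )
        if len(ocr_table) == 0:
            raise PhenolinkError(
                f"no OCR values could be extracted ({len(ocr_qc)} failure(s); see QC)"
            )
        _io.write_ocr_table(ocr_table, out / "ocr_table.tsv")
        _io.write_sidecar(out / "ocr_table.tsv", {"stage": stage, "params": params})
        _io.write_json({"trace_qc": trace_qc, "extraction_qc": ocr_qc}, out / "qc.json")

        stage = "heterogeneity"
        logger.info("stage %s: k=%d", stage, config.clustering.k)
        het = HeterogeneityModel(matrix, manifest, ocr_table=ocr_table).fit(
            k=config.clustering.k,
            linkage=config.clustering.linkage,
            metric=config.clustering.metric,
        )
        clusters = het.assignment.labels.rename_axis("cell_id").reset_index()
        clusters.to_csv(out / "clusters.tsv", sep="\t", index=False, lineterminator="\n")
        enrichment = {
            "f": {g: het.enrichment.f.loc[g].to_dict() for g in het.enrichment.f.index},
            "es": {g: het.enrichment.es.loc[g].to_dict() for g in het.enrichment.es.index},
            "tes": het.enrichment.tes.to_dict(),
            "rv": het.rv_table.to_dict(orient="records"),
            "p": het.assignment.p.to_dict(),
        }
        _io.write_json(enrichment, out / "enrichment.json")
        _io.write_sidecar(out / "enrichment.json", {"stage": stage, "params": params})
        if het.comparisons is not None:
            het.comparisons.to_csv(
                out / "group_comparisons.tsv", sep="\t", index=False,
                float_format="%.6g", lineterminator="\n",
            )

        stage = "integrate"
        logger.info("stage %s", stage)
        combined = CombinedPhenotypeModel(
            het.normalized, ocr_table.set_index("cell_id"), het.assignment
        ).fit(
            n_components=config.embedding.n_components,
            perplexity=config.embedding.perplexity,
            seed=config.seed,
            z_thresh=config.thresholds.z_thresh,
            q_thresh=config.thresholds.q_thresh,
            r_thresh=config.thresholds.r_thresh,
        )
        embedding = combined.to_frame().reset_index()
        embedding.to_csv(
            out / "embedding.tsv", sep="\t", index=False,
            float_format="%.8g", lineterminator="\n",
        )
        _io.write_sidecar(out / "embedding.tsv", {"stage": stage, "params": params})
    except PhenolinkError as exc:
        raise PhenolinkError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    import phenolink

    _io.write_json(
        {
            "version": phenolink.__version__,
            "seed": config.seed,
            "params": params,
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        },
        out / "run_log.json",
    )
    return out
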
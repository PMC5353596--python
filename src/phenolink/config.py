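"""Pipeline configuration: a validating schema over the YAML config file.

Unknown keys are rejected everywhere (``extra="forbid"``), so a typo in a
config file fails fast instead of silently using a default.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .exceptions import ConfigurationError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PathsConfig(_Strict):
    traces_dir: str
    matrix: str
    manifest: str
    out_dir: str


class WellConfig(_Strict):
    volume_pl: float = Field(140.0, gt=0)
    initial_o2_um: float = Field(200.0, ge=0)


class CalibrationConfig(_Strict):
    """Either a direct (ksv, i0) pair or a two-point calibration."""

    ksv: float | None = Field(None, gt=0)
    i0: float | None = Field(None, gt=0)
    ratio_at_anoxia: float | None = None
    ratio_at_known_c: float | None = None
    known_c: float | None = None

    @model_validator(mode="after")
    def _one_source(self):
        direct = self.ksv is not None and self.i0 is not None
        two_point = all(
            v is not None for v in (self.ratio_at_anoxia, self.ratio_at_known_c, self.known_c)
        )
        if direct == two_point:
            raise ValueError(
                "calibration needs exactly one of (ksv, i0) or "
                "(ratio_at_anoxia, ratio_at_known_c, known_c)"
            )
        return self


class SmoothingConfig(_Strict):
    enabled: bool = True
    window: int = Field(5, ge=1)


class ClusteringConfig(_Strict):
    k: int = Field(10, ge=1)
    linkage: str = "ward"
    metric: str = "euclidean"


class EmbeddingConfig(_Strict):
    n_components: int = Field(3, ge=1)
    perplexity: float = Field(15.0, gt=0)


class ThresholdsConfig(_Strict):
    z_thresh: float = Field(2.5, gt=0)
    q_thresh: float = Field(0.75, gt=0, le=1)
    r_thresh: float = Field(0.5, ge=-1, le=1)
    detection_floor: float = Field(0.1, ge=0)


class PipelineConfig(_Strict):
    paths: PathsConfig
    well: WellConfig = WellConfig()
    calibration: CalibrationConfig
    smoothing: SmoothingConfig = SmoothingConfig()
    clustering: ClusteringConfig = ClusteringConfig()
    embedding: EmbeddingConfig = EmbeddingConfig()
    thresholds: ThresholdsConfig = ThresholdsConfig()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls.model_validate(raw)
        except Exception as exc:  # pydantic ValidationError
            raise ConfigurationError(f"invalid pipeline config {path}: {exc}") from exc

    def calibration_model(self):
        from .ocr import CalibrationModel, two_point_calibrate

        c = self.calibration
        if c.ksv is not None:
            return CalibrationModel(ksv=c.ksv, i0=c.i0)
        return two_point_calibrate(c.ratio_at_anoxia, c.ratio_at_known_c, c.known_c)

    def well_geometry(self):
        from .ocr import WellGeometry

        return WellGeometry(volume_pl=self.well.volume_pl, initial_o2_um=self.well.initial_o2_um)

    def to_dict(self) -> dict:
        return self.model_dump()


def load_config(path: str | Path) -> PipelineConfig:
    return PipelineConfig.from_yaml(path)
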
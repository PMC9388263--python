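"""Structured configuration for the extraction/evaluation pipeline.

A YAML file can override any block: frequency bands, synchronization-
likelihood parameters, nonlinear-descriptor parameters, segmentation and
cross-validation settings.  Unknown keys are rejected so typos fail loudly.

Example::

    segment_s: 60
    bands:
      alpha: [8, 13]
    sl: {p_ref: 0.01, l: 10, m: 10, w1: 100, w2: 410, stride: 1}
    apen: {m: 2, r_coeff: 0.2, r_mode: sd}
    higuchi: {t_min: 1, t_max: 30}
    cv: {k: 10, classifier: LSVM, select: false, fdr_mode: reported}
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import DEFAULT_BANDS, BandDef
from .connectivity import SLParams
from .nonlinear import ApEnParams, HiguchiParams
from .pipeline import PipelineSpec

__all__ = ["Config", "load_config"]


@dataclass
class Config:
    """All tunable pipeline parameters with their defaults."""

    segment_s: float = 60.0
    filter_lo: float = 0.5
    filter_hi: float = 32.0
    bands: tuple[BandDef, ...] = DEFAULT_BANDS
    sl: SLParams = field(default_factory=SLParams)
    sl_stride: int = 1
    apen: ApEnParams = field(default_factory=ApEnParams)
    higuchi: HiguchiParams = field(default_factory=HiguchiParams)
    nonlinear_max_samples: int | None = 4096
    cv_k: int = 10
    pipeline: PipelineSpec = field(default_factory=PipelineSpec)


def load_config(path: str | Path | None) -> Config:
    """Load a YAML config, overlaying defaults; None returns the defaults."""
    cfg = Config()
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {"segment_s", "filter", "bands", "sl", "apen", "higuchi",
             "nonlinear_max_samples", "cv"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    cfg.segment_s = float(raw.get("segment_s", cfg.segment_s))
    if "filter" in raw:
        cfg.filter_lo = float(raw["filter"].get("lo", cfg.filter_lo))
        cfg.filter_hi = float(raw["filter"].get("hi", cfg.filter_hi))
    if "bands" in raw:
        bands = []
        for b in cfg.bands:
            lo, hi = raw["bands"].get(b.name, (b.lo, b.hi))
            bands.append(BandDef(b.name, float(lo), float(hi)))
        cfg.bands = tuple(bands)
    if "sl" in raw:
        sl = dict(raw["sl"])
        cfg.sl_stride = int(sl.pop("stride", cfg.sl_stride))
        cfg.sl = SLParams(**{**cfg.sl.__dict__, **sl})
    if "apen" in raw:
        cfg.apen = ApEnParams(**{**cfg.apen.__dict__, **raw["apen"]})
    if "higuchi" in raw:
        cfg.higuchi = HiguchiParams(**{**cfg.higuchi.__dict__, **raw["higuchi"]})
    if "nonlinear_max_samples" in raw:
        v = raw["nonlinear_max_samples"]
        cfg.nonlinear_max_samples = None if v in (None, "null") else int(v)
    if "cv" in raw:
        cv = dict(raw["cv"])
        cfg.cv_k = int(cv.pop("k", cfg.cv_k))
        cfg.pipeline = PipelineSpec(**{**cfg.pipeline.__dict__, **cv})
    return cfg
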
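"""End-to-end orchestration: preprocess -> artifacts -> lipid -> metrics.

The pipeline is deterministic for a fixed input and configuration; each
stage logs a one-line summary (thresholds chosen, areas found) and any
stage failure is re-raised with the stage name attached.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as m
from .artifacts import detect_artifacts
from .chemogram import Chemogram, RegionOfInterest, roi_to_columns
from .errors import ChemolipidError, PipelineStageError
from .lipid import (
    HiddenLipidParams,
    combine_lipid,
    detect_hidden_lipid,
    detect_visible_lipid,
)
from .masks import BinaryMask
from .preprocess import adjust_intensity, split_channels
from .stats import AgreementResult, agreement
from .synthetic import colormap_inverse

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "compare_methods"]

log = logging.getLogger(__name__)

METRIC_COLUMNS = ("lcbi_total", "max_lcbi_2mm", "max_lcbi_4mm")


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable parameter of a pipeline run, serializable to JSON.

    A config echo is embedded in each report so a run can be reproduced
    from its output alone.
    """

    mm_per_column: float = 0.25
    roi_start_mm: float | None = None
    roi_end_mm: float | None = None
    low_saturation_frac: float = 0.01
    high_saturation_frac: float = 0.01
    min_artifact_area_px: int = 8
    artifact_cleanup: bool = False
    delta_threshold: float = 25.0
    hidden_channel: str = "green"
    window_mode: str = "sliding"
    stride_mm: float | None = None
    block_mm: float = 2.0
    percentile_method: str = "linear"
    valid_policy: str = "reclaim"
    colormap_tolerance: int = 40
    icc_form: str = "ICC2"

    def __post_init__(self) -> None:
        if self.hidden_channel not in ("red", "green", "blue"):
            raise ValueError(f"unknown hidden channel {self.hidden_channel!r}")
        if self.window_mode not in ("blocked", "sliding"):
            raise ValueError(f"unknown window mode {self.window_mode!r}")
        if self.valid_policy not in ("reclaim", "strict"):
            raise ValueError(f"unknown valid policy {self.valid_policy!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class PipelineResult:
    report: m.LcbiReport
    masks: dict[str, BinaryMask]
    block_chemogram: m.BlockChemogram
    config: PipelineConfig

    def report_dict(self) -> dict:
        d = self.report.to_dict()
        d["config"] = self.config.to_dict()
        return d


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except ChemolipidError as e:
                raise PipelineStageError(name, e) from e

        return wrapper

    return deco


def run_pipeline(chem: Chemogram, cfg: PipelineConfig) -> PipelineResult:
    """Run the full lipid-detection pipeline on one chemogram.

    Stages: channel split and contrast adjustment; artifact segmentation on
    the adjusted red channel; visible-lipid segmentation on the adjusted
    green channel; hidden-lipid recovery inside artifact regions; LCBI
    metrics, block chemogram and lipid arcs over the ROI.
    """
    roi = RegionOfInterest(
        cfg.roi_start_mm if cfg.roi_start_mm is not None else 0.0,
        cfg.roi_end_mm if cfg.roi_end_mm is not None else chem.pullback_length_mm,
    )
    roi_cols = roi_to_columns(roi, chem)

    @_stage("preprocess")
    def _preprocess():
        red, green, blue = split_channels(chem)
        channels = {"red": red, "green": green, "blue": blue}
        adj = {
            name: adjust_intensity(
                ch, cfg.low_saturation_frac, cfg.high_saturation_frac
            )
            for name, ch in channels.items()
        }
        return adj

    adj = _preprocess()

    @_stage("artifacts")
    def _artifacts():
        mask, regions = detect_artifacts(
            adj["red"], cfg.min_artifact_area_px, cleanup=cfg.artifact_cleanup
        )
        log.info("artifacts: %d regions, %d px", len(regions), mask.area)
        return mask, regions

    artifact_mask, regions = _artifacts()

    @_stage("lipid")
    def _lipid():
        visible = detect_visible_lipid(adj["green"], artifact_mask)
        hidden = detect_hidden_lipid(
            adj[cfg.hidden_channel],
            regions,
            HiddenLipidParams(cfg.delta_threshold, cfg.hidden_channel),
        )
        combined, components = combine_lipid(visible, hidden)
        log.info(
            "lipid: visible %d px, hidden %d px, %d pools",
            visible.area,
            hidden.area,
            len(components),
        )
        return visible, hidden, combined

    visible, hidden, combined = _lipid()

    @_stage("metrics")
    def _metrics():
        valid = m.valid_mask_from(artifact_mask, hidden, policy=cfg.valid_policy)
        valid_strict = m.valid_mask_from(artifact_mask, hidden, policy="strict")
        lcbi = m.lcbi_total(combined, valid, roi_cols)
        lcbi_strict = m.lcbi_total(combined, valid_strict, roi_cols)
        v2, s2 = m.max_lcbi_window(
            combined, valid, roi_cols, chem.mm_per_column, 2.0,
            mode=cfg.window_mode, stride_mm=cfg.stride_mm,
        )
        v4, s4 = m.max_lcbi_window(
            combined, valid, roi_cols, chem.mm_per_column, 4.0,
            mode=cfg.window_mode, stride_mm=cfg.stride_mm,
        )
        prob = colormap_inverse(chem.pixels, tol=cfg.colormap_tolerance)
        blocks = m.block_chemogram(
            prob, roi_cols, chem.mm_per_column, cfg.block_mm,
            cfg.percentile_method,
        )
        arcs = m.max_lipid_arc(
            combined, roi_cols, chem.degrees_per_row, chem.mm_per_column,
            cfg.block_mm,
        )
        arced = [
            dataclasses.replace(b, arc_deg=a[1])
            for b, a in zip(blocks.blocks, arcs)
        ]
        report = m.LcbiReport(
            lcbi_total=lcbi,
            max_lcbi_2mm=v2,
            max_lcbi_2mm_start_mm=s2,
            max_lcbi_4mm=v4,
            max_lcbi_4mm_start_mm=s4,
            mode=cfg.window_mode,
            roi_start_mm=roi.start_mm,
            roi_end_mm=roi.end_mm,
            lcbi_total_strict=lcbi_strict,
            blocks=arced,
        )
        return report, m.BlockChemogram(arced, blocks.block_length_mm), valid

    report, blocks, valid = _metrics()
    masks = {
        "artifact": artifact_mask,
        "lipid_visible": visible,
        "lipid_hidden": hidden,
        "lipid_combined": combined,
        "valid": valid,
    }
    return PipelineResult(report=report, masks=masks, block_chemogram=blocks,
                          config=cfg)


def compare_methods(
    table1: pd.DataFrame | str | Path,
    table2: pd.DataFrame | str | Path,
    metrics: tuple[str, ...] = METRIC_COLUMNS,
) -> dict[str, AgreementResult]:
    """Agreement panel between two per-case metric tables.

    Each table needs a ``case_id`` column plus one column per metric; rows
    are matched on ``case_id`` and every id must appear in both tables.
    Returns one :class:`AgreementResult` per metric (Wilcoxon p, ICC with
    95% CI, Bland-Altman limits, medians and quartiles).
    """
    df1 = pd.read_csv(table1) if isinstance(table1, (str, Path)) else table1
    df2 = pd.read_csv(table2) if isinstance(table2, (str, Path)) else table2
    ids1, ids2 = set(df1["case_id"]), set(df2["case_id"])
    if ids1 != ids2:
        offenders = sorted(ids1 ^ ids2)
        raise ValueError(f"unmatched case ids between tables: {offenders}")
    a = df1.set_index("case_id").sort_index()
    b = df2.set_index("case_id").sort_index()
    return {
        metric: agreement(a[metric].to_numpy(), b[metric].to_numpy())
        for metric in metrics
    }
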
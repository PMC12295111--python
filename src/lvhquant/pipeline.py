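"""End-to-end orchestration: input -> contours -> partition -> thickness ->
severity -> bull's-eye, with a machine-readable run manifest.

The learned stages are optional and replaceable: by default the pipeline
runs on truth contours (phantom input) or caller-supplied contours with
threshold scoring, which makes the full chain deterministic under a seed.
A trained U-Net / classifier can be plugged in for the predicted path.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np

from lvhquant.aha import APEX, LEVELS, build_partition
from lvhquant.bullseye import render_bullseye
from lvhquant.phantom import PhantomSpec, generate_phantom
from lvhquant.severity import score_report
from lvhquant.thickness import mae, regional_thickness

log = logging.getLogger("lvhquant.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    out_dir: str
    phantom: dict[str, Any] | None = None  # PhantomSpec overrides; None -> input_path
    input_path: str | None = None
    input_format: str | None = None
    spacing: tuple[float, float] | None = None
    landmarks: dict[str, Any] | None = None  # lv_center/anterior/inferior override
    mode: int = 49
    sampling_step: float = 1.0
    use_unet: bool = False
    unet_model: Any = None
    use_classifier: bool = False
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def digest(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "unet_model"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class RunBundle:
    out_dir: str
    outputs: dict[str, str] = field(default_factory=dict)
    manifest: dict[str, Any] = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> RunBundle:
    """Execute the configured pipeline; outputs land under ``out_dir``.

    Any stage failure aborts with the stage name; partial outputs are kept
    alongside a ``FAILED`` marker naming the stage.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    os.makedirs(config.out_dir, exist_ok=True)
    bundle = RunBundle(out_dir=config.out_dir)
    timings: dict[str, float] = {}

    def stage(name):
        def wrap(fn, *args, **kw):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kw)
            except Exception as exc:
                with open(os.path.join(config.out_dir, "FAILED"), "w") as fh:
                    fh.write(f"stage: {name}\ncause: {exc}\n")
                raise PipelineError(name, exc) from exc
            timings[name] = time.perf_counter() - t0
            log.info("stage %s done in %.2fs", name, timings[name])
            return result

        return wrap

    truth = None
    if config.phantom is not None:
        spec = PhantomSpec(**{**config.phantom, "seed": config.seed})
        stack, truth = stage("phantom")(generate_phantom, spec)
        contours = truth.contours
        landmarks = truth.landmarks
    else:
        from lvhquant.imaging_io import read_stack

        if config.input_path is None:
            raise PipelineError("input", ValueError("neither phantom spec nor input_path given"))
        stack = stage("imaging_io")(
            read_stack, config.input_path, config.input_format, config.spacing
        )
        contours = None
        landmarks = None

    if config.use_unet:
        if config.unet_model is None:
            raise PipelineError("segmentation", ValueError("use_unet requires a trained model"))
        from lvhquant.contours import ContourSet
        from lvhquant.segmentation import masks_to_contours, predict_mask

        def _segment():
            labels = stack.level_labels or ["mid"] * len(stack)
            slices = [
                masks_to_contours(predict_mask(config.unet_model, img), stack.pixel_spacing, lvl)
                for img, lvl in zip(stack.slices, labels)
            ]
            return ContourSet(slices, stack.pixel_spacing)

        contours = stage("segmentation")(_segment)
    if contours is None:
        raise PipelineError("segmentation", ValueError("no contour source: supply a phantom, "
                                                       "contours, or a U-Net model"))

    if config.landmarks is not None:
        from lvhquant.aha import LandmarkSet

        lm = config.landmarks
        landmarks = LandmarkSet(tuple(lm["lv_center"]), lm["anterior_rv_insertion"],
                                lm["inferior_rv_insertion"])
    if landmarks is None:
        raise PipelineError("landmarks", ValueError("no landmark source"))

    levels_present = sorted({sc.level for sc in contours.slices},
                            key=lambda l: (list(LEVELS) + [APEX]).index(l))
    partition = stage("partition")(build_partition, landmarks, levels_present, config.mode)

    report = stage("thickness")(regional_thickness, contours, partition, landmarks,
                                config.sampling_step)
    severity = stage("severity")(score_report, report, partition)

    p_contours = os.path.join(config.out_dir, "contours.json")
    contours.to_json(p_contours)
    p_thick = os.path.join(config.out_dir, "thickness.csv")
    report.to_csv(p_thick, partition)
    p_sev = os.path.join(config.out_dir, "severity.csv")
    severity.to_csv(p_sev)
    p_fig = os.path.join(config.out_dir, "bullseye.svg")
    stage("bullseye")(render_bullseye, severity, partition, p_fig)
    bundle.outputs.update(contours=p_contours, thickness=p_thick, severity=p_sev, bullseye=p_fig)

    if truth is not None and config.mode == 49:
        import pandas as pd

        rids = sorted(truth.rwt_truth)
        rows = {
            "thickness_mae_mm": mae([truth.rwt_truth[r] for r in rids],
                                    [report.mean_rwt[r] for r in rids]),
            "severity_agreement_pct": float(
                np.mean([severity.scores[r] == truth.severity_truth[r] for r in rids]) * 100.0
            ),
        }
        p_metrics = os.path.join(config.out_dir, "metrics.csv")
        pd.DataFrame([rows]).to_csv(p_metrics, index=False)
        bundle.outputs["metrics"] = p_metrics

    import lvhquant

    bundle.manifest = {
        "package_version": lvhquant.__version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "mode": config.mode,
        "stages": list(timings),
        "outputs": bundle.outputs,
    }
    p_manifest = os.path.join(config.out_dir, "manifest.json")
    with open(p_manifest, "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
    bundle.outputs["manifest"] = p_manifest
    return bundle
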
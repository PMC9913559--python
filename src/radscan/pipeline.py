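"""End-to-end orchestration: boxes -> curves -> shape matrices -> classifier.

``run_pipeline`` executes the whole chain on a synthetic dataset (window and
crop stages apply when starting from raw volumes; synthetic boxes are already
windowed and cropped): binarize -> ROI -> boundary -> simplify -> radial ->
shape matrix -> joint 4D tensor -> stratified folds -> SMOTE -> training ->
metrics.  Every stage logs its parameters and a digest of its output, and the
whole run is reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import balance_metrics, preprocess, radial, synthetic, unet4d
from .boundary import dp_simplify_closed, trace_boundary
from .preprocess import NoduleBox, WindowSpec
from .radial import RadialConfig, ShapeMatrix, build_shape_matrix
from .unet4d import Tensor4DSample, UNetConfig, assemble_input

log = logging.getLogger("radscan")


def _digest(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:12]


@dataclass
class PipelineConfig:
    """All stage parameters plus the global seed, as one flat record."""

    window: WindowSpec = field(default_factory=WindowSpec)
    simplify_tolerance: float = 0.8
    simplify_enabled: bool = True
    min_roi_area: int = 9
    radial: RadialConfig = field(default_factory=RadialConfig)
    unet: UNetConfig = field(default_factory=UNetConfig)
    smote: balance_metrics.SmoteConfig = field(
        default_factory=balance_metrics.SmoteConfig
    )
    synth: synthetic.SynthConfig = field(default_factory=synthetic.SynthConfig)
    n_folds: int = 10
    seed: int = 0

    def validate(self) -> None:
        """Cross-module size consistency, checked before any compute."""
        s = self.synth.box_size
        if self.radial.n_angles != s:
            raise ValueError(
                f"n_angles={self.radial.n_angles} must equal box_size={s} "
                "for the joint 4D tensor"
            )
        div = 2 ** self.unet.depth
        if s % div:
            raise ValueError(
                f"box_size={s} not divisible by 2^depth={div}"
            )

    # -- flat key=value round-trip ----------------------------------------

    _SECTIONS = ("window", "radial", "unet", "smote", "synth")

    def to_text(self) -> str:
        lines = []
        for section in self._SECTIONS:
            obj = getattr(self, section)
            for f in dataclasses.fields(obj):
                lines.append(f"{section}.{f.name} = {getattr(obj, f.name)!r}")
        for name in ("simplify_tolerance", "simplify_enabled",
                     "min_roi_area", "n_folds", "seed"):
            lines.append(f"{name} = {getattr(self, name)!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        import ast

        values: dict[str, dict] = {s: {} for s in cls._SECTIONS}
        top: dict = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            val = ast.literal_eval(val.strip())
            if "." in key:
                section, name = key.split(".", 1)
                values[section][name] = val
            else:
                top[key] = val
        return cls(
            window=WindowSpec(**values["window"]),
            radial=RadialConfig(**values["radial"]),
            unet=UNetConfig(**values["unet"]),
            smote=balance_metrics.SmoteConfig(**values["smote"]),
            synth=synthetic.SynthConfig(**values["synth"]),
            **top,
        )


def extract_shape_matrix(
    box: NoduleBox,
    radial_cfg: RadialConfig = RadialConfig(),
    simplify_tolerance: float | None = 0.8,
    min_roi_area: int = 9,
) -> ShapeMatrix:
    """Shape matrix of one nodule box.

    Per slice: Otsu binarization, largest 8-connected ROI, Moore boundary
    trace, optional closed-curve DP simplification, then the radial scan from
    the ROI centroid.  Slices with no usable ROI become zero rows.
    """
    n_slices = box.gray.shape[0]
    curves = []
    poles = {}
    for k in range(n_slices):
        mask = preprocess.binarize(box.gray[k])
        rois = preprocess.extract_rois(mask, min_area=min_roi_area,
                                       slice_index=k)
        if not rois:
            curves.append((k, None))
            continue
        roi = rois[0]  # largest component
        pole = preprocess.roi_centroid(roi)
        try:
            curve = trace_boundary(roi)
        except ValueError:
            curves.append((k, None))
            continue
        if simplify_tolerance is not None:
            curve = dp_simplify_closed(curve, simplify_tolerance, pole)
        curves.append((k, curve))
        poles[k] = pole
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return build_shape_matrix(curves, poles, radial_cfg,
                                  n_slices=n_slices)


def boxes_to_samples(
    boxes: list[NoduleBox], cfg: PipelineConfig
) -> list[Tensor4DSample]:
    simp = cfg.simplify_tolerance if cfg.simplify_enabled else None
    samples = []
    for box in boxes:
        mat = extract_shape_matrix(box, cfg.radial, simp, cfg.min_roi_area)
        samples.append(assemble_input(box, mat))
    return samples


def run_pipeline(cfg: PipelineConfig, outdir: str | Path | None = None):
    """Synthetic end-to-end run; returns the CrossValResult.

    Writes (when ``outdir`` is given) the dataset manifest, per-fold and
    pooled metric CSVs and the training histories.
    """
    cfg.validate()
    boxes, manifest = synthetic.gen_dataset(cfg.synth)
    log.info("stage=synth n=%d digest=%s", len(boxes),
             _digest(np.stack([b.gray for b in boxes])))
    samples = boxes_to_samples(boxes, cfg)
    log.info("stage=radial digest=%s",
             _digest(np.stack([s.shape_matrix for s in samples])))
    labels = [s.label for s in samples]
    plan = balance_metrics.make_folds(labels, n_folds=cfg.n_folds,
                                      seed=cfg.seed)
    log.info("stage=folds n_folds=%d", cfg.n_folds)
    result = balance_metrics.cross_validate(samples, cfg.unet, plan,
                                            cfg.smote)
    log.info("stage=cv pooled_accuracy=%.4f", result.pooled.accuracy)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest.to_csv(outdir / "manifest.csv", index=False)
        (outdir / "config.txt").write_text(cfg.to_text())
        rows = [
            {"fold": i, **m.as_percent()} for i, m in enumerate(result.per_fold)
        ]
        rows.append({"fold": "pooled", **result.pooled.as_percent()})
        pd.DataFrame(rows).to_csv(outdir / "metrics.csv", index=False)
        hist_rows = []
        for fold, hist in enumerate(result.histories):
            for epoch, h in enumerate(hist):
                hist_rows.append({"fold": fold, "epoch": epoch, **h})
        pd.DataFrame(hist_rows).to_csv(outdir / "history.csv", index=False)
    return result
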
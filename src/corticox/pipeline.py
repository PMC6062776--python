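"""End-to-end session processing: speckle -> flow -> rCBF and decays -> pO2.

A session on disk is a directory of speckle stack TIFFs (block order; the
first block is the baseline), a ROI directory, a directory of decay CSVs
named ``{index:04d}_{roi}.csv`` in acquisition order, and a calibration
JSON. ``run_pipeline`` emits contrast and correlation-time maps, rCBF and
pO2 timecourse CSVs, and a JSON run manifest.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .errors import FormatError, ParameterError
from .lifetime import roi_pO2_timecourse
from .speckle import (
    SpeckleModelParams,
    average_contrast,
    compute_contrast,
    debias_contrast,
    flow_map,
    relative_flow,
)

log = logging.getLogger("corticox.pipeline")

_DECAY_NAME = re.compile(r"^(\d+)_(.+)\.csv$")


@dataclass
class SessionConfig:
    """Everything needed to (re)process one session deterministically."""

    stack_paths: list[str]
    roi_dir: str
    out_dir: str
    calibration_path: str | None = None
    decay_dir: str | None = None
    schedule_path: str | None = None
    exposure_T: float = 5e-3
    window: int = 7
    beta: float = 1.0
    average_n: int = 45
    offset_s: float = 2e-6
    debias: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ParameterError("window must be odd and >= 3")
        if min(self.exposure_T, self.offset_s) < 0 or self.average_n < 1:
            raise ParameterError("physical quantities must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "SessionConfig":
        payload = json.loads(Path(path).read_text())
        cfg = cls(**payload)
        for p in [*cfg.stack_paths, cfg.roi_dir, cfg.calibration_path, cfg.decay_dir,
                  cfg.schedule_path]:
            if p is not None and not Path(p).exists():
                raise FormatError(f"configured path does not exist: {p}")
        return cfg


def _stack_to_flow(stack, cfg: SessionConfig):
    """Per-frame contrast -> average -> (optional debias) -> model inversion."""
    n = min(cfg.average_n, stack.n_frames)
    images = [
        compute_contrast(stack.frames[i], cfg.window, exposure_T=cfg.exposure_T)
        for i in range(n)
    ]
    avg = average_contrast(images)
    if cfg.debias:
        avg = debias_contrast(avg)
    params = SpeckleModelParams(exposure_T=cfg.exposure_T, beta=cfg.beta)
    fmap = flow_map(avg, params)
    log.info(
        "flow block: %d/%d frames averaged, %d invalid pixels",
        n, stack.n_frames, int(np.count_nonzero(~fmap.valid_mask)),
    )
    return avg, fmap


def _load_decays(decay_dir: Path):
    entries = []
    for path in sorted(decay_dir.glob("*.csv")):
        m = _DECAY_NAME.match(path.name)
        if not m:
            raise FormatError(
                f"{path.name}: decay files must be named <index>_<roi>.csv"
            )
        entries.append((int(m.group(1)), m.group(2), cio.read_decay(path)))
    entries.sort(key=lambda e: e[0])
    return [(roi, trace) for _, roi, trace in entries]


def run_pipeline(config: SessionConfig) -> dict:
    """Run the full analysis chain for one session.

    Returns a dict of output paths; all outputs are also written under
    ``config.out_dir``. Any stage failure raises with a stage-tagged
    message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, object] = {}

    try:
        stacks = [cio.read_stack(p, exposure_T=config.exposure_T)
                  for p in config.stack_paths]
        rois = cio.read_roiset(config.roi_dir)
    except Exception as exc:
        raise FormatError(f"[stage: load] {exc}") from exc

    try:
        flows = []
        for i, stack in enumerate(stacks):
            avg, fmap = _stack_to_flow(stack, config)
            cio.write_map(out / f"contrast_{i:04d}.tif", avg.K, avg.valid_mask)
            cio.write_map(out / f"tau_c_{i:04d}.tif", fmap.tau_c, fmap.valid_mask)
            flows.append((stack, fmap))
    except Exception as exc:
        raise ParameterError(f"[stage: speckle] {exc}") from exc

    try:
        baseline = flows[0][1]
        rows = []
        t_cursor = 0.0
        for stack, fmap in flows:
            block_len = min(config.average_n, stack.n_frames) / stack.frame_rate
            t_mid = t_cursor + 0.5 * block_len
            t_cursor += stack.n_frames / stack.frame_rate
            rcbf = relative_flow(fmap, baseline, rois.masks)
            joint = fmap.valid_mask & baseline.valid_mask
            for roi, value in rcbf.items():
                rows.append(
                    dict(
                        time_s=t_mid,
                        roi_id=roi,
                        rcbf=value,
                        n_valid_pixels=int(np.count_nonzero(rois.masks[roi] & joint)),
                    )
                )
        rcbf_df = pd.DataFrame(rows)
        cio.write_timecourse(out / "rcbf_timecourse.csv", rcbf_df)
        results["rcbf"] = rcbf_df
    except Exception as exc:
        raise ParameterError(f"[stage: rcbf] {exc}") from exc

    if config.decay_dir is not None:
        try:
            cal = (
                cio.read_calibration(config.calibration_path)
                if config.calibration_path
                else None
            )
            schedule = (
                cio.read_schedule(config.schedule_path) if config.schedule_path else None
            )
            decays = _load_decays(Path(config.decay_dir))
            kwargs = {"offset": config.offset_s}
            if cal is not None:
                kwargs["cal"] = cal
            if schedule is not None:
                kwargs["pattern_rate"] = schedule.pattern_rate
            po2_df = roi_pO2_timecourse(decays, **kwargs)
            n_failed = int((~po2_df["converged"]).sum())
            if n_failed:
                log.warning("%d decay fits did not converge", n_failed)
            cio.write_timecourse(out / "po2_timecourse.csv", po2_df)
            results["po2"] = po2_df
        except Exception as exc:
            raise ParameterError(f"[stage: lifetime] {exc}") from exc

    from . import __version__

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "n_stacks": len(stacks),
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["out_dir"] = str(out)
    return results
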
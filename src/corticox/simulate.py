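"""Synthetic data generators.

Every analysis module in the toolkit can be exercised against these
generators without any external data: speckle stacks with a prescribed
correlation-time map (gamma-distributed integrated intensity, shape 1/K^2),
noisy mono-exponential phosphorescence decays at prescribed pO2, and a
scripted occlusion session combining both with ground-truth timecourses.

Pixels are statistically independent: spatial speckle correlation is not
modeled, so these stacks probe estimator bias and variance, not spatial
covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation

from .errors import InfeasibleScheduleError, ParameterError
from .lifetime import DecayTrace, SternVolmerCalibration, tau_from_pO2
from .patterning import PatternSchedule, ROISet, acquisition_plan
from .speckle import FlowMap, SpeckleModelParams, SpeckleStack, contrast_from_tau

__all__ = [
    "SpeckleScenario",
    "Depolarization",
    "StrokeTimeline",
    "StrokeSession",
    "synth_speckle_stack",
    "synth_decay",
    "synth_stroke_session",
    "default_stroke_rois",
]


@dataclass
class SpeckleScenario:
    """Recipe for one synthetic speckle stack."""

    tau_c_map: np.ndarray  # seconds, per pixel
    exposure_T: float = 5e-3
    n_frames: int = 45
    mean_intensity: float = 1000.0
    frame_rate: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.tau_c_map = np.asarray(self.tau_c_map, dtype=np.float64)
        if self.tau_c_map.ndim != 2:
            raise ParameterError("tau_c_map must be 2-D")
        if np.any(self.tau_c_map <= 0):
            raise ParameterError("all correlation times must be positive")
        if self.n_frames < 1 or self.exposure_T <= 0 or self.mean_intensity <= 0:
            raise ParameterError("n_frames, exposure_T and mean_intensity must be positive")


def synth_speckle_stack(
    scenario: SpeckleScenario, rng: np.random.Generator | None = None
) -> tuple[SpeckleStack, FlowMap]:
    """Generate a speckle stack whose local contrast converges to K(T, tau_c).

    Each pixel of each frame is drawn independently from a gamma
    distribution with shape 1/K*^2 and mean ``mean_intensity``, where K* is
    the forward-model contrast of that pixel's correlation time. Returns the
    stack and the ground-truth flow map.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    params = SpeckleModelParams(exposure_T=scenario.exposure_T, beta=1.0)
    k_star = contrast_from_tau(scenario.tau_c_map, params)
    shape = 1.0 / k_star**2
    scale = scenario.mean_intensity * k_star**2  # shape * scale = mean
    frames = rng.gamma(
        np.broadcast_to(shape, (scenario.n_frames, *shape.shape)),
        np.broadcast_to(scale, (scenario.n_frames, *shape.shape)),
    )
    stack = SpeckleStack(
        frames=frames, exposure_T=scenario.exposure_T, frame_rate=scenario.frame_rate
    )
    truth = FlowMap(
        tau_c=scenario.tau_c_map.copy(),
        valid_mask=np.ones_like(scenario.tau_c_map, dtype=bool),
        exposure_T=scenario.exposure_T,
    )
    return stack, truth


def synth_decay(
    pO2: float,
    cal: SternVolmerCalibration,
    A: float = 0.0,
    B: float = 1.0,
    sample_rate: float = 100e6,
    duration: float = 300e-6,
    n_averaged: int = 1,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> DecayTrace:
    """Generate an averaged decay trace at a prescribed oxygen tension.

    The lifetime is the calibration's tau(pO2); the signal is
    A + B exp(-t/tau) plus white Gaussian noise of standard deviation
    noise_sd / sqrt(n_averaged) (noise after averaging n_averaged decays).
    """
    if B <= 0 or sample_rate <= 0 or duration <= 0:
        raise ParameterError("B, sample_rate and duration must be positive")
    if noise_sd < 0 or n_averaged < 1:
        raise ParameterError("noise_sd must be >= 0 and n_averaged >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tau = tau_from_pO2(pO2, cal)
    if duration < 10.0 * tau:
        warnings.warn(
            f"duration {duration:.3g} s < 10 tau ({10 * tau:.3g} s): tail under-sampled"
        )
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    signal = A + B * np.exp(-t / tau)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd / np.sqrt(n_averaged), size=n)
    return DecayTrace(t=t, signal=signal, n_averaged=n_averaged, sample_rate=sample_rate)


@dataclass
class Depolarization:
    """A scripted transient dip propagating across ROIs.

    The dip is a raised-cosine template of the given duration, scaled by
    ``dip_fraction`` and delayed per ROI by ``lags``; it multiplies both the
    flow factor and the pO2 setpoint.
    """

    onset_s: float
    duration_s: float
    dip_fraction: float | dict[str, float] = 0.5
    lags: dict[str, float] | float = 0.0

    def factor(self, roi: str, t: float) -> float:
        lag = self.lags.get(roi, 0.0) if isinstance(self.lags, dict) else self.lags
        dip = (
            self.dip_fraction.get(roi, 0.0)
            if isinstance(self.dip_fraction, dict)
            else self.dip_fraction
        )
        start = self.onset_s + lag
        if not (start <= t <= start + self.duration_s) or self.duration_s <= 0:
            return 1.0
        phase = (t - start) / self.duration_s
        return 1.0 - dip * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))


@dataclass
class StrokeTimeline:
    """Script for an occlusion session: baselines plus stepwise events.

    ``events`` entries are (time_s, roi, flow_factor, pO2_setpoint_mmHg);
    at any instant the most recent event at or before it defines a ROI's
    state (baseline rCBF = 1 and ``baseline_pO2`` before the first event).
    """

    rois: ROISet
    baseline_pO2: dict[str, float]
    events: list[tuple[float, str, float, float]] = field(default_factory=list)
    depolarization: Depolarization | None = None

    def __post_init__(self) -> None:
        times = [e[0] for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ParameterError("event times must be non-decreasing")
        for t, roi, factor, p in self.events:
            if roi not in self.rois.masks:
                raise ParameterError(f"event references unknown ROI {roi!r}")
            if factor <= 0:
                raise ParameterError("flow factors must be positive")
        missing = set(self.rois.masks) - set(self.baseline_pO2)
        if missing:
            raise ParameterError(f"baseline pO2 missing for ROIs {sorted(missing)}")

    def state_at(self, roi: str, t: float) -> tuple[float, float]:
        """(flow_factor, pO2) of a ROI at time t, including any transient."""
        factor, p = 1.0, self.baseline_pO2[roi]
        for et, eroi, ef, ep in self.events:
            if et > t:
                break
            if eroi == roi:
                factor, p = ef, ep
        if self.depolarization is not None:
            dip = self.depolarization.factor(roi, t)
            factor *= dip
            p *= dip
        return factor, p


@dataclass
class StrokeSession:
    """Synthetic dual-modality session with its ground truth."""

    stacks: list[SpeckleStack]
    stack_times: np.ndarray  # block-center timestamps, s
    decays: list[tuple[str, float, DecayTrace]]  # (roi, time_s, trace)
    truth: pd.DataFrame  # time_s, roi_id, rcbf_true, pO2_true


def default_stroke_rois(
    frame_shape: tuple[int, int] = (96, 96), pixel_scale: float = 0.0027
) -> ROISet:
    """Five rectangular regions (two arterioles, a vein, two parenchyma)."""
    rows, cols = frame_shape
    rh, cw = rows // 4, cols // 4
    masks: dict[str, np.ndarray] = {}
    layout = {
        "A1": (0, 0),
        "A2": (0, 2),
        "V1": (1, 1),
        "P1": (2, 0),
        "P2": (2, 2),
    }
    for name, (r, c) in layout.items():
        m = np.zeros(frame_shape, dtype=bool)
        m[r * rh + 2 : (r + 1) * rh - 2, c * cw + 2 : (c + 1) * cw - 2] = True
        masks[name] = m
    return ROISet(masks=masks, pixel_scale=pixel_scale)


def synth_stroke_session(
    timeline: StrokeTimeline,
    scenario: SpeckleScenario,
    cal: SternVolmerCalibration,
    schedule: PatternSchedule,
    seed: int = 0,
    duration_s: float | None = None,
    decay_noise_sd: float = 0.2,
    decay_B: float = 1.0,
    decay_sample_rate: float = 10e6,
    decay_duration: float = 300e-6,
    paint_margin: int = 3,
) -> StrokeSession:
    """Generate a full occlusion session with ground truth.

    Speckle stacks are emitted in blocks of ``scenario.n_frames`` frames at
    ``scenario.frame_rate``; the correlation time of each ROI's pixels is
    the baseline map divided by that ROI's flow factor at the block center
    (rCBF = tau_init/tau by construction). One averaged decay per ROI is
    generated at each block center from the scripted pO2.

    Flow changes are painted over each ROI mask dilated by ``paint_margin``
    pixels so that contrast windows evaluated at ROI pixels do not straddle
    the flow boundary (set it to half the analysis window).
    """
    plan = acquisition_plan(schedule)
    if not plan["feasible"]:
        raise InfeasibleScheduleError(
            "schedule infeasible: decays do not fit in a pattern slot"
        )
    for name, mask in timeline.rois.masks.items():
        if mask.shape != scenario.tau_c_map.shape:
            raise ParameterError(f"ROI {name!r} does not match the scenario frame shape")

    block_dt = scenario.n_frames / scenario.frame_rate
    if duration_s is None:
        duration_s = (max((e[0] for e in timeline.events), default=0.0)) + 2 * block_dt
    n_blocks = max(1, int(np.ceil(duration_s / block_dt)))
    times = (np.arange(n_blocks) + 0.5) * block_dt

    root = np.random.SeedSequence(seed)
    stack_rng, decay_rng = (np.random.default_rng(s) for s in root.spawn(2))

    stacks: list[SpeckleStack] = []
    decays: list[tuple[str, float, DecayTrace]] = []
    truth_rows = []
    painted = {
        name: binary_dilation(mask, iterations=paint_margin) if paint_margin else mask
        for name, mask in timeline.rois.masks.items()
    }
    for t in times:
        tau_map = scenario.tau_c_map.copy()
        for name, mask in timeline.rois.masks.items():
            factor, p = timeline.state_at(name, float(t))
            tau_map[painted[name]] = scenario.tau_c_map[painted[name]] / factor
            truth_rows.append(
                dict(time_s=float(t), roi_id=name, rcbf_true=factor, pO2_true=p)
            )
            decays.append(
                (
                    name,
                    float(t),
                    synth_decay(
                        p,
                        cal,
                        A=0.0,
                        B=decay_B,
                        sample_rate=decay_sample_rate,
                        duration=decay_duration,
                        n_averaged=schedule.decays_per_pattern,
                        noise_sd=decay_noise_sd,
                        seed=decay_rng,
                    ),
                )
            )
        block = SpeckleScenario(
            tau_c_map=tau_map,
            exposure_T=scenario.exposure_T,
            n_frames=scenario.n_frames,
            mean_intensity=scenario.mean_intensity,
            frame_rate=scenario.frame_rate,
            seed=scenario.seed,
        )
        stack, _ = synth_speckle_stack(block, rng=stack_rng)
        stacks.append(stack)

    return StrokeSession(
        stacks=stacks,
        stack_times=times,
        decays=decays,
        truth=pd.DataFrame(truth_rows),
    )
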
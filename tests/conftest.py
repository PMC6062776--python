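import numpy as np
import pytest

from corticox.lifetime import SternVolmerCalibration
from corticox.speckle import SpeckleModelParams


@pytest.fixture
def cal() -> SternVolmerCalibration:
    return SternVolmerCalibration()


@pytest.fixture
def params() -> SpeckleModelParams:
    return SpeckleModelParams(exposure_T=5e-3, beta=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def recover_session_rcbf(seed: int = 0):
    """Acceptance-grade occlusion session and its recovered per-ROI rCBF.

    Flow factor 0.5 applied to A1 at t = 3.2 s; baseline is the mean of the
    two pre-event flow maps, and the recovered rCBF is averaged over the
    four post-event blocks. Returns (recovered dict, expected dict).
    """
    from corticox.patterning import PatternSchedule
    from corticox.simulate import (
        SpeckleScenario,
        StrokeTimeline,
        default_stroke_rois,
        synth_stroke_session,
    )
    from corticox.speckle import (
        FlowMap,
        average_contrast,
        compute_contrast,
        debias_contrast,
        flow_map,
        relative_flow,
    )

    shape = (256, 256)
    rois = default_stroke_rois(shape)
    scen = SpeckleScenario(tau_c_map=np.full(shape, 2.5e-3), n_frames=90, seed=1)
    timeline = StrokeTimeline(
        rois=rois,
        baseline_pO2={"A1": 80.0, "A2": 75.0, "V1": 40.0, "P1": 55.0, "P2": 55.0},
        events=[(3.2, "A1", 0.5, 20.0)],
    )
    sched = PatternSchedule(pattern_rate=10.0, decays_per_pattern=200,
                            pulse_width=20e-6, rep_rate=3000.0, n_patterns=96)
    session = synth_stroke_session(timeline, scen, SternVolmerCalibration(), sched,
                                   seed=seed, duration_s=9.0,
                                   decay_sample_rate=5e6, decay_duration=400e-6)
    flows = []
    for stack in session.stacks:
        imgs = [compute_contrast(f, 7, exposure_T=5e-3) for f in stack.frames]
        flows.append(flow_map(debias_contrast(average_contrast(imgs))))
    baseline = FlowMap(
        tau_c=np.mean([flows[0].tau_c, flows[1].tau_c], axis=0),
        valid_mask=flows[0].valid_mask & flows[1].valid_mask,
        exposure_T=2.5e-3,
    )
    acc: dict[str, list] = {name: [] for name in rois.masks}
    for fmap in flows[2:]:
        for name, value in relative_flow(fmap, baseline, rois.masks).items():
            acc[name].append(value)
    recovered = {name: float(np.mean(vals)) for name, vals in acc.items()}
    expected = {name: (0.5 if name == "A1" else 1.0) for name in rois.masks}
    return recovered, expected


def naive_contrast(frame: np.ndarray, window: int) -> np.ndarray:
    """Independent two-pass oracle for the windowed contrast.

    Explicit per-window population standard deviation over mean via
    sliding windows; border pixels are NaN. Shares no code with the
    box-filter fast path.
    """
    from numpy.lib.stride_tricks import sliding_window_view

    frame = np.asarray(frame, dtype=np.float64)
    half = window // 2
    out = np.full(frame.shape, np.nan)
    views = sliding_window_view(frame, (window, window))
    mean = views.mean(axis=(-2, -1))
    std = views.std(axis=(-2, -1), ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = std / mean
    k[mean <= 0] = np.nan
    out[half : frame.shape[0] - half, half : frame.shape[1] - half] = k
    return out
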
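"""Synthetic worm-locomotion generator and small worked examples.

The generator emulates tangent-angle posture recordings of *C. elegans*
(100 angles per frame, 30 fps) with a traveling-wave gait model

    angle_i(t) = A * sin(p(t) - 2*pi*s_i/lambda) + turn_bias_i(t) + eps_i(t)

where ``s_i = i/100`` is normalized arclength, ``lambda`` the spatial
wavelength in body lengths, and the phase ``p(t)`` advances by
``sigma(t) * 2*pi*f/fps`` per frame with ``sigma = +1`` (forward crawl or
turn), ``-1`` (backward crawl) or ``0`` (pause).  Behavior switching is a
continuous-time Markov chain sampled at the frame rate; during a pause the
last pre-pause posture is held (plus observation noise); during a turn a
transient static-curvature pulse is superimposed.  The model is the minimal
generator reproducing the qualitative regimes of real recordings - loops
under sliding-window embedding, near-stationary pause excursions,
class-dependent amplitude and behavioral variety - with no claim of
biomechanical realism.

Default class presets mimic the low-to-high viscosity contrast reported for
methylcellulose media: undulation amplitude and frequency decrease, spatial
wavelength shortens (tighter bends), and behavior switching becomes more
frequent as nominal viscosity rises.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .series import BehaviorLabelTrack, TimeSeries

N_ANGLES = 100
BEHAVIORS = ("forward", "backward", "pause", "turn")


def standard_rates(switch_rate: float) -> dict[str, dict[str, float]]:
    """Transition-rate matrix scaled by a single per-second switching rate.

    Forward bouts dominate; backward, pause and turn bouts are shorter
    (higher exit rates) and return mostly to forward crawling.
    """
    r = switch_rate
    return {
        "forward": {"backward": 0.3 * r, "pause": 0.4 * r, "turn": 0.3 * r},
        "backward": {"forward": 1.6 * r, "pause": 0.4 * r},
        "pause": {"forward": 3.0 * r, "backward": 1.0 * r},
        "turn": {"forward": 5.0 * r},
    }


@dataclass
class WormParams:
    """Parameters of one synthetic worm recording.

    amplitude : peak body-bend angle, radians
    temporal_freq : undulation frequency, Hz
    spatial_wavelength : body lengths per wave
    noise_sd : i.i.d. Gaussian observation noise per angle, radians
    behavior_rates : nested dict, per-second CTMC transition rates
    turn_amplitude : peak static-curvature pulse during turns, radians
    """

    amplitude: float = 0.45
    temporal_freq: float = 1.5
    spatial_wavelength: float = 0.8
    noise_sd: float = 0.04
    behavior_rates: dict = field(default_factory=lambda: standard_rates(0.1))
    turn_amplitude: float = 0.6
    initial_behavior: str = "forward"
    fps: float = 30.0
    n_frames: int = 10665
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.temporal_freq <= 0:
            raise ValueError("amplitude and temporal_freq must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.fps <= 0 or self.n_frames < 1:
            raise ValueError("fps must be positive and n_frames >= 1")
        for src, dests in self.behavior_rates.items():
            if src not in BEHAVIORS:
                raise ValueError(f"unknown behavior {src!r}")
            for dst, rate in dests.items():
                if dst not in BEHAVIORS or rate < 0:
                    raise ValueError(f"bad transition {src}->{dst}: {rate}")


# Frozen class presets emulating the four methylcellulose viscosity
# conditions (labels are nominal w/v percentages).  Amplitude and frequency
# fall, bends tighten, and switching rises with viscosity.
DEFAULT_CLASS_PRESETS: dict[str, WormParams] = {
    "0.5%": WormParams(amplitude=0.55, temporal_freq=1.8, spatial_wavelength=0.90,
                       behavior_rates=standard_rates(0.05), seed=0),
    "1%": WormParams(amplitude=0.45, temporal_freq=1.5, spatial_wavelength=0.80,
                     behavior_rates=standard_rates(0.10), seed=0),
    "2%": WormParams(amplitude=0.33, temporal_freq=1.2, spatial_wavelength=0.65,
                     behavior_rates=standard_rates(0.20), seed=0),
    "3%": WormParams(amplitude=0.24, temporal_freq=1.0, spatial_wavelength=0.55,
                     behavior_rates=standard_rates(0.35), seed=0),
}

# numeric regression target (nominal methylcellulose content, % w/v)
CLASS_NUMERIC_TARGETS = {"0.5%": 0.5, "1%": 1.0, "2%": 2.0, "3%": 3.0}


def _sample_behavior_track(params: WormParams, rng: np.random.Generator) -> list[str]:
    """Sample the CTMC at the frame rate."""
    dt = 1.0 / params.fps
    state = params.initial_behavior
    labels = []
    for _ in range(params.n_frames):
        labels.append(state)
        dests = params.behavior_rates.get(state, {})
        total = sum(dests.values())
        if total > 0 and rng.random() < -np.expm1(-total * dt):
            names = list(dests)
            probs = np.array([dests[k] for k in names]) / total
            state = names[rng.choice(len(names), p=probs)]
    return labels


def _turn_envelope(length: int) -> np.ndarray:
    """Smooth rise-and-fall pulse over one turn bout."""
    u = (np.arange(length) + 0.5) / length
    return np.sin(np.pi * u) ** 2


_TURN_SHAPE = np.exp(-0.5 * ((np.arange(N_ANGLES) / N_ANGLES - 0.35) / 0.12) ** 2)


def generate_worm_series(params: WormParams) -> tuple[TimeSeries, BehaviorLabelTrack]:
    """Simulate one worm recording; deterministic for a given seed."""
    rng = np.random.default_rng(params.seed)
    labels = _sample_behavior_track(params, rng)
    s = np.arange(N_ANGLES) / N_ANGLES
    spatial = 2 * np.pi * s / params.spatial_wavelength
    dphase = 2 * np.pi * params.temporal_freq / params.fps

    track = BehaviorLabelTrack(labels)
    # per-frame turn-pulse strength: a smooth rise-and-fall over each bout
    pulse = np.zeros(params.n_frames)
    for lab, start, stop in track.segments():
        if lab == "turn":
            pulse[start:stop] = params.turn_amplitude * _turn_envelope(stop - start)

    clean = np.empty((params.n_frames, N_ANGLES))
    phase = 0.0
    held = params.amplitude * np.sin(phase - spatial)
    for t, lab in enumerate(labels):
        if lab == "pause":
            clean[t] = held
            continue
        sigma = -1.0 if lab == "backward" else 1.0
        phase += sigma * dphase
        pose = params.amplitude * np.sin(phase - spatial) + pulse[t] * _TURN_SHAPE
        clean[t] = pose
        held = pose

    noise = rng.normal(0.0, params.noise_sd, size=clean.shape) if params.noise_sd else 0.0
    return TimeSeries(clean + noise, fps=params.fps), track


def generate_class_cohort(
    class_presets: dict[str, WormParams] | list[WormParams],
    n_per_class: int,
    seed: int,
    amplitude_jitter_sd: float = 0.12,
    freq_jitter_sd: float = 0.08,
) -> list[tuple[TimeSeries, str]]:
    """Labeled cohort: ``n_per_class`` simulated worms per preset.

    Individual variability is emulated with per-sample lognormal jitter on
    the preset amplitude and temporal frequency (defaults: 12% and 8%
    multiplicative sd), so class pose distributions overlap the way real
    cohorts do while class means keep the preset ordering.  Per-sample
    seeds and jitters are derived deterministically from the master seed,
    so an identical master seed reproduces the cohort exactly.
    """
    if isinstance(class_presets, dict):
        presets = list(class_presets.items())
    else:
        presets = [(f"class{i}", p) for i, p in enumerate(class_presets)]
    if len(presets) == 0:
        raise ValueError("empty preset list")
    rng = np.random.default_rng(seed)
    cohort = []
    for label, preset in presets:
        for _ in range(n_per_class):
            sub = int(rng.integers(2**31))
            amp = preset.amplitude * rng.lognormal(0.0, amplitude_jitter_sd)
            freq = preset.temporal_freq * rng.lognormal(0.0, freq_jitter_sd)
            series, _ = generate_worm_series(
                replace(preset, seed=sub, amplitude=amp, temporal_freq=freq)
            )
            cohort.append((series, label))
    return cohort


def generate_case_study(
    seed: int = 0,
    segment_lengths: tuple[int, int, int, int] = (150, 100, 50, 100),
    noise_sd: float = 0.03,
) -> tuple[TimeSeries, BehaviorLabelTrack]:
    """400-frame forward / backward / pause / backward posture series.

    Constructed so the noiseless raw angle cloud contains exactly three
    loops - the forward bout shifts gait (wavelength and amplitude) halfway
    through, giving two distinct forward loops in near-orthogonal mode
    planes, and the two backward bouts share one gait, giving a third - while
    the pause (frozen posture plus observation noise, an exactly revisited
    point of the backward loop) encloses no hole in the raw cloud.  Under a
    sliding-window embedding the entry into and exit from the pause are
    separated (windows mixing gait and frozen frames differ in block order),
    which closes a fourth loop.  The backward gait period is 20 frames, so a
    window length of 20 spans exactly one undulation cycle.
    """
    n_f, n_b1, n_p, n_b2 = segment_lengths
    fps = 30.0
    period = 20  # frames per undulation cycle (1.5 Hz at 30 fps)
    dphase = 2 * np.pi / period
    s = np.arange(N_ANGLES) / N_ANGLES

    # (amplitude, spatial mode number) per gait
    gait_f1 = (0.55, 1.0)
    gait_f2 = (0.45, 1.65)
    gait_b = (0.50, 2.40)

    def pose(amp, mode, phase):
        return amp * np.sin(phase - 2 * np.pi * mode * s)

    frames = []
    labels = []
    phase = 0.0
    n_f1 = n_f // 2
    for t in range(n_f):
        phase += dphase
        amp, mode = gait_f1 if t < n_f1 else gait_f2
        frames.append(pose(amp, mode, phase))
        labels.append("forward")
    for t in range(n_b1):
        phase -= dphase
        frames.append(pose(*gait_b, phase))
        labels.append("backward")
    frozen = frames[-1]
    for t in range(n_p):
        frames.append(frozen)
        labels.append("pause")
    for t in range(n_b2):
        phase -= dphase
        frames.append(pose(*gait_b, phase))
        labels.append("backward")

    clean = np.array(frames)
    rng = np.random.default_rng(seed)
    noisy = clean + rng.normal(0.0, noise_sd, size=clean.shape)
    return TimeSeries(noisy, fps=fps), BehaviorLabelTrack(labels)


def generate_figure_eight(n_points: int, cycles: int = 1) -> TimeSeries:
    """Figure-eight (Gerono lemniscate) curve traversed in the plane.

    The curve ``(cos u, sin u cos u)`` self-intersects at the origin (visited
    at ``u = pi/2`` and ``3*pi/2``), traversed ``cycles`` times uniformly in
    the parameter, so the first and last points close the loop.  A
    sliding-window embedding only unrolls the full loop when the series
    wraps past one period, so window-embedding demonstrations should use
    ``cycles >= 2``.
    """
    if n_points < 8:
        raise ValueError("need at least 8 points")
    u = 2 * np.pi * cycles * np.arange(n_points) / n_points
    return TimeSeries(np.c_[np.cos(u), np.sin(u) * np.cos(u)], fps=30.0)


def generate_sine(n_points: int, period: int) -> TimeSeries:
    """1-D sampled sine wave ``x_t = sin(2*pi*t/period)``.

    Its raw point set lies on a line segment and so has no degree-1
    homology; only a sliding-window embedding unrolls it into a loop.
    """
    if period < 4:
        raise ValueError("period must be >= 4")
    t = np.arange(n_points)
    return TimeSeries(np.sin(2 * np.pi * t / period), fps=30.0)


def example_2_5() -> TimeSeries:
    """The five-frame planar series ([1,2],[3,4],[5,6],[7,8],[9,10])."""
    return TimeSeries(np.arange(1.0, 11.0).reshape(5, 2), fps=1.0)


def generate_two_circles(n_per_circle: int = 40, radius: float = 1.0) -> np.ndarray:
    """Symmetric figure-eight point cloud: two equal circles sharing a point.

    Circles of radius ``r`` centered at ``(+-r, 0)`` meet at the origin; the
    left circle is the exact mirror image of the right one, so the two
    degree-1 persistence classes are born and die at identical scales and
    the diagram point has multiplicity 2.
    """
    if n_per_circle < 3:
        raise ValueError("need at least 3 points per circle")
    th = np.pi + 2 * np.pi * np.arange(n_per_circle) / n_per_circle
    right = np.c_[radius + radius * np.cos(th), radius * np.sin(th)]
    left = right[1:] * np.array([-1.0, 1.0])  # mirror; origin kept once
    return np.vstack([right, left])
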
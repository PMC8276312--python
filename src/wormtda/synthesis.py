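"""From representative cycles back to behavior: synthetic looping clips.

Each vertex of a degree-1 representative cycle in a sliding-window embedding
is a stack of ``l`` consecutive poses.  De-embedding combines those ``l``
poses into one (mean by default), and traversing the cycle in its inferred
temporal direction yields a closed sequence of postures - a synthetic,
seamlessly looping bout of stereotyped behavior that can be rendered as
midline animation frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embedding import WindowedSeries
from .persistence import RepresentativeCycle, order_cycle
from .posture import PostureBasis, angles_to_midline, reconstruct_from_projection
from .series import TimeSeries

COMBINERS = ("mean", "middle", "first")


@dataclass
class BehaviorClip:
    """Cyclic sequence of poses synthesized from a representative cycle."""

    poses: np.ndarray  # (n, d), closed loop: pose 0 follows pose n-1
    direction: str
    fps: float = 30.0
    source: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.poses = np.atleast_2d(np.asarray(self.poses, dtype=float))
        if len(self.poses) < 3:
            raise ValueError("a clip needs at least 3 poses")

    def __len__(self) -> int:
        return len(self.poses)


def infer_wave_direction(poses: np.ndarray) -> str:
    """Behavioral direction of an undulatory pose loop.

    Projects each pose onto its dominant spatial Fourier mode and measures
    the sign of the phase velocity along the sequence: a forward crawl
    advances the traveling wave's phase, a backward crawl (equivalently, a
    time-reversed forward crawl) retreats it.  This is the property of the
    arrow of time that sliding-window embeddings preserve.
    """
    poses = np.atleast_2d(np.asarray(poses, dtype=float))
    F = np.fft.rfft(poses - poses.mean(axis=1, keepdims=True), axis=1)
    if F.shape[1] < 2:
        return "forward"
    mode = 1 + int(np.argmax(np.abs(F[:, 1:]).mean(axis=0)))
    phases = np.angle(F[:, mode])
    dph = np.angle(np.exp(1j * np.diff(phases)))
    # a wave A*sin(p - k*s) with advancing undulation phase p has rfft phase
    # -p + pi/2 at its spatial mode, so forward crawl = decreasing fft phase
    return "forward" if dph.sum() <= 0 else "backward"


def deembed_point(
    v: np.ndarray, l: int, d: int, combiner: str = "mean"
) -> np.ndarray:
    """Combine the ``l`` stacked poses of an embedded point into one pose."""
    v = np.asarray(v, dtype=float).ravel()
    if v.size != l * d:
        raise ValueError(f"vector of size {v.size} is not {l} blocks of {d}")
    blocks = v.reshape(l, d)
    if combiner == "mean":
        return blocks.mean(axis=0)
    if combiner == "middle":
        return blocks[l // 2]
    if combiner == "first":
        return blocks[0]
    raise ValueError(f"unknown combiner {combiner!r}; use one of {COMBINERS}")


def cycle_to_clip(
    cycle: RepresentativeCycle,
    embedding: WindowedSeries,
    basis: PostureBasis | None = None,
    combiner: str = "mean",
) -> BehaviorClip:
    """De-embed an ordered cycle into a looping pose sequence.

    If the pipeline ran on truncated PCA coordinates, pass the fitted
    ``basis`` to back-project poses to angle space (lossy for truncated
    bases).  The cycle is ordered in place if it has no vertex sequence yet.
    """
    if not cycle.vertex_sequence:
        cycle = order_cycle(cycle, embedding)
    l, d = embedding.window_len, embedding.source_dim
    poses = np.array(
        [
            deembed_point(embedding.frames[v], l, d, combiner=combiner)
            for v in cycle.vertex_sequence
        ]
    )
    if basis is not None:
        poses = reconstruct_from_projection(
            TimeSeries(poses, fps=embedding.fps), basis
        ).frames
    return BehaviorClip(
        poses=poses,
        direction=infer_wave_direction(poses),
        fps=embedding.fps,
        source=(cycle.diagram_point,),
    )


def render_clip(
    clip: BehaviorClip, segment_length: float = 1.0, loops: int = 1
) -> list[np.ndarray]:
    """Render the clip as midline polylines, repeated ``loops`` times.

    Returns ``loops * len(clip)`` arrays of shape (101, 2).  The loop seam
    is seamless by construction (the cycle is closed); smoothness is a
    property to verify, not enforced here.
    """
    if loops < 1:
        raise ValueError("loops must be >= 1")
    one = [angles_to_midline(p, segment_length=segment_length).points for p in clip.poses]
    return one * loops


def export_gif(
    clip: BehaviorClip,
    path,
    segment_length: float = 1.0,
    loops: int = 2,
    size_px: int = 200,
) -> None:
    """Write a looping GIF of the rendered midlines (requires imageio)."""
    import imageio.v3 as iio

    frames = render_clip(clip, segment_length=segment_length, loops=loops)
    span = max(np.abs(np.concatenate(frames)).max(), 1e-9) * 1.1
    images = []
    for mid in frames:
        img = np.full((size_px, size_px), 255, dtype=np.uint8)
        px = ((mid / span + 1) / 2 * (size_px - 1)).astype(int)
        for (x0, y0), (x1, y1) in zip(px[:-1], px[1:]):
            n = max(abs(x1 - x0), abs(y1 - y0), 1)
            xs = np.linspace(x0, x1, n + 1).astype(int)
            ys = np.linspace(y0, y1, n + 1).astype(int)
            img[size_px - 1 - ys, xs] = 0
        images.append(img)
    iio.imwrite(path, np.stack(images), duration=1000.0 / clip.fps, loop=0)
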
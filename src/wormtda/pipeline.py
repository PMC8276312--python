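"""End-to-end pipeline: patches -> windows -> diagrams -> landscapes -> stats.

For every labeled posture series: split into half-overlapping patches
(default 300 frames), sliding-window embed each patch (default l = 20),
compute its degree-1 Vietoris-Rips diagram, discretize its landscape on a
grid shared by the whole experiment (default step 0.1), and average the
patch landscapes into one average persistence landscape per video.  Class
averages, distance matrices (with the zero landscape as origin, normalized
so the mean class-to-origin distance is 1), classical MDS, landscape PCA,
per-class coordinate standard deviations, pairwise permutation tests,
multiclass SVM and SVR then run on those per-video vectors.

Large embedded clouds can be capped with farthest-point subsampling
(``max_points_per_patch``), which preserves large-scale loops while keeping
the reduction tractable; the cap is the main desk-scale knob.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .embedding import make_patches, permute_frames, sliding_window
from .landscapes import (
    PersistenceLandscape,
    average_landscapes,
    grid_for_diagrams,
    landscape_distance,
    normalize_class_distances,
)
from .persistence import maxmin_subsample, vr_diagram
from .series import TimeSeries
from .stats import (
    LabeledFeatures,
    classical_mds,
    coordinatewise_std,
    landscape_pca,
    pairwise_permutation_tests,
    svm_classify,
    svr_estimate,
)
from .synthdata import CLASS_NUMERIC_TARGETS


@dataclass
class PipelineConfig:
    """Resolved hyperparameters of one pipeline run."""

    window_len: int = 20
    patch_len: int = 300
    stride: int | None = None  # None -> patch_len // 2
    grid_step: float = 0.1
    significance_ratio: float = 0.3
    n_perm: int = 10000
    svm_folds: int = 10
    svm_cost: float = 10.0
    svm_repeats: int = 20
    svr_repeats: int = 10
    max_points_per_patch: int | None = None
    seed: int = 0

    def resolved_stride(self) -> int:
        return self.patch_len // 2 if self.stride is None else self.stride

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "PipelineConfig":
        """Reduced-cost settings for laptop-scale runs: embedded patch
        clouds capped at 60 farthest-point landmarks and 2,000 permutations;
        all structural defaults unchanged."""
        return cls(max_points_per_patch=60, n_perm=2000, seed=seed)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class PipelineResult:
    """Artifacts of one run; ``None`` for stages that were skipped."""

    config: PipelineConfig
    labels: list[str]
    video_landscapes: list[PersistenceLandscape]
    class_landscapes: dict[str, PersistenceLandscape]
    sample_distances: np.ndarray
    class_distance_labels: list[str] = field(default_factory=list)
    class_distances_normalized: np.ndarray | None = None
    mds_samples: np.ndarray | None = None
    mds_classes: np.ndarray | None = None
    pca_components: np.ndarray | None = None
    pca_projections: np.ndarray | None = None
    class_coordinate_std: dict[str, np.ndarray] | None = None
    permutation_pvalues: dict[tuple[str, str], float] | None = None
    svm_accuracy: float | None = None
    svm_confusion: np.ndarray | None = None
    svr_predictions: np.ndarray | None = None

    def feature_matrix(self) -> LabeledFeatures:
        K = max(L.depth for L in self.video_landscapes)
        X = np.stack([L.pad_to_depth(K).to_vector() for L in self.video_landscapes])
        targets = None
        if all(lab in CLASS_NUMERIC_TARGETS for lab in self.labels):
            targets = np.array([CLASS_NUMERIC_TARGETS[lab] for lab in self.labels])
        return LabeledFeatures(vectors=X, labels=self.labels, numeric_targets=targets)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.Series(self.config.to_dict()).to_csv(out / "config.csv", header=False)
        if self.class_distances_normalized is not None:
            pd.DataFrame(
                self.class_distances_normalized,
                index=self.class_distance_labels,
                columns=self.class_distance_labels,
            ).to_csv(out / "class_distances_normalized.csv")
        if self.mds_samples is not None:
            pd.DataFrame(
                self.mds_samples, columns=["mds1", "mds2"]
            ).assign(label=self.labels).to_csv(out / "mds_samples.csv", index=False)
        if self.permutation_pvalues is not None:
            pd.DataFrame(
                [(a, b, p) for (a, b), p in self.permutation_pvalues.items()],
                columns=["classA", "classB", "pvalue"],
            ).to_csv(out / "permutation_pvalues.csv", index=False)
        if self.svm_confusion is not None:
            classes = list(self.class_landscapes)
            pd.DataFrame(
                self.svm_confusion, index=classes, columns=classes
            ).to_csv(out / "svm_confusion.csv")
        if self.svm_accuracy is not None:
            pd.Series({"svm_accuracy": self.svm_accuracy}).to_csv(
                out / "svm_accuracy.csv", header=False
            )
        if self.svr_predictions is not None:
            pd.DataFrame(
                {"label": self.labels, "svr_prediction": self.svr_predictions}
            ).to_csv(out / "svr_predictions.csv", index=False)


def video_average_landscape(
    series: TimeSeries, config: PipelineConfig, grid=None, seed: int = 0
):
    """Patch diagrams and (if a grid is given) the per-video average landscape.

    Returns ``(diagrams, landscape_or_None)``; two-phase so an experiment
    can first collect every diagram, then fix one shared grid.
    """
    from .landscapes import diagram_to_landscape

    patches = make_patches(series, config.patch_len, config.resolved_stride())
    diagrams = []
    for p_idx, patch in enumerate(patches.patches):
        cloud = sliding_window(patch, config.window_len).frames
        cap = config.max_points_per_patch
        if cap is not None and len(cloud) > cap:
            cloud, _ = maxmin_subsample(cloud, cap, seed=seed * 1009 + p_idx)
        diagrams.append(vr_diagram(cloud, max_degree=1)[1])
    if grid is None:
        return diagrams, None
    return diagrams, average_landscapes(
        [diagram_to_landscape(d, grid) for d in diagrams]
    )


def run_pipeline(
    samples: list[tuple[TimeSeries, str]], config: PipelineConfig | None = None
) -> PipelineResult:
    """Run the full pipeline on a labeled collection of posture series.

    Statistical stages require >= 2 classes and enough samples for the CV
    folds; with fewer, the run stops after per-video averaging and the
    corresponding result fields stay ``None``.  Deterministic given
    ``config.seed``.
    """
    from .landscapes import diagram_to_landscape

    config = config or PipelineConfig()
    if not samples:
        raise ValueError("no samples")
    labels = [lab for _, lab in samples]

    per_video_diagrams = []
    for s_idx, (series, lab) in enumerate(samples):
        try:
            diagrams, _ = video_average_landscape(
                series, config, seed=config.seed + s_idx
            )
        except Exception as exc:  # noqa: BLE001 - annotate failing stage
            raise RuntimeError(
                f"persistence stage failed for sample {s_idx} ({lab!r}): {exc}"
            ) from exc
        per_video_diagrams.append(diagrams)

    grid = grid_for_diagrams(
        [d for ds in per_video_diagrams for d in ds], step=config.grid_step
    )
    video_landscapes = [
        average_landscapes([diagram_to_landscape(d, grid) for d in ds])
        for ds in per_video_diagrams
    ]

    classes = list(dict.fromkeys(labels))
    class_landscapes = {
        c: average_landscapes(
            [L for L, lab in zip(video_landscapes, labels) if lab == c]
        )
        for c in classes
    }

    n = len(samples)
    sample_D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sample_D[i, j] = sample_D[j, i] = landscape_distance(
                video_landscapes[i], video_landscapes[j]
            )

    result = PipelineResult(
        config=config,
        labels=labels,
        video_landscapes=video_landscapes,
        class_landscapes=class_landscapes,
        sample_distances=sample_D,
    )

    counts = {c: labels.count(c) for c in classes}
    if len(classes) < 2 or min(counts.values()) < 2 or n < config.svm_folds:
        return result  # stats stages skipped

    # class distance matrix with the zero landscape (origin) appended
    zero = PersistenceLandscape(grid=grid, values=np.zeros((1, grid.n_points)))
    entries = [class_landscapes[c] for c in classes] + [zero]
    names = classes + ["origin"]
    m = len(entries)
    class_D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            class_D[i, j] = class_D[j, i] = landscape_distance(entries[i], entries[j])
    result.class_distance_labels = names
    result.class_distances_normalized = normalize_class_distances(class_D)

    result.mds_samples = classical_mds(sample_D, dim=2)
    result.mds_classes = classical_mds(result.class_distances_normalized, dim=2)

    F = result.feature_matrix()
    comps, projs, _ = landscape_pca(F, k=2)
    result.pca_components = comps
    result.pca_projections = projs
    result.class_coordinate_std = coordinatewise_std(F)
    result.permutation_pvalues = pairwise_permutation_tests(
        F, n_perm=config.n_perm, seed=config.seed
    )
    result.svm_accuracy, result.svm_confusion = svm_classify(
        F,
        folds=config.svm_folds,
        cost=config.svm_cost,
        repeats=config.svm_repeats,
        seed=config.seed,
    )
    if F.numeric_targets is not None:
        result.svr_predictions = svr_estimate(
            F, folds=config.svm_folds, repeats=config.svr_repeats, seed=config.seed
        )
    return result


def permuted_null_cohort(
    samples: list[tuple[TimeSeries, str]], seed: int = 0
) -> list[tuple[TimeSeries, str]]:
    """Frame-permuted null model of a cohort (labels preserved)."""
    return [
        (permute_frames(series, seed=seed + i), lab)
        for i, (series, lab) in enumerate(samples)
    ]


def window_length_cv(
    samples: list[tuple[TimeSeries, str]],
    lengths: list[int] = (1, 10, 20, 30),
    truncate_frames: int = 1800,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Re-run the pipeline per window length on truncated series.

    Each sample is cut to its first ``truncate_frames`` frames (default
    1800, one minute at 30 fps) and the pipeline runs once per window
    length; returns a table of SVM accuracy and the maximum pairwise
    permutation p-value per length.
    """
    if not lengths:
        raise ValueError("no window lengths given")
    config = config or PipelineConfig()
    if truncate_frames < config.patch_len:
        raise ValueError("truncate_frames shorter than the patch length")
    cut = [
        (TimeSeries(s.frames[:truncate_frames], fps=s.fps), lab) for s, lab in samples
    ]
    rows = []
    for l in lengths:
        res = run_pipeline(cut, replace(config, window_len=l))
        pmax = (
            max(res.permutation_pvalues.values())
            if res.permutation_pvalues
            else np.nan
        )
        rows.append(
            {"window_len": l, "svm_accuracy": res.svm_accuracy, "max_pvalue": pmax}
        )
    return pd.DataFrame(rows)
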
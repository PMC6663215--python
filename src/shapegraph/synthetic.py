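"""Synthetic benchmark data: a trefoil-knot point cloud and block-design fMRI.

Two generators cover the pipeline's test surface without any downloads:

* :func:`generate_trefoil` samples a closed 3-D trefoil knot, the classic
  point cloud whose Mapper shape graph reveals a topological circle.
* :func:`generate_block_fmri` emulates a block-design visual-stimulation
  experiment: K stimulus categories in fixed-length blocks separated by rest,
  each category expressed as a spatial multivoxel pattern, optionally
  convolved with a canonical double-gamma hemodynamic response, plus i.i.d.
  Gaussian noise.  :func:`haxby_like_preset` configures it to match a classic
  visual-object study: 8 categories, 24-s blocks, TR 2.5 s, 121 frames per
  session, two sessions (242 frames).

Both generators are fully deterministic under their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import gamma as _gamma

from .anchoring import VoxelMask
from .matrix import DataMatrix, LabelTrack

__all__ = [
    "TrefoilConfig",
    "generate_trefoil",
    "BlockDesignConfig",
    "generate_block_fmri",
    "haxby_like_preset",
    "double_gamma_hrf",
    "block_fmri_to_nifti",
]


@dataclass
class TrefoilConfig:
    """Trefoil point-cloud settings: n points, isotropic noise SD, seed."""

    n: int = 100
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("need at least 3 points")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_trefoil(config: TrefoilConfig | None = None) -> DataMatrix:
    """Sample n points from the closed trefoil curve

    ``x = sin p + 2 sin 2p,  y = cos p - 2 cos 2p,  z = -sin 3p``

    with p evenly spaced on [0, 2*pi).  With zero noise the points lie
    exactly on the curve; otherwise isotropic Gaussian noise is added.
    """
    config = config or TrefoilConfig()
    phi = np.linspace(0.0, 2.0 * math.pi, config.n, endpoint=False)
    pts = np.column_stack(
        [
            np.sin(phi) + 2.0 * np.sin(2.0 * phi),
            np.cos(phi) - 2.0 * np.cos(2.0 * phi),
            -np.sin(3.0 * phi),
        ]
    )
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        pts = pts + rng.normal(0.0, config.noise_sd, pts.shape)
    ids = [f"p{i:04d}" for i in range(config.n)]
    return DataMatrix(pts, ids, ["x", "y", "z"])


def double_gamma_hrf(
    tr_s: float,
    duration_s: float = 32.0,
    peak_shape: float = 6.0,
    undershoot_shape: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at the TR.

    Difference of two gamma densities (shape 6 peak minus a 1/6-weighted
    shape-16 undershoot, unit scale), normalized to unit sum so convolving a
    sustained boxcar plateaus at the boxcar amplitude.
    """
    t = np.arange(0.0, duration_s, tr_s)
    h = _gamma.pdf(t, peak_shape) - undershoot_ratio * _gamma.pdf(t, undershoot_shape)
    s = h.sum()
    if s <= 0:
        raise ValueError("degenerate HRF sampling")
    return h / s


@dataclass
class BlockDesignConfig:
    """Block-design multivoxel time-series settings.

    Durations are in seconds and are converted to whole frames by flooring
    against the repetition time ``tr_s`` (a 24-s block at TR 2.5 s contains
    9 fully acquired frames).  Each category is assigned a spatial pattern on
    a disjoint set of ``n_voxels // n_categories`` voxels with amplitude
    ``pattern_strength``; ``response`` selects a plain boxcar or a
    double-gamma HRF convolution (peak-normalized so plateaus reach the
    pattern amplitude).  ``category_names`` optionally overrides the default
    ``cond1..condK`` labels.
    """

    n_categories: int = 8
    block_length_s: float = 24.0
    tr_s: float = 2.5
    rest_length_s: float = 15.0
    initial_rest_s: float = 2.5
    n_blocks_per_category: int = 1
    n_sessions: int = 1
    n_voxels: int = 160
    pattern_strength: float = 1.0
    noise_sd: float = 0.1
    response: str = "hrf"
    seed: int = 0
    category_names: list[str] | None = None

    def __post_init__(self) -> None:
        if min(self.block_length_s, self.tr_s) <= 0 or self.rest_length_s < 0:
            raise ValueError("durations must be positive (rest may be zero)")
        if self.n_categories < 1 or self.n_blocks_per_category < 1 or self.n_sessions < 1:
            raise ValueError("counts must be >= 1")
        if self.n_voxels < self.n_categories:
            raise ValueError("need n_voxels >= n_categories for disjoint patterns")
        if self.response not in ("boxcar", "hrf"):
            raise ValueError("response must be 'boxcar' or 'hrf'")
        if self.block_frames < 1:
            raise ValueError("block shorter than one TR: schedule infeasible")
        if self.category_names is not None and len(self.category_names) != self.n_categories:
            raise ValueError("category_names length must equal n_categories")

    @property
    def block_frames(self) -> int:
        return int(self.block_length_s // self.tr_s)

    @property
    def rest_frames(self) -> int:
        return int(self.rest_length_s // self.tr_s)

    @property
    def initial_rest_frames(self) -> int:
        return int(self.initial_rest_s // self.tr_s)

    @property
    def frames_per_session(self) -> int:
        per_block = self.block_frames + self.rest_frames
        return self.initial_rest_frames + self.n_categories * self.n_blocks_per_category * per_block

    @property
    def n_frames(self) -> int:
        return self.frames_per_session * self.n_sessions

    def names(self) -> list[str]:
        if self.category_names is not None:
            return list(self.category_names)
        return [f"cond{i + 1}" for i in range(self.n_categories)]


def haxby_like_preset() -> BlockDesignConfig:
    """Two-session, 8-category block design matching a classic visual study.

    24-s blocks at TR 2.5 s (9 frames per block), 15-s rest between blocks
    plus one lead-in rest frame give 121 frames per session; two sessions
    yield the 242-frame analysis slice, with 577 voxels as for the first
    subject's ventral-temporal mask.
    """
    return BlockDesignConfig(
        n_categories=8,
        block_length_s=24.0,
        tr_s=2.5,
        rest_length_s=15.0,
        initial_rest_s=2.5,
        n_blocks_per_category=1,
        n_sessions=2,
        n_voxels=577,
        pattern_strength=1.0,
        noise_sd=0.1,
        response="hrf",
        category_names=[
            "face", "house", "cat", "bottle",
            "scissors", "shoe", "chair", "scrambledpix",
        ],
    )


def generate_block_fmri(
    config: BlockDesignConfig | None = None,
) -> tuple[DataMatrix, LabelTrack]:
    """Simulate the block-design time series and its stimulus label track.

    Per session, category block order is a seeded permutation.  The signal is
    ``response(t, category) x pattern(category)`` summed over categories,
    plus N(0, noise_sd) noise.  Labels mark the stimulus presented during
    each frame (``rest`` elsewhere); with an HRF response the measured signal
    lags those labels by the hemodynamic delay, as in real data.
    """
    cfg = config or BlockDesignConfig()
    rng = np.random.default_rng(cfg.seed)
    names = cfg.names()
    labels: list[str] = []
    for _ in range(cfg.n_sessions):
        order = [
            names[i]
            for i in rng.permutation(cfg.n_categories * cfg.n_blocks_per_category)
            % cfg.n_categories
        ]
        labels.extend(["rest"] * cfg.initial_rest_frames)
        for cat in order:
            labels.extend([cat] * cfg.block_frames)
            labels.extend(["rest"] * cfg.rest_frames)
    T = len(labels)
    assert T == cfg.n_frames

    # disjoint spatial supports, evenly sized
    support = cfg.n_voxels // cfg.n_categories
    patterns = np.zeros((cfg.n_categories, cfg.n_voxels))
    for c in range(cfg.n_categories):
        patterns[c, c * support : (c + 1) * support] = cfg.pattern_strength

    box = np.zeros((T, cfg.n_categories))
    for t, lab in enumerate(labels):
        if lab != "rest":
            box[t, names.index(lab)] = 1.0
    if cfg.response == "hrf":
        h = double_gamma_hrf(cfg.tr_s)
        resp = np.column_stack(
            [np.convolve(box[:, c], h)[:T] for c in range(cfg.n_categories)]
        )
        peak = resp.max()
        if peak > 0:
            resp = resp / peak
    else:
        resp = box
    values = resp @ patterns + rng.normal(0.0, cfg.noise_sd, (T, cfg.n_voxels))
    frames = [f"t{i:04d}" for i in range(T)]
    voxels = [f"v{j:06d}" for j in range(cfg.n_voxels)]
    return DataMatrix(values, frames, voxels), LabelTrack(labels)


def block_fmri_to_nifti(
    data: DataMatrix,
    image_path: str | Path,
    mask_path: str | Path,
    voxel_size_mm: tuple[float, float, float] = (3.5, 3.75, 3.75),
) -> VoxelMask:
    """Materialize a simulated matrix as a 4-D NIfTI plus 3-D mask.

    Voxels are laid out on a near-cubic grid; the mask marks the first V
    voxels in C order, so reloading with
    :func:`shapegraph.anchoring.load_masked_timeseries` reproduces the matrix
    column-for-column.
    """
    import nibabel as nib

    V = data.n_features
    side = int(math.ceil(V ** (1.0 / 3.0)))
    shape = (side, side, max(1, int(math.ceil(V / side**2))))
    n_cells = int(np.prod(shape))
    grid = np.zeros(n_cells, dtype=bool)
    grid[:V] = True
    grid = grid.reshape(shape)
    affine = np.diag(list(voxel_size_mm) + [1.0])
    mask = VoxelMask(grid, affine)

    vol = np.zeros(shape + (data.n_samples,), dtype=np.float32)
    vol[mask.grid] = data.values.T  # C-order placement matches extraction
    nib.save(nib.Nifti1Image(vol, affine), str(image_path))
    nib.save(
        nib.Nifti1Image(grid.astype(np.uint8), affine), str(mask_path)
    )
    return mask
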
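"""Render a movie patch from ROI footprints and their fluorescence.

Used to exercise spatial-footprint validation: every frame is the sum
over ROIs of (binary mask x instantaneous fluorescence above baseline)
plus pixel noise. Overlapping ROIs sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MovieStack", "render_movie"]


@dataclass
class MovieStack:
    frames: np.ndarray            # (n_frames, h, w)
    origin: tuple[int, int]       # top-left (row, col) in full-frame coords

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def render_movie(
    session,
    roi_subset: list[int],
    patch_size: tuple[int, int] | None = None,
    seed: int | np.random.Generator = 0,
    *,
    pixel_noise_sd: float = 0.01,
) -> MovieStack:
    """Render the movie patch covering ``roi_subset`` of a session.

    ``roi_subset`` lists cell ids; their anatomy masks define the patch
    (bounding box of all masks, padded, or ``patch_size`` centred on
    it). Per-frame ROI intensity is the cell's fluorescence minus its
    trace median, so a quiescent ROI contributes ~nothing.
    """
    if not roi_subset:
        raise ValueError("roi_subset must not be empty")
    rng = np.random.default_rng(seed)
    labels = session.cellpose_labels
    rows, cols = np.nonzero(np.isin(labels, [cid + 1 for cid in roi_subset]))
    if rows.size == 0:
        raise ValueError("no mask pixels found for requested ROIs")
    pad = 5
    r0, c0 = max(rows.min() - pad, 0), max(cols.min() - pad, 0)
    r1 = min(rows.max() + pad + 1, labels.shape[0])
    c1 = min(cols.max() + pad + 1, labels.shape[1])
    if patch_size is not None:
        ctr = ((r0 + r1) // 2, (c0 + c1) // 2)
        r0 = max(ctr[0] - patch_size[0] // 2, 0)
        c0 = max(ctr[1] - patch_size[1] // 2, 0)
        r1 = min(r0 + patch_size[0], labels.shape[0])
        c1 = min(c0 + patch_size[1], labels.shape[1])

    h, w = r1 - r0, c1 - c0
    n_frames = session.fc.shape[1]
    frames = rng.normal(0.0, pixel_noise_sd, (n_frames, h, w))
    for cid in roi_subset:
        mask = (labels[r0:r1, c0:c1] == cid + 1).astype(float)
        if not mask.any():
            continue
        intensity = session.fc[cid] - np.median(session.fc[cid])
        frames += intensity[:, None, None] * mask[None, :, :]
    return MovieStack(frames, (int(r0), int(c0)))
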
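"""Voxel-wise probability-of-event maps from the three class saliency maps.

Each rescaled class saliency map ``H_c`` (values in [0, 1]) is divided by
the equal-weight combination ``L_H = H_S + H_M + H_L``, giving maps
``D_c = H_c / L_H`` that sum to one at every voxel where any class carries
saliency. ``L_H`` vanishes wherever all three maps are zero; such voxels
are off-support and carry no class evidence, so all three ``D_c`` are set
to zero there rather than to 1/3.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .gradcam3d import SaliencyVolume
from .io_formats import VolumeGrid
from .preprocessing import SurvivalLabel

__all__ = ["ProbabilityMaps", "rescale01", "make_probability_maps"]

DEFAULT_EPSILON = 1e-8


@dataclasses.dataclass
class ProbabilityMaps:
    """Per-class probability-of-event volumes on the template grid.

    Invariant: each map lies in [0, 1], the three maps sum to 1 at every
    support voxel, and all are exactly 0 off support.
    """

    d_short: np.ndarray
    d_medium: np.ndarray
    d_long: np.ndarray
    support_mask: np.ndarray
    grid: VolumeGrid
    epsilon: float = DEFAULT_EPSILON

    def by_class(self, label: SurvivalLabel) -> np.ndarray:
        return (self.d_short, self.d_medium, self.d_long)[label.value]

    def items(self):
        return [(c, self.by_class(c)) for c in SurvivalLabel]


def rescale01(vol: SaliencyVolume) -> SaliencyVolume:
    """Global min-max rescale of a saliency volume to [0, 1].

    A constant volume carries no localization signal and rescales to all
    zeros (with a warning).
    """
    data = vol.data
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        warnings.warn("constant saliency volume rescaled to zeros", stacklevel=2)
        out = np.zeros_like(data)
    else:
        out = (data - lo) / (hi - lo)
    return SaliencyVolume(data=out, grid=vol.grid, stage=vol.stage,
                          target_class=vol.target_class)


def make_probability_maps(h_short, h_medium, h_long,
                          epsilon: float = DEFAULT_EPSILON) -> ProbabilityMaps:
    """Normalize three rescaled class saliency maps into probability maps.

    Accepts ``SaliencyVolume`` objects or plain nonnegative arrays in
    [0, 1] sharing one grid.
    """
    def _unpack(h):
        if isinstance(h, SaliencyVolume):
            return h.data, h.grid
        arr = np.asarray(h, dtype=np.float64)
        return arr, VolumeGrid(shape=arr.shape)

    hs, grid = _unpack(h_short)
    hm, grid_m = _unpack(h_medium)
    hl, grid_l = _unpack(h_long)
    if hs.shape != hm.shape or hs.shape != hl.shape:
        raise ValueError("the three saliency maps must share one grid")
    for name, arr in (("short", hs), ("medium", hm), ("long", hl)):
        if (arr < 0).any() or (arr > 1 + 1e-12).any():
            raise ValueError(f"{name} map must be rescaled to [0, 1] first")

    l_h = hs + hm + hl
    support = l_h > epsilon
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(support, 1.0 / np.where(support, l_h, 1.0), 0.0)
    return ProbabilityMaps(
        d_short=hs * w, d_medium=hm * w, d_long=hl * w,
        support_mask=support.astype(np.uint8), grid=grid, epsilon=epsilon)
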
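"""Voxelwise R2* fitting of multi-echo gradient-echo magnitude images.

The signal of a multi-gradient-echo acquisition decays mono-exponentially,
y(TE) = A * exp(-TE * R2*), and a region of interest is summarized by its
median R2* (the median being more stable than the mean with respect to the
exact ROI outline).  The default fit is a log-linear weighted least squares
(weights = signal^2, the first-order variance correction for log-transformed
magnitude data); an optional Levenberg-Marquardt refinement fits the
exponential directly.

Raw magnitude data are fitted as-is; no Rician bias correction is applied,
so R2* is slightly underestimated at low SNR (documented behaviour).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = ["MultiEchoStack", "R2StarMap", "ROISummary", "fit_r2star",
           "roi_median", "rectangular_roi"]


@dataclass
class MultiEchoStack:
    """Echo-resolved magnitude images on a common voxel grid.

    ``data`` has shape (n_echo, *grid); ``te_ms`` is strictly increasing.
    """

    te_ms: np.ndarray
    data: np.ndarray
    voxel_size_um: float = 100.0

    def __post_init__(self) -> None:
        self.te_ms = np.asarray(self.te_ms, float)
        self.data = np.asarray(self.data, float)
        if self.te_ms.ndim != 1 or self.te_ms.size < 2:
            raise ValueError("need at least two echoes")
        if np.any(np.diff(self.te_ms) <= 0):
            raise ValueError("echo times must be strictly increasing")
        if self.data.shape[0] != self.te_ms.size:
            raise ValueError("first data axis must index echoes")
        if np.any(self.data < 0):
            raise ValueError("magnitude images must be non-negative")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.data.shape[1:]


@dataclass
class R2StarMap:
    """Per-voxel decay rate, prefactor and fit diagnostics."""

    r2star: np.ndarray           # ms^-1
    prefactor: np.ndarray        # arbitrary units, >= 0
    residual_norm: np.ndarray
    valid: np.ndarray            # bool: fit produced finite parameters
    nonnegative: np.ndarray = field(default=None)  # bool: fitted R2* >= 0

    def __post_init__(self) -> None:
        if self.nonnegative is None:
            self.nonnegative = self.r2star >= 0


@dataclass
class ROISummary:
    median_r2star: float
    voxel_count: int
    roi: np.ndarray


def _loglinear(te: np.ndarray, ydata: np.ndarray):
    """Weighted linear fit of log y on TE, vectorized over voxels.

    ydata shape (n_echo, n_vox); weights y^2 undo the variance inflation of
    the log transform.  Returns (r2star, prefactor) arrays.
    """
    logy = np.log(ydata)
    w = ydata ** 2
    sw = w.sum(axis=0)
    te_col = te[:, None]
    mt = (w * te_col).sum(axis=0) / sw
    my = (w * logy).sum(axis=0) / sw
    cov = (w * (te_col - mt) * (logy - my)).sum(axis=0)
    var = (w * (te_col - mt) ** 2).sum(axis=0)
    slope = cov / var
    return -slope, np.exp(my - slope * mt)


def fit_r2star(stack: MultiEchoStack, method: str = "log-linear") -> R2StarMap:
    """Fit y = A exp(-TE * R2*) in every voxel.

    method 'log-linear' (default) performs signal^2-weighted linear
    regression on log(y); 'nonlinear' refines that start with a
    Levenberg-Marquardt fit of the exponential itself.  Voxels with
    non-positive signal at any echo are flagged invalid rather than raising.
    Negative fitted rates (possible under noise) are retained but flagged
    via the ``nonnegative`` mask.
    """
    if method not in ("log-linear", "nonlinear"):
        raise ValueError("method must be 'log-linear' or 'nonlinear'")
    te = stack.te_ms
    shape = stack.grid_shape
    flat = stack.data.reshape(len(te), -1)
    nvox = flat.shape[1]

    valid = np.all(flat > 0, axis=0)
    r2 = np.full(nvox, np.nan)
    a = np.full(nvox, np.nan)
    res = np.full(nvox, np.nan)

    if valid.any():
        r2v, av = _loglinear(te, flat[:, valid])
        if method == "nonlinear":
            r2v, av = _refine_nonlinear(te, flat[:, valid], r2v, av)
        r2[valid] = r2v
        a[valid] = av
        model = av[None, :] * np.exp(-te[:, None] * r2v[None, :])
        res[valid] = np.linalg.norm(model - flat[:, valid], axis=0)

    ok = valid & np.isfinite(r2) & np.isfinite(a)
    return R2StarMap(r2star=r2.reshape(shape), prefactor=a.reshape(shape),
                     residual_norm=res.reshape(shape),
                     valid=ok.reshape(shape))


def _refine_nonlinear(te, ydata, r2_0, a_0):
    r2 = np.empty_like(r2_0)
    a = np.empty_like(a_0)
    for k in range(ydata.shape[1]):
        y = ydata[:, k]

        def resid(p):
            return p[0] * np.exp(-te * p[1]) - y

        sol = least_squares(resid, x0=[max(a_0[k], 1e-12), r2_0[k]],
                            method="lm", xtol=1e-14, ftol=1e-14)
        a[k], r2[k] = sol.x
    return r2, a


def roi_median(r2map: R2StarMap, roi: np.ndarray) -> ROISummary:
    """Median R2* over the valid voxels of a region of interest.

    Invalid voxels (failed fits) are excluded; an ROI with no valid overlap
    is an error.
    """
    roi = np.asarray(roi, bool)
    if roi.shape != r2map.r2star.shape:
        raise ValueError("ROI mask shape does not match the map")
    sel = roi & r2map.valid
    count = int(sel.sum())
    if count == 0:
        raise ValueError("ROI does not overlap any valid voxel")
    return ROISummary(median_r2star=float(np.median(r2map.r2star[sel])),
                      voxel_count=count, roi=roi)


def rectangular_roi(grid_shape: tuple[int, ...], lo: tuple[int, ...],
                    hi: tuple[int, ...]) -> np.ndarray:
    """Boolean mask covering the half-open box [lo, hi) — a test/demo helper
    standing in for the manual, scan-guided ROI drawing of real studies."""
    mask = np.zeros(grid_shape, bool)
    mask[tuple(slice(a, b) for a, b in zip(lo, hi))] = True
    return mask
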
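"""Spectral preprocessing: edge-frame truncation, frame averaging, GF, SNV, MSC.

The raw acquisition yields several frames per fruit as it crosses the light path;
frames captured while the beam grazes only pericarp tissue are far brighter than
frames through the pulp and are removed before averaging. The averaged spectrum is
then denoised and scatter-corrected:

* **GF** — convolution with a normalized Gaussian kernel (window/sigma
  configurable, reflect padding at the edges);
* **SNV** — per-spectrum standardization (subtract mean, divide by sd), removing
  multiplicative path-length/scatter effects spectrum by spectrum;
* **MSC** — per-spectrum linear regression against a reference spectrum
  (by default the set mean); the corrected spectrum is ``(s - b) / a`` where
  ``s ~ a*r + b``;
* **GF+MSC** — Gaussian smoothing followed by MSC, the combination that performs
  best on transmission data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.ndimage import convolve1d

from .containers import SpectrumSet

__all__ = [
    "PreprocessConfig",
    "truncate_edge_frames",
    "average_frames",
    "gaussian_kernel",
    "gaussian_filter",
    "snv",
    "msc",
    "apply",
    "METHODS",
]

METHODS = ("raw", "msc", "snv", "gf", "gf+msc")


@dataclass
class PreprocessConfig:
    method: Literal["raw", "msc", "snv", "gf", "gf+msc"] = "gf+msc"
    gf_window: int = 11
    gf_sigma: float | None = None  # defaults to gf_window / 5
    msc_reference: np.ndarray | None = None  # None -> mean spectrum of the set
    truncate_factor: float = 1.5
    snv_ddof: int = 1  # sample sd denominator (n-1)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown preprocessing method {self.method!r}; one of {METHODS}")
        if self.gf_window < 3 or self.gf_window % 2 == 0:
            raise ValueError("gf_window must be odd and >= 3")
        if self.gf_sigma is not None and self.gf_sigma <= 0:
            raise ValueError("gf_sigma must be > 0")
        if self.truncate_factor <= 1:
            raise ValueError("truncate_factor must be > 1")

    @property
    def sigma(self) -> float:
        return self.gf_sigma if self.gf_sigma is not None else self.gf_window / 5.0


# -- multi-frame handling -----------------------------------------------


def truncate_edge_frames(frames: np.ndarray, truncate_factor: float = 1.5) -> np.ndarray:
    """Drop bright leading/trailing frames of one sample's stack.

    A frame is "bright" when its total intensity exceeds
    ``truncate_factor * median(frame totals)`` — the surrogate for frames where
    light crossed only the pericarp. Only a contiguous block survives; interior
    frames are never removed.
    """
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    if frames.shape[0] < 1:
        raise ValueError("need at least one frame")
    if truncate_factor <= 1:
        raise ValueError("truncate_factor must be > 1")
    totals = frames.sum(axis=1)
    threshold = truncate_factor * np.median(totals)
    lo, hi = 0, frames.shape[0]
    while lo < hi and totals[lo] > threshold:
        lo += 1
    while hi > lo and totals[hi - 1] > threshold:
        hi -= 1
    if lo >= hi:
        raise ValueError("no informative frames: every frame exceeds the truncation threshold")
    return frames[lo:hi]


def average_frames(frames: np.ndarray) -> np.ndarray:
    """Pointwise arithmetic mean across a sample's retained frames."""
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    if frames.shape[0] < 1 or frames.size == 0:
        raise ValueError("cannot average an empty frame set")
    return frames.mean(axis=0)


def collapse_frames(stack, truncate_factor: float = 1.5) -> SpectrumSet:
    """Truncate and average each sample of a :class:`~nirselect.simulate.FrameStack`."""
    rows = [average_frames(truncate_edge_frames(stack.frames[i], truncate_factor))
            for i in range(stack.frames.shape[0])]
    return SpectrumSet(
        stack.wavelengths, np.vstack(rows), stack.sample_ids,
        {"history": [f"truncate(factor={truncate_factor})+average"]},
    )


# -- Gaussian filter -----------------------------------------------------


def gaussian_kernel(window: int, sigma: float) -> np.ndarray:
    """Normalized Gaussian weights on an odd window (sum exactly 1)."""
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    half = window // 2
    d = np.arange(-half, half + 1, dtype=float)
    w = np.exp(-0.5 * (d / sigma) ** 2)
    return w / w.sum()


def gaussian_filter(x: np.ndarray, window: int = 11, sigma: float | None = None) -> np.ndarray:
    """Convolve spectra (last axis) with a normalized Gaussian, reflect padding."""
    x = np.asarray(x, dtype=float)
    if window > x.shape[-1]:
        raise ValueError(f"window {window} exceeds spectrum length {x.shape[-1]}")
    kernel = gaussian_kernel(window, sigma if sigma is not None else window / 5.0)
    return convolve1d(x, kernel, axis=-1, mode="reflect")


# -- scatter corrections -------------------------------------------------


def snv(x: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Standard normal variate: per-spectrum (x - mean) / sd."""
    x = np.asarray(x, dtype=float)
    one_d = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] < 2:
        raise ValueError("snv needs at least 2 points per spectrum")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=ddof, keepdims=True)
    if np.any(sd <= 0):
        bad = int(np.argmax(sd.ravel() <= 0))
        raise ValueError(f"constant spectrum at row {bad}: SNV undefined")
    out = (X - mu) / sd
    return out[0] if one_d else out


def msc(X: np.ndarray, reference: np.ndarray | None = None,
        sample_ids: list[str] | None = None) -> np.ndarray:
    """Multiplicative scatter correction against ``reference`` (default: set mean).

    Each spectrum ``s`` is regressed on the reference ``r`` by least squares,
    ``s ~ a*r + b``, and corrected to ``(s - b) / a``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if reference is None:
        if X.shape[0] < 2:
            raise ValueError("msc with mean reference needs at least 2 spectra")
        reference = X.mean(axis=0)
    r = np.asarray(reference, dtype=float)
    if r.shape != (X.shape[1],):
        raise ValueError("reference grid does not match spectra")
    rc = r - r.mean()
    var_r = rc @ rc
    if var_r <= 0:
        raise ValueError("reference spectrum is constant; MSC undefined")
    a = (X - X.mean(axis=1, keepdims=True)) @ rc / var_r
    if np.any(np.abs(a) < 1e-12):
        bad = int(np.argmax(np.abs(a) < 1e-12))
        name = sample_ids[bad] if sample_ids else f"row {bad}"
        raise ValueError(f"degenerate spectrum (fitted slope ~ 0) for sample {name}")
    b = X.mean(axis=1) - a * r.mean()
    return (X - b[:, None]) / a[:, None]


# -- dispatch ------------------------------------------------------------


def apply(sset: SpectrumSet, config: PreprocessConfig) -> SpectrumSet:
    """Apply the configured preprocessing method and record it in history.

    For MSC, ``config.msc_reference`` may carry an explicit reference spectrum
    (e.g. the calibration-set mean) so a prediction set is corrected without
    touching its own statistics; with ``None`` the mean of ``sset`` is used.
    """
    m = config.method
    if m == "raw":
        return sset.with_data(sset.intensities, "raw")
    if m == "gf":
        return sset.with_data(
            gaussian_filter(sset.intensities, config.gf_window, config.sigma),
            f"gf(window={config.gf_window},sigma={config.sigma:g})",
        )
    if m == "snv":
        return sset.with_data(snv(sset.intensities, config.snv_ddof),
                              f"snv(ddof={config.snv_ddof})")
    if m == "msc":
        out = msc(sset.intensities, config.msc_reference, sset.sample_ids)
        tag = "mean" if config.msc_reference is None else "explicit"
        return sset.with_data(out, f"msc(reference={tag})")
    if m == "gf+msc":
        smooth = gaussian_filter(sset.intensities, config.gf_window, config.sigma)
        out = msc(smooth, config.msc_reference, sset.sample_ids)
        tag = "mean" if config.msc_reference is None else "explicit"
        return sset.with_data(
            out, f"gf(window={config.gf_window},sigma={config.sigma:g})+msc(reference={tag})"
        )
    raise ValueError(f"unknown preprocessing method {m!r}")


def fit_reference(sset: SpectrumSet, config: PreprocessConfig) -> np.ndarray | None:
    """Compute the MSC reference this config implies on a calibration set.

    Returns the (possibly GF-smoothed) calibration mean for MSC-based methods,
    ``None`` otherwise. Feeding the result back via ``config.msc_reference``
    lets a prediction set be corrected with calibration-only statistics.
    """
    if config.method == "msc":
        return sset.intensities.mean(axis=0)
    if config.method == "gf+msc":
        return gaussian_filter(sset.intensities, config.gf_window, config.sigma).mean(axis=0)
    return None
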
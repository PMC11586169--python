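"""Synthetic Vis-NIR full-transmission calibration problems with known ground truth.

The generator emulates the statistical structure of an on-line fruit transmission
measurement: a smooth halogen-lamp envelope ``I0(lambda)``, Beer-Lambert absorption
by a small number of Gaussian constituent bands with per-sample concentrations,
large multiplicative and additive sample-to-sample scatter, detector noise, and an
orientation-dependent path-length factor (the stem-calyx axis parallel vs
perpendicular to the conveyor changes the optical path, hence overall intensity).

The recorded signal for sample *i* is

    I_i(l) = path_factor * m_i * I0(l) * 10**(-A_i(l)) + b_i + eps_i(l)

with absorbance ``A_i(l) = t_i * sum_j c_ij * a_j * exp(-(l - mu_j)^2 / (2 s_j^2))``
(the log-normal factor ``t_i`` is the per-sample optical path length),
log-normal multiplicative scatter ``m_i``, per-sample additive offset ``b_i`` and
i.i.d. Gaussian noise ``eps``. The SSC target is an affine function of one
designated band concentration plus refractometer-precision noise, so the true
informative wavelengths are known exactly and selection methods can be scored
against them.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
import json
from pathlib import Path

import numpy as np

from .containers import ReferenceTable, SpectrumSet

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "FrameStack",
    "lamp_envelope",
    "band_profiles",
    "generate",
    "generate_multiframe",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of a simulated transmission acquisition.

    Defaults describe a 96-fruit tomato run on a 2048-point 560-1072 nm grid with
    three absorbing constituents: a chlorophyll-like visible band, an
    SSC-linked sugar/carbohydrate band in the short NIR, and a water band.
    Scatter magnitudes are large (15% multiplicative) to mimic the pronounced
    intensity differences between fruit.
    """

    n_samples: int = 96
    n_wavelengths: int = 2048
    wl_min: float = 560.0
    wl_max: float = 1072.0
    band_centers: tuple[float, ...] = (675.0, 840.0, 960.0)
    band_widths: tuple[float, ...] = (12.0, 18.0, 22.0)  # Gaussian sd, nm
    band_amplitudes: tuple[float, ...] = (0.45, 0.35, 0.55)  # peak absorbance at unit conc
    ssc_band: int = 1  # which band concentration carries the SSC signal
    ssc_mean: float = 4.5  # % soluble solids, ripe-tomato scale
    ssc_sd: float = 1.0
    ssc_noise_sd: float = 0.1  # refractometer repeatability, %
    conc_sd: float = 0.2  # relative spread of band concentrations around 1
    scatter_mult_sd: float = 0.15  # sd of log multiplicative scatter
    scatter_add_sd: float = 300.0  # per-sample additive offset, counts
    path_length_sd: float = 0.08  # sd of log per-sample optical path length
    noise_sd: float = 150.0  # per-point detector noise, counts
    path_factor: float = 1.0  # orientation-dependent transmission gain
    lamp_peak: float = 40000.0  # counts
    lamp_center: float = 800.0  # nm
    lamp_width: float = 600.0  # nm
    frames_per_sample: int = 1
    edge_frame_gain: float = 2.5  # pericarp-only frames transmit far more light
    seed: int = 0

    @property
    def n_informative_bands(self) -> int:
        return len(self.band_centers)


def validate_config(config: SimulationConfig) -> None:
    c = config
    if c.n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if c.n_wavelengths < 2:
        raise ValueError("n_wavelengths must be >= 2")
    if not c.wl_min < c.wl_max:
        raise ValueError("wl_min must be < wl_max")
    if not (len(c.band_centers) == len(c.band_widths) == len(c.band_amplitudes)):
        raise ValueError("band_centers, band_widths, band_amplitudes must have equal length")
    if len(c.band_centers) == 0:
        raise ValueError("band_centers must contain at least one band")
    for mu in c.band_centers:
        if not c.wl_min <= mu <= c.wl_max:
            raise ValueError(f"band_centers entry {mu} outside [wl_min, wl_max]")
    for name in ("ssc_noise_sd", "conc_sd", "scatter_mult_sd", "scatter_add_sd",
                 "path_length_sd", "noise_sd", "ssc_sd"):
        if getattr(c, name) < 0:
            raise ValueError(f"{name} must be >= 0")
    for name in ("band_widths", "band_amplitudes"):
        if any(v <= 0 for v in getattr(c, name)):
            raise ValueError(f"{name} entries must be > 0")
    if not 0 <= c.ssc_band < len(c.band_centers):
        raise ValueError("ssc_band must index a band")
    if c.path_factor <= 0:
        raise ValueError("path_factor must be > 0")
    if c.lamp_peak <= 0 or c.lamp_width <= 0:
        raise ValueError("lamp_peak and lamp_width must be > 0")
    if c.frames_per_sample < 1:
        raise ValueError("frames_per_sample must be >= 1")
    if c.ssc_mean <= 0:
        raise ValueError("ssc_mean must be > 0")


@dataclass
class GroundTruth:
    """What the generator knows and an analyst would have to discover."""

    informative_ranges: list[tuple[int, int]]  # merged [start, end) support ranges
    band_ranges: list[tuple[int, int]]  # per-band [start, end), unmerged
    informative_indices: np.ndarray  # union of the ranges
    band_concentrations: np.ndarray  # (n_samples, n_bands)
    band_amplitudes: tuple[float, ...]
    ssc_intercept: float
    ssc_slope: float
    per_sample_ssc: np.ndarray  # noise-free affine values
    config: SimulationConfig

    def to_json(self, path: str | Path) -> None:
        d = {
            "informative_ranges": [list(r) for r in self.informative_ranges],
            "band_ranges": [list(r) for r in self.band_ranges],
            "band_amplitudes": list(self.band_amplitudes),
            "ssc_intercept": self.ssc_intercept,
            "ssc_slope": self.ssc_slope,
            "seed": self.config.seed,
            "config": asdict(self.config),
        }
        Path(path).write_text(json.dumps(d, indent=1))


@dataclass
class FrameStack:
    """Multi-frame acquisition: ``frames_per_sample`` spectra per fruit."""

    wavelengths: np.ndarray
    frames: np.ndarray  # (n_samples, n_frames, n_wavelengths)
    sample_ids: list[str]


def _grid(config: SimulationConfig) -> np.ndarray:
    return np.linspace(config.wl_min, config.wl_max, config.n_wavelengths)


def lamp_envelope(config: SimulationConfig) -> np.ndarray:
    """Smooth broad-Gaussian source spectrum ``I0(lambda)`` in counts."""
    wl = _grid(config)
    return config.lamp_peak * np.exp(-0.5 * ((wl - config.lamp_center) / config.lamp_width) ** 2)


def band_profiles(config: SimulationConfig) -> np.ndarray:
    """Unit-concentration absorbance profile of each band, shape (n_bands, w)."""
    wl = _grid(config)
    G = np.empty((config.n_informative_bands, wl.size))
    for j, (mu, s, a) in enumerate(
        zip(config.band_centers, config.band_widths, config.band_amplitudes)
    ):
        G[j] = a * np.exp(-0.5 * ((wl - mu) / s) ** 2)
    return G


def _informative_support(config: SimulationConfig, n_sd: float = 3.0) -> tuple[list, np.ndarray]:
    """Index ranges covering each band's center +/- n_sd widths."""
    wl = _grid(config)
    raw = []
    for mu, s in zip(config.band_centers, config.band_widths):
        lo = int(np.searchsorted(wl, mu - n_sd * s, side="left"))
        hi = int(np.searchsorted(wl, mu + n_sd * s, side="right"))
        raw.append((max(lo, 0), min(hi, wl.size)))
    merged: list[tuple[int, int]] = []
    for lo, hi in sorted(raw):
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    idx = np.concatenate([np.arange(lo, hi) for lo, hi in merged]) if merged else np.array([], int)
    return merged, raw, idx


def _clean_spectra(config: SimulationConfig, rng: np.random.Generator):
    """Draw concentrations/scatter and build noise-free intensities.

    RNG draw order is fixed so that single-frame multiframe output is
    bit-identical to :func:`generate`.
    """
    n, nb = config.n_samples, config.n_informative_bands
    conc = np.clip(rng.normal(1.0, config.conc_sd, size=(n, nb)), 0.2, None)
    slope = config.ssc_sd / config.conc_sd if config.conc_sd > 0 else config.ssc_sd
    intercept = config.ssc_mean - slope  # concentrations are centered on 1
    ssc_clean = intercept + slope * conc[:, config.ssc_band]
    ssc = ssc_clean + rng.normal(0.0, config.ssc_noise_sd, size=n)
    if np.any(ssc <= 0):
        raise ValueError(
            "generated SSC values are not all > 0; increase ssc_mean or reduce spreads"
        )
    mult = np.exp(rng.normal(0.0, config.scatter_mult_sd, size=n))
    add = rng.normal(0.0, config.scatter_add_sd, size=n)
    # Per-sample optical path length multiplies absorbance (Beer-Lambert A = e*c*l):
    # fruit of different diameter attenuate the same constituents differently. This
    # is the slope-type variation MSC is designed to remove.
    path = np.exp(rng.normal(0.0, config.path_length_sd, size=n))
    A = path[:, None] * (conc @ band_profiles(config))
    I0 = lamp_envelope(config)
    clean = config.path_factor * mult[:, None] * I0[None, :] * 10.0 ** (-A) + add[:, None]
    return clean, conc, ssc, ssc_clean, intercept, slope


def _assemble(config: SimulationConfig, conc, ssc, ssc_clean, intercept, slope):
    ids = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    ref = ReferenceTable(ids, ssc)
    ranges, band_ranges, idx = _informative_support(config)
    gt = GroundTruth(
        informative_ranges=ranges,
        band_ranges=band_ranges,
        informative_indices=idx,
        band_concentrations=conc,
        band_amplitudes=config.band_amplitudes,
        ssc_intercept=intercept,
        ssc_slope=slope,
        per_sample_ssc=ssc_clean,
        config=config,
    )
    return ids, ref, gt


def generate(config: SimulationConfig = SimulationConfig()):
    """Simulate one averaged transmission spectrum per sample.

    Returns
    -------
    (SpectrumSet, ReferenceTable, GroundTruth)
        Identical ``config`` (including ``seed``) reproduces identical output
        bit-for-bit.
    """
    validate_config(config)
    rng = np.random.default_rng(config.seed)
    clean, conc, ssc, ssc_clean, intercept, slope = _clean_spectra(config, rng)
    noise = rng.normal(0.0, config.noise_sd, size=clean.shape)
    ids, ref, gt = _assemble(config, conc, ssc, ssc_clean, intercept, slope)
    sset = SpectrumSet(_grid(config), clean + noise, ids,
                       {"history": [f"simulated(seed={config.seed})"]})
    return sset, ref, gt


def generate_multiframe(config: SimulationConfig = SimulationConfig()):
    """Simulate a multi-point acquisition: several frames per sample.

    When ``frames_per_sample >= 3`` the first and last frame are scaled by
    ``edge_frame_gain`` to emulate frames where light crossed only pericarp
    tissue (much higher transmitted intensity), so edge truncation has
    something to remove. With a single frame the output equals
    :func:`generate` exactly.
    """
    validate_config(config)
    if config.frames_per_sample < 1:
        raise ValueError("frames_per_sample must be >= 1")
    rng = np.random.default_rng(config.seed)
    clean, conc, ssc, ssc_clean, intercept, slope = _clean_spectra(config, rng)
    F = config.frames_per_sample
    noise = rng.normal(0.0, config.noise_sd, size=(F,) + clean.shape)
    gains = np.ones(F)
    if F >= 3:
        gains[0] = gains[-1] = config.edge_frame_gain
    frames = gains[:, None, None] * clean[None, :, :] + noise
    frames = np.moveaxis(frames, 0, 1)  # (n_samples, F, w)
    ids, ref, gt = _assemble(config, conc, ssc, ssc_clean, intercept, slope)
    return FrameStack(_grid(config), frames, ids), ref, gt


def write_dataset(out_dir: str | Path, sset: SpectrumSet, ref: ReferenceTable,
                  gt: GroundTruth) -> dict[str, str]:
    """Write the spectra/reference CSVs and ground-truth JSON; return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "spectra": str(out / "spectra.csv"),
        "reference": str(out / "reference.csv"),
        "ground_truth": str(out / "ground_truth.json"),
    }
    sset.to_csv(paths["spectra"])
    ref.to_csv(paths["reference"])
    gt.to_json(paths["ground_truth"])
    return paths
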
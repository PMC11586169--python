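"""In-memory containers for spectral calibration data.

A :class:`SpectrumSet` holds a wavelength grid (nm) plus a samples-by-wavelengths
intensity matrix; a :class:`ReferenceTable` holds the per-sample soluble solids
content (SSC, %) used as the regression target. Both round-trip through plain CSV:

* spectra CSV — row 1 is the wavelength grid in nm, column 1 the sample id,
  remaining cells the intensities;
* reference CSV — two columns, ``sample_id`` and ``ssc_percent``.

Every processing stage returns a new object and appends a short description to the
``history`` list kept in ``meta``, so the provenance of any matrix is inspectable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectrumSet",
    "ReferenceTable",
    "to_absorbance",
    "read_spectra_csv",
    "read_reference_csv",
]


@dataclass
class SpectrumSet:
    """A wavelength grid with one intensity row per sample.

    Parameters
    ----------
    wavelengths
        Strictly increasing grid in nm, shape ``(w,)``.
    intensities
        Finite matrix of shape ``(n_samples, w)``.
    sample_ids
        Unique string identifiers, one per row.
    meta
        Free-form provenance; ``meta["history"]`` is an append-only list of
        processing-step descriptions.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    sample_ids: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.wavelengths.ndim != 1:
            raise ValueError("wavelengths must be a 1-D vector")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.intensities.shape != (len(self.sample_ids), self.wavelengths.size):
            raise ValueError(
                f"intensities shape {self.intensities.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.wavelengths.size} wavelengths"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        self.meta.setdefault("history", [])

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.intensities.shape[1]

    def copy(self) -> "SpectrumSet":
        meta = {k: (list(v) if k == "history" else v) for k, v in self.meta.items()}
        return SpectrumSet(
            self.wavelengths.copy(), self.intensities.copy(), list(self.sample_ids), meta
        )

    def with_data(self, intensities: np.ndarray, step: str,
                  wavelengths: np.ndarray | None = None) -> "SpectrumSet":
        """Return a new set with replaced data and ``step`` appended to history."""
        out = SpectrumSet(
            self.wavelengths.copy() if wavelengths is None else np.asarray(wavelengths, float),
            np.asarray(intensities, dtype=float),
            list(self.sample_ids),
            {k: (list(v) if k == "history" else v) for k, v in self.meta.items()},
        )
        out.meta["history"].append(step)
        return out

    def select_samples(self, indices: Sequence[int], step: str | None = None) -> "SpectrumSet":
        idx = np.asarray(indices, dtype=int)
        out = SpectrumSet(
            self.wavelengths.copy(),
            self.intensities[idx],
            [self.sample_ids[i] for i in idx],
            {k: (list(v) if k == "history" else v) for k, v in self.meta.items()},
        )
        if step:
            out.meta["history"].append(step)
        return out

    @property
    def history(self) -> list[str]:
        return self.meta["history"]

    # -- CSV dialect -----------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.intensities, index=self.sample_ids, columns=self.wavelengths)
        df.index.name = "sample_id"
        df.to_csv(path)
        sidecar = Path(path).with_suffix(Path(path).suffix + ".meta.json")
        sidecar.write_text(json.dumps({"history": self.history}, indent=1))


def read_spectra_csv(path: str | Path) -> SpectrumSet:
    """Read the spectra CSV dialect (row 1 = nm grid, column 1 = sample id)."""
    df = pd.read_csv(path, index_col=0)
    wavelengths = df.columns.to_numpy(dtype=float)
    sset = SpectrumSet(wavelengths, df.to_numpy(dtype=float), [str(i) for i in df.index])
    sidecar = Path(path).with_suffix(Path(path).suffix + ".meta.json")
    if sidecar.exists():
        sset.meta["history"] = list(json.loads(sidecar.read_text()).get("history", []))
    return sset


@dataclass
class ReferenceTable:
    """Per-sample SSC reference values (% soluble solids)."""

    sample_ids: list[str]
    ssc: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.ssc = np.asarray(self.ssc, dtype=float).ravel()
        if len(self.sample_ids) != self.ssc.size:
            raise ValueError("sample_ids and ssc lengths differ")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")

    def __len__(self) -> int:
        return self.ssc.size

    def copy(self) -> "ReferenceTable":
        return ReferenceTable(list(self.sample_ids), self.ssc.copy())

    def select_samples(self, indices: Sequence[int]) -> "ReferenceTable":
        idx = np.asarray(indices, dtype=int)
        return ReferenceTable([self.sample_ids[i] for i in idx], self.ssc[idx])

    def aligned_to(self, sset: SpectrumSet) -> np.ndarray:
        """Return SSC values ordered like ``sset.sample_ids``."""
        lut = {s: v for s, v in zip(self.sample_ids, self.ssc)}
        missing = [s for s in sset.sample_ids if s not in lut]
        if missing:
            raise KeyError(f"reference values missing for samples: {missing[:5]}")
        return np.array([lut[s] for s in sset.sample_ids])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"sample_id": self.sample_ids, "ssc_percent": self.ssc}).to_csv(
            path, index=False
        )


def read_reference_csv(path: str | Path) -> ReferenceTable:
    df = pd.read_csv(path)
    return ReferenceTable([str(s) for s in df["sample_id"]], df["ssc_percent"].to_numpy())


def to_absorbance(sset: SpectrumSet, floor: float = 1e-9) -> SpectrumSet:
    """Convert transmission intensities to apparent absorbance ``-log10(I)``.

    The instrument records transmitted counts; Beer-Lambert linearity between
    constituent concentrations and signal holds on the log scale. The source
    envelope and per-sample path-length/scatter factors become additive terms
    that the scatter corrections (SNV/MSC) remove downstream. Intensities are
    floored at ``floor`` before taking the log.
    """
    A = -np.log10(np.clip(sset.intensities, floor, None))
    return sset.with_data(A, "absorbance:-log10(I)")
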
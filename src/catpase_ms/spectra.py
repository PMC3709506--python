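"""Spectrum/chromatogram containers and the plain-text peak-list format.

The peak-list dialect is one or more blocks of::

    #spectrum <id> msLevel=<1|2> z=<charge> rt=<seconds>
    <mz>\t<intensity>
    ...

with ``z=0`` meaning "charge unknown".  mzML input is read through
:mod:`pyteomics.mzml` and converted to the same in-memory container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MassSpectrum",
    "Chromatogram",
    "write_peaklist",
    "read_peaklist",
    "read_spectra",
]


@dataclass
class MassSpectrum:
    """An (m/z, intensity) series sorted by m/z."""

    mz: np.ndarray
    intensity: np.ndarray
    spectrum_id: str = ""
    ms_level: int = 1
    charge: int = 0
    rt: float = 0.0

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        order = np.argsort(self.mz, kind="stable")
        if not np.array_equal(order, np.arange(len(order))):
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class Chromatogram:
    """An (retention time, intensity) series with strictly increasing rt."""

    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.shape != self.intensity.shape or self.rt.ndim != 1:
            raise ValueError("rt and intensity must be 1-D arrays of equal length")
        if len(self.rt) > 1 and not np.all(np.diff(self.rt) > 0):
            raise ValueError("rt must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")

    def __len__(self) -> int:
        return len(self.rt)


def write_peaklist(spectra: Iterable[MassSpectrum], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for sp in spectra:
            fh.write(
                f"#spectrum {sp.spectrum_id or 'spec'} msLevel={sp.ms_level} "
                f"z={sp.charge} rt={sp.rt:g}\n"
            )
            for mz, inten in zip(sp.mz, sp.intensity):
                fh.write(f"{mz:.6f}\t{inten:.6g}\n")


def read_peaklist(path: str | Path) -> list[MassSpectrum]:
    spectra: list[MassSpectrum] = []
    header: dict | None = None
    mzs: list[float] = []
    ints: list[float] = []

    def flush() -> None:
        if header is not None:
            spectra.append(
                MassSpectrum(np.array(mzs), np.array(ints), **header)
            )

    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#spectrum"):
                flush()
                parts = line.split()
                kv = dict(p.split("=", 1) for p in parts[2:] if "=" in p)
                header = {
                    "spectrum_id": parts[1],
                    "ms_level": int(kv.get("msLevel", 1)),
                    "charge": int(kv.get("z", 0)),
                    "rt": float(kv.get("rt", 0.0)),
                }
                mzs, ints = [], []
            else:
                a, b = line.split("\t")
                mzs.append(float(a))
                ints.append(float(b))
    flush()
    return spectra


def read_spectra(path: str | Path) -> list[MassSpectrum]:
    """Read spectra from a peak-list TSV or an mzML file."""
    path = Path(path)
    if path.suffix.lower() != ".mzml":
        return read_peaklist(path)
    from pyteomics import mzml

    spectra = []
    with mzml.read(str(path)) as reader:
        for entry in reader:
            rt = 0.0
            scans = entry.get("scanList", {}).get("scan", [])
            if scans:
                rt = float(scans[0].get("scan start time", 0.0))
            spectra.append(
                MassSpectrum(
                    entry["m/z array"],
                    entry["intensity array"],
                    spectrum_id=entry.get("id", ""),
                    ms_level=int(entry.get("ms level", 1)),
                    rt=rt,
                )
            )
    return spectra
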
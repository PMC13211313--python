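"""Readers/writers for dense spectra and peak lists.

Dense spectra use a compressed ``.npz`` container holding the grid
metadata (start/end/n_points, nucleus) and the raw intensity array, so
round-trips are lossless at full floating precision. Peak lists use a
plain CSV schema (``shift_ppm,intensity`` for 1D,
``h_ppm,c_ppm,intensity`` for HSQC) or an equivalent JSON form with the
same field names.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Union

import numpy as np

from .spectra import (
    Nucleus,
    PeakList1D,
    PeakListHSQC,
    PpmGrid,
    Spectrum1D,
    SpectrumHSQC,
)

__all__ = [
    "ParseError",
    "write_spectrum",
    "read_spectrum",
    "write_peaklist",
    "read_peaklist",
]

Record = Union[Spectrum1D, SpectrumHSQC, PeakList1D, PeakListHSQC]


class ParseError(ValueError):
    """Malformed spectrum/peak-list file; message names the offending field."""


def write_spectrum(path, record: Union[Spectrum1D, SpectrumHSQC]) -> None:
    """Write a dense spectrum to a self-describing ``.npz`` container."""
    path = Path(path)
    if isinstance(record, Spectrum1D):
        np.savez_compressed(
            path,
            kind="spectrum1d",
            nucleus=record.nucleus.value,
            grid=np.array(
                [record.grid.start_ppm, record.grid.end_ppm, record.grid.n_points]
            ),
            intensities=record.intensities,
            normalized=record.normalized,
        )
    elif isinstance(record, SpectrumHSQC):
        np.savez_compressed(
            path,
            kind="hsqc",
            h_grid=np.array(
                [record.h_grid.start_ppm, record.h_grid.end_ppm, record.h_grid.n_points]
            ),
            c_grid=np.array(
                [record.c_grid.start_ppm, record.c_grid.end_ppm, record.c_grid.n_points]
            ),
            intensities=record.intensities,
            normalized=record.normalized,
        )
    else:
        raise TypeError(f"not a dense spectrum: {type(record).__name__}")


def _grid_from(arr: np.ndarray) -> PpmGrid:
    return PpmGrid(float(arr[0]), float(arr[1]), int(arr[2]))


def read_spectrum(path) -> Union[Spectrum1D, SpectrumHSQC]:
    """Read a dense spectrum written by :func:`write_spectrum`."""
    path = Path(path)
    try:
        with np.load(path, allow_pickle=False) as data:
            kind = str(data["kind"])
            if kind == "spectrum1d":
                return Spectrum1D(
                    nucleus=Nucleus(str(data["nucleus"])),
                    grid=_grid_from(data["grid"]),
                    intensities=data["intensities"],
                    normalized=bool(data["normalized"]),
                )
            if kind == "hsqc":
                return SpectrumHSQC(
                    h_grid=_grid_from(data["h_grid"]),
                    c_grid=_grid_from(data["c_grid"]),
                    intensities=data["intensities"],
                    normalized=bool(data["normalized"]),
                )
            raise ParseError(f"{path}: unknown spectrum kind {kind!r}")
    except KeyError as exc:
        raise ParseError(f"{path}: missing field {exc}") from exc


def write_peaklist(path, record: Union[PeakList1D, PeakListHSQC]) -> None:
    """Write a peak list as CSV (``.csv``) or JSON (``.json``)."""
    path = Path(path)
    if path.suffix == ".json":
        if isinstance(record, PeakList1D):
            obj = {
                "nucleus": record.nucleus.value,
                "peaks": [
                    {"shift_ppm": s, "intensity": i} for s, i in record.peaks
                ],
            }
        else:
            obj = {
                "peaks": [
                    {"h_ppm": h, "c_ppm": c, "intensity": i}
                    for h, c, i in record.peaks
                ]
            }
        path.write_text(json.dumps(obj, indent=1))
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        if isinstance(record, PeakList1D):
            writer.writerow(["shift_ppm", "intensity"])
            writer.writerows(record.peaks)
        else:
            writer.writerow(["h_ppm", "c_ppm", "intensity"])
            writer.writerows(record.peaks)


def _parse_float(text: str, field: str, line: int) -> float:
    try:
        return float(text)
    except ValueError as exc:
        raise ParseError(f"line {line}: field {field!r}: not a number: {text!r}") from exc


def read_peaklist(path, nucleus: Nucleus | None = None):
    """Read a peak-list CSV/JSON.

    The 1D CSV schema carries no nucleus column, so ``nucleus`` must be
    supplied for 1D files (JSON files store it). Negative intensities and
    malformed rows are rejected with the offending field and line named.
    """
    path = Path(path)
    if path.suffix == ".json":
        obj = json.loads(path.read_text())
        peaks = obj.get("peaks")
        if peaks is None:
            raise ParseError(f"{path}: missing field 'peaks'")
        if "nucleus" in obj:
            return PeakList1D(
                Nucleus(obj["nucleus"]),
                [(float(p["shift_ppm"]), float(p["intensity"])) for p in peaks],
            )
        return PeakListHSQC(
            [
                (float(p["h_ppm"]), float(p["c_ppm"]), float(p["intensity"]))
                for p in peaks
            ]
        )
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ParseError(f"{path}: empty file")
    header = [h.strip() for h in rows[0]]
    if header == ["shift_ppm", "intensity"]:
        if nucleus is None:
            raise ParseError(f"{path}: 1D peak CSV requires a nucleus argument")
        peaks1d = []
        for ln, row in enumerate(rows[1:], start=2):
            if not row:
                continue
            if len(row) != 2:
                raise ParseError(f"line {ln}: expected 2 fields, got {len(row)}")
            shift = _parse_float(row[0], "shift_ppm", ln)
            inten = _parse_float(row[1], "intensity", ln)
            if inten < 0:
                raise ParseError(f"line {ln}: field 'intensity': must be >= 0")
            peaks1d.append((shift, inten))
        return PeakList1D(nucleus, peaks1d)
    if header == ["h_ppm", "c_ppm", "intensity"]:
        peaks2d = []
        for ln, row in enumerate(rows[1:], start=2):
            if not row:
                continue
            if len(row) != 3:
                raise ParseError(f"line {ln}: expected 3 fields, got {len(row)}")
            h = _parse_float(row[0], "h_ppm", ln)
            c = _parse_float(row[1], "c_ppm", ln)
            inten = _parse_float(row[2], "intensity", ln)
            if inten < 0:
                raise ParseError(f"line {ln}: field 'intensity': must be >= 0")
            peaks2d.append((h, c, inten))
        return PeakListHSQC(peaks2d)
    raise ParseError(f"{path}: unrecognized header {header}")
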
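"""Spectrum containers and readers/writers for MSP, CSV peak tables and mzML.

The workflow's interchange unit is a centroided spectrum: a sorted list of
(m/z, intensity) peaks, optionally carrying a retention time and an
ionization label.  MSP is the NIST text library dialect that deconvolution
tools (AMDIS / NIST MS Search) export and that fragment-prediction services
consume; peak tables are plain CSV; mzML is read through pyteomics.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Peak",
    "CentroidSpectrum",
    "SpectrumParseError",
    "read_msp",
    "write_msp",
    "read_peak_table",
    "write_peak_table",
    "read_mzml_centroids",
]

#: Two peaks closer than this (Da) are considered duplicates.
DUPLICATE_MZ_TOL = 1e-6


class SpectrumParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class Peak:
    """A single centroid: m/z in Da, intensity in arbitrary units."""

    mz: float
    intensity: float
    saturated: bool = False

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class CentroidSpectrum:
    """A centroided spectrum: peaks sorted by m/z, no duplicates.

    ``rt`` is the retention time in minutes (None when unknown);
    ``ionization`` is free text, conventionally "CI" or "EI".
    """

    peaks: tuple[Peak, ...]
    rt: float | None = None
    ionization: str | None = None
    label: str = ""
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.peaks, key=lambda p: p.mz))
        object.__setattr__(self, "peaks", ordered)
        for a, b in zip(ordered, ordered[1:]):
            if b.mz - a.mz < DUPLICATE_MZ_TOL:
                raise ValueError(
                    f"duplicate peaks at m/z {a.mz!r} and {b.mz!r} "
                    f"(closer than {DUPLICATE_MZ_TOL} Da)"
                )

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz(self) -> list[float]:
        return [p.mz for p in self.peaks]

    @property
    def intensity(self) -> list[float]:
        return [p.intensity for p in self.peaks]

    def nearest_peak(self, mz: float, tol: float) -> Peak | None:
        """The closest peak within ``tol`` Da of ``mz``, or None."""
        best = None
        best_d = tol
        for p in self.peaks:  # peak lists are short; linear scan is fine
            d = abs(p.mz - mz)
            if d <= best_d:
                best, best_d = p, d
        return best


# ---------------------------------------------------------------------------
# MSP (NIST text library)
# ---------------------------------------------------------------------------

def read_msp(path: str | Path) -> list[CentroidSpectrum]:
    """Parse a NIST-style MSP library into spectra.

    Accepts the common dialect variations: header keys are case-insensitive
    and unknown ones are ignored; peak lines may be whitespace- or
    semicolon-separated and may pack several pairs per line.  Each record
    must declare ``Num Peaks:`` and list exactly that many pairs, otherwise
    a :class:`SpectrumParseError` naming the record and line is raised.
    """
    path = Path(path)
    spectra: list[CentroidSpectrum] = []
    name = ""
    rt: float | None = None
    ionization: str | None = None
    num_peaks: int | None = None
    pairs: list[tuple[float, float]] = []
    meta: dict = {}
    in_peaks = False
    record_line = 0

    def flush(line_no: int) -> None:
        nonlocal name, rt, ionization, num_peaks, pairs, meta, in_peaks
        if num_peaks is None and not pairs and not name:
            return
        if num_peaks is None:
            raise SpectrumParseError(
                f"{path}: record {name!r} starting at line {record_line} "
                f"has no 'Num Peaks:' header"
            )
        if len(pairs) != num_peaks:
            raise SpectrumParseError(
                f"{path}: record {name!r} (line {record_line}) declares "
                f"Num Peaks: {num_peaks} but lists {len(pairs)} "
                f"(record ends near line {line_no})"
            )
        spectra.append(
            CentroidSpectrum(
                peaks=tuple(Peak(mz, inten) for mz, inten in pairs),
                rt=rt,
                ionization=ionization,
                label=name,
                meta=meta,
            )
        )
        name, rt, ionization, num_peaks, pairs, meta, in_peaks = (
            "", None, None, None, [], {}, False
        )

    last_line = 0
    with path.open() as fh:
        for line_no, raw in enumerate(fh, start=1):
            last_line = line_no
            line = raw.strip()
            if not line:
                flush(line_no)
                continue
            if not in_peaks and ":" in line:
                key, _, value = line.partition(":")
                key_l = key.strip().lower()
                value = value.strip()
                if key_l == "name":
                    if name or num_peaks is not None or pairs:
                        flush(line_no)  # new record without a blank separator
                    name = value
                    record_line = line_no
                elif key_l == "num peaks":
                    try:
                        num_peaks = int(value)
                    except ValueError as exc:
                        raise SpectrumParseError(
                            f"{path}:{line_no}: invalid Num Peaks value {value!r}"
                        ) from exc
                    in_peaks = True
                elif key_l in ("retentiontime", "retention_time", "rt"):
                    rt = float(value)
                elif key_l in ("ionmode", "ionization", "spectrum_type"):
                    ionization = value
                else:
                    # other header keys (Formula:, MW:, Comments:, ...) kept
                    # as free-form metadata
                    meta[key_l] = value
                continue
            # peak line: "mz int; mz int;" or "mz int mz int"
            tokens = line.replace(";", " ").split()
            if len(tokens) % 2 != 0:
                raise SpectrumParseError(
                    f"{path}:{line_no}: odd number of values on peak line "
                    f"in record {name!r}"
                )
            try:
                values = [float(t) for t in tokens]
            except ValueError as exc:
                raise SpectrumParseError(
                    f"{path}:{line_no}: non-numeric peak value in record {name!r}"
                ) from exc
            pairs.extend(zip(values[::2], values[1::2]))
    flush(last_line)
    return spectra


def write_msp(spectra: Iterable[CentroidSpectrum], path: str | Path) -> None:
    """Write spectra as a NIST-style MSP library.

    m/z is formatted to 6 decimals and intensity to 1 decimal, so a
    read-back round-trips up to that formatting.
    """
    path = Path(path)
    with path.open("w") as fh:
        for i, spec in enumerate(spectra):
            fh.write(f"Name: {spec.label or f'spectrum_{i}'}\n")
            if spec.rt is not None:
                fh.write(f"RetentionTime: {spec.rt:.4f}\n")
            if spec.ionization:
                fh.write(f"Ionization: {spec.ionization}\n")
            if "formula" in spec.meta:
                fh.write(f"Formula: {spec.meta['formula']}\n")
            fh.write(f"Num Peaks: {len(spec.peaks)}\n")
            for p in spec.peaks:
                fh.write(f"{p.mz:.6f} {p.intensity:.1f}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# CSV peak tables
# ---------------------------------------------------------------------------

def read_peak_table(path: str | Path) -> CentroidSpectrum:
    """Read a CSV peak table with columns ``mz,intensity[,rt]``.

    The optional ``rt`` column must be constant; non-numeric or negative
    fields raise a :class:`SpectrumParseError` naming the row.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        cols = [c.strip().lower() for c in reader.fieldnames or []]
        if "mz" not in cols or "intensity" not in cols:
            raise SpectrumParseError(
                f"{path}: peak table must have columns mz,intensity "
                f"(found {reader.fieldnames})"
            )
        peaks: list[Peak] = []
        rt: float | None = None
        for row_no, row in enumerate(reader, start=2):
            clean = {k.strip().lower(): v for k, v in row.items() if k}
            try:
                mz = float(clean["mz"])
                inten = float(clean["intensity"])
            except (TypeError, ValueError) as exc:
                raise SpectrumParseError(
                    f"{path}: row {row_no}: non-numeric mz/intensity"
                ) from exc
            if inten < 0:
                raise SpectrumParseError(
                    f"{path}: row {row_no}: negative intensity {inten}"
                )
            sat = str(clean.get("saturated", "")).strip().lower() in ("1", "true")
            peaks.append(Peak(mz, inten, saturated=sat))
            if clean.get("rt"):
                rt = float(clean["rt"])
    return CentroidSpectrum(peaks=tuple(peaks), rt=rt, label=path.stem)


def write_peak_table(spectrum: CentroidSpectrum, path: str | Path) -> None:
    """Write a spectrum as a ``mz,intensity,rt,saturated`` CSV."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["mz", "intensity", "rt", "saturated"])
        for p in spectrum.peaks:
            writer.writerow(
                [f"{p.mz:.6f}", f"{p.intensity:.4f}",
                 "" if spectrum.rt is None else f"{spectrum.rt:.4f}",
                 int(p.saturated)]
            )


# ---------------------------------------------------------------------------
# mzML (read-only, centroid)
# ---------------------------------------------------------------------------

def _decode_binary_array(binary_el, cvparams: list) -> list[float]:
    """Decode one mzML <binaryDataArray> payload (64/32-bit, zlib or raw)."""
    import base64
    import struct
    import zlib

    accessions = {p.get("accession") for p in cvparams}
    text = (binary_el.text or "").strip()
    raw = base64.b64decode(text) if text else b""
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    fmt = "f" if "MS:1000521" in accessions else "d"  # 32- vs 64-bit float
    width = 4 if fmt == "f" else 8
    n = len(raw) // width
    return list(struct.unpack(f"<{n}{fmt}", raw[: n * width]))


def read_mzml_centroids(path: str | Path) -> list[CentroidSpectrum]:
    """Read centroided MS1 scans from an mzML file.

    A deliberately small reader for the subset of mzML this workflow needs:
    uncompressed or zlib-compressed 32/64-bit float m/z and intensity
    arrays of centroid spectra, with retention times (converted to minutes)
    from the scan start time.  Profile-mode scans raise a
    :class:`SpectrumParseError`: this workflow operates on centroid data
    only and does no peak picking.
    """
    from xml.etree import ElementTree

    path = Path(path)
    ns = {"mz": "http://psi.hupo.org/ms/mzml"}

    def findall(el, tag):
        return el.findall(f"mz:{tag}", ns) or el.findall(tag)

    def iterfind(el, path_expr):
        return el.iter(f"{{{ns['mz']}}}{path_expr}") if el.tag.startswith("{") \
            else el.iter(path_expr)

    tree = ElementTree.parse(path)
    root = tree.getroot()
    spectra: list[CentroidSpectrum] = []
    for spec_el in iterfind(root, "spectrum"):
        params = [p.attrib for p in findall(spec_el, "cvParam")]
        accessions = {p.get("accession") for p in params}
        scan_id = spec_el.get("id", "")
        if "MS:1000128" in accessions:  # profile spectrum
            raise SpectrumParseError(
                f"{path}: scan {scan_id!r} is profile mode; centroid data required"
            )
        rt = None
        for scan_el in iterfind(spec_el, "scan"):
            for p in findall(scan_el, "cvParam"):
                if p.get("accession") == "MS:1000016":  # scan start time
                    rt = float(p.get("value"))
                    if p.get("unitName") == "second":
                        rt /= 60.0
            break
        arrays: dict[str, list[float]] = {}
        for arr_el in iterfind(spec_el, "binaryDataArray"):
            arr_params = [p.attrib for p in findall(arr_el, "cvParam")]
            arr_acc = {p.get("accession") for p in arr_params}
            binaries = list(iterfind(arr_el, "binary"))
            if not binaries:
                continue
            values = _decode_binary_array(binaries[0], arr_params)
            if "MS:1000514" in arr_acc:
                arrays["mz"] = values
            elif "MS:1000515" in arr_acc:
                arrays["intensity"] = values
        mzs = arrays.get("mz", [])
        intens = arrays.get("intensity", [])
        if len(mzs) != len(intens):
            raise SpectrumParseError(
                f"{path}: scan {scan_id!r} has mismatched m/z and intensity arrays"
            )
        peaks = tuple(
            Peak(float(mz), float(i)) for mz, i in zip(mzs, intens) if i > 0
        )
        spectra.append(CentroidSpectrum(peaks=peaks, rt=rt, label=scan_id))
    return spectra
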
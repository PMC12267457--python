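"""Spectrum, peak-list and sample-metadata I/O.

Supported formats: mzML (read and minimal write, via pyteomics/lxml),
two-column whitespace- or comma-separated text spectra (read/write),
peak-list CSV (read/write) and sample-metadata CSV (read).  All m/z in Da.
"""

from __future__ import annotations

import base64
import logging
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "Peak",
    "PeakList",
    "SampleRecord",
    "LAYER_TO_COMPLEX",
    "COMPLEXES",
    "read_spectrum",
    "write_spectrum",
    "read_peaklist",
    "write_peaklist",
    "read_metadata",
]

#: Stratigraphic layer -> cultural complex.  The bare "rsi" label defaults to
#: Uluzzian (the sampled rsi material is Uluzzian); the explicit sub-layer
#: labels override for records known to come from the Mousterian part.
LAYER_TO_COMPLEX: dict[str, str] = {
    "cgr": "Mousterian",
    "gar": "Mousterian",
    "lower rsi": "Mousterian",
    "rsi": "Uluzzian",
    "upper rsi": "Uluzzian",
    "pie": "Uluzzian",
    "rpi": "Uluzzian",
    "rsa''": "Uluzzian",
    "rsa'": "Protoaurignacian",
}

COMPLEXES = ("Mousterian", "Uluzzian", "Protoaurignacian")


@dataclass(frozen=True)
class Spectrum:
    """One MALDI acquisition: a continuous m/z-intensity profile.

    ``history`` records the preprocessing steps already applied, so that the
    peak picker can warn when it is handed a raw profile.
    """

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    replicate_index: int = 1
    history: tuple[str, ...] = ()

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.ndim != 1 or inten.ndim != 1 or mz.size != inten.size:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size < 2:
            raise ValueError("spectrum needs at least 2 points")
        if np.any(inten < 0):
            raise ValueError("intensities must be nonnegative")
        if np.any(np.diff(mz) <= 0):
            raise ValueError("mz must be strictly increasing")
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be >= 1")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)

    def with_intensity(self, intensity: np.ndarray, step: str) -> "Spectrum":
        return replace(self, intensity=intensity, history=self.history + (step,))

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float
    snr: float


@dataclass
class PeakList:
    """Picked centroids of one replicate, sorted by m/z."""

    sample_id: str
    replicate_index: int
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self):
        self.peaks = sorted(
            ((Peak(*p) if not isinstance(p, Peak) else p) for p in self.peaks),
            key=lambda p: p.mz,
        )
        if any(p.snr < 0 for p in self.peaks):
            raise ValueError("snr must be >= 0")

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])


@dataclass(frozen=True)
class SampleRecord:
    """Excavation metadata of one sampled bone fragment."""

    sample_id: str
    layer: str
    complex: str
    square: str | None = None
    spit: str | None = None

    def __post_init__(self):
        if self.complex not in COMPLEXES:
            raise ValueError(f"{self.sample_id}: unknown complex {self.complex!r}")


# ---------------------------------------------------------------------------
# spectra


def _read_xy_text(path: Path) -> tuple[np.ndarray, np.ndarray]:
    mzs, intens = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            try:
                m, i = float(parts[0]), float(parts[1])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: line {lineno}: expected two numeric columns") from exc
            mzs.append(m)
            intens.append(i)
    if not mzs:
        raise IOError(f"{path}: empty spectrum file")
    return np.array(mzs), np.array(intens)


def _decode_binary_array(arr) -> tuple[str | None, np.ndarray]:
    """Decode one mzML <binaryDataArray>: returns (array name, values)."""
    import zlib

    accessions = {cv.get("accession") for cv in arr.iter(f"{{{_MZML_NS}}}cvParam")}
    accessions |= {cv.get("accession") for cv in arr.iter("cvParam")}
    name = None
    if "MS:1000514" in accessions:
        name = "mz"
    elif "MS:1000515" in accessions:
        name = "intensity"
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"  # default 64-bit
    node = arr.find(f"{{{_MZML_NS}}}binary")
    if node is None:
        node = arr.find("binary")
    raw = base64.b64decode(node.text or "")
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    return name, np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: Path, index: int) -> tuple[np.ndarray, np.ndarray]:
    """Minimal mzML reader (profile spectra, 32/64-bit, zlib or plain)."""
    tree = etree.parse(str(path))
    spectra = tree.findall(f".//{{{_MZML_NS}}}spectrum") or tree.findall(".//spectrum")
    if index >= len(spectra):
        raise IOError(f"{path}: no spectrum at index {index}")
    arrays: dict[str, np.ndarray] = {}
    spec = spectra[index]
    bdas = spec.findall(f".//{{{_MZML_NS}}}binaryDataArray") or spec.findall(
        ".//binaryDataArray"
    )
    for arr in bdas:
        name, values = _decode_binary_array(arr)
        if name:
            arrays[name] = values
    if "mz" not in arrays or "intensity" not in arrays:
        raise IOError(f"{path}: spectrum {index} lacks m/z or intensity arrays")
    return arrays["mz"], arrays["intensity"]


def read_spectrum(
    path: str | Path,
    format: str | None = None,
    sample_id: str = "",
    replicate_index: int = 1,
    index: int = 0,
) -> Spectrum:
    """Read a spectrum from mzML or two-column text.

    Out-of-order m/z values are sorted (with a logged warning); duplicate
    m/z values are averaged so the axis is strictly increasing.
    """
    path = Path(path)
    fmt = format or ("mzml" if path.suffix.lower() == ".mzml" else "xy_text")
    if fmt == "mzml":
        mz, inten = _read_mzml(path, index)
    elif fmt == "xy_text":
        mz, inten = _read_xy_text(path)
    else:
        raise ValueError(f"unknown spectrum format: {fmt!r}")

    if np.any(np.diff(mz) < 0):
        logger.warning("%s: m/z not sorted; sorting", path)
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
    if np.any(np.diff(mz) == 0):
        uniq, inv = np.unique(mz, return_inverse=True)
        summed = np.bincount(inv, weights=inten) / np.bincount(inv)
        logger.warning("%s: duplicate m/z values averaged", path)
        mz, inten = uniq, summed
    inten = np.clip(inten, 0.0, None)
    return Spectrum(mz, inten, sample_id=sample_id or path.stem, replicate_index=replicate_index)


_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _binary_array(parent, values: np.ndarray, accession: str, name: str):
    payload = base64.b64encode(struct.pack(f"<{values.size}d", *values)).decode()
    arr = etree.SubElement(parent, "binaryDataArray", encodedLength=str(len(payload)))
    for acc, nm in (
        ("MS:1000523", "64-bit float"),
        ("MS:1000576", "no compression"),
        (accession, name),
    ):
        etree.SubElement(arr, "cvParam", cvRef="MS", accession=acc, name=nm, value="")
    etree.SubElement(arr, "binary").text = payload


def write_spectrum(spectrum: Spectrum, path: str | Path, format: str | None = None) -> Path:
    """Write a spectrum as two-column text or minimal single-spectrum mzML."""
    path = Path(path)
    fmt = format or ("mzml" if path.suffix.lower() == ".mzml" else "xy_text")
    if fmt == "xy_text":
        with open(path, "w") as fh:
            for m, i in zip(spectrum.mz, spectrum.intensity):
                fh.write(f"{m:.12g} {i:.12g}\n")
        return path
    if fmt != "mzml":
        raise ValueError(f"unknown spectrum format: {fmt!r}")

    root = etree.Element("mzML", xmlns=_MZML_NS, version="1.1.0")
    run = etree.SubElement(root, "run", id=spectrum.sample_id or "run")
    slist = etree.SubElement(run, "spectrumList", count="1")
    spec = etree.SubElement(
        slist,
        "spectrum",
        index="0",
        id=f"sample={spectrum.sample_id} replicate={spectrum.replicate_index}",
        defaultArrayLength=str(len(spectrum)),
    )
    etree.SubElement(spec, "cvParam", cvRef="MS", accession="MS:1000511", name="ms level", value="1")
    etree.SubElement(spec, "cvParam", cvRef="MS", accession="MS:1000128", name="profile spectrum", value="")
    blist = etree.SubElement(spec, "binaryDataArrayList", count="2")
    _binary_array(blist, spectrum.mz, "MS:1000514", "m/z array")
    _binary_array(blist, spectrum.intensity, "MS:1000515", "intensity array")
    etree.ElementTree(root).write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)
    return path


# ---------------------------------------------------------------------------
# peak lists

_PEAKLIST_COLUMNS = ["mz", "intensity", "snr"]


def write_peaklist(peaks: PeakList, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sample_id: {peaks.sample_id}\n")
        fh.write(f"# replicate_index: {peaks.replicate_index}\n")
        fh.write(",".join(_PEAKLIST_COLUMNS) + "\n")
        for p in peaks.peaks:
            fh.write(f"{p.mz:.6f},{p.intensity:.6f},{p.snr:.6f}\n")
    return path


def read_peaklist(path: str | Path) -> PeakList:
    path = Path(path)
    sample_id, replicate_index = path.stem, 1
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            if key.strip() == "sample_id":
                sample_id = value.strip()
            elif key.strip() == "replicate_index":
                replicate_index = int(value)
            body_start += 1
        else:
            break
    try:
        df = pd.read_csv(path, skiprows=body_start)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed peak-list CSV: {exc}") from exc
    missing = [c for c in _PEAKLIST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: peak-list CSV missing column(s) {missing}")
    peaks = [Peak(r.mz, r.intensity, r.snr) for r in df.itertuples()]
    return PeakList(sample_id=sample_id, replicate_index=replicate_index, peaks=peaks)


# ---------------------------------------------------------------------------
# sample metadata


def read_metadata(
    path: str | Path, layer_to_complex: dict[str, str] | None = None
) -> list[SampleRecord]:
    """Read sample metadata CSV (columns: sample_id, layer[, square, spit, complex]).

    The cultural complex is inferred from the layer when absent.  Unknown
    layer labels are collected and reported in a single error.
    """
    mapping = layer_to_complex or LAYER_TO_COMPLEX
    df = pd.read_csv(path, dtype=str).fillna("")
    for col in ("sample_id", "layer"):
        if col not in df.columns:
            raise ValueError(f"{path}: metadata CSV missing required column {col!r}")
    records, bad = [], []
    for row in df.itertuples():
        layer = row.layer.strip()
        complex_ = getattr(row, "complex", "") or mapping.get(layer, "")
        if not complex_:
            bad.append(f"row {row.Index + 2}: sample {row.sample_id!r} layer {layer!r}")
            continue
        records.append(
            SampleRecord(
                sample_id=row.sample_id,
                layer=layer,
                complex=complex_,
                square=(getattr(row, "square", "") or None),
                spit=(getattr(row, "spit", "") or None),
            )
        )
    if bad:
        raise ValueError(f"{path}: unknown layer label(s):\n" + "\n".join(bad))
    return records
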
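"""Reading, writing and inspecting centroided LC-HRMS runs.

A run is an RT-ordered list of centroided scans.  mzML and mzXML input is
parsed with :mod:`pyteomics`; output is written as standard mzML 1.1.0 with
64-bit zlib-compressed arrays so that trimmed or simulated runs can be fed to
any downstream picker.  Retention time is always stored in seconds.
"""

from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree as ET
from xml.sax.saxutils import quoteattr

import numpy as np

__all__ = [
    "CentroidScan",
    "SpectraRun",
    "RunSummary",
    "SpectraParseError",
    "EmptyRunError",
    "read_spectra",
    "write_spectra",
    "inspect_run",
    "centroid_profile",
]


class SpectraParseError(ValueError):
    """Raised when a spectra file cannot be parsed."""


class EmptyRunError(ValueError):
    """Raised when a run contains no usable scans."""


@dataclass
class CentroidScan:
    """One centroided mass spectrum.

    Parameters
    ----------
    rt : float
        Retention time in seconds (>= 0).
    mz : ndarray
        Strictly ascending m/z values (Thomson).
    intensity : ndarray
        Non-negative intensities, same length as ``mz``.
    ms_level : int
        MS level, >= 1.
    polarity : str
        ``positive``, ``negative`` or ``unknown``.
    """

    rt: float
    mz: np.ndarray
    intensity: np.ndarray
    ms_level: int = 1
    polarity: str = "unknown"

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly ascending within a scan")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.rt < 0:
            raise ValueError("retention time must be >= 0")
        if self.ms_level < 1:
            raise ValueError("ms_level must be >= 1")

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())


@dataclass
class SpectraRun:
    """An RT-ordered collection of centroided scans for one sample."""

    scans: list[CentroidScan]
    sample_id: str = "sample"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.scans]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError("scan retention times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.scans)

    @property
    def rts(self) -> np.ndarray:
        return np.array([s.rt for s in self.scans], dtype=np.float64)

    def flatten(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (rt, mz, intensity) of every centroid in the run."""
        if not self.scans:
            empty = np.empty(0)
            return empty, empty.copy(), empty.copy()
        rt = np.concatenate([np.full(s.mz.size, s.rt) for s in self.scans])
        mz = np.concatenate([s.mz for s in self.scans])
        inten = np.concatenate([s.intensity for s in self.scans])
        return rt, mz, inten


@dataclass
class RunSummary:
    n_scans: int
    rt_range: tuple[float, float]
    mz_range: tuple[float, float]
    tic: list[tuple[float, float]]


def centroid_profile(mz: np.ndarray, intensity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reduce a profile-mode spectrum to its local intensity maxima."""
    mz = np.asarray(mz, dtype=np.float64)
    intensity = np.asarray(intensity, dtype=np.float64)
    if mz.size < 3:
        keep = intensity > 0
        return mz[keep], intensity[keep]
    left = np.r_[-np.inf, intensity[:-1]]
    right = np.r_[intensity[1:], -np.inf]
    apex = (intensity > left) & (intensity >= right) & (intensity > 0)
    return mz[apex], intensity[apex]


def _detect_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".mzml":
        return "mzml"
    if suffix == ".mzxml":
        return "mzxml"
    # fall back to sniffing the root element
    with open(path, "rb") as fh:
        head = fh.read(4096).decode("utf-8", errors="replace")
    if "mzXML" in head:
        return "mzxml"
    if "mzML" in head:
        return "mzml"
    raise SpectraParseError(f"cannot determine spectra dialect of {path}")


def _rt_seconds(value) -> float:
    """Convert a pyteomics scan-start-time to seconds using its unit info."""
    unit = getattr(value, "unit_info", None)
    v = float(value)
    if unit and "minute" in str(unit):
        return v * 60.0
    return v


def _decode_binary(b64_text: str, precision: int, compressed: bool) -> np.ndarray:
    raw = base64.b64decode(b64_text.strip())
    if compressed:
        raw = zlib.decompress(raw)
    code = "d" if precision == 64 else "f"
    n = len(raw) // struct.calcsize(f"<{code}")
    return np.asarray(struct.unpack(f"<{n}{code}", raw), dtype=np.float64)


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _iter_mzml_scans(path: Path):
    """Stream (rt_seconds, mz, intensity, ms_level, polarity, is_profile) from mzML."""
    context = ET.iterparse(str(path), events=("end",))
    for _, elem in context:
        if _localname(elem.tag) != "spectrum":
            continue
        ms_level = 1
        polarity = "unknown"
        is_profile = False
        rt = None
        arrays: dict[str, np.ndarray] = {}
        for cv in elem.iter():
            name = _localname(cv.tag)
            if name == "cvParam":
                acc = cv.get("accession", "")
                if acc == "MS:1000511":
                    ms_level = int(cv.get("value", "1"))
                elif acc == "MS:1000128":
                    is_profile = True
                elif acc == "MS:1000130":
                    polarity = "positive"
                elif acc == "MS:1000129":
                    polarity = "negative"
                elif acc == "MS:1000016":
                    rt = float(cv.get("value", "0"))
                    if "minute" in (cv.get("unitName") or "").lower():
                        rt *= 60.0
        for bda in elem.iter():
            if _localname(bda.tag) != "binaryDataArray":
                continue
            precision = 64
            compressed = False
            kind = None
            b64_text = ""
            for child in bda:
                name = _localname(child.tag)
                if name == "cvParam":
                    acc = child.get("accession", "")
                    if acc == "MS:1000521":
                        precision = 32
                    elif acc == "MS:1000523":
                        precision = 64
                    elif acc == "MS:1000574":
                        compressed = True
                    elif acc == "MS:1000514":
                        kind = "mz"
                    elif acc == "MS:1000515":
                        kind = "intensity"
                elif name == "binary":
                    b64_text = child.text or ""
            if kind:
                arrays[kind] = _decode_binary(b64_text, precision, compressed)
        if rt is None:
            raise SpectraParseError(f"spectrum {elem.get('id')!r} lacks a scan start time")
        mz = arrays.get("mz", np.empty(0))
        inten = arrays.get("intensity", np.empty(0))
        elem.clear()
        yield rt, mz, inten, ms_level, polarity, is_profile


def read_spectra(path, ms_level: int = 1) -> SpectraRun:
    """Read an mzML/mzXML file into a :class:`SpectraRun`.

    Only scans at ``ms_level`` are returned.  Profile-mode scans are reduced
    to local maxima and the run is flagged with ``meta['centroided_on_read']``.
    """
    path = Path(path)
    if not path.exists():
        raise SpectraParseError(f"no such file: {path}")
    dialect = _detect_dialect(path)
    scans: list[CentroidScan] = []
    centroided_on_read = False
    if dialect == "mzml":
        iterator = _iter_mzml_scans(path)
    else:
        from pyteomics import mzxml as _reader

        iterator = (
            (
                _rt_seconds(spec["retentionTime"]),
                np.asarray(spec["m/z array"], dtype=np.float64),
                np.asarray(spec["intensity array"], dtype=np.float64),
                int(spec.get("msLevel", 1)),
                {"+": "positive", "-": "negative"}.get(spec.get("polarity", ""), "unknown"),
                False,
            )
            for spec in _reader.read(str(path))
        )

    idx = -1
    try:
        for idx, (rt, mz, inten, level, polarity, is_profile) in enumerate(iterator):
            if level != ms_level:
                continue
            if is_profile:
                mz, inten = centroid_profile(mz, inten)
                centroided_on_read = True
            order = np.argsort(mz, kind="stable")
            mz, inten = mz[order], inten[order]
            # collapse exact m/z duplicates so the ascending invariant holds
            if mz.size > 1 and np.any(np.diff(mz) == 0):
                uniq, inverse = np.unique(mz, return_inverse=True)
                summed = np.zeros_like(uniq)
                np.add.at(summed, inverse, inten)
                mz, inten = uniq, summed
            scans.append(
                CentroidScan(rt=rt, mz=mz, intensity=inten, ms_level=ms_level, polarity=polarity)
            )
    except (SpectraParseError, EmptyRunError):
        raise
    except Exception as exc:  # corrupt file content
        raise SpectraParseError(f"failed to parse {path} at scan index {idx + 1}: {exc}") from exc
    if not scans:
        raise EmptyRunError(f"{path} contains no scans at MS level {ms_level}")
    scans.sort(key=lambda s: s.rt)
    meta = {"source": str(path)}
    if centroided_on_read:
        meta["centroided_on_read"] = True
    return SpectraRun(scans=scans, sample_id=path.stem, meta=meta)


def _encode_array(values: np.ndarray) -> str:
    raw = struct.pack(f"<{values.size}d", *np.asarray(values, dtype=np.float64))
    return base64.b64encode(zlib.compress(raw)).decode("ascii")


_POLARITY_CV = {
    "positive": ("MS:1000130", "positive scan"),
    "negative": ("MS:1000129", "negative scan"),
}


def write_spectra(run: SpectraRun, path) -> None:
    """Write a run as mzML 1.1.0 (64-bit float, zlib-compressed arrays)."""
    if not run.scans:
        raise EmptyRunError("cannot write an empty run")
    path = Path(path)
    lines: list[str] = []
    w = lines.append
    w('<?xml version="1.0" encoding="utf-8"?>')
    w(
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0" '
        f"id={quoteattr(run.sample_id)}>"
    )
    w('  <cvList count="2">')
    w(
        '    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" '
        'URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
    )
    w(
        '    <cv id="UO" fullName="Unit Ontology" '
        'URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>'
    )
    w("  </cvList>")
    w("  <fileDescription>")
    w("    <fileContent>")
    w('      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>')
    w('      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>')
    w("    </fileContent>")
    w("  </fileDescription>")
    w(f'  <run id={quoteattr(run.sample_id)}>')
    w(f'    <spectrumList count="{len(run.scans)}">')
    for i, scan in enumerate(run.scans):
        mz_b64 = _encode_array(scan.mz)
        in_b64 = _encode_array(scan.intensity)
        w(
            f'      <spectrum index="{i}" id="scan={i + 1}" '
            f'defaultArrayLength="{scan.mz.size}">'
        )
        w(
            f'        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" '
            f'value="{scan.ms_level}"/>'
        )
        w('        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>')
        if scan.polarity in _POLARITY_CV:
            acc, name = _POLARITY_CV[scan.polarity]
            w(f'        <cvParam cvRef="MS" accession="{acc}" name="{name}" value=""/>')
        w('        <scanList count="1">')
        w("          <scan>")
        w(
            f'            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
            f'value="{scan.rt!r}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>'
        )
        w("          </scan>")
        w("        </scanList>")
        w('        <binaryDataArrayList count="2">')
        for accession, arr_name, b64 in (
            ("MS:1000514", "m/z array", mz_b64),
            ("MS:1000515", "intensity array", in_b64),
        ):
            w(f'          <binaryDataArray encodedLength="{len(b64)}">')
            w('            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>')
            w('            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>')
            w(
                f'            <cvParam cvRef="MS" accession="{accession}" name="{arr_name}" value=""/>'
            )
            w(f"            <binary>{b64}</binary>")
            w("          </binaryDataArray>")
        w("        </binaryDataArrayList>")
        w("      </spectrum>")
    w("    </spectrumList>")
    w("  </run>")
    w("</mzML>")
    try:
        path.write_text("\n".join(lines), encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot write mzML to {path}: {exc}") from exc


def inspect_run(run: SpectraRun) -> RunSummary:
    """Whole-run summary: scan count, RT/mz extrema and the TIC trace."""
    if not run.scans:
        raise EmptyRunError("cannot inspect an empty run")
    ms1 = [s for s in run.scans if s.ms_level == 1]
    tic = [(s.rt, s.tic) for s in ms1]
    nonempty = [s for s in run.scans if s.mz.size]
    rts = [s.rt for s in run.scans]
    if nonempty:
        mz_lo = min(float(s.mz[0]) for s in nonempty)
        mz_hi = max(float(s.mz[-1]) for s in nonempty)
    else:
        mz_lo = mz_hi = float("nan")
    return RunSummary(
        n_scans=len(run.scans),
        rt_range=(min(rts), max(rts)),
        mz_range=(mz_lo, mz_hi),
        tic=tic,
    )
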
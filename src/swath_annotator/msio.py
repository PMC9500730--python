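"""Centroided LC-MS run I/O (mzML) and extracted-ion-chromatogram slicing.

The reader/writer here covers the subset of mzML 1.1.0 this pipeline needs:
centroided MS1 and MS2 spectra, scan start times, scan polarity, and the
precursor isolation window of every MS2 scan (from which the SWATH window
scheme is recovered).  Binary arrays are 64-bit floats, base64-encoded,
optionally zlib-compressed; files written here are readable by standard
tools (validated against Bioconductor mzR in the test suite).  Profile-mode
spectra are rejected rather than silently centroided.

Retention time is minutes end-to-end; second-based files are converted at
the boundary.
"""

from __future__ import annotations

import base64
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from lxml import etree

from .errors import ConfigurationError, FormatError, UnsupportedDataError
from .ionization import SwathWindowScheme

_NS = "http://psi.hupo.org/ms/mzml"


@dataclass
class SpectrumScan:
    """One centroided scan: sorted m/z array, intensities, RT in minutes."""

    ms_level: int
    rt: float  # minutes
    mz_values: np.ndarray
    intensities: np.ndarray
    isolation_window: tuple[float, float] | None = None  # (lo, hi) Da, MS2 only
    polarity: str = "positive"

    def validate(self) -> None:
        if len(self.mz_values) != len(self.intensities):
            raise FormatError("m/z and intensity arrays differ in length")
        if self.rt < 0:
            raise FormatError(f"negative retention time {self.rt}")
        if len(self.mz_values) > 1 and not np.all(np.diff(self.mz_values) > 0):
            raise FormatError("m/z values must be strictly increasing")
        if self.ms_level == 2 and self.isolation_window is None:
            raise FormatError("MS2 scan lacks an isolation window")


@dataclass
class Run:
    """A time-ordered LC-MS run, optionally with its SWATH window scheme."""

    scans: list[SpectrumScan]
    polarity: str = "positive"
    scheme: SwathWindowScheme | None = None

    def validate(self) -> None:
        rts = [s.rt for s in self.scans]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise FormatError("scan retention times must be non-decreasing")
        for s in self.scans:
            s.validate()
        if self.scheme is not None:
            for s in self.scans:
                if s.ms_level == 2 and self.scheme.window_of(*s.isolation_window) is None:
                    raise FormatError(
                        f"MS2 isolation window {s.isolation_window} not in declared scheme")

    def ms1_scans(self) -> list[SpectrumScan]:
        return [s for s in self.scans if s.ms_level == 1]

    def ms2_scans(self, window_index: int) -> list[SpectrumScan]:
        if self.scheme is None:
            raise ConfigurationError("run has no SWATH window scheme")
        lo, hi = self.scheme.window_bounds(window_index)
        return [s for s in self.scans
                if s.ms_level == 2 and abs(s.isolation_window[0] - lo) <= 1e-6
                and abs(s.isolation_window[1] - hi) <= 1e-6]


@dataclass
class Xic:
    """Extracted-ion chromatogram: summed centroid intensity per scan vs RT."""

    target_mz: float
    tol: float
    rt: np.ndarray  # minutes, one per contributing scan
    intensity: np.ndarray
    scan_indices: np.ndarray | None = None  # indices into Run.scans

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.rt.tolist(), self.intensity.tolist()))

    def __len__(self) -> int:
        return len(self.rt)


# ---------------------------------------------------------------------------
# XIC extraction

def _scan_subset(run: Run, ms_level: int, window_index: int | None
                 ) -> tuple[list[SpectrumScan], np.ndarray]:
    if ms_level == 1:
        if window_index is not None:
            raise ConfigurationError("window_index applies to MS2 extraction only")
        idx = [i for i, s in enumerate(run.scans) if s.ms_level == 1]
    else:
        if window_index is None:
            raise ConfigurationError("MS2 extraction requires a window_index")
        if run.scheme is None:
            raise ConfigurationError("run has no SWATH window scheme")
        lo, hi = run.scheme.window_bounds(window_index)
        idx = [i for i, s in enumerate(run.scans)
               if s.ms_level == 2 and abs(s.isolation_window[0] - lo) <= 1e-6
               and abs(s.isolation_window[1] - hi) <= 1e-6]
    return [run.scans[i] for i in idx], np.asarray(idx, dtype=np.int64)


def extract_xics(run: Run, ms_level: int, lo: np.ndarray, hi: np.ndarray,
                 window_index: int | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised extraction of many mass slices at once.

    Returns ``(rts, matrix, scan_indices)`` with ``matrix[i, j]`` the summed
    centroid intensity of slice ``[lo[j], hi[j]]`` in the i-th qualifying
    scan.  Used by the screening stage, which slices hundreds of precursor
    windows per run.
    """
    lo = np.atleast_1d(np.asarray(lo, dtype=float))
    hi = np.atleast_1d(np.asarray(hi, dtype=float))
    scans, idx = _scan_subset(run, ms_level, window_index)
    rts = np.array([s.rt for s in scans], dtype=float)
    out = np.zeros((len(scans), len(lo)), dtype=float)
    for i, scan in enumerate(scans):
        if len(scan.mz_values) == 0:
            continue
        csum = np.concatenate(([0.0], np.cumsum(scan.intensities)))
        a = np.searchsorted(scan.mz_values, lo, side="left")
        b = np.searchsorted(scan.mz_values, hi, side="right")
        out[i] = csum[b] - csum[a]
    return rts, out, idx


def extract_xic(run: Run, ms_level: int, target_mz: float, tol: float,
                window_index: int | None = None) -> Xic:
    """XIC of ``target_mz`` +- ``tol`` Da from MS1 scans or one SWATH window's MS2."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    rts, mat, idx = extract_xics(run, ms_level, np.array([target_mz - tol]),
                                 np.array([target_mz + tol]), window_index)
    return Xic(target_mz=target_mz, tol=tol, rt=rts, intensity=mat[:, 0], scan_indices=idx)


# ---------------------------------------------------------------------------
# mzML writing

def _b64(arr: np.ndarray, compress: bool) -> str:
    raw = np.asarray(arr, dtype=np.float64).tobytes()
    if compress:
        raw = zlib.compress(raw)
    return base64.b64encode(raw).decode("ascii")


def _cv(accession: str, name: str, value: str = "", unit: tuple[str, str, str] | None = None) -> str:
    extra = ""
    if unit is not None:
        extra = (f' unitCvRef="{unit[0]}" unitAccession="{unit[1]}" unitName="{unit[2]}"')
    return f'<cvParam cvRef="MS" accession="{accession}" name="{name}" value="{value}"{extra}/>'


def _spectrum_xml(index: int, scan: SpectrumScan, compress: bool) -> str:
    n = len(scan.mz_values)
    parts = [f'<spectrum index="{index}" id="scan={index + 1}" defaultArrayLength="{n}">']
    parts.append(_cv("MS:1000511", "ms level", str(scan.ms_level)))
    if scan.ms_level == 1:
        parts.append(_cv("MS:1000579", "MS1 spectrum"))
    else:
        parts.append(_cv("MS:1000580", "MSn spectrum"))
    parts.append(_cv("MS:1000127", "centroid spectrum"))
    if scan.polarity == "positive":
        parts.append(_cv("MS:1000130", "positive scan"))
    else:
        parts.append(_cv("MS:1000129", "negative scan"))
    parts.append(
        '<scanList count="1">' + _cv("MS:1000795", "no combination") + "<scan>"
        + _cv("MS:1000016", "scan start time", repr(float(scan.rt)),
              ("UO", "UO:0000031", "minute"))
        + "</scan></scanList>")
    if scan.isolation_window is not None:
        lo, hi = scan.isolation_window
        tgt = 0.5 * (lo + hi)
        mz_unit = ("MS", "MS:1000040", "m/z")
        parts.append(
            '<precursorList count="1"><precursor><isolationWindow>'
            + _cv("MS:1000827", "isolation window target m/z", repr(tgt), mz_unit)
            + _cv("MS:1000828", "isolation window lower offset", repr(tgt - lo), mz_unit)
            + _cv("MS:1000829", "isolation window upper offset", repr(hi - tgt), mz_unit)
            + '</isolationWindow><selectedIonList count="1"><selectedIon>'
            + _cv("MS:1000744", "selected ion m/z", repr(tgt), mz_unit)
            + "</selectedIon></selectedIonList><activation>"
            + _cv("MS:1000044", "dissociation method")
            + "</activation></precursor></precursorList>")
    comp_cv = (_cv("MS:1000574", "zlib compression") if compress
               else _cv("MS:1000576", "no compression"))
    arrays = []
    for arr, acc, nm in ((scan.mz_values, "MS:1000514", "m/z array"),
                         (scan.intensities, "MS:1000515", "intensity array")):
        b = _b64(arr, compress)
        arrays.append(
            f'<binaryDataArray encodedLength="{len(b)}">'
            + _cv("MS:1000523", "64-bit float") + comp_cv + _cv(acc, nm)
            + f"<binary>{b}</binary></binaryDataArray>")
    parts.append(f'<binaryDataArrayList count="2">{"".join(arrays)}</binaryDataArrayList>')
    parts.append("</spectrum>")
    return "".join(parts)


def write_run(run: Run, path, compress: bool = True) -> None:
    """Write a run as mzML 1.1.0 (deterministic output: no timestamps)."""
    run.validate()
    spectra = "".join(_spectrum_xml(i, s, compress) for i, s in enumerate(run.scans))
    doc = (
        '<?xml version="1.0" encoding="utf-8"?>'
        f'<mzML xmlns="{_NS}" version="1.1.0">'
        '<cvList count="2">'
        '<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology"'
        ' URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
        '<cv id="UO" fullName="Unit Ontology"'
        ' URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>'
        "</cvList>"
        "<fileDescription><fileContent>"
        + _cv("MS:1000294", "mass spectrum")
        + "</fileContent></fileDescription>"
        '<softwareList count="1"><software id="swath_annotator" version="0.1.0"/></softwareList>'
        '<instrumentConfigurationList count="1"><instrumentConfiguration id="IC1"/>'
        "</instrumentConfigurationList>"
        '<dataProcessingList count="1"><dataProcessing id="dp1">'
        '<processingMethod order="0" softwareRef="swath_annotator"/>'
        "</dataProcessing></dataProcessingList>"
        '<run id="run1" defaultInstrumentConfigurationRef="IC1">'
        f'<spectrumList count="{len(run.scans)}" defaultDataProcessingRef="dp1">'
        f"{spectra}</spectrumList></run></mzML>"
    )
    Path(path).write_text(doc)


# ---------------------------------------------------------------------------
# mzML reading

def _decode_binary(bda: etree._Element) -> np.ndarray:
    names = {c.get("name") for c in bda.iter(f"{{{_NS}}}cvParam")}
    binary = bda.find(f"{{{_NS}}}binary")
    raw = base64.b64decode(binary.text or "")
    if "zlib compression" in names:
        raw = zlib.decompress(raw)
    dtype = np.float32 if "32-bit float" in names else np.float64
    return np.frombuffer(raw, dtype=dtype).astype(np.float64)


def _parse_spectrum(elem: etree._Element) -> SpectrumScan:
    cvnames = {}
    for cv in elem.iter(f"{{{_NS}}}cvParam"):
        cvnames.setdefault(cv.get("name"), cv)
    if "profile spectrum" in cvnames:
        raise UnsupportedDataError("profile-mode spectra are not supported; centroid first")
    ms_level = int(cvnames["ms level"].get("value")) if "ms level" in cvnames else 1

    rt = 0.0
    scan_el = elem.find(f"{{{_NS}}}scanList/{{{_NS}}}scan")
    if scan_el is not None:
        for cv in scan_el.iter(f"{{{_NS}}}cvParam"):
            if cv.get("name") == "scan start time":
                rt = float(cv.get("value"))
                if cv.get("unitName") == "second":
                    rt /= 60.0
    polarity = "negative" if "negative scan" in cvnames else "positive"

    iso = None
    iso_el = elem.find(f"{{{_NS}}}precursorList/{{{_NS}}}precursor/{{{_NS}}}isolationWindow")
    if iso_el is not None:
        vals = {cv.get("name"): float(cv.get("value"))
                for cv in iso_el.iter(f"{{{_NS}}}cvParam")}
        try:
            tgt = vals["isolation window target m/z"]
            iso = (tgt - vals["isolation window lower offset"],
                   tgt + vals["isolation window upper offset"])
        except KeyError as exc:
            raise FormatError(f"incomplete isolation window metadata: {exc}") from exc
    if ms_level >= 2 and iso is None:
        raise FormatError("MS2 scan without isolation-window metadata")

    mz = np.array([], dtype=np.float64)
    inten = np.array([], dtype=np.float64)
    for bda in elem.iter(f"{{{_NS}}}binaryDataArray"):
        names = {c.get("name") for c in bda.iter(f"{{{_NS}}}cvParam")}
        if "m/z array" in names:
            mz = _decode_binary(bda)
        elif "intensity array" in names:
            inten = _decode_binary(bda)
    return SpectrumScan(ms_level=ms_level, rt=rt, mz_values=mz, intensities=inten,
                        isolation_window=iso, polarity=polarity)


def _infer_scheme(scans: Sequence[SpectrumScan]) -> SwathWindowScheme | None:
    bounds = sorted({s.isolation_window for s in scans if s.ms_level == 2})
    if not bounds:
        return None
    widths = [hi - lo for lo, hi in bounds]
    width = float(np.median(widths))
    start, end = bounds[0][0], bounds[-1][1]
    scheme = SwathWindowScheme(start=start, end=end, width=width)
    # accept only if the observed windows are exactly the scheme's tiling
    if all(scheme.window_of(lo, hi, tol=1e-4) is not None for lo, hi in bounds):
        return scheme
    return None


def read_run(path) -> Run:
    """Read a centroided mzML file into a :class:`Run`.

    The SWATH window scheme is inferred from the set of MS2 isolation
    windows when they tile a contiguous fixed-width range.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    scans: list[SpectrumScan] = []
    try:
        for _, elem in etree.iterparse(str(path), events=("end",),
                                       tag=f"{{{_NS}}}spectrum"):
            scans.append(_parse_spectrum(elem))
            elem.clear()
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"not a readable mzML file: {exc}") from exc
    polarity = scans[0].polarity if scans else "positive"
    run = Run(scans=scans, polarity=polarity, scheme=_infer_scheme(scans))
    run.validate()
    return run
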
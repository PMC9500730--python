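"""Spectral-library parsing and curation into a DIA transition database.

A raw MS/MS library record (one acquisition, keyed by its SPLASH) is turned
into a per-compound transition entry in four steps:

1. intensities are rescaled so the base peak is exactly 100 (relative %),
2. fragments below 5% relative intensity are discarded; survivors are tagged
   ``D`` (main daughter, > 75%) or ``F`` (secondary daughter),
3. near-duplicate fragment m/z (within a small tolerance, default 0.01 Da)
   are collapsed keeping the most intense representative,
4. per-adduct precursor m/z values are computed and assigned to SWATH
   windows; entries whose adducts all fall outside the acquisition range, or
   that retain no ``D`` fragment, are rejected.

Thresholds follow strict-inequality semantics: exactly 5% is retained (as
``F``), exactly 75% is ``F`` not ``D``.  Multiple fragments may be tagged
``D``; the base peak is simply the 100% fragment.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

from .errors import ConfigurationError, DegenerateSpectrumError, ParseError
from .ionization import AdductDefinition, SwathWindowScheme, adduct_mz, assign_window

log = logging.getLogger(__name__)

REL_INT_MIN_PCT = 5.0
D_THRESHOLD_PCT = 75.0
DEDUP_MZ_TOL = 0.01

_CSV_COLUMNS = [
    "compound_id", "splash_id", "compound_name", "neutral_mass", "polarity",
    "resolution", "collision_energy", "fragment_mz", "fragment_intensity",
]


@dataclass
class LibrarySpectrum:
    """One acquired MS/MS record with raw fragment intensities."""

    splash_id: str
    compound_id: str
    compound_name: str
    neutral_mass: float  # monoisotopic, Da
    polarity: str  # "positive" | "negative"
    fragments: list[tuple[float, float]]  # (mz Da, intensity counts)
    resolution: str = "high"  # "high" | "low"
    collision_energy: float | None = None

    def validate(self, index: int | None = None) -> None:
        where = f"record {index}" if index is not None else f"spectrum {self.splash_id}"
        if self.neutral_mass <= 0:
            raise ParseError(f"{where}: neutral mass must be positive, got {self.neutral_mass}")
        if not self.fragments:
            raise ParseError(f"{where}: no fragments")
        for mz, inten in self.fragments:
            if mz <= 0:
                raise ParseError(f"{where}: fragment m/z must be positive, got {mz}")
            if inten < 0:
                raise ParseError(f"{where}: negative fragment intensity {inten}")


@dataclass(frozen=True)
class CuratedFragment:
    """A retained transition: m/z, relative intensity (% of base peak), D/F tag."""

    mz: float
    relative_intensity: float
    tag: str  # "D" | "F"


@dataclass(frozen=True)
class PrecursorIon:
    adduct_name: str
    mz: float
    window_index: int


@dataclass
class DiaLibraryEntry:
    """Curated per-compound transition record of the DIA database."""

    compound_id: str
    splash_id: str
    polarity: str
    precursors: list[PrecursorIon]
    fragments: list[CuratedFragment]  # sorted by descending relative intensity
    compound_name: str = ""
    neutral_mass: float = 0.0

    @property
    def has_d(self) -> bool:
        return any(f.tag == "D" for f in self.fragments)


@dataclass(frozen=True)
class Rejection:
    """A spectrum excluded from the DIA database, with the reason logged."""

    splash_id: str
    compound_id: str
    reason: str


# ---------------------------------------------------------------------------
# parsing

def parse_spectra(source, dialect: str,
                  where: Callable[[LibrarySpectrum], bool] | None = None,
                  ) -> list[LibrarySpectrum]:
    """Parse library records from ``source`` (path) in the given dialect.

    Supported dialects: ``msp`` (NIST-style blocks, via matchms), ``csv``
    (one row per fragment, columns documented in docs/library_formats.md),
    ``json`` (one object per spectrum).  Records with zero fragments are
    logged and dropped; any malformed record raises :class:`ParseError`
    naming its index.  ``where`` is an optional user predicate (e.g. a
    biospecimen filter) applied after parsing.
    """
    if dialect == "msp":
        spectra = _parse_msp(source)
    elif dialect == "csv":
        spectra = _parse_csv(source)
    elif dialect == "json":
        spectra = _parse_json(source)
    else:
        raise ConfigurationError(f"unknown library dialect {dialect!r}")

    out: list[LibrarySpectrum] = []
    for i, spec in enumerate(spectra):
        if not spec.fragments:
            log.warning("record %d (%s): zero fragments, dropped", i, spec.splash_id)
            continue
        spec.validate(index=i)
        if where is None or where(spec):
            out.append(spec)
    return out


def _coerce_polarity(value) -> str:
    v = str(value).strip().lower()
    if v in ("positive", "pos", "p", "1", "+"):
        return "positive"
    if v in ("negative", "neg", "n", "-1", "-"):
        return "negative"
    raise ParseError(f"unrecognised polarity {value!r}")


def _coerce_ce(value) -> float | None:
    if value is None or value == "" or (isinstance(value, float) and pd.isna(value)):
        return None
    try:
        return float(str(value).lower().replace("ev", "").strip())
    except ValueError:
        return None  # e.g. "ramp 20-50": treated as unknown


def _parse_msp(source) -> list[LibrarySpectrum]:
    from matchms.importing import load_from_msp

    out = []
    try:
        records = list(load_from_msp(str(source), metadata_harmonization=False))
    except Exception as exc:  # matchms raises assorted errors on bad blocks
        raise ParseError(f"failed to parse MSP file {source}: {exc}") from exc
    for i, rec in enumerate(records):
        if rec is None:
            raise ParseError(f"record {i}: unreadable MSP block")
        meta = rec.metadata
        mass = meta.get("exactmass") or meta.get("parent_mass") or meta.get("exact_mass")
        if mass is None:
            raise ParseError(f"record {i}: missing EXACTMASS")
        out.append(LibrarySpectrum(
            splash_id=str(meta.get("splash", f"record-{i}")),
            compound_id=str(meta.get("compound_id", meta.get("db#", f"record-{i}"))),
            compound_name=str(meta.get("compound_name", meta.get("name", ""))),
            neutral_mass=float(mass),
            polarity=_coerce_polarity(meta.get("ionmode", "positive")),
            resolution=str(meta.get("resolution", "high")).lower(),
            collision_energy=_coerce_ce(meta.get("collision_energy")),
            fragments=[(float(m), float(x)) for m, x in zip(rec.peaks.mz, rec.peaks.intensities)],
        ))
    return out


def _parse_csv(source) -> list[LibrarySpectrum]:
    df = pd.read_csv(source)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns and c not in
               ("compound_name", "resolution", "collision_energy")]
    if missing:
        raise ParseError(f"CSV library missing columns: {missing}")
    out = []
    for splash, grp in df.groupby("splash_id", sort=False):
        first = grp.iloc[0]
        out.append(LibrarySpectrum(
            splash_id=str(splash),
            compound_id=str(first["compound_id"]),
            compound_name=str(first.get("compound_name", "")),
            neutral_mass=float(first["neutral_mass"]),
            polarity=_coerce_polarity(first["polarity"]),
            resolution=str(first.get("resolution", "high")).lower(),
            collision_energy=_coerce_ce(first.get("collision_energy")),
            fragments=list(zip(grp["fragment_mz"].astype(float), grp["fragment_intensity"].astype(float))),
        ))
    return out


def _parse_json(source) -> list[LibrarySpectrum]:
    with open(source) as fh:
        records = json.load(fh)
    if not isinstance(records, list):
        raise ParseError("JSON library must be a list of spectrum objects")
    out = []
    for i, rec in enumerate(records):
        try:
            out.append(LibrarySpectrum(
                splash_id=str(rec["splash_id"]),
                compound_id=str(rec["compound_id"]),
                compound_name=str(rec.get("compound_name", "")),
                neutral_mass=float(rec["neutral_mass"]),
                polarity=_coerce_polarity(rec["polarity"]),
                resolution=str(rec.get("resolution", "high")),
                collision_energy=_coerce_ce(rec.get("collision_energy")),
                fragments=[(float(m), float(x)) for m, x in rec["fragments"]],
            ))
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"record {i}: {exc}") from exc
    return out


def write_spectra(spectra: Sequence[LibrarySpectrum], path, dialect: str) -> None:
    """Serialize raw spectra back to a library file (csv/json/msp)."""
    path = Path(path)
    if dialect == "csv":
        rows = [
            {
                "compound_id": s.compound_id, "splash_id": s.splash_id,
                "compound_name": s.compound_name, "neutral_mass": s.neutral_mass,
                "polarity": s.polarity, "resolution": s.resolution,
                "collision_energy": s.collision_energy,
                "fragment_mz": mz, "fragment_intensity": inten,
            }
            for s in spectra for mz, inten in s.fragments
        ]
        pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
    elif dialect == "json":
        payload = [
            {
                "splash_id": s.splash_id, "compound_id": s.compound_id,
                "compound_name": s.compound_name, "neutral_mass": s.neutral_mass,
                "polarity": s.polarity, "resolution": s.resolution,
                "collision_energy": s.collision_energy,
                "fragments": [[mz, inten] for mz, inten in s.fragments],
            }
            for s in spectra
        ]
        path.write_text(json.dumps(payload, indent=1))
    elif dialect == "msp":
        blocks = []
        for s in spectra:
            lines = [
                f"NAME: {s.compound_name}",
                f"SPLASH: {s.splash_id}",
                f"COMPOUND_ID: {s.compound_id}",
                f"EXACTMASS: {s.neutral_mass!r}",
                f"IONMODE: {s.polarity}",
                f"RESOLUTION: {s.resolution}",
            ]
            if s.collision_energy is not None:
                lines.append(f"COLLISION_ENERGY: {s.collision_energy!r}")
            lines.append(f"Num Peaks: {len(s.fragments)}")
            lines += [f"{mz!r} {inten!r}" for mz, inten in s.fragments]
            blocks.append("\n".join(lines))
        path.write_text("\n\n".join(blocks) + "\n")
    else:
        raise ConfigurationError(f"unknown library dialect {dialect!r}")


# ---------------------------------------------------------------------------
# curation

def normalize_relative(spectrum: LibrarySpectrum) -> list[tuple[float, float]]:
    """Rescale raw intensities so the base peak is exactly 100 (order preserved)."""
    if not spectrum.fragments:
        raise DegenerateSpectrumError(f"{spectrum.splash_id}: no fragments")
    top = max(inten for _, inten in spectrum.fragments)
    if top <= 0:
        raise DegenerateSpectrumError(f"{spectrum.splash_id}: all intensities are zero")
    # divide before scaling so the base peak is exactly 100.0 in floats
    return [(mz, 100.0 * (inten / top)) for mz, inten in spectrum.fragments]


def tag_and_filter(fragments: Iterable[tuple[float, float]],
                   rel_int_min_pct: float = REL_INT_MIN_PCT,
                   d_threshold_pct: float = D_THRESHOLD_PCT) -> list[CuratedFragment]:
    """Drop fragments below 5% relative intensity; tag survivors D (> 75%) or F.

    Boundaries are strict: exactly 5 is retained (F), exactly 75 is F.
    """
    out = []
    for mz, rel in fragments:
        if rel < rel_int_min_pct:
            continue
        tag = "D" if rel > d_threshold_pct else "F"
        out.append(CuratedFragment(mz=mz, relative_intensity=rel, tag=tag))
    return out


def collapse_near_duplicates(fragments: Sequence[CuratedFragment],
                             mz_tol: float = DEDUP_MZ_TOL) -> list[CuratedFragment]:
    """Merge fragments whose m/z agree within ``mz_tol`` Da.

    Public spectral repositories pool records from heterogeneous instruments,
    so the same transition often recurs with a slight mass shift.  The most
    intense representative wins (ties: lower m/z).  Output is sorted by
    descending relative intensity.
    """
    if mz_tol <= 0:
        raise ValueError("mz_tol must be positive")
    kept: list[CuratedFragment] = []
    for frag in sorted(fragments, key=lambda f: (-f.relative_intensity, f.mz)):
        if any(abs(frag.mz - k.mz) <= mz_tol for k in kept):
            continue
        kept.append(frag)
    return kept


def curate_spectrum(spectrum: LibrarySpectrum,
                    rel_int_min_pct: float = REL_INT_MIN_PCT,
                    d_threshold_pct: float = D_THRESHOLD_PCT,
                    dedup_mz_tol: float = DEDUP_MZ_TOL) -> list[CuratedFragment]:
    """normalize -> tag_and_filter -> collapse_near_duplicates (idempotent)."""
    rel = normalize_relative(spectrum)
    tagged = tag_and_filter(rel, rel_int_min_pct, d_threshold_pct)
    return collapse_near_duplicates(tagged, dedup_mz_tol)


def build_dia_entry(spectrum: LibrarySpectrum,
                    adducts: Sequence[AdductDefinition],
                    scheme: SwathWindowScheme,
                    fragments: Sequence[CuratedFragment] | None = None,
                    **curation_kwargs) -> DiaLibraryEntry | Rejection:
    """Build the transition-database entry for one curated spectrum.

    Returns a :class:`Rejection` (not an exception) when no fragment is
    tagged D or when every adduct precursor falls outside the acquisition
    range.  Individual out-of-range adducts are silently dropped.
    """
    wrong = [a.name for a in adducts if a.polarity != spectrum.polarity]
    if wrong:
        raise ConfigurationError(
            f"adducts {wrong} do not match spectrum polarity {spectrum.polarity}")
    if fragments is None:
        fragments = curate_spectrum(spectrum, **curation_kwargs)
    fragments = sorted(fragments, key=lambda f: (-f.relative_intensity, f.mz))
    if not any(f.tag == "D" for f in fragments):
        log.info("rejecting %s: no main-daughter (D) fragment", spectrum.splash_id)
        return Rejection(spectrum.splash_id, spectrum.compound_id,
                         "no main-daughter (D) fragment after curation")
    precursors = []
    for add in adducts:
        mz = adduct_mz(spectrum.neutral_mass, add)
        if scheme.contains(mz):
            precursors.append(PrecursorIon(add.name, mz, assign_window(mz, scheme)))
    if not precursors:
        log.info("rejecting %s: all adduct m/z outside acquisition range", spectrum.splash_id)
        return Rejection(spectrum.splash_id, spectrum.compound_id,
                         "all adduct m/z outside acquisition range")
    return DiaLibraryEntry(
        compound_id=spectrum.compound_id, splash_id=spectrum.splash_id,
        polarity=spectrum.polarity, precursors=precursors, fragments=list(fragments),
        compound_name=spectrum.compound_name, neutral_mass=spectrum.neutral_mass,
    )


def build_dia_library(spectra: Sequence[LibrarySpectrum],
                      adducts: Sequence[AdductDefinition],
                      scheme: SwathWindowScheme,
                      **curation_kwargs) -> tuple[list[DiaLibraryEntry], list[Rejection]]:
    entries, rejections = [], []
    for spec in spectra:
        result = build_dia_entry(spec, adducts, scheme, **curation_kwargs)
        (entries if isinstance(result, DiaLibraryEntry) else rejections).append(result)
    return entries, rejections


# ---------------------------------------------------------------------------
# DIA database I/O

def write_dia_library(entries: Sequence[DiaLibraryEntry], path, fmt: str = "csv") -> None:
    """Write the transition database (long CSV, or nested JSON)."""
    path = Path(path)
    if fmt == "csv":
        rows = [
            {
                "compound_id": e.compound_id, "splash_id": e.splash_id,
                "compound_name": e.compound_name, "neutral_mass": e.neutral_mass,
                "polarity": e.polarity, "adduct": p.adduct_name,
                "precursor_mz": p.mz, "window_index": p.window_index,
                "fragment_mz": f.mz, "relative_intensity": f.relative_intensity,
                "tag": f.tag,
            }
            for e in entries for p in e.precursors for f in e.fragments
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
    elif fmt == "json":
        payload = [
            {
                "compound_id": e.compound_id, "splash_id": e.splash_id,
                "compound_name": e.compound_name, "neutral_mass": e.neutral_mass,
                "polarity": e.polarity,
                "precursors": [
                    {"adduct": p.adduct_name, "mz": p.mz, "window_index": p.window_index}
                    for p in e.precursors
                ],
                "fragments": [
                    {"mz": f.mz, "relative_intensity": f.relative_intensity, "tag": f.tag}
                    for f in e.fragments
                ],
            }
            for e in entries
        ]
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ConfigurationError(f"unknown DIA library format {fmt!r}")


def read_dia_library(path, fmt: str | None = None) -> list[DiaLibraryEntry]:
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    entries: list[DiaLibraryEntry] = []
    if fmt == "csv":
        df = pd.read_csv(path)
        for splash, grp in df.groupby("splash_id", sort=False):
            first = grp.iloc[0]
            prec = grp.drop_duplicates(subset=["adduct"])
            frags = grp.drop_duplicates(subset=["fragment_mz", "relative_intensity", "tag"])
            entries.append(DiaLibraryEntry(
                compound_id=str(first["compound_id"]), splash_id=str(splash),
                polarity=str(first["polarity"]),
                compound_name=str(first.get("compound_name", "")),
                neutral_mass=float(first.get("neutral_mass", 0.0)),
                precursors=[PrecursorIon(str(r["adduct"]), float(r["precursor_mz"]),
                                         int(r["window_index"]))
                            for _, r in prec.iterrows()],
                fragments=sorted(
                    (CuratedFragment(float(r["fragment_mz"]), float(r["relative_intensity"]),
                                     str(r["tag"])) for _, r in frags.iterrows()),
                    key=lambda f: (-f.relative_intensity, f.mz)),
            ))
    elif fmt == "json":
        for rec in json.loads(path.read_text()):
            entries.append(DiaLibraryEntry(
                compound_id=rec["compound_id"], splash_id=rec["splash_id"],
                polarity=rec["polarity"], compound_name=rec.get("compound_name", ""),
                neutral_mass=rec.get("neutral_mass", 0.0),
                precursors=[PrecursorIon(p["adduct"], p["mz"], p["window_index"])
                            for p in rec["precursors"]],
                fragments=[CuratedFragment(f["mz"], f["relative_intensity"], f["tag"])
                           for f in rec["fragments"]],
            ))
    else:
        raise ConfigurationError(f"unknown DIA library format {fmt!r}")
    return entries


# ---------------------------------------------------------------------------
# HMDB converter stub

#: Expected field mapping for a converter from an HMDB spectral export to the
#: CSV dialect above.  Bulk HMDB parsing is out of scope; this documents the
#: contract for anyone writing that converter.
HMDB_FIELD_MAPPING = {
    "accession": "compound_id",
    "splash_key": "splash_id",
    "name": "compound_name",
    "monisotopic_molecular_weight": "neutral_mass",
    "ionization_mode": "polarity",
    "collision_energy_voltage": "collision_energy",
    "ms_ms_peaks.mass_charge": "fragment_mz",
    "ms_ms_peaks.intensity": "fragment_intensity",
}


def convert_hmdb_export(*args, **kwargs):  # pragma: no cover - documented stub
    """Stub: converting a bulk HMDB export is not implemented.

    See :data:`HMDB_FIELD_MAPPING` for the field correspondence a converter
    must honour; records lacking experimental high-resolution MS/MS peaks
    should be skipped.
    """
    raise NotImplementedError("HMDB bulk-export conversion is out of scope; "
                              "see HMDB_FIELD_MAPPING for the expected schema")
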
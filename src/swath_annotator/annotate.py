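"""Fragment alignment, filtration, scoring and redundancy resolution.

For each screened candidate precursor the library fragments are extracted
from the MS2 scans of the candidate's SWATH window (+-0.05 Da), peak
detection being restricted to the neighbourhood of the precursor apex.
Fragments are then aligned to their precursor through two dimensionless
shift statistics::

    rt_shift    = |parent_RT   - fragment_RT|   / parent_RT
    width_shift = |parent_FWHM - fragment_FWHM| / parent_FWHM

and retained when rt_shift < 0.1417% and width_shift < 17.4965% (percent
reading; see :mod:`swath_annotator.params`), the fragment's sample:blank
height ratio is >= 5, and - after a second pass that rescales retained
heights so the tallest is 100 - the observed relative intensity is >= 5%.
Identifications whose surviving fragments contain no main daughter (D) are
discarded; fragment XICs claimed by several compounds are awarded to the
one with the smaller precursor mass error; multiple adducts of one compound
merge into a single identification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .msio import Run, Xic, extract_xics
from .params import FiltrationParams
from .peaks import PeakFeature, detect_peak, height_ratio
from .screen import CandidatePrecursor, screen_precursors
from .speclib import DiaLibraryEntry

log = logging.getLogger(__name__)


def rt_shift(parent_rt: float, fragment_rt: float) -> float:
    """Relative apex-RT mismatch of a fragment from its precursor."""
    if parent_rt <= 0:
        raise ValueError(f"parent RT must be positive, got {parent_rt}")
    return abs(parent_rt - fragment_rt) / parent_rt


def width_shift(parent_fwhm: float, fragment_fwhm: float) -> float:
    """Relative FWHM mismatch of a fragment from its precursor."""
    if parent_fwhm <= 0:
        raise ValueError(f"parent FWHM must be positive, got {parent_fwhm}")
    return abs(parent_fwhm - fragment_fwhm) / parent_fwhm


@dataclass
class AlignedFragment:
    """One library fragment after XIC extraction against its precursor."""

    library_mz: float
    tag: str  # "D" | "F"
    library_relative_intensity: float
    peak: PeakFeature | None = None
    rt_shift: float = float("nan")
    width_shift: float = float("nan")
    blank_ratio: float = float("inf")
    observed_relative_intensity: float = float("nan")
    retained: bool = False


@dataclass
class Identification:
    """A candidate precursor with its aligned, filtered fragments and a score."""

    compound_id: str
    splash_id: str
    adducts: list[str]
    candidate: CandidatePrecursor
    fragments: list[AlignedFragment]
    score: float = float("nan")

    @property
    def has_d(self) -> bool:
        return any(f.retained and f.tag == "D" for f in self.fragments)

    @property
    def n_retained(self) -> int:
        return sum(f.retained for f in self.fragments)


def align_fragments(candidate: CandidatePrecursor, run: Run,
                    entry: DiaLibraryEntry, params: FiltrationParams | None = None,
                    blank: Run | None = None) -> list[AlignedFragment]:
    """Extract and align every library fragment in the candidate's SWATH window.

    Fragment peaks are searched within apex +- 3 parent FWHM.  Fragments
    with no detectable peak come back with ``peak=None, retained=False``.
    """
    params = params or FiltrationParams()
    if run.scheme is None or not 0 <= candidate.window_index < run.scheme.n_windows:
        raise ConfigurationError(
            f"candidate window {candidate.window_index} not valid for this run")
    frags = entry.fragments
    if not frags:
        return []
    mzs = np.array([f.mz for f in frags])
    rts, mat, idx = extract_xics(run, 2, mzs - params.frag_tol_da,
                                 mzs + params.frag_tol_da, candidate.window_index)
    if blank is not None and params.fragment_blank_gate:
        b_rts, b_mat, b_idx = extract_xics(blank, 2, mzs - params.frag_tol_da,
                                           mzs + params.frag_tol_da,
                                           candidate.window_index)
    parent = candidate.peak
    halfwidth = 3.0 * parent.fwhm
    out: list[AlignedFragment] = []
    for j, frag in enumerate(frags):
        af = AlignedFragment(library_mz=frag.mz, tag=frag.tag,
                             library_relative_intensity=frag.relative_intensity)
        xic = Xic(target_mz=frag.mz, tol=params.frag_tol_da, rt=rts,
                  intensity=mat[:, j], scan_indices=idx)
        peak = detect_peak(xic, expected_rt=parent.apex_rt,
                           rt_halfwidth=halfwidth) if len(xic) >= 5 else None
        if peak is not None:
            af.peak = peak
            af.rt_shift = rt_shift(parent.apex_rt, peak.apex_rt)
            af.width_shift = width_shift(parent.fwhm, peak.fwhm)
            if blank is not None and params.fragment_blank_gate:
                b_xic = Xic(target_mz=frag.mz, tol=params.frag_tol_da, rt=b_rts,
                            intensity=b_mat[:, j], scan_indices=b_idx)
                b_peak = detect_peak(b_xic, expected_rt=peak.apex_rt,
                                     rt_halfwidth=2.0 * peak.fwhm) if len(b_xic) >= 5 else None
                af.blank_ratio = height_ratio(peak, b_peak)
        out.append(af)
    return out


def apply_filtration(fragments: list[AlignedFragment],
                     params: FiltrationParams | None = None) -> list[AlignedFragment]:
    """Two-pass fragment filtration (mutates and returns ``fragments``).

    Pass 1 gates on peak presence, blank ratio (inclusive >=), RT shift and
    width shift (strict <).  Pass 2 recomputes relative intensities over the
    pass-1 survivors only - so a background-dominated tall XIC cannot
    distort the scale - and drops fragments below 5%.
    """
    params = params or FiltrationParams()
    survivors = []
    for f in fragments:
        f.retained = False
        if f.peak is None:
            continue
        if not f.blank_ratio >= params.filter_blank_ratio_min:
            continue
        if not (f.rt_shift < params.rt_shift_max and f.width_shift < params.width_shift_max):
            continue
        survivors.append(f)
    if not survivors:
        return fragments
    base = max(f.peak.height for f in survivors)
    for f in survivors:
        f.observed_relative_intensity = 100.0 * f.peak.height / base
        f.retained = f.observed_relative_intensity >= params.rel_int_min_pct
    return fragments


def score(identification: Identification,
          params: FiltrationParams | None = None) -> float:
    """Composite identification score in [0, 1].

    score = w_cov * (library-weighted retained coverage)
          + w_rt  * (1 - mean retained rt_shift / rt_shift_max)
          + w_cos * (cosine between observed and library relative intensities)

    with default weights 0.5 / 0.3 / 0.2.  The score is the package's own
    construction: deterministic, documented, with configurable weights.
    """
    params = params or FiltrationParams()
    frags = identification.fragments
    retained = [f for f in frags if f.retained]
    if not retained:
        return float("nan")
    total_w = sum(f.library_relative_intensity for f in frags)
    cov = sum(f.library_relative_intensity for f in retained) / total_w if total_w > 0 else 0.0
    rt_term = 1.0 - float(np.mean([min(f.rt_shift / params.rt_shift_max, 1.0)
                                   for f in retained]))
    obs = np.array([f.observed_relative_intensity for f in retained])
    lib = np.array([f.library_relative_intensity for f in retained])
    denom = np.linalg.norm(obs) * np.linalg.norm(lib)
    cos = float(obs @ lib / denom) if denom > 0 else 0.0
    total = params.w_coverage + params.w_rt + params.w_cosine
    return (params.w_coverage * cov + params.w_rt * rt_term + params.w_cosine * cos) / total


def _fragments_clash(a: AlignedFragment, b: AlignedFragment,
                     params: FiltrationParams) -> bool:
    """Do two retained fragments claim the same XIC (same m/z slice and apex)?"""
    if a.peak is None or b.peak is None:
        return False
    if abs(a.library_mz - b.library_mz) > params.dedup_mz_tol:
        return False
    ref = max(a.peak.apex_rt, b.peak.apex_rt)
    return abs(a.peak.apex_rt - b.peak.apex_rt) <= params.rt_shift_max * ref


def dedup_redundant(identifications: list[Identification],
                    params: FiltrationParams | None = None) -> list[Identification]:
    """Resolve shared fragment XICs and merge multi-adduct identifications.

    A fragment XIC claimed by identifications of *different* compounds (same
    window, m/z within the dedup tolerance, apices within the RT-shift gate)
    is kept only for the compound whose precursor mass error is smaller
    (tie: higher score).  Identifications left without retained fragments or
    without a D fragment are dropped.  Several adducts of one compound merge
    into a single identification listing all adducts (the best-scoring
    candidate becomes primary) - cross-adduct redundancy is informative, not
    erroneous.
    """
    params = params or FiltrationParams()

    # merge adducts of the same compound first
    by_compound: dict[str, list[Identification]] = {}
    for ident in identifications:
        by_compound.setdefault(ident.compound_id, []).append(ident)
    merged: list[Identification] = []
    for cid, group in by_compound.items():
        group.sort(key=lambda x: (-(x.score if np.isfinite(x.score) else -1.0),
                                  x.candidate.adduct_name))
        primary = group[0]
        primary.adducts = sorted({g.candidate.adduct_name for g in group})
        merged.append(primary)

    # cross-compound fragment-XIC arbitration
    for i, a in enumerate(merged):
        for b in merged[i + 1:]:
            if a.candidate.window_index != b.candidate.window_index:
                continue
            for fa in a.fragments:
                if not fa.retained:
                    continue
                for fb in b.fragments:
                    if not fb.retained or not _fragments_clash(fa, fb, params):
                        continue
                    key_a = (abs(a.candidate.ppm_error), -(a.score if np.isfinite(a.score) else -1))
                    key_b = (abs(b.candidate.ppm_error), -(b.score if np.isfinite(b.score) else -1))
                    loser = fb if key_a <= key_b else fa
                    loser.retained = False

    out = []
    for ident in merged:
        if ident.n_retained == 0 or not ident.has_d:
            log.info("dropping %s after redundancy resolution (no retained D)",
                     ident.compound_id)
            continue
        ident.score = score(ident, params)
        out.append(ident)
    out.sort(key=lambda x: (x.compound_id, x.adducts[0] if x.adducts else ""))
    return out


def identifications_to_frame(identifications: list[Identification]):
    """Flat result table, stably sorted by (compound_id, adduct)."""
    import pandas as pd

    rows = [
        {
            "compound_id": i.compound_id, "splash_id": i.splash_id,
            "adducts": ";".join(i.adducts),
            "library_mz": i.candidate.library_mz,
            "observed_mz": i.candidate.observed_mz,
            "ppm_error": i.candidate.ppm_error,
            "window_index": i.candidate.window_index,
            "apex_rt": i.candidate.peak.apex_rt,
            "height": i.candidate.peak.height,
            "fwhm": i.candidate.peak.fwhm,
            "snr": i.candidate.snr,
            "blank_ratio": i.candidate.blank_ratio,
            "n_fragments_retained": i.n_retained,
            "n_fragments_library": len(i.fragments),
            "score": i.score,
        }
        for i in identifications
    ]
    cols = ["compound_id", "splash_id", "adducts", "library_mz", "observed_mz",
            "ppm_error", "window_index", "apex_rt", "height", "fwhm", "snr",
            "blank_ratio", "n_fragments_retained", "n_fragments_library", "score"]
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["compound_id", "adducts"], kind="stable", ignore_index=True)


def fragments_to_frame(identifications: list[Identification]):
    """Per-fragment alignment table across all identifications."""
    import pandas as pd

    rows = []
    for i in identifications:
        for f in i.fragments:
            rows.append({
                "compound_id": i.compound_id, "splash_id": i.splash_id,
                "fragment_mz": f.library_mz, "tag": f.tag,
                "library_relative_intensity": f.library_relative_intensity,
                "detected": f.peak is not None,
                "apex_rt": f.peak.apex_rt if f.peak else float("nan"),
                "height": f.peak.height if f.peak else float("nan"),
                "fwhm": f.peak.fwhm if f.peak else float("nan"),
                "rt_shift": f.rt_shift, "width_shift": f.width_shift,
                "blank_ratio": f.blank_ratio,
                "observed_relative_intensity": f.observed_relative_intensity,
                "retained": f.retained,
            })
    cols = ["compound_id", "splash_id", "fragment_mz", "tag",
            "library_relative_intensity", "detected", "apex_rt", "height",
            "fwhm", "rt_shift", "width_shift", "blank_ratio",
            "observed_relative_intensity", "retained"]
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["compound_id", "fragment_mz"], kind="stable", ignore_index=True)


def annotate_run(sample: Run, blank: Run | None,
                 library: list[DiaLibraryEntry],
                 params: FiltrationParams | None = None) -> list[Identification]:
    """Full pipeline: screen -> align -> filter -> score -> de-duplicate.

    Deterministic for identical inputs and parameters; output is stably
    sorted by (compound_id, adduct).
    """
    params = params or FiltrationParams()
    entries = {e.splash_id: e for e in library}
    candidates = screen_precursors(sample, blank, library, params)
    identifications: list[Identification] = []
    for cand in candidates:
        entry = entries[cand.splash_id]
        frags = align_fragments(cand, sample, entry, params, blank=blank)
        apply_filtration(frags, params)
        ident = Identification(compound_id=cand.compound_id, splash_id=cand.splash_id,
                               adducts=[cand.adduct_name], candidate=cand,
                               fragments=frags)
        if ident.n_retained == 0 or not ident.has_d:
            continue  # precursors without a prominent daughter are neglected
        ident.score = score(ident, params)
        identifications.append(ident)
    return dedup_redundant(identifications, params)
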
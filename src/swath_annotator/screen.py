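"""Precursor screening: find library precursors in the MS1 of a SWATH run.

Every (compound, adduct) precursor m/z in the transition database is sliced
out of the sample's MS1 scans at +-10 ppm, peak-detected, and gated on
XIC signal-to-noise (> 30) and the sample:blank height ratio (> 5, strict
at this stage).  Each passing pair yields exactly one candidate - the best
detected peak - carrying the measured apex RT, height and FWHM that the
fragment-alignment stage aligns against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .ionization import ppm_window
from .msio import Run, Xic, extract_xics
from .params import FiltrationParams
from .peaks import PeakFeature, detect_peak, estimate_snr, height_ratio
from .speclib import DiaLibraryEntry

log = logging.getLogger(__name__)


@dataclass
class CandidatePrecursor:
    """A library precursor found in MS1 and surviving the screening gates."""

    compound_id: str
    splash_id: str
    adduct_name: str
    library_mz: float
    observed_mz: float
    ppm_error: float
    window_index: int
    peak: PeakFeature
    blank_ratio: float
    snr: float


def _observed_mz(run: Run, scan_idx: int, lo: float, hi: float, fallback: float) -> float:
    """Intensity-weighted mean m/z inside the extraction window at the apex scan."""
    scan = run.scans[scan_idx]
    a = np.searchsorted(scan.mz_values, lo, side="left")
    b = np.searchsorted(scan.mz_values, hi, side="right")
    if b <= a:
        return fallback
    mz = scan.mz_values[a:b]
    w = scan.intensities[a:b]
    tot = float(w.sum())
    return float((mz * w).sum() / tot) if tot > 0 else fallback


def screen_precursors(sample: Run, blank: Run | None,
                      library: list[DiaLibraryEntry],
                      params: FiltrationParams | None = None) -> list[CandidatePrecursor]:
    """Search every library precursor in the sample MS1 and apply the gates.

    ``blank`` may be ``None``, in which case every blank ratio is +inf and a
    loud warning is emitted (a blank injection is part of the published
    acquisition design).
    """
    params = params or FiltrationParams()
    if blank is not None and blank.polarity != sample.polarity:
        raise ConfigurationError(
            f"sample polarity {sample.polarity} != blank polarity {blank.polarity}")
    if blank is None:
        log.warning("no blank run supplied: blank ratios set to +inf")

    targets = [(entry, prec) for entry in library
               if entry.polarity == sample.polarity
               for prec in entry.precursors]
    if not targets:
        return []
    lohi = np.array([ppm_window(p.mz, params.ppm_tol) for _, p in targets])
    s_rts, s_mat, s_idx = extract_xics(sample, 1, lohi[:, 0], lohi[:, 1])
    if blank is not None:
        b_rts, b_mat, b_idx = extract_xics(blank, 1, lohi[:, 0], lohi[:, 1])

    candidates: list[CandidatePrecursor] = []
    for j, (entry, prec) in enumerate(targets):
        xic = Xic(target_mz=prec.mz, tol=prec.mz * params.ppm_tol * 1e-6,
                  rt=s_rts, intensity=s_mat[:, j], scan_indices=s_idx)
        if len(xic) < 5:
            continue
        peak = detect_peak(xic)
        if peak is None:
            continue
        snr = estimate_snr(xic, peak)
        if not snr > params.snr_min:
            continue
        blank_peak = None
        if blank is not None:
            b_xic = Xic(target_mz=prec.mz, tol=xic.tol, rt=b_rts,
                        intensity=b_mat[:, j], scan_indices=b_idx)
            if len(b_xic) >= 5:
                blank_peak = detect_peak(b_xic, expected_rt=peak.apex_rt,
                                         rt_halfwidth=2.0 * peak.fwhm)
        ratio = height_ratio(peak, blank_peak)
        if not ratio > params.screen_blank_ratio_min:
            continue
        apex_scan = int(s_idx[peak.apex_index])
        obs = _observed_mz(sample, apex_scan, lohi[j, 0], lohi[j, 1], prec.mz)
        ppm_err = (obs - prec.mz) / prec.mz * 1e6
        if abs(ppm_err) > params.ppm_tol:
            continue
        candidates.append(CandidatePrecursor(
            compound_id=entry.compound_id, splash_id=entry.splash_id,
            adduct_name=prec.adduct_name, library_mz=prec.mz, observed_mz=obs,
            ppm_error=ppm_err, window_index=prec.window_index, peak=peak,
            blank_ratio=ratio, snr=snr))
    return candidates
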
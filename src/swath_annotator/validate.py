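"""Threshold calibration and inclusion/exclusion validation statistics.

Calibration mirrors the way the published gates were derived: precursor
ions of authentic standards are matched between an IDA (DDA) acquisition
and a SWATH acquisition, the relative RT and FWHM shifts are computed per
ion, and the pooled standard deviation (times a configurable multiplier)
becomes the filtration threshold.

Validation evaluates the identified-compound set against a known-present
inclusion list and a known-absent exclusion list, yielding the standard
confusion matrix: sensitivity, specificity, and false-positive rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, InsufficientDataError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ShiftObservation:
    """Relative RT / width shift of one precursor ion matched IDA <-> SWATH."""

    compound_id: str
    rt_shift: float
    width_shift: float

    def __post_init__(self) -> None:
        if self.rt_shift < 0 or self.width_shift < 0:
            raise ValueError("shifts are absolute and must be >= 0")


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    unlisted: int = 0  # identified compounds on neither list (never counted as FP)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def fpr(self) -> float:
        return self.fp / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
                "unlisted": self.unlisted, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "fpr": self.fpr}


def estimate_thresholds(observations: Sequence[ShiftObservation],
                        multiplier: float = 1.0,
                        statistic: Callable[[np.ndarray], float] | None = None,
                        ) -> tuple[float, float]:
    """(rt_shift_max, width_shift_max) = multiplier x pooled SD per shift type.

    The population standard deviation (ddof=0) of the pooled per-ion shifts
    is the default statistic; pass ``statistic`` to plug in another
    estimator.  Requires >= 2 observations.
    """
    if len(observations) < 2:
        raise InsufficientDataError(
            f"threshold estimation needs >= 2 observations, got {len(observations)}")
    stat = statistic or (lambda a: float(np.std(a, ddof=0)))
    rt = np.array([o.rt_shift for o in observations], dtype=float)
    wd = np.array([o.width_shift for o in observations], dtype=float)
    rt_max = multiplier * stat(rt)
    wd_max = multiplier * stat(wd)
    if rt_max == 0 or wd_max == 0:
        log.warning("degenerate threshold estimate (zero variance): rt=%g width=%g",
                    rt_max, wd_max)
    return rt_max, wd_max


def evaluate_inclusion_exclusion(identified: Iterable[str],
                                 inclusion: Sequence[str],
                                 exclusion: Sequence[str]) -> ConfusionMetrics:
    """Confusion statistics of an identified-compound set against the two lists.

    Identified compounds on neither list are reported in ``unlisted`` but
    excluded from the matrix, mirroring the two-list validation design.
    """
    inc, exc = set(inclusion), set(exclusion)
    overlap = inc & exc
    if overlap:
        raise ConfigurationError(
            f"inclusion and exclusion lists overlap: {sorted(overlap)[:5]}")
    ids = set(identified)
    tp = len(ids & inc)
    fn = len(inc - ids)
    fp = len(ids & exc)
    tn = len(exc - ids)
    unlisted = len(ids - inc - exc)
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn, unlisted=unlisted)


@dataclass
class OverlapReport:
    """Greedy nearest-m/z matching summary between two fragment lists."""

    n_a: int
    n_b: int
    n_matched: int
    pairs: list[tuple[float, float]] = field(default_factory=list)  # (mz_a, mz_b)

    @property
    def fraction_of_b_in_a(self) -> float:
        return self.n_matched / self.n_b if self.n_b else float("nan")

    @property
    def fraction_of_a_in_b(self) -> float:
        return self.n_matched / self.n_a if self.n_a else float("nan")


def fragment_overlap_report(set_a: Sequence[float], set_b: Sequence[float],
                            mz_tol: float) -> OverlapReport:
    """One-to-one greedy matching of two fragment m/z lists within ``mz_tol``.

    Candidate pairs are ranked by |delta m/z| (ties toward lower m/z) and
    matched greedily; each fragment participates in at most one pair.
    """
    if mz_tol <= 0:
        raise ValueError("mz_tol must be positive")
    pairs = [(abs(a - b), a, b, i, j)
             for i, a in enumerate(set_a) for j, b in enumerate(set_b)
             if abs(a - b) <= mz_tol]
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched: list[tuple[float, float]] = []
    for _, a, b, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((a, b))
    return OverlapReport(n_a=len(set_a), n_b=len(set_b), n_matched=len(matched),
                         pairs=matched)
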
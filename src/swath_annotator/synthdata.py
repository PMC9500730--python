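"""Synthetic spectral libraries and ground-truthed SWATH/IDA runs.

Every pipeline stage is testable without instrument data: the generator
emits (a) raw + curated spectral libraries with known D/F/excluded intensity
bands, and (b) paired sample/blank runs in which each spiked compound elutes
as a Gaussian peak (default sigma 0.05 min) whose fragments co-elute in the
precursor's SWATH window with small multiplicative RT and width jitters -
the same relative quantities the filtration gates test.

Acquisition geometry emulated: a survey (MS1) scan per cycle followed by one
product-ion (MS2) scan per 50 Da isolation window, 50-1100 Da; IDA mode
instead triggers up to 15 narrow-window MS2 scans on precursors above a
200-count threshold, with a 3 s dynamic-exclusion rule.

The noise model is shot-noise flavoured - additive Gaussian with
sigma = max(baseline_sd, sqrt(intensity)) on signals, plus
exponentially-distributed background centroids scattered uniformly in m/z -
a deliberate stand-in, not an instrument model.  Everything is driven by a
single integer seed; regeneration with the same seed is bit-identical.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .ionization import SwathWindowScheme, default_adducts
from .msio import Run, SpectrumScan
from .speclib import (CuratedFragment, DiaLibraryEntry, LibrarySpectrum,
                      build_dia_library)

GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


# ---------------------------------------------------------------------------
# synthetic spectral library

def make_synthetic_library(n_compounds: int = 50,
                           fragments_per_compound: tuple[int, int] = (4, 12),
                           seed: int = 0, polarity: str = "positive",
                           scheme: SwathWindowScheme | None = None,
                           ) -> tuple[list[LibrarySpectrum], list[DiaLibraryEntry]]:
    """Random compounds with fragments spanning the D / F / excluded bands.

    Returns both the raw (pre-curation) spectra and the curated DIA entries
    so curation itself is testable.  Neutral masses are uniform in
    (150, 900) Da; each spectrum has one base peak (rel. 100), ~15% extra
    fragments in the D band (> 75%), ~20% below the 5% exclusion band, the
    rest secondary (5-75%).
    """
    if n_compounds < 1:
        raise ConfigurationError("n_compounds must be >= 1")
    scheme = scheme or SwathWindowScheme()
    rng = np.random.default_rng(seed)
    lo_n, hi_n = fragments_per_compound
    spectra: list[LibrarySpectrum] = []
    for i in range(n_compounds):
        mass = float(rng.uniform(150.0, 900.0))
        n_frag = int(rng.integers(lo_n, hi_n + 1))
        # distinct fragment m/z below the (protonated) precursor
        mzs: list[float] = []
        while len(mzs) < n_frag:
            cand = float(rng.uniform(60.0, mass - 10.0))
            if all(abs(cand - m) > 0.1 for m in mzs):
                mzs.append(cand)
        rels = [100.0]
        for _ in range(n_frag - 1):
            u = rng.random()
            if u < 0.15:
                rels.append(float(rng.uniform(75.5, 99.5)))
            elif u < 0.35:
                rels.append(float(rng.uniform(0.5, 4.5)))
            else:
                rels.append(float(rng.uniform(5.5, 74.5)))
        scale = float(rng.uniform(50.0, 500.0))
        spectra.append(LibrarySpectrum(
            splash_id=f"splash10-syn-{seed}-{i:04d}",
            compound_id=f"SYN{i:04d}",
            compound_name=f"synthetic compound {i}",
            neutral_mass=mass, polarity=polarity,
            fragments=[(mz, rel * scale) for mz, rel in zip(mzs, rels)],
        ))
    entries, _ = build_dia_library(spectra, default_adducts(polarity), scheme)
    return spectra, entries


# ---------------------------------------------------------------------------
# ground truth

@dataclass
class FragmentTruth:
    mz: float
    height: float  # counts, at the primary adduct's precursor height
    apex_rt: float  # minutes (parent RT x RT jitter)
    sigma: float  # minutes (parent sigma x width jitter)


@dataclass
class SpikedSpecies:
    adduct_name: str
    mz: float
    window_index: int
    height: float


@dataclass
class SpikedCompound:
    compound_id: str
    splash_id: str
    apex_rt: float
    sigma: float
    species: list[SpikedSpecies]
    fragments: list[FragmentTruth]
    in_sample: bool = True
    in_blank: bool = False


@dataclass
class GroundTruth:
    """Everything needed to regenerate a run pair bit-identically."""

    compounds: list[SpikedCompound]
    seed: int
    polarity: str = "positive"
    scheme_start: float = 50.0
    scheme_end: float = 1100.0
    scheme_width: float = 50.0
    cycle_time: float = 0.012  # minutes (~0.7 s SWATH cycle)
    run_length: float = 8.0  # minutes
    baseline_sd: float = 30.0  # counts
    n_noise_ms1: int = 40  # background centroids per MS1 scan
    n_noise_ms2: int = 25  # background centroids per MS2 scan
    mz_jitter_ppm: float = 2.0  # per-point mass-measurement jitter
    noise_scale: float = 1.0  # multiplies the signal noise SD; 0 = noiseless

    @property
    def scheme(self) -> SwathWindowScheme:
        return SwathWindowScheme(self.scheme_start, self.scheme_end, self.scheme_width)

    @property
    def spiked_ids(self) -> list[str]:
        return [c.compound_id for c in self.compounds if c.in_sample and not c.in_blank]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        compounds = [
            SpikedCompound(
                compound_id=c["compound_id"], splash_id=c["splash_id"],
                apex_rt=c["apex_rt"], sigma=c["sigma"],
                species=[SpikedSpecies(**s) for s in c["species"]],
                fragments=[FragmentTruth(**f) for f in c["fragments"]],
                in_sample=c["in_sample"], in_blank=c["in_blank"])
            for c in data.pop("compounds")
        ]
        return cls(compounds=compounds, **data)


def make_ground_truth(entries: list[DiaLibraryEntry], n_spike: int, seed: int,
                      rt_range: tuple[float, float] = (3.0, 7.0),
                      height_range: tuple[float, float] = (1e4, 1e5),
                      sigma_rt: float = 0.05,
                      rt_jitter_sd: float = 0.0005,
                      width_jitter_sd: float = 0.05,
                      secondary_adduct_prob: float = 0.3,
                      n_background: int = 0,
                      **run_kwargs) -> GroundTruth:
    """Choose ``n_spike`` library compounds and draw their elution truth.

    RT jitter is multiplicative in RT (SD 0.0005, matching the relative
    RT-shift gate) and width jitter multiplicative in FWHM (SD 5%).  Each
    compound is spiked via its first-listed adduct; with probability
    ``secondary_adduct_prob`` a second adduct is added at 30% height.
    ``n_background`` extra compounds appear in *both* sample and blank
    (matrix background that the blank-ratio gate must remove).
    """
    if n_spike + n_background > len(entries):
        raise ConfigurationError("not enough library entries to spike")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(entries), size=n_spike + n_background, replace=False)
    compounds: list[SpikedCompound] = []
    for k, idx in enumerate(chosen):
        entry = entries[int(idx)]
        apex = float(rng.uniform(*rt_range))
        height = float(10 ** rng.uniform(np.log10(height_range[0]),
                                         np.log10(height_range[1])))
        by_name = {p.adduct_name: p for p in entry.precursors}
        primary = (by_name.get("[M+H]+") or by_name.get("[M-H]-")
                   or entry.precursors[0])
        species = [SpikedSpecies(primary.adduct_name, primary.mz,
                                 primary.window_index, height)]
        secondary = by_name.get("[M+Na]+") or by_name.get("[M+Na-2H]-")
        if secondary is not None and rng.random() < secondary_adduct_prob:
            species.append(SpikedSpecies(secondary.adduct_name, secondary.mz,
                                         secondary.window_index, 0.3 * height))
        frags = [
            FragmentTruth(
                mz=f.mz,
                height=height * f.relative_intensity / 100.0,
                apex_rt=apex * (1.0 + float(rng.normal(0.0, rt_jitter_sd))),
                sigma=sigma_rt * max(1.0 + float(rng.normal(0.0, width_jitter_sd)), 0.25),
            )
            for f in entry.fragments
        ]
        compounds.append(SpikedCompound(
            compound_id=entry.compound_id, splash_id=entry.splash_id,
            apex_rt=apex, sigma=sigma_rt, species=species, fragments=frags,
            in_sample=True, in_blank=k >= n_spike))
    polarity = entries[0].polarity if entries else "positive"
    return GroundTruth(compounds=compounds, seed=seed, polarity=polarity, **run_kwargs)


# ---------------------------------------------------------------------------
# run simulation

def _noise_arrays(rng, n_scans: int, n_points: int, lo: float, hi: float,
                  scale: float) -> tuple[np.ndarray, np.ndarray]:
    mz = rng.uniform(lo, hi, size=(n_scans, n_points))
    inten = rng.exponential(scale, size=(n_scans, n_points))
    order = np.argsort(mz, axis=1)
    return (np.take_along_axis(mz, order, axis=1),
            np.take_along_axis(inten, order, axis=1))


def _profile_points(rng, times: np.ndarray, mz: float, height: float,
                    apex: float, sigma: float, baseline_sd: float,
                    ppm_jitter: float, noise_scale: float = 1.0,
                    ) -> list[tuple[int, float, float]]:
    """(scan_index, mz, intensity) triples where the Gaussian exceeds 1 count."""
    prof = height * np.exp(-0.5 * ((times - apex) / sigma) ** 2)
    nz = np.nonzero(prof > 1.0)[0]
    if len(nz) == 0:
        return []
    vals = prof[nz]
    noise_sd = noise_scale * np.maximum(baseline_sd, np.sqrt(vals))
    vals = vals + rng.normal(0.0, 1.0, len(nz)) * noise_sd
    mzs = mz * (1.0 + rng.normal(0.0, ppm_jitter * 1e-6, len(nz)))
    return [(int(i), float(m), float(v))
            for i, m, v in zip(nz, mzs, vals) if v > 0.0]


def _assemble_scan(ms_level: int, rt: float, noise_mz: np.ndarray,
                   noise_int: np.ndarray, extras: list[tuple[float, float]] | None,
                   polarity: str, iso: tuple[float, float] | None) -> SpectrumScan:
    if extras:
        emz = np.array([e[0] for e in extras])
        eint = np.array([e[1] for e in extras])
        mz = np.concatenate([noise_mz, emz])
        inten = np.concatenate([noise_int, eint])
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
    else:
        mz, inten = noise_mz, noise_int
    return SpectrumScan(ms_level=ms_level, rt=rt, mz_values=mz, intensities=inten,
                        isolation_window=iso, polarity=polarity)


def _simulate_swath(truth: GroundTruth, rng, as_blank: bool) -> Run:
    scheme = truth.scheme
    n_win = scheme.n_windows
    n_cycles = int(round(truth.run_length / truth.cycle_time))
    dt = truth.cycle_time / (n_win + 1)
    ms1_times = np.arange(n_cycles) * truth.cycle_time

    nmz1, nint1 = _noise_arrays(rng, n_cycles, truth.n_noise_ms1,
                                scheme.start, scheme.end, truth.baseline_sd)
    nmz2, nint2 = _noise_arrays(rng, n_cycles * n_win, truth.n_noise_ms2,
                                scheme.start, scheme.end, truth.baseline_sd)

    ms1_extra: dict[int, list[tuple[float, float]]] = defaultdict(list)
    ms2_extra: dict[tuple[int, int], list[tuple[float, float]]] = defaultdict(list)
    for comp in truth.compounds:
        present = comp.in_blank if as_blank else comp.in_sample
        if not present:
            continue
        primary_height = comp.species[0].height
        for sp in comp.species:
            for i, m, v in _profile_points(rng, ms1_times, sp.mz, sp.height,
                                           comp.apex_rt, comp.sigma,
                                           truth.baseline_sd, truth.mz_jitter_ppm,
                                           truth.noise_scale):
                ms1_extra[i].append((m, v))
            scale = sp.height / primary_height
            w_times = ms1_times + (sp.window_index + 1) * dt
            for frag in comp.fragments:
                for i, m, v in _profile_points(rng, w_times, frag.mz,
                                               scale * frag.height, frag.apex_rt,
                                               frag.sigma, truth.baseline_sd,
                                               truth.mz_jitter_ppm,
                                               truth.noise_scale):
                    ms2_extra[(sp.window_index, i)].append((m, v))

    scans: list[SpectrumScan] = []
    for c in range(n_cycles):
        t0 = ms1_times[c]
        scans.append(_assemble_scan(1, float(t0), nmz1[c], nint1[c],
                                    ms1_extra.get(c), truth.polarity, None))
        for w in range(n_win):
            row = c * n_win + w
            scans.append(_assemble_scan(
                2, float(t0 + (w + 1) * dt), nmz2[row], nint2[row],
                ms2_extra.get((w, c)), truth.polarity, scheme.window_bounds(w)))
    return Run(scans=scans, polarity=truth.polarity, scheme=scheme)


def _simulate_ida(truth: GroundTruth, rng, as_blank: bool,
                  top_n: int = 15, trigger_threshold: float = 200.0,
                  exclusion_s: float = 3.0, occurrences: int = 3) -> Run:
    """Minimal IDA (DDA) emulation: top-N triggering with dynamic exclusion."""
    scheme = truth.scheme
    n_cycles = int(round(truth.run_length / truth.cycle_time))
    ms1_times = np.arange(n_cycles) * truth.cycle_time
    nmz1, nint1 = _noise_arrays(rng, n_cycles, truth.n_noise_ms1,
                                scheme.start, scheme.end, truth.baseline_sd)

    species = []  # (compound, species) pairs present in this run
    for comp in truth.compounds:
        if (comp.in_blank if as_blank else comp.in_sample):
            species.extend((comp, sp) for sp in comp.species)

    ms1_extra: dict[int, list[tuple[float, float]]] = defaultdict(list)
    profiles = []
    for comp, sp in species:
        prof = sp.height * np.exp(-0.5 * ((ms1_times - comp.apex_rt) / comp.sigma) ** 2)
        profiles.append(prof)
        for i, m, v in _profile_points(rng, ms1_times, sp.mz, sp.height,
                                       comp.apex_rt, comp.sigma,
                                       truth.baseline_sd, truth.mz_jitter_ppm,
                                       truth.noise_scale):
            ms1_extra[i].append((m, v))

    scans: list[SpectrumScan] = []
    streak = np.zeros(len(species), dtype=int)
    excluded_until = np.full(len(species), -1.0)
    dt = truth.cycle_time / (top_n + 1)
    for c in range(n_cycles):
        t0 = float(ms1_times[c])
        scans.append(_assemble_scan(1, t0, nmz1[c], nint1[c],
                                    ms1_extra.get(c), truth.polarity, None))
        intens = np.array([p[c] for p in profiles]) if species else np.array([])
        eligible = [k for k in range(len(species))
                    if intens[k] > trigger_threshold and t0 >= excluded_until[k]]
        eligible.sort(key=lambda k: -intens[k])
        selected = eligible[:top_n]
        for k in range(len(species)):
            if k in selected:
                streak[k] += 1
                if streak[k] >= occurrences:
                    excluded_until[k] = t0 + exclusion_s / 60.0
                    streak[k] = 0
            else:
                streak[k] = 0
        for rank, k in enumerate(selected):
            comp, sp = species[k]
            scale = sp.height / comp.species[0].height
            extras = []
            for frag in comp.fragments:
                h = scale * frag.height * np.exp(
                    -0.5 * ((t0 - frag.apex_rt) / frag.sigma) ** 2)
                if h > 1.0:
                    v = float(h + rng.normal(0.0, max(truth.baseline_sd, np.sqrt(h))))
                    if v > 0:
                        extras.append((float(frag.mz * (1.0 + rng.normal(0.0, truth.mz_jitter_ppm * 1e-6))), v))
            extras.sort()
            nm = rng.uniform(scheme.start, scheme.end, truth.n_noise_ms2)
            ni = rng.exponential(truth.baseline_sd, truth.n_noise_ms2)
            order = np.argsort(nm)
            scans.append(_assemble_scan(
                2, t0 + (rank + 1) * dt, nm[order], ni[order], extras,
                truth.polarity, (sp.mz - 0.5, sp.mz + 0.5)))
    return Run(scans=scans, polarity=truth.polarity, scheme=None)


def simulate_run(truth: GroundTruth, scheme: SwathWindowScheme | None = None,
                 mode: str = "swath") -> tuple[Run, Run]:
    """Generate the (sample, blank) run pair for a ground truth.

    The blank contains background centroids plus any compounds flagged
    ``in_blank`` - never the spiked compounds.  Separate deterministic RNG
    streams drive sample and blank, both derived from ``truth.seed``.
    """
    if scheme is not None and scheme != truth.scheme:
        raise ConfigurationError("scheme disagrees with the ground truth's scheme")
    for comp in truth.compounds:
        for sp in comp.species:
            if not truth.scheme.contains(sp.mz):
                raise ConfigurationError(
                    f"{comp.compound_id} precursor {sp.mz} outside acquisition range")
    if mode == "swath":
        sample = _simulate_swath(truth, np.random.default_rng([truth.seed, 0]), False)
        blank = _simulate_swath(truth, np.random.default_rng([truth.seed, 1]), True)
    elif mode == "ida":
        sample = _simulate_ida(truth, np.random.default_rng([truth.seed, 2]), False)
        blank = _simulate_ida(truth, np.random.default_rng([truth.seed, 3]), True)
    else:
        raise ConfigurationError(f"unknown acquisition mode {mode!r}")
    return sample, blank
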
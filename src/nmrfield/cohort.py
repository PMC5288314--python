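"""Seeded synthetic 1H-NMR cohorts with the study's statistical structure.

Spectra are sums of Lorentzian multiplets on a uniform ppm grid, plus a
smooth cosine baseline and i.i.d. Gaussian noise.  Class structure enters
through per-metabolite log-concentration offsets derived from an
:class:`~nmrfield.library.EffectTable`; paired-subject structure through an
additive per-subject random effect shared by all of a subject's samples.
Sample-to-sample pH variation is emulated by a per-metabolite chemical-shift
jitter, and imperfect referencing by a per-spectrum global shift (which the
TSP-alignment preprocessing step is meant to undo).

All randomness flows from the design's single seed through spawned
``numpy.random.SeedSequence`` children, so identical inputs give bit-identical
cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import SPECTROMETER_MHZ, PpmGrid, SpectrumSet
from .library import EffectTable, MetaboliteSignature, default_effect_table, \
    default_signatures

__all__ = [
    "CohortDesign", "simulate_spectrum", "simulate_cohort", "default_design",
    "default_effect_table", "default_signatures", "TABLE1_CLASS_SIZES",
]

#: Sample counts of the nine tissue classes (211 spectra in total).
TABLE1_CLASS_SIZES = {1: 68, 2: 7, 3: 30, 4: 7, 5: 4, 6: 28, 7: 29, 8: 9, 9: 29}

#: Classes acquired after chemotherapy.
POSTCHEMO_CLASSES = frozenset({7, 8, 9})

_VALID_CLASSES = frozenset(range(1, 10))

#: Digital-resolution floor: simulated lines always span at least this many
#: grid points FWHM, as they do at the instrument's native 32k resolution.
#: Without it, sub-grid-spacing linewidths on coarse desk-scale grids would
#: make peak heights alias with tiny referencing shifts.
MIN_POINTS_PER_FWHM = 4


@dataclass
class CohortDesign:
    """Cohort layout and noise model for :func:`simulate_cohort`.

    Parameters
    ----------
    class_sizes
        Map tissue class id (1-9) -> number of samples.
    pairing
        Map subject_id -> list of (class_id, index-within-class) pairs; every
        sample not claimed here gets its own singleton subject.
    noise_sd
        SD of additive spectral noise (intensity units; unit-concentration
        peaks have height ~1).
    shift_jitter_sd
        SD (ppm) of the per-metabolite chemical-shift jitter (pH effect).
    baseline_amplitude
        Amplitude scale of the smooth cosine baseline.
    subject_sd
        SD of the per-subject random effect on log-concentration.
    concentration_sd
        SD of per-sample log-concentration noise.
    global_shift_sd
        SD (ppm) of the per-spectrum referencing error (shifts TSP too).
    seed
        Mandatory integer seed.
    """

    class_sizes: dict
    pairing: dict = field(default_factory=dict)
    noise_sd: float = 0.005
    shift_jitter_sd: float = 0.002
    baseline_amplitude: float = 0.05
    subject_sd: float = 0.2
    concentration_sd: float = 0.15
    global_shift_sd: float = 0.005
    seed: int = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("CohortDesign.seed is mandatory")
        bad = set(self.class_sizes) - _VALID_CLASSES
        if bad:
            raise ValueError(f"unknown tissue class id(s): {sorted(bad)}")
        for c, n in self.class_sizes.items():
            if n < 0:
                raise ValueError(f"class {c}: negative class size {n}")
        for subj, samples in self.pairing.items():
            for cls, i in samples:
                if cls not in self.class_sizes or i >= self.class_sizes[cls]:
                    raise ValueError(
                        f"pairing for subject {subj!r} references sample "
                        f"({cls}, {i}) outside the design")

    @property
    def n_samples(self) -> int:
        return int(sum(self.class_sizes.values()))


def default_design(seed: int, **overrides) -> CohortDesign:
    """The nine-class, 211-sample study layout with its pairing structure.

    Controls (class 1) are singleton subjects; the 7 Barrett's patients each
    contribute a normal and a Barrett's sample (classes 2 and 4); EAC subjects
    contribute normal/Barrett's/tumour tissue pre- and post-chemotherapy with
    15 paired normal and 14 paired tumour pre/post sets.
    """
    pairing: dict = {}
    for i in range(7):
        pairing[f"B{i + 1:02d}"] = [(2, i), (4, i)]

    def add(subj: str, cls: int, idx: int) -> None:
        pairing.setdefault(subj, []).append((cls, idx))

    for i in range(30):                      # pre-chemo normal in EAC patients
        add(f"E{i + 1:02d}", 3, i)
    for j in range(29):                      # post-chemo normal; 15 paired
        subj = j + 1 if j < 15 else 31 + (j - 15)
        add(f"E{subj:02d}", 7, j)
    for i in range(28):                      # pre-chemo tumour
        add(f"E{i + 1:02d}", 6, i)
    for j in range(29):                      # post-chemo tumour; 14 paired
        subj = j + 1 if j < 14 else 29 + (j - 14)
        add(f"E{subj:02d}", 9, j)
    for i in range(4):                       # pre-chemo Barrett's in EAC pts
        add(f"E{i + 1:02d}", 5, i)
    for j in range(9):                       # post-chemo Barrett's in EAC pts
        add(f"E{j + 1:02d}", 8, j)

    kwargs = dict(class_sizes=dict(TABLE1_CLASS_SIZES), pairing=pairing,
                  seed=seed)
    kwargs.update(overrides)
    return CohortDesign(**kwargs)


def _lorentzian_sum(grid_values: np.ndarray, centers, heights, hwidths
                    ) -> np.ndarray:
    """Sum of Lorentzians; height equals the value at the nominal center."""
    c = np.asarray(centers)[:, None]
    h = np.asarray(heights)[:, None]
    hw = np.asarray(hwidths)[:, None]
    return np.sum(h * hw**2 / ((grid_values[None, :] - c) ** 2 + hw**2), axis=0)


def simulate_spectrum(signatures, log_concentrations: dict, grid: PpmGrid,
                      jitter_sd: float = 0.0, baseline_amplitude: float = 0.0,
                      noise_sd: float = 0.0, seed=0,
                      global_shift_ppm: float = 0.0) -> np.ndarray:
    """One frequency-domain spectrum on ``grid``.

    intensity = sum over metabolites of exp(log_concentration) x sum over
    peaks of Lorentzian(center + jitter, linewidth) + smooth baseline +
    i.i.d. Gaussian noise.  Deterministic given ``seed`` (an int or a
    ``numpy.random.Generator``).

    Jitter is drawn once per metabolite (whole multiplets move together);
    signatures with ``jitter=False`` (the TSP reference) are pinned.
    ``global_shift_ppm`` shifts every peak, references included.
    """
    signatures = list(signatures)
    if not signatures:
        raise ValueError("signature list is empty")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)

    centers, heights, hwidths = [], [], []
    for sig in signatures:
        if not isinstance(sig, MetaboliteSignature):
            sig = MetaboliteSignature(*sig)   # re-validate raw tuples
        jit = rng.normal(0.0, jitter_sd) if (sig.jitter and jitter_sd > 0) \
            else 0.0
        amp = math.exp(float(log_concentrations.get(
            sig.name, sig.base_log_concentration)))
        for c, h, w in sig.peaks:
            if w <= 0:
                raise ValueError(f"non-positive linewidth for {sig.name!r}")
            # truncate so the jittered center stays inside the grid
            cc = min(max(c + jit + global_shift_ppm, grid.ppm_min),
                     grid.ppm_max)
            centers.append(cc)
            heights.append(amp * h)
            hwidths.append(max(w / SPECTROMETER_MHZ / 2.0,
                               MIN_POINTS_PER_FWHM * grid.spacing / 2.0))

    y = _lorentzian_sum(grid.values, centers, heights, hwidths)

    if baseline_amplitude > 0:
        span = grid.ppm_max - grid.ppm_min
        x = (grid.values - grid.ppm_min) / span
        for k in (1, 2, 3):
            a = baseline_amplitude * rng.uniform(0.5, 1.0) / k
            phi = rng.uniform(0.0, 2.0 * math.pi)
            y = y + a * np.cos(2.0 * math.pi * k * x + phi)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=grid.n_points)
    return y


def _sample_roster(design: CohortDesign) -> pd.DataFrame:
    """Expand the design into one metadata row per sample."""
    subject_of = {}
    for subj in sorted(design.pairing):
        for cls, i in design.pairing[subj]:
            subject_of[(cls, i)] = subj
    rows = []
    for cls in sorted(design.class_sizes):
        for i in range(design.class_sizes[cls]):
            sid = f"c{cls}_s{i + 1:03d}"
            rows.append({
                "sample_id": sid,
                "subject_id": subject_of.get((cls, i), f"solo_{sid}"),
                "class_id": cls,
                "chemo_flag": int(cls in POSTCHEMO_CLASSES),
            })
    return pd.DataFrame(rows)


def simulate_cohort(design: CohortDesign, effects: EffectTable | None = None,
                    signatures=None, grid: PpmGrid | None = None,
                    return_truth: bool = False):
    """Simulate a full cohort as a :class:`SpectrumSet`.

    Per-sample log-concentration of each metabolite:
    ``base + ln(2) * class_offset + subject_effect + sample_noise`` where the
    class offsets are the least-squares reconciliation of the pairwise
    ``EffectTable`` (see :meth:`EffectTable.class_offsets`), subject effects
    are N(0, subject_sd) shared within a subject, and sample noise is
    N(0, concentration_sd).  The TSP reference (``jitter=False``) is held at
    constant concentration.

    With ``return_truth=True`` also returns the sample x metabolite matrix of
    generated log-concentrations.
    """
    effects = default_effect_table() if effects is None else effects
    signatures = default_signatures() if signatures is None else list(signatures)
    grid = PpmGrid.default() if grid is None else grid
    if not signatures:
        raise ValueError("signature list is empty")

    meta = _sample_roster(design)
    n = len(meta)
    classes = sorted(meta["class_id"].unique())
    subjects = sorted(meta["subject_id"].unique())

    ss = np.random.SeedSequence(design.seed)
    conc_rng = np.random.default_rng(ss.spawn(1)[0])
    spectrum_seeds = ss.spawn(n + 1)[1:]

    varying = [s for s in signatures if s.jitter]
    offsets = {s.name: effects.class_offsets(s.name, classes) for s in varying}

    # subject effects: one draw per (subject, metabolite), fixed order
    subj_eff = {
        subj: {s.name: conc_rng.normal(0.0, design.subject_sd)
               for s in varying}
        for subj in subjects
    }

    logc = np.empty((n, len(signatures)))
    for j, sig in enumerate(signatures):
        base = sig.base_log_concentration
        if not sig.jitter:                      # reference compound: constant
            logc[:, j] = base
            continue
        off = offsets[sig.name]
        for i, row in enumerate(meta.itertuples(index=False)):
            logc[i, j] = (base
                          + math.log(2.0) * off[row.class_id]
                          + subj_eff[row.subject_id][sig.name]
                          + conc_rng.normal(0.0, design.concentration_sd))

    names = [s.name for s in signatures]
    intensities = np.empty((n, grid.n_points))
    for i in range(n):
        rng = np.random.default_rng(spectrum_seeds[i])
        shift = rng.normal(0.0, design.global_shift_sd) \
            if design.global_shift_sd > 0 else 0.0
        intensities[i] = simulate_spectrum(
            signatures, dict(zip(names, logc[i])), grid,
            jitter_sd=design.shift_jitter_sd,
            baseline_amplitude=design.baseline_amplitude,
            noise_sd=design.noise_sd, seed=rng, global_shift_ppm=shift)

    sset = SpectrumSet(intensities, grid.values.copy(), meta,
                       [{"step": "simulate", "seed": design.seed,
                         "n_samples": n}])
    if return_truth:
        truth = pd.DataFrame(logc, columns=names,
                             index=meta["sample_id"].to_numpy())
        return sset, truth
    return sset
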
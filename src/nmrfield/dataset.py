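"""Core containers: the ppm axis and the spectra-plus-metadata set.

Every pipeline stage consumes and produces a :class:`SpectrumSet` — a samples
× ppm-grid intensity matrix, a chemical-shift axis, per-sample metadata
(sample, subject, tissue class, chemotherapy flag), and an append-only log of
the processing steps applied so far.

The ppm axis is stored ascending internally; the descending display
convention of NMR spectroscopy is applied only at export/plot time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Spectrometer proton frequency assumed when converting linewidths in Hz to ppm.
SPECTROMETER_MHZ = 600.0

#: Metadata columns every SpectrumSet must carry.
METADATA_COLUMNS = ("sample_id", "subject_id", "class_id", "chemo_flag")


@dataclass(frozen=True)
class PpmGrid:
    """A strictly increasing, uniformly spaced chemical-shift axis.

    Parameters
    ----------
    values
        Chemical shifts in ppm, ascending, with constant spacing
        (tolerance 1e-9 ppm).
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("ppm grid must be a 1-D array with at least 2 points")
        d = np.diff(v)
        if np.any(d <= 0):
            raise ValueError("ppm grid must be strictly increasing")
        if np.ptp(d) > 1e-9:
            raise ValueError("ppm grid spacing must be uniform to within 1e-9 ppm")

    @classmethod
    def default(cls, n_points: int = 2**14, ppm_min: float = -0.5,
                ppm_max: float = 10.0) -> "PpmGrid":
        """Desk-scale default axis: 2^14 points over [-0.5, 10.0] ppm."""
        return cls(np.linspace(ppm_min, ppm_max, n_points))

    @property
    def n_points(self) -> int:
        return int(self.values.size)

    @property
    def spacing(self) -> float:
        return float(self.values[1] - self.values[0])

    @property
    def ppm_min(self) -> float:
        return float(self.values[0])

    @property
    def ppm_max(self) -> float:
        return float(self.values[-1])

    def index_of(self, ppm: float) -> int:
        """Index of the grid point nearest to ``ppm``."""
        return int(np.argmin(np.abs(self.values - ppm)))


@dataclass
class SpectrumSet:
    """A cohort of frequency-domain 1D spectra with per-sample metadata.

    ``ppm`` may become non-uniform after region exclusion; uniformity is only
    guaranteed for freshly simulated sets.
    """

    intensities: np.ndarray          # (n_samples, n_points)
    ppm: np.ndarray                  # (n_points,), strictly increasing
    metadata: pd.DataFrame           # one row per sample
    processing_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.ppm = np.asarray(self.ppm, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D samples x points matrix")
        if self.intensities.shape[1] != self.ppm.size:
            raise ValueError(
                f"grid length {self.ppm.size} != column count "
                f"{self.intensities.shape[1]}")
        if len(self.metadata) != self.intensities.shape[0]:
            raise ValueError(
                f"metadata rows {len(self.metadata)} != sample count "
                f"{self.intensities.shape[0]}")
        missing = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise ValueError(f"metadata missing required column(s): {missing}")
        if np.any(np.diff(self.ppm) <= 0):
            raise ValueError("ppm axis must be strictly increasing")
        ids = self.metadata["sample_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicated sample_id: {dup!r}")

    @property
    def n_samples(self) -> int:
        return int(self.intensities.shape[0])

    @property
    def n_points(self) -> int:
        return int(self.intensities.shape[1])

    def copy(self) -> "SpectrumSet":
        return SpectrumSet(
            self.intensities.copy(), self.ppm.copy(),
            self.metadata.copy().reset_index(drop=True),
            [dict(e) for e in self.processing_log],
        )

    def logged(self, step: str, **params) -> "SpectrumSet":
        """Return self with a step record appended to the processing log."""
        self.processing_log.append({"step": step, **params})
        return self

    def replace(self, intensities: np.ndarray | None = None,
                ppm: np.ndarray | None = None) -> "SpectrumSet":
        """New SpectrumSet sharing metadata/log (log copied), new data."""
        return SpectrumSet(
            self.intensities if intensities is None else intensities,
            self.ppm if ppm is None else ppm,
            self.metadata.copy().reset_index(drop=True),
            [dict(e) for e in self.processing_log],
        )
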
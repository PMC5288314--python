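"""Plain-text interchange: the spectrum-matrix CSV dialect and run logs.

One CSV per cohort: a header of metadata column names followed by the ppm
axis printed to 4 decimal places (descending, the NMR display convention),
then one row per sample with sample_id, subject_id, class_id, chemo_flag and
the intensities at full float precision.  Reading flips the axis back to the
ascending internal convention, so write-then-read is exact to the stated
ppm precision and bit-exact in the intensities.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .dataset import METADATA_COLUMNS, SpectrumSet

__all__ = ["write_spectrum_matrix", "read_spectrum_matrix",
           "write_processing_log"]


def write_spectrum_matrix(sset: SpectrumSet, path) -> None:
    """Write a SpectrumSet to the CSV dialect (ppm descending, 4 dp)."""
    order = np.argsort(sset.ppm)[::-1]
    cols = [f"{p:.4f}" for p in sset.ppm[order]]
    if len(set(cols)) != len(cols):
        raise ValueError(
            "ppm axis not representable at 4 decimal places (duplicate "
            "columns); use a coarser grid or wider spacing")
    df = pd.DataFrame(sset.intensities[:, order], columns=cols)
    meta = sset.metadata.reset_index(drop=True)
    out = pd.concat([meta[list(METADATA_COLUMNS)], df], axis=1)
    out.to_csv(path, index=False)


def read_spectrum_matrix(path) -> SpectrumSet:
    """Read the CSV dialect back into a SpectrumSet (ascending ppm)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty data section")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata column(s): {missing}")
    ppm_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    if not ppm_cols:
        raise ValueError(f"{path}: no ppm columns")
    try:
        ppm = np.array([float(c) for c in ppm_cols])
    except ValueError as e:
        raise ValueError(f"{path}: non-numeric ppm column header: {e}")
    diffs = np.diff(ppm)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        bad = int(np.flatnonzero(np.sign(diffs) != np.sign(diffs[0]))[0]) + 1
        raise ValueError(
            f"{path}: ppm header not strictly monotone at column index {bad}")
    meta = df[list(METADATA_COLUMNS)].copy()
    if meta["sample_id"].duplicated().any():
        dup = meta["sample_id"][meta["sample_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicated sample_id {dup!r}")
    inten = df[ppm_cols].to_numpy(dtype=float)
    if ppm[0] > ppm[-1]:                       # flip to ascending
        ppm = ppm[::-1].copy()
        inten = inten[:, ::-1].copy()
    return SpectrumSet(inten, ppm, meta.reset_index(drop=True),
                       [{"step": "read", "path": str(path)}])


def write_processing_log(sset: SpectrumSet, path) -> None:
    """Processing log as JSON lines (one step per line)."""
    with open(path, "w") as fh:
        for entry in sset.processing_log:
            fh.write(json.dumps(entry, sort_keys=True, default=str) + "\n")
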
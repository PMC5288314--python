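"""Metabolite signature library and class-effect tables.

The shipped defaults cover the ~25 metabolites of the esophageal tissue study
plus the TSP chemical-shift reference; both the library and the effect table
are plain YAML and can be replaced by user files of the same shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml


@dataclass(frozen=True)
class MetaboliteSignature:
    """One metabolite's multiplet pattern.

    peaks: list of (center_ppm, relative_intensity, linewidth_hz); every
    entry must have positive intensity and linewidth.
    """

    name: str
    peaks: tuple
    base_log_concentration: float = 0.0
    jitter: bool = True

    def __post_init__(self) -> None:
        if len(self.peaks) == 0:
            raise ValueError(f"metabolite {self.name!r} has no peaks")
        for c, h, w in self.peaks:
            if h <= 0:
                raise ValueError(
                    f"metabolite {self.name!r}: relative_intensity must be > 0")
            if w <= 0:
                raise ValueError(
                    f"metabolite {self.name!r}: linewidth_hz must be > 0")


@dataclass
class EffectTable:
    """Designed log2 fold changes keyed by (class_a, class_b, metabolite).

    ``entries[(a, b, m)] = f`` means metabolite ``m`` changes by ``f`` log2
    units going from class ``a`` to class ``b``.  Reversed pairs are resolved
    by sign flip.
    """

    entries: dict = field(default_factory=dict)

    def log2fc(self, class_a: int, class_b: int, metabolite: str) -> float:
        """Designed log2FC from class_a to class_b (0.0 if undesigned)."""
        if (class_a, class_b, metabolite) in self.entries:
            return float(self.entries[(class_a, class_b, metabolite)])
        if (class_b, class_a, metabolite) in self.entries:
            return -float(self.entries[(class_b, class_a, metabolite)])
        return 0.0

    def metabolites(self) -> list:
        return sorted({m for (_, _, m) in self.entries})

    def classes(self) -> list:
        return sorted({c for (a, b, _) in self.entries for c in (a, b)})

    def class_offsets(self, metabolite: str, classes) -> dict:
        """Per-class log2 offsets consistent (least squares) with the pairwise design.

        The pairwise entries form a constraint graph ``o_b - o_a = log2fc``;
        the returned offsets are its least-squares solution anchored so the
        lowest class id sits at 0.  For a consistent graph the pairwise
        differences are reproduced exactly; inconsistent designs are
        compromised in the usual least-squares sense (signs of dominant
        effects are preserved).
        """
        classes = sorted(classes)
        idx = {c: i for i, c in enumerate(classes)}
        rows, rhs = [], []
        for (a, b, m), f in self.entries.items():
            if m != metabolite or a not in idx or b not in idx:
                continue
            r = np.zeros(len(classes))
            r[idx[b]] = 1.0
            r[idx[a]] = -1.0
            rows.append(r)
            rhs.append(float(f))
        if not rows:
            return {c: 0.0 for c in classes}
        # anchor: offset of the lowest class = 0
        anchor = np.zeros(len(classes))
        anchor[0] = 1.0
        A = np.vstack(rows + [anchor])
        y = np.asarray(rhs + [0.0])
        sol, *_ = np.linalg.lstsq(A, y, rcond=None)
        sol = sol - sol[0]
        return {c: float(sol[idx[c]]) for c in classes}


def _load_yaml(path_or_default, default_name: str):
    if path_or_default is None:
        text = (resources.files("nmrfield") / "data" / default_name).read_text()
    else:
        with open(path_or_default) as fh:
            text = fh.read()
    return yaml.safe_load(text)


def load_signatures(path=None) -> list:
    """Metabolite library from YAML (shipped defaults when path is None)."""
    doc = _load_yaml(path, "metabolites.yml")
    sigs = []
    for m in doc["metabolites"]:
        sigs.append(MetaboliteSignature(
            name=str(m["name"]),
            peaks=tuple((float(c), float(h), float(w)) for c, h, w in m["peaks"]),
            base_log_concentration=float(m.get("base_log_concentration", 0.0)),
            jitter=bool(m.get("jitter", True)),
        ))
    names = [s.name for s in sigs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate metabolite names in library")
    return sigs


def load_effect_table(path=None) -> EffectTable:
    """Effect table from YAML (shipped defaults when path is None)."""
    doc = _load_yaml(path, "effects.yml")
    entries = {}
    for a, b, m, f in doc["effects"]:
        key = (int(a), int(b), str(m))
        if key in entries:
            raise ValueError(f"duplicate effect entry {key}")
        entries[key] = float(f)
    return EffectTable(entries)


def default_effect_table() -> EffectTable:
    """The shipped class-effect design (directions of the nine-class study)."""
    return load_effect_table(None)


def default_signatures() -> list:
    """The shipped metabolite library (incl. the TSP reference singlet)."""
    return load_signatures(None)
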
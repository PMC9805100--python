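"""Digital reference libraries and R² correlation classification.

Because mass-calibrated profiles share an axis across gels, a collection
of profiles from well-defined protein modifications (native, UV-stressed,
heat-stressed, deglycosylated, ...) forms a reference library against
which an unknown sample can be classified: the best match is the library
entry with the highest squared Pearson correlation (R²) to the query.
Pearson's affine invariance makes the comparison independent of exposure
or loading differences, which is what makes cross-gel libraries work
without any intensity normalisation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import MassProfile
from .image import GelError

LIBRARY_SCHEMA_VERSION = 1


def profile_correlation(a: MassProfile, b: MassProfile) -> float:
    """Squared Pearson correlation of two mass profiles on the same grid.

    Raises on grid mismatch and on zero-variance (constant) profiles,
    whose correlation is undefined — reported as an error, never as 0.
    """
    if not a.same_grid(b):
        raise GelError("profiles are on different mass grids")
    x, y = a.intensities, b.intensities
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise GelError("correlation undefined for a zero-variance profile")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


@dataclass
class CorrelationResult:
    """R² matrix (rows = queries, cols = references) with per-query best
    match; ties resolve to the first reference in library order and are
    flagged."""

    r2: pd.DataFrame
    best_match: dict  # query label -> (ref label, r2, tie_flag)

    def to_csv(self, path) -> None:
        self.r2.round(3).to_csv(path, float_format="%.3f")


def correlate_sets(queries: list[MassProfile],
                   refs: list[MassProfile]) -> CorrelationResult:
    """Full R² matrix between query and reference profile sets."""
    if not queries or not refs:
        raise GelError("correlate_sets needs non-empty query and reference sets")
    q_labels = [p.meta.get("label", f"query_{i}") for i, p in enumerate(queries)]
    r_labels = [p.meta.get("label", f"ref_{i}") for i, p in enumerate(refs)]
    mat = np.empty((len(queries), len(refs)))
    for i, q in enumerate(queries):
        for j, r in enumerate(refs):
            mat[i, j] = profile_correlation(q, r)
    df = pd.DataFrame(mat, index=q_labels, columns=r_labels)
    best = {}
    for i, ql in enumerate(q_labels):
        j = int(np.argmax(mat[i]))  # first maximum in library order
        tie = bool(np.sum(mat[i] == mat[i, j]) > 1)
        best[ql] = (r_labels[j], float(mat[i, j]), tie)
    return CorrelationResult(df, best)


@dataclass
class ReferenceLibrary:
    """Labelled MassProfiles sharing one mass grid, with provenance."""

    grid: np.ndarray
    entries: dict = field(default_factory=dict)  # label -> MassProfile
    version: int = LIBRARY_SCHEMA_VERSION
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)

    def add(self, profile: MassProfile, label: str | None = None) -> None:
        label = label or profile.meta.get("label")
        if not label:
            raise GelError("library entries need a label")
        if label in self.entries:
            raise GelError(f"duplicate library label {label!r}")
        if (profile.mass_grid.shape != self.grid.shape or
                not np.allclose(profile.mass_grid, self.grid,
                                rtol=1e-12, atol=0.0)):
            raise GelError(f"entry {label!r} is on a different mass grid")
        meta = dict(profile.meta)
        meta["label"] = label
        self.entries[label] = MassProfile(self.grid.copy(),
                                          profile.intensities.copy(), meta)

    @property
    def labels(self) -> list[str]:
        return list(self.entries)

    def profiles(self) -> list[MassProfile]:
        return list(self.entries.values())

    def classify(self, query: MassProfile) -> list[tuple[str, float]]:
        """All references ranked by R² to the query, best first."""
        if not self.entries:
            raise GelError("cannot classify against an empty library")
        scores = [(label, profile_correlation(query, p))
                  for label, p in self.entries.items()]
        scores.sort(key=lambda t: -t[1])
        return scores


def classify(query: MassProfile, lib: ReferenceLibrary
             ) -> list[tuple[str, float]]:
    """Module-level alias of :meth:`ReferenceLibrary.classify`."""
    return lib.classify(query)


def save_library(lib: ReferenceLibrary, manifest_path) -> None:
    """Write a library as a JSON manifest plus a CSV intensity matrix.

    The CSV holds one row per grid cell (``mass_kDa`` column) and one
    column per entry; full double precision is written so the round trip
    is bit-exact.  Human-inspectable and diff-able by design.
    """
    manifest_path = Path(manifest_path)
    matrix_path = manifest_path.with_suffix(".csv")
    data = {"mass_kDa": lib.grid}
    for label, profile in lib.entries.items():
        data[label] = profile.intensities
    pd.DataFrame(data).to_csv(matrix_path, index=False, float_format="%.17g")
    manifest = {
        "schema_version": lib.version,
        "provenance": lib.provenance,
        "matrix_csv": matrix_path.name,
        "n_grid_cells": int(lib.grid.size),
        "entries": {label: {k: v for k, v in p.meta.items()
                            if isinstance(v, (str, int, float, bool, type(None)))}
                    for label, p in lib.entries.items()},
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))


def load_library(manifest_path) -> ReferenceLibrary:
    """Load a library written by :func:`save_library` (lossless)."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    version = manifest.get("schema_version")
    if version != LIBRARY_SCHEMA_VERSION:
        raise GelError(f"unsupported library schema version {version!r}")
    matrix = pd.read_csv(manifest_path.parent / manifest["matrix_csv"],
                         float_precision="round_trip")
    grid = matrix["mass_kDa"].to_numpy()
    lib = ReferenceLibrary(grid, provenance=manifest.get("provenance", {}))
    for label, meta in manifest["entries"].items():
        profile = MassProfile(grid, matrix[label].to_numpy(), dict(meta))
        lib.add(profile, label)
    return lib
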
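"""End-to-end analysis driver: image -> geometry -> lanes -> calibration
-> mass profiles -> optional quantification and classification.

Every intermediate is persisted as plain text (JSON / CSV) so a run can be
audited stage by stage; given the same configuration and inputs the
outputs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration as cal
from . import lanes as ln
from . import library as lb
from . import quantify as qt
from .image import (GelError, GelGeometry, GelImage, detect_gel_region,
                    estimate_rotation, load_gel_image, rectify)

log = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


class ConfigError(GelError):
    """Invalid run configuration (caught before any computation)."""


class StageError(GelError):
    """Failure inside a pipeline stage; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one analysis run.

    ``protein_pmol`` maps lane index -> loaded protein amount for the
    optional absolute quantification; ``library_path`` points at a saved
    reference library for the optional classification step.
    """

    image_path: str | None = None
    channels: tuple = ("700nm", "800nm")
    n_lanes: int = 10
    marker_lanes: tuple = (0,)
    marker_channel: str = "800nm"
    sample_channel: str = "700nm"
    ladder: tuple = (250.0, 150.0, 100.0, 75.0, 50.0, 37.0, 25.0)
    min_prominence: float = 0.05
    background_window: int = 51
    grid_cells: int = 500
    grid_top_kda: float = 260.0
    grid_bottom_kda: float = 10.0
    bleed_correction: bool = True
    rotation_search_deg: float = 5.0
    rotation_step_deg: float = 0.1
    standards_path: str | None = None
    protein_pmol: dict = field(default_factory=dict)
    n_lysine: int | None = None
    library_path: str | None = None
    classify: bool = False
    lane_labels: dict = field(default_factory=dict)
    out_dir: str = "fecgel_out"

    def validate(self) -> None:
        if self.n_lanes < 1:
            raise ConfigError("n_lanes must be >= 1")
        if self.marker_channel not in self.channels:
            raise ConfigError("marker_channel not among declared channels")
        if self.sample_channel not in self.channels:
            raise ConfigError("sample_channel not among declared channels")
        if any(not 0 <= i < self.n_lanes for i in self.marker_lanes):
            raise ConfigError("marker lane index out of range")
        if not self.ladder or len(self.ladder) < 2:
            raise ConfigError("ladder specification required (>= 2 masses)")
        if not 0.0 < self.min_prominence <= 1.0:
            raise ConfigError("min_prominence must be in (0, 1]")
        if self.image_path is not None and not Path(self.image_path).exists():
            raise ConfigError(f"image not found: {self.image_path}")
        if self.standards_path is not None \
                and not Path(self.standards_path).exists():
            raise ConfigError(f"standards file not found: {self.standards_path}")
        if self.classify:
            if self.library_path is None:
                raise ConfigError("classification requested without a library")
            if not Path(self.library_path).exists():
                raise ConfigError(f"library not found: {self.library_path}")
        if self.protein_pmol and self.standards_path is None:
            raise ConfigError("quantification requires a standards file")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        cfg = cls(**raw)
        for key in ("channels", "marker_lanes", "ladder"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        cfg.protein_pmol = {int(k): float(v)
                            for k, v in cfg.protein_pmol.items()}
        cfg.lane_labels = {int(k): str(v) for k, v in cfg.lane_labels.items()}
        return cfg


@dataclass
class AnalysisBundle:
    """Everything one run produced, plus the files it wrote."""

    geometry: GelGeometry
    rotation_deg: float
    bleed_k: float | None
    lanes: list
    profiles: dict            # (lane, channel) -> background-subtracted profile
    bands: dict               # (lane, channel) -> list[Band]
    curve: cal.CalibrationCurve
    mass_profiles: dict       # lane -> MassProfile (sample channel)
    labelling: dict           # lane -> LabellingResult
    classification: dict      # lane -> ranked [(label, r2)]
    files: dict


def _read_standards(path) -> list[tuple[float, float]]:
    df = pd.read_csv(path, comment="#")
    cols = {c.lower(): c for c in df.columns}
    mole_col = next((cols[k] for k in ("moles", "pmol", "amount") if k in cols),
                    df.columns[0])
    int_col = next((cols[k] for k in ("intensity", "signal") if k in cols),
                   df.columns[1])
    return list(zip(df[mole_col].astype(float), df[int_col].astype(float)))


def run_analysis(cfg: RunConfig, img: GelImage | None = None
                 ) -> AnalysisBundle:
    """Execute the full pipeline and persist every intermediate.

    ``img`` may be passed directly (e.g. straight from the simulator);
    otherwise ``cfg.image_path`` is loaded.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict = {}

    def stage(name):
        class _Ctx:
            def __enter__(self):
                log.info("stage %s", name)
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc
                return False
        return _Ctx()

    with stage("load"):
        if img is None:
            img = load_gel_image(cfg.image_path, cfg.channels)

    with stage("geometry"):
        geom0 = detect_gel_region(img)
        angle = estimate_rotation(img, geom0, cfg.rotation_search_deg,
                                  cfg.rotation_step_deg)
        rectified = rectify(img, angle) if angle != 0.0 else img
        geom = detect_gel_region(rectified)
        geom.rotation_deg = angle
        log.info("gel cols [%d, %d), resolving border row %d, bottom %d, "
                 "rotation %+.1f deg", geom.left_col, geom.right_col,
                 geom.resolving_top_row, geom.bottom_row, angle)

    lanes = ln.segment_lanes(geom, cfg.n_lanes)

    bleed_k = None
    with stage("bleed"):
        if cfg.bleed_correction and cfg.sample_channel != cfg.marker_channel:
            bleed_k = cal.estimate_bleed(rectified, geom, lanes,
                                         cfg.sample_channel,
                                         cfg.marker_channel,
                                         cfg.marker_lanes)
            rectified = cal.correct_bleed(rectified, bleed_k,
                                          cfg.sample_channel,
                                          cfg.marker_channel)
            log.info("bleed coefficient k = %.4f", bleed_k)

    with stage("profiles"):
        raw, subtracted, all_bands = {}, {}, {}
        for lane in lanes:
            for ch in cfg.channels:
                p = ln.extract_profile(rectified, geom, lane, ch)
                raw[(lane.index, ch)] = p
                ps = ln.subtract_background(p, cfg.background_window)
                subtracted[(lane.index, ch)] = ps
                all_bands[(lane.index, ch)] = ln.detect_bands(
                    ps, cfg.min_prominence)

    with stage("calibration"):
        marker_bands: list = []
        for li in cfg.marker_lanes:
            if len(all_bands[(li, cfg.marker_channel)]) > len(marker_bands):
                marker_bands = all_bands[(li, cfg.marker_channel)]
        anchors = cal.assign_marker_masses(marker_bands,
                                           cal.LadderSpec(cfg.ladder))
        curve = cal.fit_calibration(anchors)
        grid = cal.default_mass_grid(cfg.grid_cells, cfg.grid_top_kda,
                                     cfg.grid_bottom_kda)
        mass_profiles = {}
        for lane in lanes:
            if lane.index in cfg.marker_lanes:
                continue
            label = cfg.lane_labels.get(lane.index, f"lane{lane.index}")
            mass_profiles[lane.index] = cal.profile_to_mass_axis(
                subtracted[(lane.index, cfg.sample_channel)], curve, grid,
                meta={"label": label})

    labelling: dict = {}
    with stage("quantify"):
        if cfg.standards_path is not None and cfg.protein_pmol:
            curve_std = qt.fit_standard_curve(
                _read_standards(cfg.standards_path))
            for li, pmol in cfg.protein_pmol.items():
                total = ln.lane_signal_total(raw[(li, cfg.sample_channel)],
                                             cfg.background_window)
                res = qt.degree_of_labelling(total, curve_std, pmol)
                if cfg.n_lysine:
                    res = qt.with_lysine_fraction(res, cfg.n_lysine)
                labelling[li] = res

    classification: dict = {}
    with stage("classify"):
        if cfg.classify:
            library = lb.load_library(cfg.library_path)
            for li, mp in mass_profiles.items():
                classification[li] = library.classify(mp)

    with stage("persist"):
        files["geometry"] = out / "geometry.json"
        files["geometry"].write_text(json.dumps(geom.to_dict(), indent=2))

        prof_rows = [{"lane_index": li, "channel": ch, "distance_px": int(d),
                      "intensity": i}
                     for (li, ch), p in sorted(raw.items())
                     for d, i in zip(p.distances, p.intensities)]
        files["profiles"] = out / "profiles.csv"
        pd.DataFrame(prof_rows).to_csv(files["profiles"], index=False,
                                       float_format=FLOAT_FMT)

        band_rows = [{"lane_index": li, "channel": ch,
                      "apex_px": b.apex_distance, "height": b.height,
                      "prominence": b.prominence, "area": b.area}
                     for (li, ch), bs in sorted(all_bands.items()) for b in bs]
        files["bands"] = out / "bands.csv"
        pd.DataFrame(band_rows,
                     columns=["lane_index", "channel", "apex_px", "height",
                              "prominence", "area"]
                     ).to_csv(files["bands"], index=False,
                              float_format=FLOAT_FMT)

        files["calibration"] = out / "calibration.json"
        cal_doc = curve.to_dict()
        cal_doc["bleed_k"] = bleed_k
        files["calibration"].write_text(json.dumps(cal_doc, indent=2))
        files["anchors"] = out / "calibration_anchors.csv"
        pd.DataFrame(curve.anchors, columns=["distance_px", "mass_kDa"]
                     ).to_csv(files["anchors"], index=False,
                              float_format=FLOAT_FMT)

        mp_rows = []
        extrap_lo = curve.mass(curve.distances[0])
        extrap_hi = curve.mass(curve.distances[-1])
        for li, mp in sorted(mass_profiles.items()):
            extrap = (mp.mass_grid > extrap_lo) | (mp.mass_grid < extrap_hi)
            for m, i, e in zip(mp.mass_grid, mp.intensities, extrap):
                mp_rows.append({"lane_index": li, "mass_kDa": m,
                                "intensity": i,
                                "extrapolated": bool(e)})
        files["mass_profiles"] = out / "mass_profiles.csv"
        pd.DataFrame(mp_rows).to_csv(files["mass_profiles"], index=False,
                                     float_format=FLOAT_FMT)

        if labelling:
            files["labelling"] = out / "labelling.json"
            files["labelling"].write_text(json.dumps(
                {str(li): r.to_dict() for li, r in sorted(labelling.items())},
                indent=2))
        if classification:
            files["classification"] = out / "classification.csv"
            rows = [{"lane_index": li, "rank": k, "label": lab,
                     "r2": round(r2, 3)}
                    for li, ranked in sorted(classification.items())
                    for k, (lab, r2) in enumerate(ranked)]
            pd.DataFrame(rows).to_csv(files["classification"], index=False,
                                      float_format=FLOAT_FMT)

    return AnalysisBundle(geometry=geom, rotation_deg=angle, bleed_k=bleed_k,
                          lanes=lanes, profiles=subtracted, bands=all_bands,
                          curve=curve, mass_profiles=mass_profiles,
                          labelling=labelling, classification=classification,
                          files={k: str(v) for k, v in files.items()})
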
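"""Canned in-silico experiments mirroring the reference-library workflow.

The central claim behind digital gel libraries is that mass-calibrated
profiles are comparable across independently run gels: different
rotation, exposure, noise and loading must not change what a sample is.
:func:`cross_gel_classification` builds that experiment end to end from
two simulated gels and reports the classification outcome.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field

from . import sim
from .library import ReferenceLibrary
from .pipeline import RunConfig, run_analysis


@dataclass
class CrossGelResult:
    assignments: dict          # query label -> (expected, got, r2)
    accuracy: float            # fraction of correct top-1 assignments
    library_labels: list = field(default_factory=list)


def cross_gel_classification(seed: int = 0, jitter: float = 0.1,
                             exposure_ref: float = 2.0,
                             exposure_query: float = 0.5,
                             noise_sigma: float = 8.0,
                             out_dir: str | None = None) -> CrossGelResult:
    """Two-gel library experiment with intermediate and spike-in queries.

    Gel A (reference) and gel B (query) carry the same four modification
    classes with independent 10 % band jitter, different rotations,
    opposite extreme exposure scales and independent noise.  Gel B adds
    two perturbed samples: the UV pattern at intermediate intensity
    (a shorter UV dose) and a 20 % spike-in of the deglycosylated class
    into native sample.  Both gels pass through the full pipeline; the
    library is built from gel A and every gel B sample is classified
    against it.
    """
    classes = sim.canonical_classes()
    native, uv, _, deglyc = classes
    extra = [
        ("uv_5min", [(m, a * uv.scale * 0.45) for m, a in uv.bands]),
        ("spike20", sim.spike_in_bands(deglyc, native, 0.2)),
    ]
    cfg_a = sim.class_gel_config(classes, jitter=jitter, seed=seed * 2 + 1,
                                 rotation_deg=1.5, noise_sigma=noise_sigma,
                                 exposure=exposure_ref, bleed_k=0.05)
    cfg_b = sim.class_gel_config(classes, jitter=jitter, seed=seed * 2 + 2,
                                 rotation_deg=-2.5, noise_sigma=noise_sigma,
                                 exposure=exposure_query, bleed_k=0.05,
                                 extra_lanes=extra)
    img_a, _ = sim.simulate_gel(cfg_a)
    img_b, _ = sim.simulate_gel(cfg_b)

    if out_dir is None:
        out_dir = tempfile.mkdtemp(prefix="fecgel_xgel_")
    labels_a = {i + 1: c.label for i, c in enumerate(classes)}
    labels_b = dict(labels_a)
    labels_b[5], labels_b[6] = "uv_5min", "spike20"
    bundle_a = run_analysis(RunConfig(out_dir=f"{out_dir}/gelA",
                                      lane_labels=labels_a), img=img_a)
    bundle_b = run_analysis(RunConfig(out_dir=f"{out_dir}/gelB",
                                      lane_labels=labels_b), img=img_b)

    lib = ReferenceLibrary(bundle_a.mass_profiles[1].mass_grid,
                           provenance={"source": "simulated gel A"})
    for i, c in enumerate(classes):
        lib.add(bundle_a.mass_profiles[i + 1], c.label)

    expected = {c.label: c.label for c in classes}
    expected["uv_5min"] = uv.label
    expected["spike20"] = deglyc.label
    assignments, correct = {}, 0
    for lane, label in labels_b.items():
        ranked = lib.classify(bundle_b.mass_profiles[lane])
        got, r2 = ranked[0]
        assignments[label] = (expected[label], got, r2)
        correct += got == expected[label]
    return CrossGelResult(assignments, correct / len(assignments),
                          lib.labels)
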
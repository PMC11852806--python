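"""Synthetic tumour phantoms with planted habitats and graded biopsies.

A phantom emulates one patient's co-registered slice: a tumour mask
partitioned into 2-4 spatially contiguous habitats, each with its own
mean SNR_Pyr (substrate delivery), k_PL (metabolic conversion, s^-1) and
%NG (Gd enhancement), plus additive Gaussian noise per map kind, and a
set of biopsy points whose WHO/ISUP grades are drawn conditionally on
the habitat containing the point. The default cohort plants a
perfusion/metabolism "mismatch" habitat (low SNR_Pyr, high k_PL) that
carries high-grade disease, so the full pipeline -- clustering, mismatch
statistics, diagnostic evaluation -- is exercisable without any
patient data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from skimage import draw

from .biopsy import Biopsy
from .kinetics import simulate_dynamic_curves, snr_from_curve
from .maps import ParameterMap, TumourROI

#: Map kinds a phantom generates and that require a noise_sd entry.
PHANTOM_MAP_KINDS = ("SNR_Pyr", "k_PL", "T1w_pre", "T1w_ng")

#: Baseline pre-contrast T1w signal used inside the tumour (arbitrary units).
T1W_BASELINE = 100.0


@dataclass
class Ellipse:
    """Ellipse in pixel coordinates: center (row, col), semi-axes, rotation."""

    center: tuple[float, float]
    axes: tuple[float, float]
    rotation_deg: float = 0.0

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = draw.ellipse(
            self.center[0], self.center[1], self.axes[0], self.axes[1],
            shape=shape, rotation=np.deg2rad(self.rotation_deg),
        )
        mask = np.zeros(shape, dtype=bool)
        mask[rr, cc] = True
        return mask


@dataclass
class Polygon:
    """Simple polygon given as a list of (row, col) vertices."""

    vertices: list[tuple[float, float]]

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        v = np.asarray(self.vertices, dtype=float)
        rr, cc = draw.polygon(v[:, 0], v[:, 1], shape=shape)
        mask = np.zeros(shape, dtype=bool)
        mask[rr, cc] = True
        return mask


@dataclass
class HabitatSpec:
    """Ground-truth description of one habitat."""

    geometry: Ellipse | Polygon
    mean_snr_pyr: float
    mean_kpl: float
    mean_png: float
    label: int

    def validate(self, shape: tuple[int, int]) -> np.ndarray:
        for name, v in (("mean_snr_pyr", self.mean_snr_pyr),
                        ("mean_kpl", self.mean_kpl),
                        ("mean_png", self.mean_png)):
            if not np.isfinite(v):
                raise ValueError(f"habitat {self.label}: {name} is not finite")
        if self.mean_snr_pyr < 0 or self.mean_kpl < 0:
            raise ValueError(f"habitat {self.label}: SNR_Pyr and k_PL means must be >= 0")
        if self.label < 1:
            raise ValueError("habitat label must be >= 1")
        mask = self.geometry.rasterize(shape)
        if mask.sum() < 4:
            raise ValueError(f"habitat {self.label}: degenerate geometry (area < 4 px)")
        return mask


@dataclass
class PhantomSpec:
    """Full generative description of one synthetic tumour slice."""

    grid_shape: tuple[int, int]
    habitats: list[HabitatSpec]
    noise_sd: dict[str, float]
    n_biopsies: int = 7
    grade_rule: dict[int, dict[int, float]] = field(default_factory=dict)
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)
    seed: int = 0
    patient_id: str = "P0"
    slice_id: str = "0"

    def validate(self) -> list[np.ndarray]:
        if len(self.grid_shape) != 2 or any(s < 4 for s in self.grid_shape):
            raise ValueError("grid_shape must be a pair of sizes >= 4")
        if any(s <= 0 for s in self.pixel_spacing_mm):
            raise ValueError("pixel spacing must be positive")
        missing = [k for k in PHANTOM_MAP_KINDS if k not in self.noise_sd]
        if missing:
            raise ValueError(f"noise_sd missing entries for {missing}")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise_sd values must be non-negative")
        if self.n_biopsies < 1:
            raise ValueError("n_biopsies must be >= 1")
        masks = [h.validate(tuple(self.grid_shape)) for h in self.habitats]
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                if (masks[i] & masks[j]).any():
                    raise ValueError(
                        "overlapping habitat geometries: labels "
                        f"{self.habitats[i].label} and {self.habitats[j].label}"
                    )
        for rule in self.grade_rule.values():
            if any(g not in (1, 2, 3, 4) for g in rule):
                raise ValueError("grades must be in {1,2,3,4}")
            if abs(sum(rule.values()) - 1.0) > 1e-9:
                raise ValueError("grade probabilities must sum to 1")
        return masks


@dataclass
class Phantom:
    """A generated synthetic patient slice: maps, truth labels, biopsies."""

    maps: dict[str, ParameterMap]
    truth_labels: np.ndarray
    roi: TumourROI
    biopsies: list[Biopsy]
    spec: PhantomSpec


def generate_phantom(spec: PhantomSpec, snr_mode: str = "planted") -> Phantom:
    """Generate a phantom from its spec; bit-identical under a fixed seed.

    ``snr_mode='planted'`` writes each habitat's mean SNR_Pyr directly
    into the map; ``'curves'`` derives it from a simulated two-site
    dynamic curve (time-summed pyruvate / noise SD) whose initial
    pyruvate signal is scaled so the noiseless SNR equals the planted
    mean, giving the map mechanistic provenance.
    """
    if snr_mode not in ("planted", "curves"):
        raise ValueError("snr_mode must be 'planted' or 'curves'")
    masks = spec.validate()
    shape = tuple(spec.grid_shape)
    rng = np.random.default_rng(spec.seed)

    labels = np.zeros(shape, dtype=int)
    snr = np.zeros(shape)
    kpl = np.zeros(shape)
    pre = np.full(shape, T1W_BASELINE)
    ng = np.full(shape, T1W_BASELINE)
    for hab, mask in zip(spec.habitats, masks):
        labels[mask] = hab.label
        snr[mask] = _habitat_snr(hab, spec, snr_mode)
        kpl[mask] = hab.mean_kpl
        ng[mask] = T1W_BASELINE * (1.0 + hab.mean_png / 100.0)

    for arr, kind in ((snr, "SNR_Pyr"), (kpl, "k_PL"), (pre, "T1w_pre"), (ng, "T1w_ng")):
        sd = spec.noise_sd[kind]
        if sd > 0:
            arr += rng.normal(0.0, sd, size=shape)

    maps = {
        kind: ParameterMap(arr, kind, tuple(spec.pixel_spacing_mm), spec.slice_id)
        for arr, kind in ((snr, "SNR_Pyr"), (kpl, "k_PL"), (pre, "T1w_pre"), (ng, "T1w_ng"))
    }
    roi = TumourROI(labels > 0, spec.slice_id, spec.patient_id)
    phantom = Phantom(maps, labels, roi, [], spec)
    phantom.biopsies = sample_biopsies(
        phantom, spec.n_biopsies, spec.grade_rule,
        seed=int(rng.integers(2**31)),
    )
    return phantom


def _habitat_snr(hab: HabitatSpec, spec: PhantomSpec, snr_mode: str) -> float:
    if snr_mode == "planted":
        return hab.mean_snr_pyr
    times = np.arange(0.0, 60.0, 4.0)
    noise_ref = max(spec.noise_sd["SNR_Pyr"], 1e-6)
    pyr, _ = simulate_dynamic_curves(hab.mean_kpl, 1 / 30, 1 / 30, times, p0=1.0)
    p0 = hab.mean_snr_pyr * noise_ref / pyr.sum()
    pyr_scaled, _ = simulate_dynamic_curves(hab.mean_kpl, 1 / 30, 1 / 30, times, p0=p0)
    return snr_from_curve(pyr_scaled, noise_ref)


def sample_biopsies(
    phantom: Phantom,
    n: int,
    rule: dict[int, dict[int, float]],
    seed: int,
) -> list[Biopsy]:
    """Sample ``n`` biopsy points uniformly over distinct in-mask pixels.

    Grades are drawn from ``rule[habitat_label]`` (a grade -> probability
    mapping) conditioned on the habitat containing each point; habitats
    without a rule entry default to grade 2.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mask = phantom.roi.mask
    flat = np.flatnonzero(mask.ravel())
    if flat.size == 0:
        raise ValueError("tumour mask is empty")
    if n > flat.size:
        raise ValueError(f"requested {n} biopsies but only {flat.size} distinct in-mask pixels")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(flat, size=n, replace=False)
    ncols = mask.shape[1]
    biopsies = []
    for i, fidx in enumerate(chosen):
        r, c = divmod(int(fidx), ncols)
        hab = int(phantom.truth_labels[r, c])
        hab_rule = rule.get(hab, {2: 1.0})
        grades = sorted(hab_rule)
        probs = np.array([hab_rule[g] for g in grades])
        grade = int(rng.choice(grades, p=probs / probs.sum()))
        biopsies.append(
            Biopsy(
                patient_id=phantom.spec.patient_id,
                slice_id=phantom.spec.slice_id,
                x_px=float(c),
                y_px=float(r),
                grade=grade,
            )
        )
    return biopsies


# ---------------------------------------------------------------------------
# Default study conditions


#: Geometry of the canonical 3-habitat tumour on a 64x64 grid.
_CANONICAL_GEOMETRY = (
    Ellipse((24, 20), (11, 9), 15),
    Ellipse((30, 41), (9, 8), -10),
    Ellipse((45, 28), (8, 10), 0),
)


def default_phantom_spec(seed: int = 0, patient_id: str = "P1",
                         n_biopsies: int = 7) -> PhantomSpec:
    """Canonical 3-habitat mismatch phantom on a 64x64, 1 mm grid.

    Habitat 2 is the planted perfusion/metabolism mismatch region: low
    pyruvate delivery but high conversion. It shares its SNR_Pyr with
    habitat 1 and its k_PL with habitat 3, so neither single channel can
    isolate it — only the combined [SNR_Pyr + k_PL] feature space
    separates all three habitats, the regime the method is built for.
    The mismatch habitat preferentially carries WHO/ISUP grade 4. Noise
    SDs reflect a high-SNR clinical acquisition: 4 SNR units on the
    pyruvate map, 0.004 s^-1 on the k_PL fit, 2 signal units on the
    T1-weighted phases.
    """
    g1, g2, g3 = _CANONICAL_GEOMETRY
    habitats = [
        HabitatSpec(g1, mean_snr_pyr=20.0, mean_kpl=0.010, mean_png=30.0, label=1),
        HabitatSpec(g2, mean_snr_pyr=20.0, mean_kpl=0.035, mean_png=25.0, label=2),
        HabitatSpec(g3, mean_snr_pyr=60.0, mean_kpl=0.035, mean_png=90.0, label=3),
    ]
    return PhantomSpec(
        grid_shape=(64, 64),
        habitats=habitats,
        noise_sd={"SNR_Pyr": 4.0, "k_PL": 0.004, "T1w_pre": 2.0, "T1w_ng": 2.0},
        n_biopsies=n_biopsies,
        grade_rule={
            1: {2: 0.7, 3: 0.3},
            2: {4: 0.9, 3: 0.1},
            3: {3: 0.6, 2: 0.3, 4: 0.1},
        },
        seed=seed,
        patient_id=patient_id,
    )


def recovery_phantom_spec(seed: int = 0, noise_fraction: float = 0.25) -> PhantomSpec:
    """3-habitat phantom for the habitat-recovery study.

    Habitat means are three distinct levels per channel (SNR_Pyr
    25/10/40; k_PL 0.010/0.025/0.035 s^-1) so every habitat pair differs
    in both channels. ``noise_fraction`` scales the per-channel noise SD
    as a fraction of the inter-habitat contrast (the smallest difference
    between habitat means in that channel: 15 SNR units, 0.010 s^-1);
    0 gives noiseless maps that reproduce the planted means exactly.
    """
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    g1, g2, g3 = _CANONICAL_GEOMETRY
    habitats = [
        HabitatSpec(g1, mean_snr_pyr=25.0, mean_kpl=0.010, mean_png=40.0, label=1),
        HabitatSpec(g2, mean_snr_pyr=10.0, mean_kpl=0.025, mean_png=25.0, label=2),
        HabitatSpec(g3, mean_snr_pyr=40.0, mean_kpl=0.035, mean_png=90.0, label=3),
    ]
    snr_contrast, kpl_contrast = 15.0, 0.010
    return PhantomSpec(
        grid_shape=(64, 64),
        habitats=habitats,
        noise_sd={
            "SNR_Pyr": noise_fraction * snr_contrast,
            "k_PL": noise_fraction * kpl_contrast,
            "T1w_pre": 2.0 * (noise_fraction > 0),
            "T1w_ng": 2.0 * (noise_fraction > 0),
        },
        n_biopsies=7,
        grade_rule={1: {2: 1.0}, 2: {4: 1.0}, 3: {3: 1.0}},
        seed=seed,
    )


def default_cohort(seed: int = 0, n_patients: int = 6) -> list[Phantom]:
    """The demo cohort: patients sharing the canonical anatomy, distinct
    noise/biopsy realisations, 44 biopsies in total of which two are
    flagged low-cellularity (excluded downstream), leaving 42."""
    counts = [8, 7, 7, 8, 7, 7]
    if n_patients != 6:
        counts = [7] * n_patients
    rng = np.random.default_rng(seed)
    phantoms = []
    for i in range(n_patients):
        spec = default_phantom_spec(
            seed=int(rng.integers(2**31)),
            patient_id=f"P{i + 1}",
            n_biopsies=counts[i],
        )
        phantoms.append(generate_phantom(spec))
    all_biopsies = [b for ph in phantoms for b in ph.biopsies]
    if len(all_biopsies) > 2:
        drop = rng.choice(len(all_biopsies), size=2, replace=False)
        for d in drop:
            all_biopsies[d].cellularity_ok = False
    return phantoms


# ---------------------------------------------------------------------------
# Spec serialisation (YAML)


def spec_to_yaml(spec: PhantomSpec, path) -> None:
    doc = {
        "grid_shape": list(spec.grid_shape),
        "pixel_spacing_mm": list(spec.pixel_spacing_mm),
        "noise_sd": {k: float(v) for k, v in spec.noise_sd.items()},
        "n_biopsies": spec.n_biopsies,
        "seed": spec.seed,
        "patient_id": spec.patient_id,
        "slice_id": spec.slice_id,
        "grade_rule": {int(k): {int(g): float(p) for g, p in v.items()}
                       for k, v in spec.grade_rule.items()},
        "habitats": [],
    }
    for h in spec.habitats:
        g = h.geometry
        if isinstance(g, Ellipse):
            geom = {"type": "ellipse", "center": list(g.center),
                    "axes": list(g.axes), "rotation_deg": g.rotation_deg}
        else:
            geom = {"type": "polygon", "vertices": [list(v) for v in g.vertices]}
        doc["habitats"].append({
            "geometry": geom, "mean_snr_pyr": h.mean_snr_pyr,
            "mean_kpl": h.mean_kpl, "mean_png": h.mean_png, "label": h.label,
        })
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def spec_from_yaml(path) -> PhantomSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    habitats = []
    for h in doc["habitats"]:
        g = h["geometry"]
        if g["type"] == "ellipse":
            geom = Ellipse(tuple(g["center"]), tuple(g["axes"]),
                           g.get("rotation_deg", 0.0))
        elif g["type"] == "polygon":
            geom = Polygon([tuple(v) for v in g["vertices"]])
        else:
            raise ValueError(f"unknown geometry type {g['type']!r}")
        habitats.append(HabitatSpec(geom, h["mean_snr_pyr"], h["mean_kpl"],
                                    h["mean_png"], h["label"]))
    return PhantomSpec(
        grid_shape=tuple(doc["grid_shape"]),
        habitats=habitats,
        noise_sd=dict(doc["noise_sd"]),
        n_biopsies=doc.get("n_biopsies", 7),
        grade_rule={int(k): {int(g): float(p) for g, p in v.items()}
                    for k, v in doc.get("grade_rule", {}).items()},
        pixel_spacing_mm=tuple(doc.get("pixel_spacing_mm", (1.0, 1.0))),
        seed=int(doc.get("seed", 0)),
        patient_id=doc.get("patient_id", "P0"),
        slice_id=doc.get("slice_id", "0"),
    )
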
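"""Biopsy-to-habitat assignment and per-habitat diagnostic performance.

Each biopsy carries a WHO/ISUP grade (1-4). Within a patient, the
positive class is "highest grade within the tumour": a biopsy is
positive iff its grade equals the maximum grade among that patient's
included (sufficient-cellularity) biopsies. Each habitat is then scored
as a binary test — biopsy-in-habitat = test-positive — pooled across
patients into one 2x2 confusion table per habitat, from which
sensitivity, specificity, PPV and NPV are computed, with half-up
rounding to whole percent for report output. The AUC of the single
binary operating point is (sensitivity + specificity) / 2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CLUSTER_NAMES = {1: "low", 2: "medium", 3: "high"}


@dataclass
class Biopsy:
    """A 2-D biopsy point on the habitat grid (x_px = column, y_px = row)."""

    patient_id: str
    slice_id: str
    x_px: float
    y_px: float
    grade: int
    cellularity_ok: bool = True

    def __post_init__(self) -> None:
        if self.grade not in (1, 2, 3, 4):
            raise ValueError(f"WHO/ISUP grade must be 1-4, got {self.grade}")
        if not (math.isfinite(self.x_px) and math.isfinite(self.y_px)):
            raise ValueError("biopsy coordinates must be finite")


@dataclass
class ConfusionTable:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.n == 0:
            raise ValueError("confusion table must contain at least one sample")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class DiagnosticMetrics:
    """Sensitivity/specificity/PPV/NPV in [0,1]; None when the denominator is 0."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    auc: float | None

    def as_percent(self) -> dict[str, int | None]:
        """Half-up integer-percent rounding, for Table-style reports."""
        return {
            name: None if v is None else round_half_up(100.0 * v)
            for name, v in (
                ("sensitivity", self.sensitivity), ("specificity", self.specificity),
                ("ppv", self.ppv), ("npv", self.npv),
            )
        }


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def assign_biopsy(
    habitats, biopsy: Biopsy, rescue_radius: float = 1.0
) -> int | None:
    """Habitat label of the pixel containing the biopsy point.

    If the containing pixel is background (label 0), the nearest
    non-background pixel within ``rescue_radius`` (Euclidean, pixels) is
    used; ties break in row-major order. Returns None when no habitat
    pixel is within reach (biopsy flagged unassigned by the caller).
    """
    labels = habitats.labels
    r, c = int(round(biopsy.y_px)), int(round(biopsy.x_px))
    if not (0 <= r < labels.shape[0] and 0 <= c < labels.shape[1]):
        raise ValueError(f"biopsy at ({biopsy.x_px}, {biopsy.y_px}) is off-grid")
    if labels[r, c] > 0:
        return int(labels[r, c])
    reach = int(math.ceil(rescue_radius))
    best = None  # (distance, row, col, label)
    for rr in range(max(0, r - reach), min(labels.shape[0], r + reach + 1)):
        for cc in range(max(0, c - reach), min(labels.shape[1], c + reach + 1)):
            if labels[rr, cc] == 0:
                continue
            d = math.hypot(rr - r, cc - c)
            if d <= rescue_radius and (best is None or (d, rr, cc) < best[:3]):
                best = (d, rr, cc, int(labels[rr, cc]))
    return None if best is None else best[3]


def positive_labels(biopsies: list[Biopsy]) -> tuple[list[Biopsy], np.ndarray]:
    """Included biopsies and their highest-grade-within-tumour positivity.

    Biopsies failing the cellularity criterion are excluded; a biopsy is
    positive iff its grade equals the maximum grade among its patient's
    included biopsies. Patients ending up with zero included biopsies
    are dropped with a warning.
    """
    included = [b for b in biopsies if b.cellularity_ok]
    dropped = {b.patient_id for b in biopsies} - {b.patient_id for b in included}
    for pid in sorted(dropped):
        warnings.warn(f"patient {pid}: no biopsy with sufficient cellularity; excluded",
                      stacklevel=2)
    if not included:
        raise ValueError("no biopsy passes the cellularity criterion")
    max_grade: dict[str, int] = {}
    for b in included:
        max_grade[b.patient_id] = max(max_grade.get(b.patient_id, 0), b.grade)
    positives = np.array([b.grade == max_grade[b.patient_id] for b in included])
    return included, positives


def cluster_confusion(
    assignments: np.ndarray, positives: np.ndarray, cluster_label: int
) -> ConfusionTable:
    """2x2 table for one habitat treated as a binary test (in-habitat = positive)."""
    assignments = np.asarray(assignments)
    positives = np.asarray(positives, dtype=bool)
    if assignments.shape != positives.shape:
        raise ValueError("assignments and positives must have equal length")
    if cluster_label not in set(int(a) for a in assignments) and cluster_label < 1:
        raise ValueError(f"unknown cluster label {cluster_label}")
    inside = assignments == cluster_label
    return ConfusionTable(
        tp=int((inside & positives).sum()),
        fp=int((inside & ~positives).sum()),
        fn=int((~inside & positives).sum()),
        tn=int((~inside & ~positives).sum()),
    )


def diagnostic_metrics(ct: ConfusionTable) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV and the binary-point AUC.

    A metric whose denominator is zero is reported as None (undefined),
    never as 0. The AUC is the trapezoid over the single operating
    point, (sensitivity + specificity) / 2.
    """
    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else num / den

    sens = ratio(ct.tp, ct.tp + ct.fn)
    spec = ratio(ct.tn, ct.tn + ct.fp)
    auc = None if sens is None or spec is None else (sens + spec) / 2.0
    return DiagnosticMetrics(
        sensitivity=sens, specificity=spec,
        ppv=ratio(ct.tp, ct.tp + ct.fp), npv=ratio(ct.tn, ct.tn + ct.fn),
        auc=auc,
    )


def evaluate_all(
    habitat_maps: dict[str, dict[str, "HabitatMap"]],
    biopsies: list[Biopsy],
    rescue_radius: float = 1.0,
) -> pd.DataFrame:
    """Per-approach, per-habitat diagnostic performance pooled across patients.

    ``habitat_maps`` maps approach name -> {slice key -> HabitatMap},
    where the slice key is ``"<patient_id>/<slice_id>"``. Returns one
    row per approach x habitat with counts, the fractional metrics, the
    integer-percent report values and the binary-point AUC.
    """
    if not biopsies:
        raise ValueError("empty biopsy table")
    included, positives = positive_labels(biopsies)
    rows = []
    for approach, per_slice in habitat_maps.items():
        assignments, pos_used = [], []
        for b, is_pos in zip(included, positives):
            key = f"{b.patient_id}/{b.slice_id}"
            if key not in per_slice:
                raise KeyError(f"approach {approach!r}: no habitat map for slice {key}")
            label = assign_biopsy(per_slice[key], b, rescue_radius)
            if label is None:
                warnings.warn(
                    f"approach {approach!r}: biopsy at ({b.x_px},{b.y_px}) of "
                    f"{b.patient_id} unassigned (background beyond rescue radius)",
                    stacklevel=2,
                )
                continue
            assignments.append(label)
            pos_used.append(is_pos)
        assignments = np.array(assignments)
        pos_used = np.array(pos_used, dtype=bool)
        k = max(hm.k for hm in per_slice.values())
        for label in range(1, k + 1):
            ct = cluster_confusion(assignments, pos_used, label)
            dm = diagnostic_metrics(ct)
            pct = dm.as_percent()
            rows.append({
                "approach": approach,
                "cluster": CLUSTER_NAMES.get(label, str(label)),
                "label": label, "n": ct.n,
                "tp": ct.tp, "fp": ct.fp, "tn": ct.tn, "fn": ct.fn,
                "sensitivity": dm.sensitivity, "specificity": dm.specificity,
                "ppv": dm.ppv, "npv": dm.npv, "auc": dm.auc,
                "sensitivity_pct": pct["sensitivity"], "specificity_pct": pct["specificity"],
                "ppv_pct": pct["ppv"], "npv_pct": pct["npv"],
            })
    return pd.DataFrame(rows)


def format_report(table: pd.DataFrame) -> str:
    """Pretty-print the evaluation table in the Table-1 layout."""
    lines = ["Clustering Approach  Sensitivity  Specificity  PPV   NPV   AUC"]
    for approach, grp in table.groupby("approach", sort=False):
        lines.append(f"{approach}")
        for _, row in grp.sort_values("label").iterrows():
            def pct(v):
                return "  na" if v is None or (isinstance(v, float) and np.isnan(v)) else f"{int(v):3d}%"
            auc = "  na" if pd.isna(row["auc"]) else f"{row['auc']:.2f}"
            lines.append(
                f"  {row['cluster']:<18} {pct(row['sensitivity_pct']):>6}  "
                f"{pct(row['specificity_pct']):>6}  {pct(row['ppv_pct']):>4}  "
                f"{pct(row['npv_pct']):>4}  {auc}"
            )
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# CSV I/O


def biopsies_to_csv(biopsies: list[Biopsy], path) -> None:
    pd.DataFrame(
        [
            {"patient_id": b.patient_id, "slice_id": b.slice_id, "x_px": b.x_px,
             "y_px": b.y_px, "grade": b.grade, "cellularity_ok": b.cellularity_ok}
            for b in biopsies
        ]
    ).to_csv(path, index=False)


def biopsies_from_csv(path) -> list[Biopsy]:
    df = pd.read_csv(path)
    return [
        Biopsy(
            patient_id=str(r.patient_id), slice_id=str(r.slice_id),
            x_px=float(r.x_px), y_px=float(r.y_px), grade=int(r.grade),
            cellularity_ok=bool(getattr(r, "cellularity_ok", True)),
        )
        for r in df.itertuples(index=False)
    ]
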
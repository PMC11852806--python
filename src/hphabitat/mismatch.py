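"""Per-habitat normalized means, the perfusion/metabolism mismatch ratio,
and cross-habitat statistical comparisons.

Maps are normalized by their mean over all clustered (non-background)
pixels of the slice, so 1.0 is the neutral value and the pixel-weighted
average of habitat means is exactly 1. The mismatch ratio of a habitat
is its normalized mean k_PL divided by its normalized mean SNR_Pyr: a
ratio well above 1 marks a region with high metabolic conversion
relative to substrate delivery — the perfusion/metabolism mismatch that
flags aggressive, putatively hypoxic tumour.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .clustering import HabitatMap
from .maps import ParameterMap


@dataclass
class ClusterSummary:
    label: int
    n_pixels: int
    norm_mean_snr: float
    norm_mean_kpl: float
    norm_mean_combined: float
    mismatch_ratio: float


def normalize_map(pmap: ParameterMap, habitats: HabitatMap | np.ndarray) -> ParameterMap:
    """Divide by the mean over clustered pixels; that mean becomes 1 exactly."""
    mask = habitats.clustered_mask if isinstance(habitats, HabitatMap) else np.asarray(habitats, bool)
    if pmap.shape != mask.shape:
        raise ValueError("map/habitat shape mismatch")
    if not mask.any():
        raise ValueError("no clustered pixels")
    m = float(pmap.values[mask].mean())
    if not np.isfinite(m) or m <= 0:
        raise ValueError(f"non-positive or non-finite mean ({m}) over clustered pixels")
    return ParameterMap(pmap.values / m, pmap.kind, pmap.pixel_spacing_mm, pmap.slice_id)


def cluster_summaries(
    habitats: HabitatMap, snr_map: ParameterMap, kpl_map: ParameterMap
) -> list[ClusterSummary]:
    """One summary per habitat label 1..k (empty habitats omitted with a warning).

    The combined metric is the mean of the two normalized channels, so
    it is dimensionless on the same tumour-mean=1 scale.
    """
    nsnr = normalize_map(snr_map, habitats).values
    nkpl = normalize_map(kpl_map, habitats).values
    out = []
    for label in range(1, habitats.k + 1):
        sel = habitats.labels == label
        n = int(sel.sum())
        if n == 0:
            warnings.warn(f"habitat {label} has no pixels; omitted", stacklevel=2)
            continue
        ms, mk = float(nsnr[sel].mean()), float(nkpl[sel].mean())
        out.append(
            ClusterSummary(
                label=label, n_pixels=n, norm_mean_snr=ms, norm_mean_kpl=mk,
                norm_mean_combined=(ms + mk) / 2.0,
                mismatch_ratio=mk / ms,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Cross-habitat comparisons


def _dunn_pairwise(groups: list[np.ndarray]) -> list[tuple[int, int, float]]:
    """Dunn's rank-based pairwise z-tests with tie correction.

    Raw two-sided p-values per pair; the caller applies the multiple-
    comparison adjustment (Dunn's procedure multiplies by the number of
    comparisons).
    """
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes, start = [], [], 0
    for g in groups:
        mean_ranks.append(ranks[start: start + g.size].mean())
        sizes.append(g.size)
        start += g.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    out = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0:
            p = 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * stats.norm.sf(abs(z))
        out.append((i, j, p))
    return out


@dataclass
class ComparisonResult:
    method: str                    # 'anova+holm-sidak' | 'kruskal+dunn' | 't-test' | 'mann-whitney'
    omnibus_stat: float
    omnibus_p: float
    pairwise: list[dict]           # [{'groups': (i, j), 'p_adj': float}, ...]
    normal: bool


def compare_across_clusters(
    groups: list[np.ndarray], alpha: float = 0.05, route: str = "auto"
) -> ComparisonResult:
    """Normality-gated omnibus + pairwise comparison across habitats.

    If every group passes Shapiro–Wilk at ``alpha``: one-way ANOVA with
    Holm–Šidák-adjusted pairwise t-tests. Otherwise: Kruskal–Wallis with
    Dunn's tie-corrected pairwise tests (adjusted by the number of
    comparisons, capped at 1). With exactly two groups this degrades to
    an unpaired t-test or Mann–Whitney U test. ``route`` overrides the
    normality gate ('parametric' or 'nonparametric').
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
    if route not in ("auto", "parametric", "nonparametric"):
        raise ValueError(f"unknown route {route!r}")

    def _is_normal(g: np.ndarray) -> bool:
        if g.size < 3 or np.ptp(g) == 0:
            return False
        return stats.shapiro(g).pvalue > alpha

    if route == "auto":
        normal = all(_is_normal(g) for g in groups)
    else:
        normal = route == "parametric"

    if len(groups) == 2:
        if normal:
            r = stats.ttest_ind(groups[0], groups[1])
            method = "t-test"
        else:
            r = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
            method = "mann-whitney"
        p = float(r.pvalue)
        return ComparisonResult(method, float(r.statistic), p,
                                [{"groups": (0, 1), "p_adj": p}], normal)

    if normal:
        stat, p = stats.f_oneway(*groups)
        raw = [(i, j, float(stats.ttest_ind(groups[i], groups[j]).pvalue))
               for i, j in itertools.combinations(range(len(groups)), 2)]
        adj = multipletests([r[2] for r in raw], method="holm-sidak")[1]
        pairwise = [{"groups": (i, j), "p_adj": float(a)}
                    for (i, j, _), a in zip(raw, adj)]
        return ComparisonResult("anova+holm-sidak", float(stat), float(p), pairwise, True)

    if all(np.ptp(g) == 0 for g in groups) and np.ptp(np.concatenate(groups)) == 0:
        # all observations identical: no evidence of any difference
        pairwise = [{"groups": (i, j), "p_adj": 1.0}
                    for i, j in itertools.combinations(range(len(groups)), 2)]
        return ComparisonResult("kruskal+dunn", 0.0, 1.0, pairwise, False)
    stat, p = stats.kruskal(*groups)
    raw = _dunn_pairwise(groups)
    m = len(raw)
    pairwise = [{"groups": (i, j), "p_adj": float(min(1.0, pv * m))}
                for i, j, pv in raw]
    return ComparisonResult("kruskal+dunn", float(stat), float(p), pairwise, False)
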
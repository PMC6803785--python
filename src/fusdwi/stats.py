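"""Layered metric extraction, reference normalization, and group statistics.

The analysis mirrors a standard lesion-assessment protocol: per-layer means
of each diffusion metric at each timepoint, normalization to a reference
region from the matching timepoint (splenium-analogue, chosen for its robust
anisotropic signature), paired pre-vs-post tests per (layer, metric) cell
with Benjamini-Hochberg FDR over the 15-cell family, and per-timepoint
one-way ANOVA across the three layers per metric with Tukey HSD post-hoc.

Pairing unit
------------
The pre/post paired tests pair VOXELS within each layer mask.  With real
cohorts the natural pairing unit is the animal; a single phantom provides
one "animal", so voxel-level pairing is the testable surrogate.  When
several phantoms (or subjects) are available, pair their per-subject layer
means instead by calling :func:`paired_t_test` directly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import DegenerateVarianceError, EmptyROIError
from .segmentation import LesionLayers
from .tensor import ScalarMap

__all__ = [
    "StatsResult",
    "roi_mean",
    "normalize_to_reference",
    "paired_t_test",
    "fdr_adjust",
    "oneway_anova",
    "tukey_hsd",
    "LesionLayerAnalysis",
    "LayerAnalysisResults",
    "build_layer_report",
]

METRICS = ("ADC", "AD", "RD", "MD", "FA")
ALPHA = 0.05


@dataclass
class StatsResult:
    """One hypothesis test: statistic, degrees of freedom, p-values."""

    test: str
    statistic: float
    df: tuple
    p_value: float
    p_adjusted: float | None = None
    comparison: str = ""

    @property
    def significant(self) -> bool:
        p = self.p_value if self.p_adjusted is None else self.p_adjusted
        return bool(p < ALPHA)


def roi_mean(scalar_map: ScalarMap, mask: np.ndarray) -> float:
    """Arithmetic mean of the map over valid voxels inside the mask."""
    mask = np.asarray(mask, dtype=bool)
    sel = mask & scalar_map.valid_mask
    if not np.any(sel):
        raise EmptyROIError("mask contains no valid voxels")
    return float(scalar_map.data[sel].mean())


def normalize_to_reference(roi_value: float, ref_value: float) -> float:
    """Express a ROI value as a percentage of the reference value."""
    if ref_value <= 0:
        raise ValueError("reference value must be positive")
    return 100.0 * roi_value / ref_value


def paired_t_test(x, y) -> StatsResult:
    """Two-sided paired Student t-test on matched samples.

    All-zero differences return t=0, p=1 by convention; zero-variance
    differences with nonzero mean are degenerate (the statistic is infinite).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    n = d.size
    if np.all(d == 0):
        return StatsResult("paired-t", 0.0, (n - 1,), 1.0)
    if np.std(d, ddof=1) == 0:
        raise DegenerateVarianceError("zero variance of nonzero paired differences")
    t, p = sps.ttest_rel(x, y)
    return StatsResult("paired-t", float(t), (n - 1,), float(p))


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def oneway_anova(groups) -> StatsResult:
    """One-way fixed-effects ANOVA across two or more groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups, each with >= 2 observations")
    f, p = sps.f_oneway(*groups)
    k = len(groups)
    n = sum(g.size for g in groups)
    if not np.isfinite(f):  # identical constant groups
        f, p = 0.0, 1.0
    return StatsResult("anova", float(f), (k - 1, n - k), float(p))


def tukey_hsd(groups) -> list:
    """All-pairs Tukey honest-significant-difference comparisons.

    Returns k*(k-1)/2 :class:`StatsResult` rows, statistic = mean difference
    (group j minus group i), p from the studentized range distribution.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups, each with >= 2 observations")
    res = sps.tukey_hsd(*groups)
    k = len(groups)
    n = sum(g.size for g in groups)
    out = []
    for i, j in itertools.combinations(range(k), 2):
        p = float(res.pvalue[i, j])
        if not np.isfinite(p):  # zero within-group variance everywhere
            p = 1.0 if groups[i].mean() == groups[j].mean() else 0.0
        out.append(
            StatsResult(
                "tukey-hsd",
                float(groups[j].mean() - groups[i].mean()),
                (k, n - k),
                p,
                comparison=f"{i}-{j}",
            )
        )
    return out


class LesionLayerAnalysis:
    """Layered pre/post diffusion-metric comparison for one lesion.

    Parameters
    ----------
    pre_maps, post_maps : dict of metric kind -> ScalarMap
        Must contain the five kinds {ADC, AD, RD, MD, FA} on one grid.
    layers : LesionLayers
        Segmentation output; analysis defaults to the disjoint shells
        (core, boundary shell, outer shell), set ``nested=True`` for the
        nested masks instead.
    reference_mask : bool array
        Reference region for percent normalization, per timepoint.
    """

    def __init__(self, pre_maps: dict, post_maps: dict, layers: LesionLayers,
                 reference_mask: np.ndarray, nested: bool = False):
        for maps in (pre_maps, post_maps):
            missing = set(METRICS) - set(maps)
            if missing:
                raise ValueError(f"missing metric maps: {sorted(missing)}")
        shapes = {maps[m].data.shape for maps in (pre_maps, post_maps) for m in METRICS}
        shapes.add(np.asarray(reference_mask).shape)
        shapes.add(layers.region.shape)
        if len(shapes) != 1:
            raise ValueError("all maps, layers and reference must share one grid")
        self.pre_maps = pre_maps
        self.post_maps = post_maps
        self.layer_masks = layers.nested() if nested else layers.disjoint()
        self.reference_mask = np.asarray(reference_mask, dtype=bool)

    def fit(self) -> "LayerAnalysisResults":
        rows = []
        ref_means = {}
        for timepoint, maps in (("pre", self.pre_maps), ("post", self.post_maps)):
            for metric in METRICS:
                ref_means[timepoint, metric] = roi_mean(maps[metric], self.reference_mask)
        for timepoint, maps in (("pre", self.pre_maps), ("post", self.post_maps)):
            for layer, mask in self.layer_masks.items():
                for metric in METRICS:
                    raw = roi_mean(maps[metric], mask)
                    ref = ref_means[timepoint, metric]
                    rows.append(
                        {
                            "timepoint": timepoint,
                            "layer": layer,
                            "metric": metric,
                            "raw_mean": raw,
                            "ref_mean": ref,
                            "normalized_pct": normalize_to_reference(raw, ref),
                            "n_voxels": int((mask & maps[metric].valid_mask).sum()),
                        }
                    )
        table = pd.DataFrame(rows)

        # Paired pre-vs-post per (layer, metric) on raw voxel values.  With
        # voxel-level pairing inside one subject both timepoints share units,
        # and dividing each timepoint by its own (noisy) reference mean would
        # inject a common offset into every pair and destroy type-I-error
        # calibration; reference-normalized values belong to the summary
        # table (and to animal-level pairing across subjects), not here.
        paired_rows = []
        for layer, mask in self.layer_masks.items():
            for metric in METRICS:
                pre_m, post_m = self.pre_maps[metric], self.post_maps[metric]
                sel = mask & pre_m.valid_mask & post_m.valid_mask
                x = pre_m.data[sel]
                y = post_m.data[sel]
                res = paired_t_test(x, y)
                paired_rows.append(
                    {
                        "layer": layer,
                        "metric": metric,
                        "statistic": res.statistic,
                        "df": res.df[0],
                        "p_raw": res.p_value,
                    }
                )
        paired = pd.DataFrame(paired_rows)
        paired["p_adj"] = fdr_adjust(paired["p_raw"].to_numpy())
        paired["significant"] = paired["p_adj"] < ALPHA

        # per-timepoint ANOVA across the three layers, per metric, raw values
        anova_rows, tukey_rows = [], []
        layer_names = list(self.layer_masks)
        for timepoint, maps in (("pre", self.pre_maps), ("post", self.post_maps)):
            for metric in METRICS:
                m = maps[metric]
                groups = [
                    m.data[self.layer_masks[name] & m.valid_mask] for name in layer_names
                ]
                res = oneway_anova(groups)
                anova_rows.append(
                    {
                        "timepoint": timepoint,
                        "metric": metric,
                        "F": res.statistic,
                        "df_between": res.df[0],
                        "df_within": res.df[1],
                        "p": res.p_value,
                        "significant": res.significant,
                    }
                )
                for pair in tukey_hsd(groups):
                    i, j = (int(k) for k in pair.comparison.split("-"))
                    tukey_rows.append(
                        {
                            "timepoint": timepoint,
                            "metric": metric,
                            "comparison": f"{layer_names[i]}-{layer_names[j]}",
                            "mean_diff": pair.statistic,
                            "p": pair.p_value,
                            "significant": pair.significant,
                        }
                    )
        return LayerAnalysisResults(
            layer_table=table,
            paired_tests=paired,
            anova=pd.DataFrame(anova_rows),
            tukey=pd.DataFrame(tukey_rows),
        )


@dataclass
class LayerAnalysisResults:
    """Tables produced by :class:`LesionLayerAnalysis.fit`."""

    layer_table: pd.DataFrame
    paired_tests: pd.DataFrame
    anova: pd.DataFrame
    tukey: pd.DataFrame

    def significant_fraction(self) -> float:
        """Fraction of FDR-significant (layer, metric) pre/post cells."""
        return float(self.paired_tests["significant"].mean())

    def summary(self) -> str:
        lines = ["Lesion layer analysis", "", "Normalized means (% of reference):"]
        piv = self.layer_table.pivot_table(
            index=["layer", "metric"], columns="timepoint", values="normalized_pct",
            sort=False,
        )
        lines.append(piv.round(2).to_string())
        lines.append("")
        nsig = int(self.paired_tests["significant"].sum())
        lines.append(
            f"Paired pre/post tests: {nsig}/{len(self.paired_tests)} significant "
            f"(BH-FDR, alpha={ALPHA})"
        )
        nsig_a = int(self.anova["significant"].sum())
        lines.append(f"Layer ANOVAs: {nsig_a}/{len(self.anova)} significant")
        return "\n".join(lines)


def build_layer_report(pre_maps: dict, post_maps: dict, layers: LesionLayers,
                       reference_mask: np.ndarray, nested: bool = False) -> LayerAnalysisResults:
    """Functional wrapper: ``LesionLayerAnalysis(...).fit()``."""
    return LesionLayerAnalysis(pre_maps, post_maps, layers, reference_mask, nested).fit()
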
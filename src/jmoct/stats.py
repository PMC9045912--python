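"""Region quantification and hypothesis tests.

Workflow mirrored here: binary tumor/control masks drawn per intensity
B-scan are applied to the contrast volumes, the mean of each contrast
over the region of interest of each B-scan becomes one data point, the
two groups are summarized with box-whisker statistics and compared with a
two-sided Mann-Whitney U test (equality of distributions) and a Levene
test (equality of variances) at significance level 0.05.

Method details
--------------
* Mann-Whitney U: midrank ties; the two-sided p-value is computed by
  exact enumeration of the rank distribution when ``n1 + n2 <= 16`` and
  the pooled data are tie-free, otherwise by the normal approximation
  with tie-corrected variance and continuity correction.
* Levene: one-way ANOVA F statistic on absolute deviations from the
  group center (mean by default, median gives the Brown-Forsythe
  variant), p from F(1, n1+n2-2).
* Box summary: quartiles by linear interpolation between order
  statistics; whiskers extend to the most extreme points within 1.5*IQR
  of the box and anything beyond is an outlier.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .volumes import ScalarVolume

ALPHA = 0.05


@dataclass
class RegionMaskSet:
    """Per-B-scan binary masks for labelled regions.

    masks : dict label -> bool ndarray of shape (n_bscans, z, x)
        Labels are typically "tumor" and "control"; masks must be
        pairwise disjoint on every B-scan.
    """

    masks: dict
    volume_ref: str = ""

    def __post_init__(self) -> None:
        if not self.masks:
            raise ValueError("at least one labelled mask is required")
        shapes = {np.asarray(m).shape for m in self.masks.values()}
        if len(shapes) != 1:
            raise ValueError("all masks must share one shape")
        self.masks = {k: np.asarray(m, dtype=bool) for k, m in self.masks.items()}
        labels = list(self.masks)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                if np.any(self.masks[a] & self.masks[b]):
                    raise ValueError(f"masks {a!r} and {b!r} overlap")

    @property
    def labels(self) -> list:
        return list(self.masks)

    @property
    def n_bscans(self) -> int:
        return next(iter(self.masks.values())).shape[0]


def region_means_per_bscan(volume: ScalarVolume, masks: RegionMaskSet) -> dict:
    """Mean contrast value per B-scan per label.

    The volume is ``(z, x, n_bscans)``; each mask B-scan is ``(z, x)``.
    NaN voxels (undefined contrast) are excluded; B-scans whose mask is
    empty or covers only NaNs are skipped.
    """
    data = volume.data
    if data.ndim != 3:
        raise ValueError("expected a (z, x, n_bscans) volume")
    nz, nx, nb = data.shape
    out = {}
    for label, mask in masks.masks.items():
        if mask.shape != (nb, nz, nx):
            raise ValueError(f"mask {label!r} shape {mask.shape} does not match "
                             f"volume B-scans {(nb, nz, nx)}")
        means = []
        for b in range(nb):
            vals = data[:, :, b][mask[b]]
            vals = vals[np.isfinite(vals)]
            if vals.size:
                means.append(float(vals.mean()))
        out[label] = means
    return out


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` with U the statistic of the first sample.  Exact
    enumeration is used for tie-free pooled samples with ``n1+n2 <= 16``,
    otherwise the tie-corrected normal approximation with continuity
    correction.  If every pooled value is identical the samples overlap
    perfectly: ``U = n1*n2/2`` and ``p = 1``.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 1 or b.size < 1:
        raise ValueError("each sample needs at least one value")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return a.size * b.size / 2.0, 1.0
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (tie_free and pooled.size <= 16) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def levene_test(a: Sequence[float], b: Sequence[float],
                center: str = "mean") -> tuple[float, float]:
    """Levene test for equality of variances of two samples.

    ``center`` is "mean" (classic Levene) or "median" (Brown-Forsythe).
    Returns ``(W, p)``; identical deviation patterns give ``W=0, p=1``.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two values")
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    cfun = np.mean if center == "mean" else np.median
    da = np.abs(a - cfun(a))
    db = np.abs(b - cfun(b))
    if np.ptp(np.concatenate([da, db])) == 0:
        return 0.0, 1.0
    w, p = sps.levene(a, b, center=center)
    return float(w), float(p)


@dataclass
class BoxSummary:
    median: float
    q25: float
    q75: float
    whisker_lo: float
    whisker_hi: float
    outliers: list = field(default_factory=list)


def box_summary(values: Sequence[float]) -> BoxSummary:
    """Box-whisker summary with 1.5*IQR whiskers.

    Whiskers sit on the most extreme data points within 1.5*IQR of the
    box; values beyond are listed as outliers.
    """
    x = np.asarray(values, dtype=np.float64)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite values")
    q25, med, q75 = np.percentile(x, [25, 50, 75])
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = x[(x < lo_fence) | (x > hi_fence)]
    return BoxSummary(median=float(med), q25=float(q25), q75=float(q75),
                      whisker_lo=float(inside.min()), whisker_hi=float(inside.max()),
                      outliers=sorted(float(v) for v in outliers))


@dataclass
class ContrastStats:
    """Two-group comparison of one contrast."""

    contrast: str
    means: dict                    # label -> per-B-scan means
    boxes: dict                    # label -> BoxSummary
    u_statistic: float
    p_mann_whitney: float
    w_statistic: float
    p_levene: float
    significant_mw: bool
    significant_levene: bool
    direction: str                 # e.g. "tumor < control"


@dataclass
class StatsReport:
    """Per-contrast statistics of a labelled two-region comparison."""

    contrasts: dict                # contrast name -> ContrastStats
    alpha: float = ALPHA
    volume_ref: str = ""

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path=None, indent: int = 2):
        payload = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    def to_csv(self, path):
        """Per-B-scan means as a tidy CSV (contrast, label, bscan, mean)."""
        import pandas as pd
        rows = [
            {"contrast": cname, "label": label, "bscan": i, "mean": m}
            for cname, cs in self.contrasts.items()
            for label, means in cs.means.items()
            for i, m in enumerate(means)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def compare_regions(volumes: dict, masks: RegionMaskSet,
                    group_a: str = "tumor", group_b: str = "control",
                    alpha: float = ALPHA) -> StatsReport:
    """Compare two labelled regions across several contrast volumes.

    ``volumes`` maps contrast name -> ScalarVolume aligned with the mask
    set.  For each contrast the per-B-scan region means are compared with
    Mann-Whitney and Levene tests; the report records the direction of
    the median difference.
    """
    out = {}
    for cname, vol in volumes.items():
        means = region_means_per_bscan(vol, masks)
        xa, xb = means[group_a], means[group_b]
        u, p_mw = mann_whitney_u(xa, xb)
        w, p_lev = levene_test(xa, xb)
        med_a, med_b = np.median(xa), np.median(xb)
        if med_a < med_b:
            direction = f"{group_a} < {group_b}"
        elif med_a > med_b:
            direction = f"{group_a} > {group_b}"
        else:
            direction = f"{group_a} = {group_b}"
        out[cname] = ContrastStats(
            contrast=cname, means=means,
            boxes={lbl: box_summary(v) for lbl, v in means.items()},
            u_statistic=u, p_mann_whitney=p_mw,
            w_statistic=w, p_levene=p_lev,
            significant_mw=bool(p_mw < alpha),
            significant_levene=bool(p_lev < alpha),
            direction=direction)
    return StatsReport(contrasts=out, alpha=alpha, volume_ref=masks.volume_ref)


def analyze_tumor_control(jones, masks: RegionMaskSet, *,
                          depth_sep: int = 2, dopu_kernel: tuple = (3, 5),
                          noise_power: float | None = None,
                          debias_attenuation: bool = True,
                          alpha: float = ALPHA) -> StatsReport:
    """End-to-end quantification of a Jones volume against a mask set.

    Computes the four contrasts (intensity in dB for reporting,
    attenuation from the linear intensity, naive local birefringence,
    DOPU) and runs :func:`compare_regions`.
    """
    from . import contrasts as ct

    lin = ct.scatter_intensity(jones)
    volumes = {
        "intensity_db": ct.scatter_intensity(jones, db=True),
        "attenuation": ct.attenuation_depth_resolved(lin, debias=debias_attenuation),
        "birefringence": ct.local_birefringence(jones, depth_sep=depth_sep,
                                                noise_power=noise_power)[0],
        "dopu": ct.dopu(jones, kernel=dopu_kernel),
    }
    return compare_regions(volumes, masks, alpha=alpha)


def plot_boxes(report: StatsReport, path=None, contrasts: Sequence[str] | None = None):
    """Box-whisker figure of the per-B-scan means, one panel per contrast."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    names = list(contrasts or report.contrasts)
    fig, axes = plt.subplots(1, len(names), figsize=(3 * len(names), 3.2))
    axes = np.atleast_1d(axes)
    for ax, cname in zip(axes, names):
        cs = report.contrasts[cname]
        labels = list(cs.means)
        ax.boxplot([cs.means[l] for l in labels], tick_labels=labels, whis=1.5)
        ax.set_title(f"{cname}\nMW p={cs.p_mann_whitney:.3g}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
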
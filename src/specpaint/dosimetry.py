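"""Plan-quality metrics: conformity, DVH-derived doses, paired comparison.

For a target PTV with prescription Rx the three conformity quantities are

    I1 = PTV95 / V_PTV        (target coverage)
    I2 = PTV95 / V_iso95      (conformity index)
    CN = I1 * I2              (conformation number)

where PTV95 is the target volume receiving >= 95% of Rx and V_iso95 the
total volume enclosed by that isodose.  Organ-at-risk exposure is reported
as the near-maximum dose D1% (lowest dose received by the hottest 1% of
the structure) and, for normal brain, the dose-volumes V18 / V36 / V50
(fraction of the structure receiving at least 18 / 36 / 50 Gy, in %).

Volumes are voxel-center counts times the voxel volume — the convention of
TPS-style DVHs, and exactly reproducible by brute-force counting.  Paired
plan comparisons use the two-sided Wilcoxon signed-rank test, exact for
small samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .grids import BinaryMask, VolumeImage

__all__ = [
    "DoseGrid",
    "DvhCurve",
    "ConformityReport",
    "dvh",
    "conformity",
    "dose_at_top_volume",
    "volume_at_dose",
    "compare_paired",
    "NoTestError",
]


class NoTestError(ValueError):
    """A paired test cannot be formed (all pairs tied, or too few pairs)."""


@dataclass
class DoseGrid(VolumeImage):
    """Absorbed dose (Gy) on a grid, with the prescriptions it implements."""

    prescriptions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.array < 0):
            raise ValueError("dose must be non-negative")


@dataclass
class DvhCurve:
    """Cumulative dose-volume histogram of one structure.

    ``cumulative[i]`` is the fraction of the structure receiving at least
    ``edges[i]`` Gy; the curve starts at 1 (everything receives >= 0 Gy)
    and is non-increasing.  ``doses`` keeps the raw voxel doses so that
    point metrics (D1%, Vx) are computed exactly rather than from bins.
    """

    edges: np.ndarray
    cumulative: np.ndarray
    mask_volume_cm3: float
    doses: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        if self.edges.shape != self.cumulative.shape:
            raise ValueError("edges and cumulative must align")
        if np.any(np.diff(self.cumulative) > 1e-12):
            raise ValueError("cumulative volume must be non-increasing")


@dataclass
class ConformityReport:
    """Coverage/conformity of one target under one prescription."""

    ptv95_cm3: float
    vtot_ptv_cm3: float
    viso95_cm3: float
    i1: float
    i2: float | None
    cn: float | None
    prescription_gy: float

    @property
    def i2_defined(self) -> bool:
        return self.i2 is not None


def dvh(dose: DoseGrid, mask: BinaryMask, bin_width_gy: float = 0.1) -> DvhCurve:
    """Cumulative DVH by voxel counting (exact at voxel granularity)."""
    dose.require_same_grid(mask)
    if not mask.array.any():
        raise ValueError("cannot build a DVH over an empty structure")
    if bin_width_gy <= 0:
        raise ValueError("bin width must be positive")
    doses = dose.array[mask.array]
    top = float(doses.max())
    edges = np.arange(0.0, top + 2 * bin_width_gy, bin_width_gy)
    cumulative = np.array([(doses >= e).mean() for e in edges])
    return DvhCurve(
        edges=edges,
        cumulative=cumulative,
        mask_volume_cm3=mask.volume_cm3,
        doses=doses,
    )


def conformity(
    dose: DoseGrid, ptv: BinaryMask, prescription_gy: float, isodose_fraction: float = 0.95
) -> ConformityReport:
    """I1, I2 and CN of a target at the 95% isodose of its prescription."""
    if prescription_gy <= 0:
        raise ValueError("prescription must be positive")
    dose.require_same_grid(ptv)
    level = isodose_fraction * prescription_gy
    iso = dose.array >= level
    vv = ptv.voxel_volume_cm3
    n_ptv = int(ptv.array.sum())
    n_iso = int(iso.sum())
    n_cov = int((iso & ptv.array).sum())
    if n_ptv == 0:
        raise ValueError("empty PTV")
    i1 = n_cov / n_ptv
    if n_iso == 0:
        i2 = cn = None
    else:
        i2 = n_cov / n_iso
        cn = i1 * i2
    return ConformityReport(
        ptv95_cm3=n_cov * vv,
        vtot_ptv_cm3=n_ptv * vv,
        viso95_cm3=n_iso * vv,
        i1=i1,
        i2=i2,
        cn=cn,
        prescription_gy=prescription_gy,
    )


def dose_at_top_volume(curve: DvhCurve, fraction: float = 0.01) -> float:
    """Near-maximum dose: lowest dose received by the hottest ``fraction``.

    D1% is the smallest dose D such that the relative volume receiving
    >= D is <= fraction.  Computed from the raw voxel doses when the curve
    carries them (exact), otherwise from the binned curve (one-bin
    resolution).  ``fraction = 1`` returns the minimum structure dose.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if curve.doses is not None and len(curve.doses):
        doses = np.sort(np.asarray(curve.doses, dtype=float))
        n = len(doses)
        if fraction >= 1.0:
            return float(doses[0])
        # smallest dose with (# voxels >= d) / n <= fraction
        k = int(np.floor(fraction * n))  # allow at most k voxels at/above
        if k == 0:
            return float(doses[-1])  # hottest-fraction smaller than one voxel
        return float(doses[n - k])
    drop = np.flatnonzero(curve.cumulative <= fraction)
    if drop.size == 0:
        raise ValueError("degenerate DVH: curve never falls to the fraction")
    return float(curve.edges[drop[0]])


def volume_at_dose(curve: DvhCurve, dose_gy: float) -> float:
    """Fraction of the structure receiving at least ``dose_gy`` (0..1)."""
    if dose_gy < 0:
        raise ValueError("dose must be >= 0")
    if curve.doses is not None and len(curve.doses):
        return float((np.asarray(curve.doses) >= dose_gy).mean())
    idx = np.searchsorted(curve.edges, dose_gy, side="left")
    if idx >= len(curve.edges):
        return 0.0
    return float(curve.cumulative[idx])


def compare_paired(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired plan metrics.

    Zero differences are dropped (Wilcoxon's convention); the exact null
    distribution is used for up to 25 informative pairs, the normal
    approximation with continuity correction above that.  Returns
    (statistic, two-sided p).  Raises :class:`NoTestError` when fewer than
    3 informative pairs remain.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1D sequences")
    diffs = a - b
    informative = np.count_nonzero(diffs)
    if informative < 3:
        raise NoTestError(
            f"only {informative} informative (non-tied) pairs; need >= 3"
        )
    method = "exact" if informative <= 25 else "approx"
    res = stats.wilcoxon(
        a, b, zero_method="wilcox", correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    return float(res.statistic), float(res.pvalue)
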
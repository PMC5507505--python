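"""Daily secretion rates, enamel extension rates and their spatial profiles.

Two rates summarize enamel growth.  The daily secretion rate (DSR,
um/day) is how fast a single ameloblast deposits matrix along its prism:
segment length divided by its cross-striation count.  The enamel
extension rate (EER, um/day) is how fast new secretory ameloblasts are
recruited along the enamel-dentine junction (EDJ): EDJ interval length
divided by its formation days.  In deciduous incisors the EER starts very
high in the cusp and decelerates sharply toward the cervix, while the DSR
near the EDJ stays nearly constant and accelerates toward the outer
surface.

For regional comparisons the prenatal EDJ is split into three unequal
portions — cuspal-middle (0-70% of EDJ length), middle-neonatal (70-90%)
and neonatal (last 10%) — unequal because the cuspal EDJ forms so fast
that a short time span covers a long stretch of junction.

The module also fits a smooth topographic DSR surface over (position
along the crown, depth from the EDJ) via thin-plate splines with a
generalized-cross-validated ridge penalty, and per-tooth EDJ growth
profiles (cumulative EDJ length vs cumulative days) via loess.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .enamel_data import EDJInterval, Finding, PrismSegment, ToothRecord

__all__ = [
    "RegionPartition",
    "DSRSurface",
    "GrowthProfile",
    "segment_dsr",
    "interval_eer",
    "assign_region",
    "region_summaries",
    "fit_dsr_surface",
    "edj_growth_profile",
]

DEFAULT_LABELS = ("cuspal-middle", "middle-neonatal", "neonatal")


@dataclass(frozen=True)
class RegionPartition:
    """Partition of the prenatal EDJ fraction axis [0, 1] into labelled regions."""

    boundaries: tuple[float, ...] = (0.70, 0.90)
    labels: tuple[str, ...] = DEFAULT_LABELS

    def __post_init__(self) -> None:
        bs = self.boundaries
        if not all(0.0 < a < 1.0 for a in bs) or list(bs) != sorted(set(bs)):
            raise ValueError(f"boundaries must be strictly increasing in (0,1), got {bs}")
        if len(self.labels) != len(bs) + 1:
            raise ValueError("need exactly one more label than boundaries")

    def region_of(self, fraction: float) -> str:
        """Region containing ``fraction``; boundary ties go to the earlier
        (more cuspal) region."""
        i = int(np.sum(np.asarray(self.boundaries) < fraction))
        return self.labels[i]


@dataclass
class DSRSurface:
    """Smoothed topographic DSR field over the enamel cap.

    Axes: ``x`` = position along the crown (um from the dentine horn),
    ``w`` = depth from the EDJ toward the outer surface.  ``grid_rate`` may
    be floored at a small epsilon for display; statistics should use the
    raw evaluation via :meth:`predict`.
    """

    points: np.ndarray  # (n, 3): x, w, rate
    grid_x: np.ndarray
    grid_w: np.ndarray
    grid_rate: np.ndarray  # (len(grid_w), len(grid_x))
    explained_deviance: float
    ridge_lambda: float
    _coef: np.ndarray = field(repr=False, default=None)
    _centers: np.ndarray = field(repr=False, default=None)
    _scale: tuple = field(repr=False, default=None)

    def predict(self, x: "np.ndarray | float", w: "np.ndarray | float") -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        w = np.atleast_1d(np.asarray(w, dtype=float))
        P = _tps_design(np.column_stack([x, w]), self._centers, self._scale)
        return P @ self._coef


@dataclass
class GrowthProfile:
    """Cumulative EDJ growth (days vs um) for one tooth, raw and smoothed."""

    tooth_id: str
    samples: np.ndarray  # (n, 2): cumulative days, cumulative EDJ length um
    smoothed: np.ndarray | None  # (m, 2) on an evaluation grid, or None
    findings: list[Finding] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Elementary rates
# ---------------------------------------------------------------------------


def segment_dsr(segment: PrismSegment) -> float:
    """Daily secretion rate of one prism segment: length / day count."""
    if not segment.count_days or segment.count_days <= 0:
        raise ValueError(f"{segment.tooth_id}/segment[{segment.index}]: non-positive day count")
    return segment.length_um / segment.count_days


def interval_eer(interval: EDJInterval) -> float:
    """Enamel extension rate of one EDJ interval: length / days."""
    if interval.days <= 0:
        raise ValueError(f"{interval.tooth_id}/edj[{interval.index}]: non-positive days")
    return interval.length_um / interval.days


def assign_region(interval: EDJInterval, partition: RegionPartition | None = None) -> str:
    """Region of the interval's EDJ-fraction midpoint (ties go cuspal)."""
    partition = partition or RegionPartition()
    return partition.region_of(interval.midpoint_fraction)


# ---------------------------------------------------------------------------
# Regional summaries
# ---------------------------------------------------------------------------


def _five_number(values: Sequence[float]) -> dict:
    if len(values) == 0:
        return {"n": 0}
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {
        "n": int(v.size),
        "min": float(v.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(v.max()),
    }


def region_summaries(
    records: Iterable[ToothRecord], partition: RegionPartition | None = None
) -> dict:
    """Per-region five-number summaries of DSR and EER across a cohort.

    EER values are regionalized by the interval midpoint fraction.  Prism
    segments carry no EDJ position of their own, so a segment inherits the
    region of the same-index EDJ interval of its tooth; segments without a
    matching interval are omitted from the regional DSR summaries.  The
    raw per-region value lists are returned under ``values`` for use by the
    rank-based tests.
    """
    partition = partition or RegionPartition()
    dsr_by_region: dict[str, list[float]] = {lab: [] for lab in partition.labels}
    eer_by_region: dict[str, list[float]] = {lab: [] for lab in partition.labels}
    for rec in records:
        intervals_by_index = {iv.index: iv for iv in rec.edj_intervals}
        for iv in rec.edj_intervals:
            eer_by_region[assign_region(iv, partition)].append(interval_eer(iv))
        for seg in rec.segments:
            iv = intervals_by_index.get(seg.index)
            if iv is not None:
                dsr_by_region[assign_region(iv, partition)].append(segment_dsr(seg))
    return {
        "dsr": {lab: _five_number(vals) for lab, vals in dsr_by_region.items()},
        "eer": {lab: _five_number(vals) for lab, vals in eer_by_region.items()},
        "values": {"dsr": dsr_by_region, "eer": eer_by_region},
    }


# ---------------------------------------------------------------------------
# Thin-plate-spline DSR surface
# ---------------------------------------------------------------------------


def _tps_kernel(r: np.ndarray) -> np.ndarray:
    out = np.zeros_like(r)
    pos = r > 0
    out[pos] = r[pos] ** 2 * np.log(r[pos])
    return out


def _tps_design(xy: np.ndarray, centers: np.ndarray, scale: tuple) -> np.ndarray:
    (x0, xs), (w0, ws) = scale
    u = np.column_stack([(xy[:, 0] - x0) / xs, (xy[:, 1] - w0) / ws])
    d = np.sqrt(((u[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2))
    K = _tps_kernel(d)
    P = np.column_stack([np.ones(len(u)), u])
    return np.hstack([K, P])


def fit_dsr_surface(
    points: "np.ndarray | list",
    grid_shape: tuple[int, int] = (40, 40),
    lambdas: "Sequence[float] | None" = None,
    display_floor: float = 1e-6,
) -> DSRSurface:
    """Fit a smooth DSR surface to scattered (x, w, rate) measurements.

    Thin-plate radial basis centred on the (unit-square normalized) sample
    points plus an affine part, with a ridge penalty on the basis
    coefficients selected by generalized cross-validation over a
    log-spaced grid.  The fraction of (centred) rate variance explained is
    reported as the explained deviance.  Display grids floor the smoothed
    rate at a small positive epsilon; the sample-point fit is not floored.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be (n, 3): (x_um, depth_um, rate_um_day)")
    n = len(pts)
    if n < 20:
        raise ValueError(f"need at least 20 points, got {n}")
    x, w, z = pts[:, 0], pts[:, 1], pts[:, 2]
    if np.ptp(x) == 0 or np.ptp(w) == 0:
        raise np.linalg.LinAlgError("collinear sample points: no spread on one axis")

    scale = ((x.min(), np.ptp(x)), (w.min(), np.ptp(w)))
    centers = np.column_stack([(x - x.min()) / np.ptp(x), (w - w.min()) / np.ptp(w)])
    A = _tps_design(pts[:, :2], centers, scale)

    # Penalize only the RBF coefficients (affine part unpenalized).
    pen = np.zeros(A.shape[1])
    pen[:n] = 1.0
    if lambdas is None:
        lambdas = np.logspace(-8, 2, 21)

    best = None
    AtA = A.T @ A
    Atz = A.T @ z
    for lam in lambdas:
        M = AtA + lam * np.diag(pen)
        try:
            coef = np.linalg.solve(M, Atz)
            Minv = np.linalg.inv(M)
        except np.linalg.LinAlgError:
            continue
        fitted = A @ coef
        # effective dof = trace of the hat matrix A (AtA + lam P)^-1 At
        edf = float(np.trace(AtA @ Minv))
        rss = float(np.sum((z - fitted) ** 2))
        denom = max(n - edf, 1e-8)
        gcv = n * rss / denom**2
        if best is None or gcv < best[0]:
            best = (gcv, lam, coef, fitted)
    if best is None:
        raise np.linalg.LinAlgError("surface fit failed for all ridge penalties")
    _, lam, coef, fitted = best

    tss = float(np.sum((z - z.mean()) ** 2))
    rss = float(np.sum((z - fitted) ** 2))
    explained = 1.0 if tss == 0 else 1.0 - rss / tss

    gx = np.linspace(x.min(), x.max(), grid_shape[1])
    gw = np.linspace(w.min(), w.max(), grid_shape[0])
    GX, GW = np.meshgrid(gx, gw)
    surf = DSRSurface(
        points=pts,
        grid_x=gx,
        grid_w=gw,
        grid_rate=np.empty(GX.shape),
        explained_deviance=explained,
        ridge_lambda=float(lam),
        _coef=coef,
        _centers=centers,
        _scale=scale,
    )
    grid_vals = surf.predict(GX.ravel(), GW.ravel()).reshape(GX.shape)
    surf.grid_rate = np.maximum(grid_vals, display_floor)
    return surf


# ---------------------------------------------------------------------------
# Per-tooth EDJ growth profile (loess)
# ---------------------------------------------------------------------------


def _loess(x: np.ndarray, y: np.ndarray, grid: np.ndarray, span: float) -> np.ndarray:
    """Local linear regression with tricube weights, evaluated at ``grid``.

    At each evaluation point the bandwidth is the distance to the
    ceil(span * n)-th nearest sample; a weighted straight line is fit and
    evaluated there (no interpolation between sample fits).
    """
    n = x.size
    k = max(int(np.ceil(span * n)), 2)
    out = np.empty(grid.size)
    for j, g in enumerate(grid):
        d = np.abs(x - g)
        h = np.sort(d)[k - 1]
        if h <= 0:
            h = max(d.max(), 1e-12)
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        w_sum = w.sum()
        xm = np.sum(w * x) / w_sum
        ym = np.sum(w * y) / w_sum
        sxx = np.sum(w * (x - xm) ** 2)
        slope = np.sum(w * (x - xm) * (y - ym)) / sxx if sxx > 0 else 0.0
        out[j] = ym + slope * (g - xm)
    return out


def edj_growth_profile(
    record: ToothRecord, span: float = 0.75, n_eval: int = 100
) -> GrowthProfile:
    """Cumulative EDJ length vs cumulative days, loess-smoothed.

    Locally weighted linear regression (tricube weights, default span
    0.75) of cumulative EDJ length on cumulative formation days, evaluated
    on a regular day grid; an isotonic pass then enforces the physical
    constraint that EDJ length never decreases in time.  With fewer than 4
    intervals only the raw points are returned, with a finding.
    """
    days = np.cumsum([iv.days for iv in record.edj_intervals])
    lengths = np.cumsum([iv.length_um for iv in record.edj_intervals])
    samples = np.column_stack([days, lengths]) if len(days) else np.empty((0, 2))
    if len(days) < 4:
        return GrowthProfile(
            tooth_id=record.id,
            samples=samples,
            smoothed=None,
            findings=[
                Finding(
                    "warning",
                    record.id,
                    f"only {len(days)} EDJ interval(s); profile left unsmoothed",
                )
            ],
        )
    t0 = np.concatenate([[0.0], days])
    l0 = np.concatenate([[0.0], lengths])
    grid = np.linspace(t0.min(), t0.max(), n_eval)
    smoothed = _loess(t0, l0, grid, span)
    smoothed = np.maximum.accumulate(smoothed)  # isotonic: EDJ never shrinks
    return GrowthProfile(
        tooth_id=record.id,
        samples=samples,
        smoothed=np.column_stack([grid, smoothed]),
    )
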
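"""Tumour-growth division model and the thickness x DCCD risk-plane scans.

A primary tumour of thickness ``t`` (treated as a sphere of melanoma cells
of 18 um diameter at 60% packing) holds N = (t/d)^3 * packing cells, having
arisen from N_T = log2(N) doublings of a single founding cell.  A sentinel
node colony of DCCD cells likewise encodes n_L = log2(DCCD) divisions after
dissemination.  The risk of acquiring a genomic alteration is modelled as

    E = a * n_T + b * n_L

with n_T the divisions incurred in the primary before dissemination; the
(a, b) pair defines four prototype categories whose equal-risk lines in the
(n_L, N_T) plane are ascending (category 1, a=1 b=0), horizontal (2, a=b=1,
equal growth rates), descending (3, a=1 b=2g) or vertical (4, a=0 b=1).

The empirical counterpart scans displaced-set-point linear classifiers over
the scaled log(DCCD)-log(thickness) plane, tests each split locus-wise by
(weighted) Fisher exact tests with BH correction across loci, and reports
per-locus minimum-FDR classifiers together with corrected angles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import bh_fdr, fisher_exact, fisher_noninteger

__all__ = [
    "GrowthRiskSpec", "divisions_from_thickness", "risk_value",
    "corrected_angle", "classifier_scan", "dccd_threshold_scan",
    "thin_thick_scan", "ScanResult",
]


@dataclass(frozen=True)
class GrowthRiskSpec:
    """Geometry and kinetics of the division model.

    cell_diameter_um : melanoma cell diameter (default 18 um).
    packing_fraction : tumour-cell volume fraction of the sphere (0.6).
    ghat : ratio g_T/g_L of primary to node growth rates (default 1).
    a, b : risk-function coefficients.
    """

    cell_diameter_um: float = 18.0
    packing_fraction: float = 0.6
    ghat: float = 1.0
    a: float = 1.0
    b: float = 0.0

    def __post_init__(self):
        if self.cell_diameter_um <= 0:
            raise ValueError("cell diameter must be > 0")
        if not 0 < self.packing_fraction <= 1:
            raise ValueError("packing fraction must be in (0, 1]")
        if self.ghat <= 0:
            raise ValueError("growth-rate ratio must be > 0")


def cells_from_thickness(t_mm, spec: GrowthRiskSpec = GrowthRiskSpec()):
    """Number of tumour cells in a sphere of diameter ``t_mm``."""
    t_mm = np.asarray(t_mm, dtype=float)
    if np.any(t_mm <= 0):
        raise ValueError("thickness must be > 0")
    return (t_mm * 1000.0 / spec.cell_diameter_um) ** 3 * spec.packing_fraction


def divisions_from_thickness(t_mm, spec: GrowthRiskSpec = GrowthRiskSpec()):
    """Cell divisions N_T = log2(cells) behind a tumour of thickness t_mm.

    Thicknesses so small that the sphere holds less than one cell are in
    the sub-single-cell regime: a warning is emitted and 0 is returned.
    """
    n = cells_from_thickness(t_mm, spec)
    scalar = np.ndim(n) == 0
    n = np.atleast_1d(n)
    if np.any(n < 1):
        warnings.warn("thickness below single-cell regime; divisions clamped to 0",
                      stacklevel=2)
    out = np.where(n >= 1, np.log2(np.maximum(n, 1.0)), 0.0)
    return float(out[0]) if scalar else out


def risk_value(spec: GrowthRiskSpec, n_t, n_l):
    """Risk function E = a*n_T + b*n_L (n_T, n_L >= 0)."""
    n_t = np.asarray(n_t, dtype=float)
    n_l = np.asarray(n_l, dtype=float)
    if np.any(n_t < 0) or np.any(n_l < 0):
        raise ValueError("division counts must be >= 0")
    return spec.a * n_t + spec.b * n_l


def corrected_angle(phi_deg: float, wrap_threshold: float = 157.5) -> float:
    """Correct a raw classifier angle for the qualitative DCCD axis.

    The log(DCCD) axis is re-scaled by 1/2 (doubling the x component of
    the classifier normal and renormalising); angles at or above the wrap
    threshold are mapped near 0 by subtracting 180 degrees.
    """
    if not 0.0 <= phi_deg < 180.0:
        raise ValueError("angle must lie in [0, 180)")
    r = math.radians(phi_deg)
    ang = math.degrees(math.atan2(math.sin(r), 2.0 * math.cos(r))) % 180.0
    if ang >= wrap_threshold:
        ang -= 180.0
    return ang


# ---------------------------------------------------------------------------
# classifier machinery


def _scale01(x: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        raise ValueError("need at least two distinct values per axis")
    return (x - lo) / (hi - lo)


def _min_gap(x: np.ndarray) -> float:
    u = np.unique(x)
    return float(np.min(np.diff(u)))


@dataclass
class ScanResult:
    """Outcome of a classifier scan.

    ``best`` has one row per locus: minimum FDR, the raw and corrected
    angles attaining it (ties collapsed to a representative plus a range)
    and the set point used.  ``surface`` (optional) is the long-format
    FDR surface over (set point, angle, locus).
    """

    best: pd.DataFrame
    surface: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)


def _prepare_plane(dccd, thickness):
    dccd = np.asarray(dccd, dtype=float)
    thickness = np.asarray(thickness, dtype=float)
    if np.any(dccd < 1):
        raise ValueError("classifier plane requires DCCD >= 1 for all samples")
    if np.any(thickness <= 0):
        raise ValueError("thickness must be > 0")
    x = _scale01(np.log(dccd))
    y = _scale01(np.log(thickness))
    return np.column_stack([x, y])


def _set_points(points: np.ndarray) -> np.ndarray:
    """Four displaced set points per distinct experimental (DCCD, thickness)
    pair: the pair shifted by (+-dx/2, +-dy/2) with dx, dy the minimal
    absolute differences between distinct scaled values per axis."""
    dx = _min_gap(points[:, 0])
    dy = _min_gap(points[:, 1])
    pairs = np.unique(points, axis=0)
    offs = np.array([[sx * dx / 2, sy * dy / 2]
                     for sx in (-1, 1) for sy in (-1, 1)])
    return (pairs[:, None, :] + offs[None, :, :]).reshape(-1, 2), pairs, (dx, dy)


def _split_table(states_col: np.ndarray, mask: np.ndarray,
                 w: np.ndarray | None) -> np.ndarray | None:
    sts = np.unique(states_col)
    rows = []
    for side in (mask, ~mask):
        v = states_col[side]
        if w is None:
            rows.append(np.array([(v == s).sum() for s in sts], dtype=float))
        else:
            ws = w[side]
            rows.append(np.array([ws[v == s].sum() for s in sts]))
    tab = np.vstack(rows)
    tab = tab[:, tab.sum(axis=0) > 0]
    if tab.shape[1] < 2:
        return None
    return tab


def _mask_pvalues(states: pd.DataFrame, mask: np.ndarray,
                  weights: pd.DataFrame | None) -> np.ndarray:
    pv = np.ones(states.shape[1])
    for j, locus in enumerate(states.columns):
        col = states[locus].to_numpy()
        w = None
        if weights is not None:
            w = weights.loc[locus].to_numpy(dtype=float)
        tab = _split_table(col, mask, w)
        if tab is None:
            continue
        if w is None:
            pv[j] = fisher_exact(tab)
        else:
            pv[j] = fisher_noninteger(tab)
    return pv


def classifier_scan(dccd, thickness, states: pd.DataFrame,
                    weights: pd.DataFrame | None = None,
                    angle_step: float = 1.0,
                    min_class_size: int = 10,
                    keep_surface: bool = False) -> ScanResult:
    """Scan displaced-set-point linear classifiers over the scaled
    log(DCCD)-log(thickness) plane.

    For every experimental (DCCD, thickness) pair, 4 displaced set points
    are formed; angles phi in [0, 180) are scanned in ``angle_step`` steps,
    samples split by the sign of (sample - set point) . (cos phi, sin phi),
    each locus tested on the split's contingency table and BH-adjusted
    across loci per classifier.  Splits leaving all samples on one side are
    skipped.  Per-locus best-angle summaries only admit classifiers with at
    least ``min_class_size`` samples per class.

    ``states`` is a samples x loci DataFrame; ``weights`` an optional
    loci x samples weight table (see :func:`occultevo.stats.optimise_weights`).
    """
    points = _prepare_plane(dccd, thickness)
    sps, pairs, (dx, dy) = _set_points(points)
    angles = np.arange(0.0, 180.0, angle_step)
    normals = np.column_stack([np.cos(np.radians(angles)),
                               np.sin(np.radians(angles))])
    n = points.shape[0]
    loci = list(states.columns)

    # distinct splits: many (set point, angle) classifiers induce the same
    # binary partition; p values are computed once per distinct split.
    split_cache: dict[bytes, np.ndarray] = {}
    records = []  # (sp_idx, angle_idx, mask_key, n_small_side)
    for si, sp in enumerate(sps):
        diff = points - sp
        proj = diff @ normals.T  # n x n_angles
        masks = proj > 0
        for ai in range(angles.size):
            mask = masks[:, ai]
            k = int(mask.sum())
            if k == 0 or k == n:
                continue
            records.append((si, ai, mask.tobytes(), min(k, n - k)))
            split_cache.setdefault(mask.tobytes(), mask.copy())

    fdr_by_key: dict[bytes, np.ndarray] = {}
    for key, mask in split_cache.items():
        pv = _mask_pvalues(states, mask, weights)
        fdr_by_key[key] = bh_fdr(pv)

    nl = len(loci)
    best_fdr = np.full(nl, np.inf)
    best_entries: list[list[tuple]] = [[] for _ in range(nl)]
    surface_rows = [] if keep_surface else None
    for si, ai, key, small in records:
        fdr = fdr_by_key[key]
        if surface_rows is not None:
            pair_idx = si // 4
            for j in range(nl):
                surface_rows.append((pair_idx, si, angles[ai], loci[j], fdr[j]))
        if small < min_class_size:
            continue
        for j in range(nl):
            if fdr[j] < best_fdr[j] * (1 - 1e-9):
                best_fdr[j] = fdr[j]
                best_entries[j] = [(si, angles[ai])]
            elif fdr[j] <= best_fdr[j] * (1 + 1e-9):
                best_entries[j].append((si, angles[ai]))

    rows = []
    for j, locus in enumerate(loci):
        if not best_entries[j]:
            rows.append({"locus": locus, "min_fdr": np.nan, "angle": np.nan,
                         "corrected_angle": np.nan, "angle_lo": np.nan,
                         "angle_hi": np.nan, "set_point_x": np.nan,
                         "set_point_y": np.nan, "n_tied": 0})
            continue
        tied = sorted({a for _, a in best_entries[j]})
        corr = [corrected_angle(a) for a in tied]
        # representative: the tied corrected angle closest to the tied-set
        # median (a medoid, stable under ties)
        med = float(np.median(corr))
        pick = int(np.argmin(np.abs(np.asarray(corr) - med)))
        si = [s for s, a in best_entries[j] if a == tied[pick]][0]
        rows.append({"locus": locus, "min_fdr": best_fdr[j],
                     "angle": tied[pick], "corrected_angle": corr[pick],
                     "angle_lo": tied[0], "angle_hi": tied[-1],
                     "set_point_x": sps[si][0], "set_point_y": sps[si][1],
                     "n_tied": len(tied)})
    best = pd.DataFrame(rows)
    surface = None
    if surface_rows is not None:
        surface = pd.DataFrame(
            surface_rows, columns=["pair", "set_point", "angle", "locus", "fdr"])
    return ScanResult(best=best, surface=surface,
                      meta={"dx": dx, "dy": dy, "n_set_points": len(sps),
                            "angles": angles})


def dccd_threshold_scan(dccd, thickness, states: pd.DataFrame,
                        grid=None, weights: pd.DataFrame | None = None,
                        fdr_limit: float = 0.05) -> pd.DataFrame:
    """Vertical-classifier (angle 0) scan over DCCD thresholds.

    For each threshold in ``grid`` (defaults to the distinct observed DCCD
    values), samples are split by DCCD with the set point placed just left
    of the threshold; per-locus Fisher + BH across loci.  Returns one row
    per locus with the minimum FDR, the peak DCCD (threshold attaining it)
    and a colonisation-signature flag (min FDR < ``fdr_limit``).
    """
    dccd = np.asarray(dccd, dtype=float)
    if grid is None:
        grid = np.unique(dccd)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    if np.any(grid < dccd.min()) or np.any(grid > dccd.max()):
        raise ValueError("grid must lie within the observed DCCD range")
    loci = list(states.columns)
    n = dccd.size
    best = np.full(len(loci), np.inf)
    peak = np.full(len(loci), np.nan)
    for thr in grid:
        mask = dccd >= thr  # set point left of the threshold value
        k = int(mask.sum())
        if k == 0 or k == n:
            continue
        pv = _mask_pvalues(states, mask,
                           weights if weights is not None else None)
        fdr = bh_fdr(pv)
        upd = fdr < best * (1 - 1e-9)
        peak[upd] = thr
        best[upd] = fdr[upd]
    return pd.DataFrame({
        "locus": loci, "min_fdr": best, "peak_dccd": peak,
        "signature": (best < fdr_limit)})


def thin_thick_scan(dccd, thickness, states: pd.DataFrame,
                    dccd_limits, thickness_splits,
                    weights: pd.DataFrame | None = None,
                    min_per_side: int = 2) -> pd.DataFrame:
    """Pre-colonisation thin-vs-thick scan (DCCD limit x thickness split).

    For each DCCD limit, samples with DCCD <= limit are split into thin
    and thick primaries at each thickness split (set point left of the
    split value) and tested locus-wise with BH across loci; the minimum
    FDR across loci is recorded.  Cells with fewer than ``min_per_side``
    samples on either side are skipped (NaN).
    """
    dccd = np.asarray(dccd, dtype=float)
    thickness = np.asarray(thickness, dtype=float)
    dccd_limits = np.asarray(dccd_limits, dtype=float)
    thickness_splits = np.asarray(thickness_splits, dtype=float)
    if dccd_limits.size == 0 or thickness_splits.size == 0:
        raise ValueError("limits and splits must be non-empty")
    rows = []
    for lim in dccd_limits:
        sel = dccd <= lim
        for spl in thickness_splits:
            mask_all = thickness >= spl  # set point left of the split
            mask = mask_all[sel]
            n1, n0 = int(mask.sum()), int((~mask).sum())
            if n1 < min_per_side or n0 < min_per_side:
                rows.append((lim, spl, n1 + n0, np.nan, None))
                continue
            sub = states.loc[sel]
            pv = _mask_pvalues(sub, mask, weights)
            fdr = bh_fdr(pv)
            j = int(np.argmin(fdr))
            rows.append((lim, spl, n1 + n0, float(fdr[j]), states.columns[j]))
    return pd.DataFrame(rows, columns=["dccd_limit", "thickness_split",
                                       "n_samples", "min_fdr", "best_locus"])
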
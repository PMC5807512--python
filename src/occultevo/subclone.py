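"""Bounding the probability that sentinel-node DCCs derive from hidden
primary-tumour subclones.

Bulk metaphase CGH of a primary-tumour sample reports, per locus, only an
interval for the mean allele frequency: I1 = [1, 1.4] (loss detected),
I2 = (1.4, 2.6) (balanced) or I3 = [2.6, 3] (gain detected), because an
aberration must be carried by at least 60% of cells to be called.  A DCC
genotype D in {1, 2, 3} (deleted / balanced / amplified per locus) may
therefore hide inside the bulk at some clone fraction f.  For each patient
the largest fractions consistent with every locus are found by maximising
the product of fractions subject to the interval constraints (the
conservative, DCC-friendliest estimate); a dissemination fold change d
maps the tumour fractions to node fractions p = d f / (1 + (d-1) sum f).
The number of DCC samples that cannot be excluded from subclone origin at
level alpha then follows from the exact Poisson-binomial distribution of
the per-sample origin indicators.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "INTERVALS", "SubcloneProblem", "ExclusionResult",
    "max_product_fractions", "adjust_for_fold",
    "poisson_binomial_pmf", "poisson_binomial_pmf_partition",
    "max_unexcludable", "scan_fold_fraction", "PAPER_CLASS_FRACTIONS",
]

#: bulk CGH mean-allele-frequency intervals; the open interval I2 is closed
#: by a small epsilon for feasibility checks
_EPS = 1e-9
INTERVALS = {"I1": (1.0, 1.4), "I2": (1.4 + _EPS, 2.6 - _EPS), "I3": (2.6, 3.0)}

#: maximum DCC-like clone fractions of the matched cohort: 5 DCCs at 0.1,
#: 9 at 0.2 and 10 at 0.4
PAPER_CLASS_FRACTIONS = ((0.1, 5), (0.2, 9), (0.4, 10))


@dataclass
class SubcloneProblem:
    """One patient's bulk intervals and DCC genotypes.

    bulk : mapping PT sample id -> array (L,) of interval tags I1/I2/I3.
    dccs : mapping DCC sample id -> array (L,) of genotypes in {1, 2, 3}.
    """

    bulk: dict
    dccs: dict

    def __post_init__(self):
        ls = set()
        for sid, tags in self.bulk.items():
            tags = np.asarray(tags)
            if not set(tags) <= set(INTERVALS):
                raise ValueError(f"{sid}: unknown interval tag")
            self.bulk[sid] = tags
            ls.add(tags.size)
        for sid, d in self.dccs.items():
            d = np.asarray(d, dtype=int)
            if not set(d.tolist()) <= {1, 2, 3}:
                raise ValueError(f"{sid}: DCC genotypes must be 1, 2 or 3")
            self.dccs[sid] = d
            ls.add(d.size)
        if len(ls) > 1:
            raise ValueError("all samples must share one locus set")


@dataclass
class ExclusionResult:
    fractions: dict           # dcc id -> f
    fold: float
    adjusted: dict            # dcc id -> p
    alpha: float
    pmf: np.ndarray
    n_star: int
    max_unexcludable: int
    assignment: dict = field(default_factory=dict)  # dcc id -> pt id


def _bounds_arrays(tags: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([INTERVALS[t][0] for t in tags])
    hi = np.array([INTERVALS[t][1] for t in tags])
    return lo, hi


def _solve_single_pt(d: np.ndarray, lo: np.ndarray,
                     hi: np.ndarray) -> np.ndarray:
    """Maximise sum(log f_k) for the DCCs of one PT sample.

    The unmeasured non-DCC clone frequency C_i in [1, 3] is eliminated
    analytically: feasibility of locus i reduces to the linear pair
    (1 - S) * 1 + sum f_k D_ki <= hi_i and (1 - S) * 3 + sum f_k D_ki >= lo_i
    with S = sum f.  The all-zero vector is always feasible; the maximiser
    of the concave product objective over the polytope is found by SLSQP
    with a grid fallback.
    """
    m = d.shape[0]
    if m == 0:
        return np.zeros(0)

    def upper_single(dk):
        # closed form for one DCC: intersect per-locus caps
        cap = 1.0
        for dki, l, h in zip(dk, lo, hi):
            if dki > 1:
                cap = min(cap, (h - 1.0) / (dki - 1.0))
            if dki < 3:
                cap = min(cap, (3.0 - l) / (3.0 - dki))
        return max(cap, 0.0)

    if m == 1:
        return np.array([upper_single(d[0])])

    caps = np.array([upper_single(d[k]) for k in range(m)])
    if np.any(caps <= 0):
        # at least one DCC is fully excluded; the max-product vector is 0
        return np.zeros(m)

    def feasible(f, slack=1e-9):
        s = f.sum()
        if s > 1 + slack or np.any(f < -slack):
            return False
        comp = f @ d
        return (np.all((1 - s) + comp <= hi + slack)
                and np.all(3 * (1 - s) + comp >= lo - slack))

    cons = []
    # (1-S) + f.D <= hi  ->  hi - 1 + S - f.D >= 0
    cons.append({"type": "ineq",
                 "fun": lambda f: hi - 1.0 + f.sum() - f @ d})
    # 3(1-S) + f.D >= lo  ->  3 - lo - 3S + f.D >= 0
    cons.append({"type": "ineq",
                 "fun": lambda f: 3.0 - lo - 3.0 * f.sum() + f @ d})
    cons.append({"type": "ineq", "fun": lambda f: 1.0 - f.sum()})

    best_f, best_val = np.zeros(m), -np.inf
    starts = [np.minimum(caps, 1.0 / m) * sc for sc in (0.9, 0.5, 0.1)]
    for x0 in starts:
        x0 = np.clip(x0, 1e-6, None)
        if not feasible(x0, slack=1e-6):
            x0 = np.full(m, 1e-4)
        res = optimize.minimize(
            lambda f: -np.sum(np.log(np.maximum(f, 1e-12))),
            x0, method="SLSQP", constraints=cons,
            bounds=[(1e-12, 1.0)] * m,
            options={"maxiter": 500, "ftol": 1e-12})
        f = np.clip(res.x, 0.0, 1.0)
        if feasible(f) and res.success:
            val = float(np.sum(np.log(np.maximum(f, 1e-300))))
            if val > best_val:
                best_val, best_f = val, f

    # grid fallback / refinement at 1e-3 resolution for small m
    if m <= 2:
        grid = np.arange(0.0, 1.0 + 1e-12, 1e-3)
        if m == 2:
            g1, g2 = np.meshgrid(grid, grid, indexing="ij")
            s = g1 + g2
            comp1 = g1[..., None] * d[0] + g2[..., None] * d[1]
            ok = (s <= 1.0)
            ok &= np.all((1 - s)[..., None] + comp1 <= hi + 1e-9, axis=-1)
            ok &= np.all(3 * (1 - s)[..., None] + comp1 >= lo - 1e-9, axis=-1)
            prod = np.where(ok, g1 * g2, -1.0)
            idx = np.unravel_index(np.argmax(prod), prod.shape)
            if prod[idx] > 0:
                cand = np.array([grid[idx[0]], grid[idx[1]]])
                if float(np.sum(np.log(cand))) > best_val:
                    best_f = cand
    return best_f


def max_product_fractions(problem: SubcloneProblem) -> tuple[dict, dict]:
    """Maximum-product DCC-like clone fractions for one patient.

    Every assignment of DCCs to PT samples is tried (T^D possibilities);
    within an assignment each PT sample's subproblem is solved separately
    and the assignment with the largest product of fractions is kept.
    Returns (fractions by DCC id, chosen assignment DCC id -> PT id).
    """
    pt_ids = sorted(problem.bulk)
    dcc_ids = sorted(problem.dccs)
    if not pt_ids or not dcc_ids:
        raise ValueError("need at least one PT and one DCC sample")
    bounds = {pid: _bounds_arrays(problem.bulk[pid]) for pid in pt_ids}

    best_prod, best_fr, best_asg = -np.inf, None, None
    for assignment in itertools.product(pt_ids, repeat=len(dcc_ids)):
        fr = {}
        for pid in pt_ids:
            members = [k for k, a in zip(dcc_ids, assignment) if a == pid]
            if not members:
                continue
            dmat = np.stack([problem.dccs[k] for k in members]).astype(float)
            lo, hi = bounds[pid]
            f = _solve_single_pt(dmat, lo, hi)
            for k, fk in zip(members, f):
                fr[k] = float(fk)
        prod = float(np.prod([fr[k] for k in dcc_ids]))
        if prod > best_prod + 1e-15:
            best_prod = prod
            best_fr = fr
            best_asg = dict(zip(dcc_ids, assignment))
    return best_fr, best_asg


def adjust_for_fold(fractions, d: float):
    """Node clone fractions under a d-fold dissemination advantage:
    p_i = d f_i / (1 + (d - 1) sum_k f_k), with the sum over the same
    patient's fractions."""
    f = np.asarray(fractions, dtype=float)
    if d <= 0:
        raise ValueError("fold change must be > 0")
    if f.sum() > 1 + 1e-9 or np.any(f < 0):
        raise ValueError("fractions must be >= 0 and sum to at most 1")
    return d * f / (1.0 + (d - 1.0) * f.sum())


def poisson_binomial_pmf(p) -> np.ndarray:
    """Exact Poisson-binomial pmf by sequential convolution."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    pmf = np.array([1.0])
    for pi in p:
        pmf = np.convolve(pmf, [1.0 - pi, pi])
    return pmf


def poisson_binomial_pmf_partition(values, counts) -> np.ndarray:
    """Poisson-binomial pmf via the class-partition sum.

    With K distinct success probabilities occurring N[k] times each,
    pr(n) = sum over partitions (n[1],...,n[K]) of n with n[k] <= N[k]
    of the product of per-class binomial pmf terms.  Serves as an
    independent cross-check of the convolution route.
    """
    values = np.asarray(values, dtype=float)
    counts = np.asarray(counts, dtype=int)
    if values.shape != counts.shape or np.any(counts < 0):
        raise ValueError("values and counts must match")
    ntot = int(counts.sum())
    out = np.zeros(ntot + 1)

    def partitions(n, caps):
        if len(caps) == 1:
            if n <= caps[0]:
                yield (n,)
            return
        for first in range(min(n, caps[0]) + 1):
            for rest in partitions(n - first, caps[1:]):
                yield (first,) + rest

    caps = counts.tolist()
    for n in range(ntot + 1):
        tot = 0.0
        for part in partitions(n, caps):
            term = 1.0
            for nk, pk, ck in zip(part, values, counts):
                term *= stats.binom.pmf(nk, ck, pk)
            tot += term
        out[n] = tot
    return out


def max_unexcludable(p, alpha: float = 0.05) -> int:
    """Largest number of DCC samples that cannot be excluded from hidden
    subclone origin at level alpha.

    n* is the smallest n with upper-tail P(X >= n) <= alpha under the
    Poisson-binomial law of the origin indicators; one less than n* is
    returned.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    pmf = poisson_binomial_pmf(p)
    upper = np.concatenate([np.cumsum(pmf[::-1])[::-1], [0.0]])
    # upper[n] = P(X >= n); find smallest n with upper[n] <= alpha
    n_star = int(np.argmax(upper <= alpha + 1e-15))
    return n_star - 1


def scan_fold_fraction(fractions_by_patient: dict, s_grid, d_grid,
                       alpha: float = 0.05, f_ref: float = 0.4):
    """Fraction x fold-change scan of the exclusion bound.

    ``fractions_by_patient`` maps patient id -> array of maximum DCC-like
    fractions.  For each scale s (fractions f * s) and fold d, the node
    fractions are computed per patient and pooled, and the maximum number
    of unexcludable samples recorded.  Returns (matrix indexed by
    [d, s], x-axis reference values f_ref * s).
    """
    s_grid = np.asarray(s_grid, dtype=float)
    d_grid = np.asarray(d_grid, dtype=float)
    if s_grid.size == 0 or d_grid.size == 0:
        raise ValueError("grids must be non-empty")
    mat = np.zeros((d_grid.size, s_grid.size), dtype=int)
    for di, d in enumerate(d_grid):
        for si, s in enumerate(s_grid):
            pooled = []
            for f in fractions_by_patient.values():
                pooled.extend(adjust_for_fold(np.asarray(f) * s, d))
            mat[di, si] = max_unexcludable(pooled, alpha)
    return mat, f_ref * s_grid


def class_fractions_to_vector(classes=PAPER_CLASS_FRACTIONS) -> np.ndarray:
    """Expand (fraction, multiplicity) classes into a flat vector."""
    out = []
    for value, count in classes:
        out.extend([value] * count)
    return np.asarray(out)
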
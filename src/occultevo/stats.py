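"""Shared statistical kernel: exact Fisher tests for 2x2/2x3 tables, a
simplex-interpolated Fisher test for non-integer (weighted) tables,
Benjamini-Hochberg FDR and locus-specific sample-weight maximisation.

The exact test for 2x3 tables and its continuous extension to weighted
tables are implemented here from first principles: scipy only covers the
integer 2x2 case, and the weighted analyses downstream produce fractional
cell counts for which no off-the-shelf exact test exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "fisher_exact",
    "fisher_noninteger",
    "bh_fdr",
    "optimise_weights",
    "WeightSet",
]

# Relative slack when comparing table probabilities against the observed
# table's probability; matches the tolerance scipy uses for 2x2 tables so
# near-ties are resolved identically by both routes.
_P_SLACK = 1e-7


def _validate_table(table: np.ndarray) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] not in (2, 3):
        raise ValueError(f"expected a 2x2 or 2x3 table, got shape {t.shape}")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("table entries must be finite and non-negative")
    return t


@lru_cache(maxsize=200_000)
def _fisher_exact_cached(cells: tuple[int, ...], ncol: int) -> float:
    t = np.array(cells, dtype=np.int64).reshape(2, ncol)
    t = t[:, t.sum(axis=0) > 0]  # all-zero state columns carry no signal
    ncol = t.shape[1]
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = int(t.sum())
    if n == 0 or ncol < 2 or np.any(row == 0):
        # degenerate margin: a single admissible table
        return 1.0

    const = gammaln(row + 1).sum() + gammaln(col + 1).sum() - gammaln(n + 1)

    def logp(first_row: np.ndarray) -> float:
        second = col - first_row
        return const - gammaln(first_row + 1).sum() - gammaln(second + 1).sum()

    logp_obs = logp(t[0])
    log_cut = logp_obs + np.log1p(_P_SLACK)

    total = 0.0
    r0 = int(row[0])
    if ncol == 2:
        lo = max(0, r0 - int(col[1]))
        hi = min(r0, int(col[0]))
        for a in range(lo, hi + 1):
            fr = np.array([a, r0 - a])
            if np.all(col - fr >= 0):
                lp = logp(fr)
                if lp <= log_cut:
                    total += np.exp(lp)
    else:
        for a in range(0, min(r0, int(col[0])) + 1):
            for b in range(0, min(r0 - a, int(col[1])) + 1):
                c = r0 - a - b
                if c > int(col[2]):
                    continue
                fr = np.array([a, b, c])
                lp = logp(fr)
                if lp <= log_cut:
                    total += np.exp(lp)
    return float(min(total, 1.0))


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p value for an integer 2x2 or 2x3 table.

    The p value sums the conditional (multivariate hypergeometric)
    probabilities of every table with the observed margins whose
    probability does not exceed the observed table's.  Tables with a zero
    row or column margin return 1 by convention.
    """
    t = _validate_table(table)
    ti = np.rint(t).astype(np.int64)
    if not np.allclose(t, ti, atol=1e-9):
        raise ValueError("fisher_exact requires integer entries; "
                         "use fisher_noninteger for weighted tables")
    return _fisher_exact_cached(tuple(int(x) for x in ti.ravel()), ti.shape[1])


def fisher_noninteger(table) -> float:
    """Fisher exact p value linearly interpolated for non-integer tables.

    Let r be the number of fractional entries.  A simplex is rooted at the
    entry-wise rounded table and directed towards the observed table; the
    p value is the affine interpolation of the exact Fisher p values at
    its r+1 integer vertices, with the fractional offsets as coordinates.
    Coincides exactly with :func:`fisher_exact` on integer tables.
    """
    t = _validate_table(table)
    base = np.floor(t + 0.5)  # deterministic round-half-up
    frac_idx = np.flatnonzero(~np.isclose(t.ravel(), np.rint(t).ravel(), atol=1e-12))
    flat_t = t.ravel()
    flat_base = base.ravel().copy()
    # rounding may not produce negatives (entries are >= 0), but guard anyway
    flat_base = np.maximum(flat_base, 0.0)

    ncol = t.shape[1]
    p0 = _fisher_exact_cached(tuple(int(x) for x in flat_base), ncol)
    if frac_idx.size == 0:
        return p0
    p = p0
    for j in frac_idx:
        step = np.sign(flat_t[j] - flat_base[j])
        if step == 0:
            continue
        theta = abs(flat_t[j] - flat_base[j])
        vert = flat_base.copy()
        vert[j] += step
        if vert[j] < 0:
            vert[j] = 0.0
        pj = _fisher_exact_cached(tuple(int(x) for x in vert), ncol)
        p += theta * (pj - p0)
    return float(min(max(p, 0.0), 1.0))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (order preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# locus-specific sample weights


@dataclass
class WeightSet:
    """Per-locus sample weights interpolating between patient weights
    (w = 1/n_i) and full sample weights (w = 1).

    gamma[l] is the interpolation coefficient for locus l: a sample of a
    patient with n_i samples receives weight (1-gamma)/n_i + gamma.  The
    effective sample count M[l] = sum of weights lies between the number
    of patients P and the number of samples N.
    """

    loci: tuple[str, ...]
    sample_ids: tuple[str, ...]
    gamma: dict = field(default_factory=dict)       # locus -> gamma in [0,1]
    weights: pd.DataFrame | None = None             # loci x samples
    effective_m: dict = field(default_factory=dict)  # locus -> M

    def weights_for(self, locus: str) -> pd.Series:
        return self.weights.loc[locus]


def _weighted_state_counts(values: np.ndarray, w: np.ndarray,
                           states: np.ndarray) -> np.ndarray:
    return np.array([w[values == s].sum() for s in states])


def optimise_weights(values: pd.DataFrame, patient_of: dict,
                     positions: pd.DataFrame | None = None,
                     p_limit: float = 0.95, k: int = 5,
                     tol: float = 1e-3) -> WeightSet:
    """Maximise locus-specific sample weights while keeping the weighted
    gain/balance/loss distribution statistically equivalent to the
    patient-weight (1/n_i) distribution.

    Parameters
    ----------
    values : DataFrame (samples x loci) of states in {-1, 0, +1} (or {0,1}).
    patient_of : mapping sample_id -> patient_id.
    positions : optional DataFrame indexed by patient_id with columns
        ('x', 'y'), the patient centroids in scaled log(DCCD)-log(thickness)
        space used to define the k-nearest-patient neighbourhoods.
    p_limit : the interpolated-Fisher p value below which the candidate
        weighting is no longer considered equivalent.
    k : number of nearest patient neighbours for the local tests.

    For each locus the one-parameter family w(gamma) = (1-gamma)/n_i + gamma
    is scanned by bisection for the largest gamma whose weighted state
    distribution stays equivalent (p >= p_limit) to gamma = 0, both
    globally and within every neighbourhood.
    """
    sample_ids = tuple(values.index)
    patients = pd.Series({s: patient_of[s] for s in sample_ids})
    n_per_patient = patients.value_counts()
    n_i = patients.map(n_per_patient).to_numpy(dtype=float)

    unique_patients = list(n_per_patient.index)
    n_patients = len(unique_patients)
    if n_patients < 2:
        raise ValueError("optimise_weights needs at least two patients")

    # neighbourhood sample masks (each neighbourhood: the patient and its
    # k nearest patient neighbours)
    neighbourhoods: list[np.ndarray] = []
    if positions is not None and n_patients > 1:
        k_eff = min(k, n_patients - 1)
        pos = positions.loc[unique_patients, ["x", "y"]].to_numpy(dtype=float)
        d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
        for i in range(n_patients):
            order = np.argsort(d2[i], kind="stable")
            members = {unique_patients[j] for j in order[: k_eff + 1]}
            neighbourhoods.append(patients.isin(members).to_numpy())

    result = WeightSet(loci=tuple(values.columns), sample_ids=sample_ids)
    wmat = pd.DataFrame(index=list(values.columns), columns=list(sample_ids),
                        dtype=float)

    def weights_at(gamma: float) -> np.ndarray:
        return (1.0 - gamma) / n_i + gamma

    w0 = weights_at(0.0)

    for locus in values.columns:
        v = values[locus].to_numpy()
        states = np.unique(v)

        def equivalent(gamma: float) -> bool:
            w = weights_at(gamma)
            masks = [np.ones(len(v), dtype=bool)] + neighbourhoods
            for m in masks:
                ref = _weighted_state_counts(v[m], w0[m], states)
                cand = _weighted_state_counts(v[m], w[m], states)
                cols = (ref > 0) | (cand > 0)
                tab = np.vstack([ref[cols], cand[cols]])
                if tab.shape[1] < 2:
                    continue  # single-state distribution: trivially equal
                if tab.shape[1] > 3:  # cannot occur with 3-state data
                    raise RuntimeError("unexpected table width")
                if fisher_noninteger(tab) < p_limit:
                    return False
            return True

        if np.all(n_i == 1) or equivalent(1.0):
            gamma_l = 1.0
        else:
            lo, hi = 0.0, 1.0  # gamma=0 is equivalent by construction
            while hi - lo > tol:
                mid = 0.5 * (lo + hi)
                if equivalent(mid):
                    lo = mid
                else:
                    hi = mid
            gamma_l = lo
        result.gamma[locus] = gamma_l
        w = weights_at(gamma_l)
        wmat.loc[locus] = w
        result.effective_m[locus] = float(w.sum())

    result.weights = wmat
    return result
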
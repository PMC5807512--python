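"""Copy-number-alteration profiles: data model, TSV I/O, descriptive
statistics, PT-vs-DCC locus comparisons, hierarchical clustering, and the
allelic drop-out / clonality statistics for single-cell mutation assays.

Profiles are ordered vectors over a fixed locus set with states -1 (loss),
0 (balanced) and +1 (gain); the mutation pseudo-loci ``BRAFmut`` and
``NRASmut`` use states {0, 1} (wild-type / mutant).  Loci are opaque
ordered labels - no genome-coordinate arithmetic happens here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .stats import bh_fdr, fisher_exact, fisher_noninteger

__all__ = [
    "LocusSet", "CNAProfile", "MUTATION_LOCI",
    "read_profiles", "write_profiles", "profiles_frame",
    "aberration_counts", "variable_loci", "cluster_profiles",
    "locus_fisher_scan", "ado_rate", "clonality_test",
    "patient_mutation_call", "histology_breakdown",
]

#: pseudo-loci carrying point-mutation status rather than copy number
MUTATION_LOCI = ("BRAFmut", "NRASmut")

_META_COLS = ("sample_id", "patient_id", "sample_type")
# TSV column aliases for the mutation pseudo-loci
_MUT_TSV = {"braf": "BRAFmut", "nras": "NRASmut"}
_MUT_TSV_INV = {v: k for k, v in _MUT_TSV.items()}


@dataclass(frozen=True)
class LocusSet:
    """Ordered, unique locus names; the order fixes column order everywhere."""

    names: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("locus names must be unique")

    def __len__(self):
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def is_mutation(self, name: str) -> bool:
        return name in MUTATION_LOCI

    def subset(self, keep) -> "LocusSet":
        keep = set(keep)
        return LocusSet(tuple(n for n in self.names if n in keep))


@dataclass
class CNAProfile:
    sample_id: str
    patient_id: str
    sample_type: str  # "PT" or "DCC"
    values: np.ndarray  # int8 over the LocusSet

    def __post_init__(self):
        if self.sample_type not in ("PT", "DCC"):
            raise ValueError(f"sample_type must be PT or DCC, got {self.sample_type!r}")
        self.values = np.asarray(self.values, dtype=np.int8)

    def validate(self, loci: LocusSet) -> None:
        if self.values.shape != (len(loci),):
            raise ValueError(f"{self.sample_id}: expected {len(loci)} values")
        for j, name in enumerate(loci):
            allowed = (0, 1) if loci.is_mutation(name) else (-1, 0, 1)
            if self.values[j] not in allowed:
                raise ValueError(
                    f"sample {self.sample_id}, locus {name}: "
                    f"value {self.values[j]} outside {allowed}")


def _locus_to_col(name: str) -> str:
    return _MUT_TSV_INV.get(name, name)


def write_profiles(path, loci: LocusSet, profiles: list[CNAProfile]) -> None:
    cols = list(_META_COLS) + [_locus_to_col(n) for n in loci]
    rows = []
    for p in profiles:
        p.validate(loci)
        rows.append([p.sample_id, p.patient_id, p.sample_type,
                     *p.values.tolist()])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_profiles(path) -> tuple[LocusSet, list[CNAProfile]]:
    """Read a profile TSV; exact inverse of :func:`write_profiles`.

    Raises a parse error naming the offending sample and locus for any
    value outside the locus' state space, and on duplicate sample ids.
    """
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in _META_COLS})
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    locus_cols = [c for c in df.columns if c not in _META_COLS]
    loci = LocusSet(tuple(_MUT_TSV.get(c, c) for c in locus_cols))
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id(s): {dups}")
    profiles = []
    for _, row in df.iterrows():
        vals = []
        for c, name in zip(locus_cols, loci):
            v = row[c]
            try:
                iv = int(v)
            except (TypeError, ValueError):
                raise ValueError(
                    f"sample {row['sample_id']}, locus {name}: "
                    f"non-integer value {v!r}") from None
            vals.append(iv)
        p = CNAProfile(row["sample_id"], row["patient_id"],
                       row["sample_type"], np.array(vals))
        p.validate(loci)
        profiles.append(p)
    return loci, profiles


def profiles_frame(loci: LocusSet, profiles: list[CNAProfile]) -> pd.DataFrame:
    """Samples x loci DataFrame of states, indexed by sample_id."""
    return pd.DataFrame(
        [p.values for p in profiles],
        index=pd.Index([p.sample_id for p in profiles], name="sample_id"),
        columns=list(loci))


def aberration_counts(profile: CNAProfile) -> tuple[int, int]:
    """(number of gains, number of losses) in a profile."""
    v = profile.values
    return int((v == 1).sum()), int((v == -1).sum())


def variable_loci(loci: LocusSet, profiles: list[CNAProfile],
                  sd_min: float = 0.25) -> LocusSet:
    """Loci with cross-sample standard deviation above ``sd_min``.

    Low-variance loci cannot discriminate classes and are dropped before
    locus-wise testing (default threshold 0.25).
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    mat = np.stack([p.values for p in profiles]).astype(float)
    sd = mat.std(axis=0, ddof=1)
    return LocusSet(tuple(n for n, s in zip(loci, sd) if s > sd_min))


def cluster_profiles(profiles: list[CNAProfile]):
    """Complete-linkage agglomerative clustering on Euclidean distances.

    Profiles are ordered lexicographically by sample_id before linkage so
    the merge order is deterministic under input permutation (ties broken
    by that ordering).  Returns (ordered sample ids, scipy linkage matrix).
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    ordered = sorted(profiles, key=lambda p: p.sample_id)
    ids = [p.sample_id for p in ordered]
    mat = np.stack([p.values for p in ordered]).astype(float)
    z = linkage(pdist(mat, metric="euclidean"), method="complete")
    return ids, z


def _group_table(va: np.ndarray, vb: np.ndarray, wa, wb,
                 states: np.ndarray) -> np.ndarray:
    if wa is None:
        ra = np.array([(va == s).sum() for s in states], dtype=float)
        rb = np.array([(vb == s).sum() for s in states], dtype=float)
    else:
        ra = np.array([wa[va == s].sum() for s in states])
        rb = np.array([wb[vb == s].sum() for s in states])
    tab = np.vstack([ra, rb])
    return tab[:, tab.sum(axis=0) > 0]  # drop all-zero state columns


def locus_fisher_scan(loci: LocusSet, group_a: list[CNAProfile],
                      group_b: list[CNAProfile],
                      weights: dict | None = None) -> pd.DataFrame:
    """Per-locus Fisher exact comparison of two profile groups with BH FDR.

    Each locus is tested on the 2 x {states present} table of group against
    state counts; with ``weights`` (sample_id -> weight) the counts are
    weight sums and the interpolated Fisher test is used.  Returns a
    DataFrame (locus, p, fdr) in locus order.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    fa = profiles_frame(loci, group_a)
    fb = profiles_frame(loci, group_b)
    pvals = []
    for name in loci:
        va, vb = fa[name].to_numpy(), fb[name].to_numpy()
        wa = wb = None
        if weights is not None:
            wa = np.array([weights[s] for s in fa.index])
            wb = np.array([weights[s] for s in fb.index])
        states = np.unique(np.concatenate([va, vb]))
        tab = _group_table(va, vb, wa, wb, states)
        if tab.shape[1] < 2:
            pvals.append(1.0)
        elif weights is None:
            pvals.append(fisher_exact(tab))
        else:
            pvals.append(fisher_noninteger(tab))
    return pd.DataFrame({"locus": list(loci), "p": pvals,
                         "fdr": bh_fdr(pvals)})


def ado_rate(detected: int, total: int) -> tuple[float, int]:
    """Allelic drop-out rate in percent: 100 * (1 - detected/total).

    Returns the exact percentage and its rounded integer value, e.g.
    79/86 detected wild-type alleles give (8.14, 8).
    """
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= detected <= total:
        raise ValueError("need 0 <= detected <= total")
    pct = 100.0 * (1.0 - detected / total)
    return pct, int(round(pct))


def clonality_test(dcc_detect: tuple[int, int],
                   control_detect: tuple[int, int]) -> float:
    """Two-sided Fisher p comparing mutant-allele detection in sibling DCCs
    against control single cells (2x2 detection table)."""
    (h1, t1), (h2, t2) = dcc_detect, control_detect
    if t1 <= 0 or t2 <= 0:
        raise ValueError("totals must be > 0")
    return fisher_exact([[h1, t1 - h1], [h2, t2 - h2]])


def patient_mutation_call(calls) -> int:
    """Patient-level mutation status: positive if any area / DCC is mutant."""
    arr = np.asarray(list(calls), dtype=int)
    return int((arr == 1).any())


def histology_breakdown(n_negative: int, n_itc: int,
                        n_micromet: int) -> dict[str, float]:
    """Percentages of histopathology classes among DCC-positive nodes
    (negative / isolated tumour cells / micrometastasis)."""
    total = n_negative + n_itc + n_micromet
    if total <= 0:
        raise ValueError("empty breakdown")
    return {
        "negative": 100.0 * n_negative / total,
        "itc": 100.0 * n_itc / total,
        "micrometastasis": 100.0 * n_micromet / total,
    }
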
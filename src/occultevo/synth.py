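"""Synthetic patient cohorts with the statistical structure the downstream
analyses assume.

Per patient the generator draws a tumour thickness, a dissemination event
(cure-fraction standard log-logistic in thickness: event probability
pi * t/(t + theta_d)), a dissemination thickness t_L for disseminated
patients (the base law truncated to [0, t]), and a disseminated-cell
density from exponential colony growth over the divisions elapsed between
t_L and t.  Copy-number profiles for primary-tumour clones and DCCs are
then drawn per locus with aberration probability 1 - exp(-kappa * E),
where E = a*n_T + b*n_L is the risk function of the division model, and
observed either through a 60%-detection bulk CGH (interval categories) or
as single-cell allele reads subject to allelic drop-out.

Randomness is split hierarchically (one child stream per patient index),
so outputs are bit-reproducible and per-patient draws are stable when the
cohort size changes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
import yaml
from scipy import optimize
from scipy import stats as st

from .cna import MUTATION_LOCI, CNAProfile, LocusSet, write_profiles
from .riskplane import GrowthRiskSpec, divisions_from_thickness

__all__ = [
    "LocusSpec", "CohortParams", "SyntheticPatient",
    "default_locus_panel", "generate_cohort", "generate_cna_profiles",
    "observe_bulk_cgh", "observe_single_cells", "dccd_scale",
    "sample_thickness", "simulate_current_status",
    "write_cohort", "cohort_frame", "params_from_yaml",
    "CATEGORY_COEFFS", "T_STAGE_EDGES_MM", "T_STAGE_COUNTS",
]

#: (a, b) risk coefficients of the four prototype categories
CATEGORY_COEFFS = {1: (1.0, 0.0), 2: (1.0, 1.0), 3: (1.0, 2.0), 4: (0.0, 1.0)}

#: T-stage thickness bins (mm) and the cohort's stage composition
#: (T1 <=1, T2 1.01-2, T3 2.01-4, T4 >4; n = 1027)
T_STAGE_EDGES_MM = (1.0, 2.0, 4.0)
T_STAGE_COUNTS = (83, 496, 315, 133)


@lru_cache(maxsize=1)
def _t_stage_lognormal() -> tuple[float, float]:
    """(mu, sigma) of the log-normal ML-fitted to the T-stage bin counts."""
    counts = np.asarray(T_STAGE_COUNTS, dtype=float)
    edges = np.asarray(T_STAGE_EDGES_MM)

    def nll(x):
        c = st.norm.cdf((np.log(edges) - x[0]) / math.exp(x[1]))
        p = np.diff(np.concatenate([[0.0], c, [1.0]]))
        return -(counts * np.log(np.clip(p, 1e-12, 1))).sum()

    res = optimize.minimize(nll, [math.log(1.8), math.log(0.6)],
                            method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-10})
    return float(res.x[0]), float(math.exp(res.x[1]))


def sample_thickness(rng: np.random.Generator, n: int,
                     law: str = "t_stage",
                     median_mm: float = 1.8,
                     sigma_log: float = 0.6) -> np.ndarray:
    """Draw tumour thicknesses (mm).

    ``t_stage`` (default) draws the stage from the cohort's printed stage
    composition and the thickness within the stage bin from a truncated
    log-normal whose parameters are ML-fitted to those same bin counts -
    the closest available emulation of the unpublished thickness data.
    ``log_normal`` draws from a plain log-normal with the given median and
    log-scale.
    """
    if law == "log_normal":
        return np.exp(rng.normal(math.log(median_mm), sigma_log, size=n))
    if law != "t_stage":
        raise ValueError(f"unknown thickness law {law!r}")
    mu, sig = _t_stage_lognormal()
    freq = np.asarray(T_STAGE_COUNTS, dtype=float)
    freq /= freq.sum()
    edges = [0.0, *T_STAGE_EDGES_MM, np.inf]
    bins = rng.choice(len(freq), size=n, p=freq)
    lo = np.array([edges[b] for b in bins])
    hi = np.array([edges[b + 1] for b in bins])
    a = st.norm.cdf((np.log(np.maximum(lo, 1e-9)) - mu) / sig)
    b = np.where(np.isinf(hi), 1.0, st.norm.cdf((np.log(hi) - mu) / sig))
    u = a + rng.random(n) * (b - a)
    return np.exp(mu + sig * st.norm.ppf(np.clip(u, 1e-12, 1 - 1e-12)))


@dataclass(frozen=True)
class LocusSpec:
    """One simulated locus: name, risk category and coefficients.

    ``sign`` fixes whether the locus aberrates as a gain (+1) or loss (-1);
    mutation pseudo-loci use state 1.  ``kappa`` scales the per-division
    risk: aberration probability is 1 - exp(-kappa * E).
    """

    name: str
    category: int
    kappa: float
    sign: int = 1
    a: float | None = None
    b: float | None = None

    def __post_init__(self):
        if self.category not in CATEGORY_COEFFS:
            raise ValueError(f"unknown risk category {self.category}")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be -1 or +1")

    @property
    def coeffs(self) -> tuple[float, float]:
        a, b = CATEGORY_COEFFS[self.category]
        return (self.a if self.a is not None else a,
                self.b if self.b is not None else b)

    @property
    def is_mutation(self) -> bool:
        return self.name in MUTATION_LOCI


def default_locus_panel() -> list[LocusSpec]:
    """A compact panel spanning the four risk categories.

    Losses are rarer than gains (smaller kappa), mirroring the cohort's
    gain excess; the colonisation-signature loci 9p21-24 (loss), 7q21-36
    (gain) and BRAFmut sit in the node-division-driven categories.
    """
    return [
        LocusSpec("10q21-26", 1, 0.030, -1),
        LocusSpec("6q14-27", 1, 0.040, 1),
        LocusSpec("1p11-13", 2, 0.020, 1),
        LocusSpec("20q11-13", 2, 0.025, 1),
        LocusSpec("8q23-24.3", 3, 0.020, 1),
        LocusSpec("BRAFmut", 3, 0.025, 1),
        LocusSpec("9p21-24", 4, 0.060, -1),
        LocusSpec("7q21-36", 4, 0.070, 1),
        LocusSpec("18q21-23", 4, 0.030, -1),
    ]


@dataclass(frozen=True)
class CohortParams:
    """Generating parameters of a synthetic cohort.

    thickness_median_mm / thickness_sigma_log : log-normal thickness law
        (location given as the median in mm, scale in log-mm).
    pi, theta_d_mm : cure asymptote and median of the standard log-logistic
        dissemination law (event probability pi * t/(t + theta_d)).
    td50_colonisation_mm : thickness at which half of the DCC-positive
        patients have colonised (DCCD > 100); calibrates the DCCD scale.
    ghat : growth-rate ratio g_T/g_L of the division model.
    max_node_cells : saturation of the node colony (10^6 cells).
    ado_wt, ado_mut : allelic drop-out probabilities.
    """

    n_patients: int = 1027
    thickness_law: str = "t_stage"
    thickness_median_mm: float = 1.8
    thickness_sigma_log: float = 0.6
    pi: float = 0.652
    theta_d_mm: float = 0.5
    td50_colonisation_mm: float = 10.3
    ghat: float = 1.0
    max_node_cells: float = 1e6
    dccd_noise_log2: float = 3.0
    loci: tuple[LocusSpec, ...] = field(
        default_factory=lambda: tuple(default_locus_panel()))
    n_dcc_per_patient: int = 1
    n_pt_clones: int = 2
    ado_wt: float = 0.08
    ado_mut: float = 0.0
    seed: int = 0
    growth: GrowthRiskSpec = field(default_factory=GrowthRiskSpec)

    def __post_init__(self):
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must lie in [0, 1]")
        for name in ("thickness_median_mm", "thickness_sigma_log",
                     "theta_d_mm", "td50_colonisation_mm", "ghat"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0")
        for name in ("ado_wt", "ado_mut"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        names = [sp.name for sp in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("locus names must be unique")

    @property
    def locus_set(self) -> LocusSet:
        return LocusSet(tuple(sp.name for sp in self.loci))


@dataclass
class SyntheticPatient:
    patient_id: str
    thickness_mm: float
    disseminated: bool
    t_l_mm: float | None  # thickness at dissemination; None if never
    dccd: int  # gp100+ cells per 10^6 node cells; 0 iff not disseminated
    pt_clones: list[tuple[CNAProfile, float]] = field(default_factory=list)
    dcc_profiles: list[CNAProfile] = field(default_factory=list)

    def __post_init__(self):
        if (self.dccd == 0) != (not self.disseminated):
            raise ValueError("dccd must be 0 exactly when not disseminated")
        if self.t_l_mm is not None and self.t_l_mm > self.thickness_mm + 1e-12:
            raise ValueError("t_L must not exceed the observed thickness")


def _f0(t, theta):
    return t / (t + theta)


def dccd_scale(params: CohortParams) -> float:
    """Calibration of DCCD = 2^(ghat * dN * s) against the colonisation law.

    ``s`` is solved in closed form so that at thickness TD50 the *median*
    node colony holds exactly 100 cells, i.e. colonisation (DCCD > 100)
    reaches 50% at TD50, reproducing the exponential colonisation curve
    without modelling node cellularity.
    """
    td50 = params.td50_colonisation_mm
    v = 0.5 * _f0(td50, params.theta_d_mm)  # median truncated quantile
    t_l_med = params.theta_d_mm * v / (1.0 - v)
    with warnings.catch_warnings():
        # a sub-single-cell median dissemination thickness is fine here
        warnings.simplefilter("ignore", UserWarning)
        dn = (divisions_from_thickness(td50, params.growth)
              - divisions_from_thickness(max(t_l_med, 1e-9), params.growth))
    if dn <= 0:
        raise ValueError("degenerate calibration: no node divisions at TD50")
    return math.log2(100.0) / (params.ghat * dn)


def _patient_rng(params: CohortParams, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=params.seed, spawn_key=(index,)))


def generate_cohort(params: CohortParams) -> list[SyntheticPatient]:
    """Draw thickness, dissemination status, t_L and DCCD for each patient."""
    s = dccd_scale(params)
    out = []
    for i in range(params.n_patients):
        rng = _patient_rng(params, i)
        t = float(sample_thickness(rng, 1, params.thickness_law,
                                   params.thickness_median_mm,
                                   params.thickness_sigma_log)[0])
        disseminated = bool(rng.random() < params.pi * _f0(t, params.theta_d_mm))
        t_l = None
        dccd = 0
        if disseminated:
            v = rng.random() * _f0(t, params.theta_d_mm)
            t_l = params.theta_d_mm * v / (1.0 - v)
            with warnings.catch_warnings():
                # very early dissemination can fall below the single-cell
                # thickness; zero divisions is the intended reading there
                warnings.simplefilter("ignore", UserWarning)
                dn = (divisions_from_thickness(t, params.growth)
                      - divisions_from_thickness(max(t_l, 1e-9), params.growth))
            dn = max(dn, 0.0)
            # realised colony size disperses around the kinetic expectation:
            # the division <-> DCCD mapping is qualitative (growth-rate
            # variability, disaggregation and counting noise), modelled as
            # ~one order of magnitude of log-normal spread; the zero-median
            # noise preserves the TD50 calibration of dccd_scale
            log2_d = params.ghat * dn * s + rng.normal(0.0, params.dccd_noise_log2)
            log2_d = min(max(log2_d, 0.0), math.log2(params.max_node_cells))
            dccd = max(1, int(round(2.0 ** log2_d)))
        out.append(SyntheticPatient(
            patient_id=f"P{i:05d}", thickness_mm=t,
            disseminated=disseminated, t_l_mm=t_l, dccd=dccd))
    return out


def simulate_current_status(n: int, family: str, params: dict,
                            pi: float = 1.0, seed: int = 0,
                            thickness_law: str = "t_stage") -> tuple[np.ndarray, np.ndarray]:
    """Current-status observations drawn directly from a parametric law.

    Thicknesses follow the cohort thickness law; each event indicator is
    Bernoulli(pi * F0(t)) for the given family and parameters.  Used for
    parameter-recovery studies where the event mechanism itself, not the
    growth model, is under test.  Returns (thickness, event).
    """
    from .dissemination import FAMILIES

    fam = FAMILIES[family]
    p = np.array([params[k] for k in fam.param_names])
    rng = np.random.default_rng(seed)
    t = sample_thickness(rng, n, thickness_law)
    event = rng.random(n) < pi * fam.cdf(t, p)
    return t, event


def _division_counts(patient: SyntheticPatient,
                     params: CohortParams) -> tuple[float, float]:
    """(n_T, n_L) for a disseminated cell: node divisions are the colony
    doublings n_L = log2(DCCD) and the pre-dissemination divisions follow
    the growth identity n_T = N_T - ghat * n_L (non-negative)."""
    n_l = math.log2(max(patient.dccd, 1))
    big_n_t = divisions_from_thickness(patient.thickness_mm, params.growth)
    n_t = max(big_n_t - params.ghat * n_l, 0.0)
    return n_t, n_l


def generate_cna_profiles(patient: SyntheticPatient, params: CohortParams,
                          index: int | None = None) -> SyntheticPatient:
    """Fill in PT-clone and DCC copy-number profiles for one patient.

    Each DCC acquires an aberration at a locus with probability
    1 - exp(-kappa * (a*n_T + b*n_L)); PT clones use the same risk with
    n_L = 0 and n_T evaluated at the observed thickness (primary cells
    keep dividing until surgery).  Clone fractions are Dirichlet-drawn.
    """
    if index is None:
        index = int(patient.patient_id.lstrip("P"))
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=params.seed, spawn_key=(index, 1)))
    loci = params.locus_set
    n_t_dcc, n_l = _division_counts(patient, params)
    n_t_pt = divisions_from_thickness(patient.thickness_mm, params.growth)

    fractions = rng.dirichlet(np.ones(params.n_pt_clones))
    pt_clones = []
    for c in range(params.n_pt_clones):
        vals = np.zeros(len(loci), dtype=np.int8)
        for j, sp in enumerate(params.loci):
            a, b = sp.coeffs
            e = a * n_t_pt  # n_L = 0 inside the primary
            if rng.random() < -np.expm1(-sp.kappa * e):
                vals[j] = 1 if sp.is_mutation else sp.sign
        pt_clones.append((CNAProfile(f"{patient.patient_id}-PT{c}",
                                     patient.patient_id, "PT", vals),
                          float(fractions[c])))

    dccs = []
    if patient.disseminated:
        for d in range(params.n_dcc_per_patient):
            vals = np.zeros(len(loci), dtype=np.int8)
            for j, sp in enumerate(params.loci):
                a, b = sp.coeffs
                e = a * n_t_dcc + b * n_l
                if rng.random() < -np.expm1(-sp.kappa * e):
                    vals[j] = 1 if sp.is_mutation else sp.sign
            dccs.append(CNAProfile(f"{patient.patient_id}-DCC{d}",
                                   patient.patient_id, "DCC", vals))
    patient.pt_clones = pt_clones
    patient.dcc_profiles = dccs
    return patient


def prototype_plane_cohort(category: int, n_dcc: int = 87, seed: int = 0,
                           kappa: float | None = None,
                           t_range_mm: tuple[float, float] = (0.6, 10.0),
                           growth: GrowthRiskSpec = GrowthRiskSpec()):
    """Category preset in the prototype division-space geometry.

    Generates ``n_dcc`` DCC samples with thickness log-uniform over the
    experimental range and node divisions n_L uniform over half the span
    of the total division count N_T - the regime in which the theoretical
    equal-risk-line angles (135/90/45/0 degrees for categories 1-4) are
    exactly recovered after the half-axis DCCD correction.  The locus
    aberration indicator is drawn with probability 1 - exp(-kappa * E),
    E = a*n_T + b*n_L with n_T = N_T - ghat*n_L.

    Returns (dccd, thickness_mm, states) with a single-locus state frame.
    """
    rng = np.random.default_rng(seed)
    lo, hi = t_range_mm
    t = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n_dcc))
    big_n = np.asarray(divisions_from_thickness(t, growth))
    span = (divisions_from_thickness(hi, growth)
            - divisions_from_thickness(lo, growth))
    n_l = rng.uniform(0.0, span / 2.0, size=n_dcc)
    dccd = np.maximum(np.round(2.0 ** n_l), 1).astype(int)
    n_l = np.log2(dccd)  # realised (integer-DCCD) divisions
    n_t = np.maximum(big_n - growth.ghat * n_l, 0.0)
    a, b = CATEGORY_COEFFS[category]
    if kappa is None:
        kappa = {1: 0.04, 2: 0.05, 3: 0.03, 4: 0.3}[category]
    e = a * n_t + b * n_l
    states = (rng.random(n_dcc) < -np.expm1(-kappa * e)).astype(int)
    frame = pd.DataFrame({f"cat{category}": states})
    return dccd.astype(float), t, frame


def observe_bulk_cgh(clones: list[tuple[CNAProfile, float]]) -> list[str]:
    """Bulk metaphase-CGH call per locus for a clone mixture.

    The composite mean allele frequency m_i = sum fraction * (2 + value)
    is categorised as I1 (m <= 1.4), I3 (m >= 2.6) or I2 otherwise: an
    aberration must be carried by at least 60% of cells to be detected.
    """
    if not clones:
        raise ValueError("empty clone list")
    fr = np.array([f for _, f in clones], dtype=float)
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("clone fractions must sum to 1")
    vals = np.stack([p.values for p, _ in clones]).astype(float)
    m = (fr[:, None] * (2.0 + vals)).sum(axis=0)
    return ["I1" if x <= 1.4 else "I3" if x >= 2.6 else "I2" for x in m]


def observe_single_cells(genotype: tuple[int, int], ado: tuple[float, float],
                         n_cells: int, seed: int = 0) -> pd.DataFrame:
    """Single-cell allele observations under allelic drop-out.

    ``genotype`` flags whether the wild-type / mutant alleles are present;
    each cell reports a present allele with probability 1 - its drop rate.
    """
    wt_present, mut_present = genotype
    p_wt, p_mut = ado
    if not (0 <= p_wt <= 1 and 0 <= p_mut <= 1):
        raise ValueError("drop probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    wt = wt_present * (rng.random(n_cells) >= p_wt)
    mut = mut_present * (rng.random(n_cells) >= p_mut)
    return pd.DataFrame({"wt_detected": wt.astype(int),
                         "mut_detected": mut.astype(int)})


# ---------------------------------------------------------------------------
# I/O


def cohort_frame(patients: list[SyntheticPatient]) -> pd.DataFrame:
    return pd.DataFrame({
        "patient_id": [p.patient_id for p in patients],
        "thickness_mm": [p.thickness_mm for p in patients],
        "disseminated": [int(p.disseminated) for p in patients],
        "t_l_mm": [p.t_l_mm if p.t_l_mm is not None else "" for p in patients],
        "dccd": [p.dccd for p in patients],
    })


def write_cohort(path, patients: list[SyntheticPatient]) -> None:
    cohort_frame(patients).to_csv(path, sep="\t", index=False)


def write_cohort_profiles(path, params: CohortParams,
                          patients: list[SyntheticPatient]) -> None:
    profiles = []
    for p in patients:
        profiles.extend([c for c, _ in p.pt_clones])
        profiles.extend(p.dcc_profiles)
    write_profiles(path, params.locus_set, profiles)


def params_from_yaml(path) -> CohortParams:
    """Load CohortParams from a YAML mapping (locus entries as mappings)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "loci" in raw:
        raw["loci"] = tuple(LocusSpec(**d) for d in raw["loci"])
    if "growth" in raw:
        raw["growth"] = GrowthRiskSpec(**raw["growth"])
    return CohortParams(**raw)


def with_seed(params: CohortParams, seed: int) -> CohortParams:
    return replace(params, seed=seed)
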
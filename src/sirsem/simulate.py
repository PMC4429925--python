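"""Synthetic test-day data with the exact structure the analysis assumes.

The generator emulates a milk-recording scheme: repeated test-day records on
first-lactation cows, each cow nested in one herd and sired by one AI bull,
bulls related through a sire-MGS pedigree.  Phenotypes follow the recursive
structural equation model in reduced form,

    y = (I - Lambda)^-1 (X b + h + p + s + e),

with sire effects drawn jointly from N(0, G (x) A), herd, permanent
environment and residual effects i.i.d. across levels from H, P and R.

Because full covariance matrices for the emulated study were never published,
:func:`default_truth` completes the published marginal summaries
(heritabilities, correlations, curd-firmness variance components) into
consistent positive-definite matrices; the completion rules are a documented
modeling choice of this package, not published data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import calibration as cal
from .exceptions import InputError
from .pedigree import SireMgsPedigree, build_A_sire_mgs, make_pedigree, write_pedigree
from .structure import (
    CausalStructure,
    TraitSet,
    identity_minus_lambda_inverse,
    preset_structure,
)

#: Variance shares of the non-genetic remainder assigned to cow permanent
#: environment and herd on the multi-trait scale (documented defaults of the
#: completion; residual takes the rest).
PE_SHARE = 0.30
HERD_SHARE = 0.10

#: Days-in-milk class contrasts (classes 1-3 vs. reference class 4) on the
#: structural scale, one row per contrast, one column per trait.  Modest
#: early-lactation trends: higher cell score and slower, weaker coagulation
#: right after calving, a small casein dip.
DIM_CONTRASTS = np.array(
    [
        [0.30, -0.06, 0.60, -1.50],
        [0.15, -0.04, 0.35, -0.90],
        [0.05, -0.02, 0.15, -0.40],
    ]
)


@dataclass(frozen=True)
class TrueParameters:
    """Ground-truth dispersion and location parameters for simulation.

    ``G``, ``P``, ``H`` are sire, permanent-environment and herd covariance
    matrices on the structural scale (trait^2 units); ``R`` is the residual
    covariance (diagonal whenever the structure has edges); ``Lambda`` the
    structural coefficient matrix; ``b`` the fixed effects (intercept plus
    days-in-milk contrasts, one column per trait).
    """

    structure: CausalStructure
    G: np.ndarray
    P: np.ndarray
    H: np.ndarray
    R: np.ndarray
    Lambda: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        T = self.structure.traits.n
        for name in ("G", "P", "H", "R"):
            m = getattr(self, name)
            if m.shape != (T, T):
                raise InputError(f"{name} must be {T}x{T}")
            if not np.allclose(m, m.T):
                raise InputError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(m).min() <= 0:
                raise InputError(f"{name} must be positive definite")
        if self.structure.has_edges:
            off = self.R - np.diag(np.diag(self.R))
            if np.abs(off).max() > 0:
                raise InputError("R must be diagonal when the structure has edges")

    @property
    def traits(self) -> TraitSet:
        return self.structure.traits

    def mtm_scale(self) -> dict[str, np.ndarray]:
        """Map the truth to the multi-trait scale: M* = (I-L)^-1 M (I-L)'^-1."""
        Binv = identity_minus_lambda_inverse(self.Lambda)
        return {
            name: Binv @ getattr(self, name) @ Binv.T for name in ("G", "P", "H", "R")
        }


@dataclass(frozen=True)
class StudyDesign:
    """Who was measured where: cows, herds, sires, records and the pedigree."""

    n_cows: int
    n_herds: int
    n_sires: int
    cow_herd: np.ndarray  # herd index per cow
    cow_sire: np.ndarray  # pedigree row per cow's sire
    record_cow: np.ndarray  # cow index per record
    dim_class: np.ndarray  # 1..4 per record
    pedigree: SireMgsPedigree
    sire_rows: np.ndarray  # pedigree rows of the observed sires
    scale: float = 1.0
    seed: int | None = None

    @property
    def n_records(self) -> int:
        return len(self.record_cow)

    def herd_ids(self) -> list[str]:
        return [f"H{j + 1:04d}" for j in range(self.n_herds)]

    def cow_ids(self) -> list[str]:
        return [f"C{j + 1:05d}" for j in range(self.n_cows)]


@dataclass(frozen=True)
class SimulationResult:
    """Simulated records plus the full audit trail of realized effects."""

    records: pd.DataFrame
    design: StudyDesign
    truth: TrueParameters
    effects: dict[str, np.ndarray] = field(repr=False)


def nearest_psd(m: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD matrix (eigenvalue clip).

    Eigenvalues are floored at ``floor * mean(diag)`` so the result stays
    usable as a covariance matrix (strictly PD).
    """
    m = 0.5 * (m + m.T)
    w, v = np.linalg.eigh(m)
    lo = floor * max(np.trace(m) / m.shape[0], 1.0)
    if w.min() >= lo:
        return m
    w = np.clip(w, lo, None)
    return (v * w) @ v.T


def _pair_matrix(diag: np.ndarray, corr: dict, traits: tuple[str, ...]) -> np.ndarray:
    """Covariance matrix from variances and a pairwise correlation table."""
    T = len(traits)
    out = np.diag(diag.astype(float))
    for i in range(T):
        for j in range(i + 1, T):
            r = corr.get((traits[i], traits[j]), corr.get((traits[j], traits[i]), 0.0))
            out[i, j] = out[j, i] = r * np.sqrt(diag[i] * diag[j])
    return out


def _solve_structural_residuals(
    lam: np.ndarray, mtm_diag: np.ndarray
) -> np.ndarray:
    """Diagonal structural residual variances whose multi-trait-scale
    diagonal equals ``mtm_diag``: solve sum_j ((I-L)^-1)_ij^2 r_j = d_i."""
    Binv = identity_minus_lambda_inverse(lam)
    M = Binv**2
    r = np.linalg.solve(M, mtm_diag)
    if r.min() <= 0:
        raise InputError(
            "structural residual variances are not positive under this "
            f"calibration (got {r}); causal coefficients too large for the "
            "requested phenotypic variances"
        )
    return r


def default_truth(model: str = "M3") -> TrueParameters:
    """Ground truth calibrated to the published estimates of the emulated study.

    The multi-trait-scale targets are: observed phenotypic variances (the
    model-based value for curd firmness), baseline heritabilities, baseline
    genetic and phenotypic correlations, and the posterior-mean causal
    coefficients of the requested structure.  Unreported covariances are
    completed by fixed variance shares (permanent environment
    ``PE_SHARE``, herd ``HERD_SHARE`` of each trait's non-genetic variance)
    and, where the assembled matrices are indefinite, a nearest-PSD
    projection (a warning is emitted).
    """
    structure = preset_structure(model)
    traits = cal.TRAITS
    T = len(traits)
    if model in cal.CAUSAL_EFFECTS:
        lam = structure.lambda_matrix(
            {edge: cal.CAUSAL_EFFECTS[model][edge] for edge in structure.edges}
        )
    else:
        lam = np.zeros((T, T))

    sigma_y = cal.trait_sd_vector() ** 2
    sigma_y[traits.index("a30")] = cal.A30_PHENOTYPIC_VARIANCE["M0"]
    sigma_s = np.array([cal.H2_M0[t] * vy / 4.0 for t, vy in zip(traits, sigma_y)])
    sigma_s[traits.index("a30")] = cal.A30_SIRE_VARIANCE["M0"]

    nongen = sigma_y - sigma_s
    p_diag = PE_SHARE * nongen
    h_diag = HERD_SHARE * nongen
    r_diag_mtm = nongen - p_diag - h_diag

    G_star = _pair_matrix(sigma_s, cal.GENETIC_CORR_M0, traits)
    T_star = _pair_matrix(sigma_y, cal.PHENOTYPIC_CORR_M0, traits)

    if structure.has_edges:
        r_struct = _solve_structural_residuals(lam, r_diag_mtm)
        Binv = identity_minus_lambda_inverse(lam)
        R_star = Binv @ np.diag(r_struct) @ Binv.T
        R = np.diag(r_struct)
    else:
        # Baseline multi-trait model: the residual covariance may be full and
        # absorbs whatever the other components do not claim.
        R_star = None
        R = None

    # Split the remaining phenotypic covariance between permanent environment
    # and herd in proportion to their variance shares.
    P_star = np.diag(p_diag).astype(float)
    H_star = np.diag(h_diag).astype(float)
    wp = PE_SHARE / (PE_SHARE + HERD_SHARE)
    for i in range(T):
        for j in range(i + 1, T):
            c = T_star[i, j] - G_star[i, j]
            if R_star is not None:
                c -= R_star[i, j]
                P_star[i, j] = P_star[j, i] = wp * c
                H_star[i, j] = H_star[j, i] = (1 - wp) * c
            else:
                # MTM: share among P, H, R by their variance shares.
                tot = p_diag[i] + h_diag[i] + r_diag_mtm[i]
                P_star[i, j] = P_star[j, i] = c * p_diag[i] / tot
                H_star[i, j] = H_star[j, i] = c * h_diag[i] / tot
    if R is None:
        R_star = T_star - G_star - P_star - H_star
        R = R_star

    mats = {}
    B = np.eye(T) - lam
    for name, star in (("G", G_star), ("P", P_star), ("H", H_star)):
        if np.linalg.eigvalsh(star).min() <= 0:
            warnings.warn(
                f"{name} completion is indefinite; projecting to nearest PSD",
                stacklevel=2,
            )
            star = nearest_psd(star)
        mats[name] = B @ star @ B.T if structure.has_edges else star
    if not structure.has_edges and np.linalg.eigvalsh(R).min() <= 0:
        warnings.warn("R completion is indefinite; projecting to nearest PSD",
                      stacklevel=2)
        R = nearest_psd(R)

    means = cal.trait_mean_vector()
    intercept = B @ means
    b = np.vstack([intercept, DIM_CONTRASTS])
    return TrueParameters(
        structure=structure, G=nearest_psd(mats["G"]), P=nearest_psd(mats["P"]),
        H=nearest_psd(mats["H"]), R=R, Lambda=lam, b=b,
    )


def _truncated_poisson_mu(target_mean: float) -> float:
    """Poisson rate whose zero-truncated mean equals ``target_mean``."""
    return brentq(
        lambda m: m / (1.0 - np.exp(-m)) - target_mean, 1e-6, 4 * target_mean
    )


def random_pedigree(
    n_total: int,
    n_observed: int,
    rng: np.random.Generator,
    p_sire_known: float = 0.85,
    p_mgs_known: float = 0.60,
) -> tuple[SireMgsPedigree, np.ndarray]:
    """Generation-free random sire-MGS pedigree of ``n_total`` bulls.

    Early individuals are founders; each later bull draws a known sire/MGS
    from earlier bulls with the given probabilities.  The ``n_observed``
    youngest bulls are the ones siring cows in the data.  Returns the pedigree
    and the pedigree rows of the observed bulls.
    """
    if n_total < n_observed:
        raise InputError("pedigree smaller than the number of observed sires")
    n_founder = max(3, int(round(0.25 * n_total)))
    entries = []
    for i in range(n_total):
        ind = f"B{i + 1:05d}"
        s = g = "0"
        if i >= n_founder:
            if rng.random() < p_sire_known:
                s = f"B{rng.integers(0, i) + 1:05d}"
            if rng.random() < p_mgs_known:
                g = f"B{rng.integers(0, i) + 1:05d}"
                if g == s:  # a bull cannot be both sire and maternal grandsire
                    g = "0"
        entries.append((ind, s, g))
    ped = make_pedigree(entries)
    observed = ped.index_of([f"B{i + 1:05d}" for i in range(n_total - n_observed, n_total)])
    return ped, observed


def default_design(
    seed: int,
    scale: float = 1.0,
    sires_per_herd: int = 15,
    mean_records: float = cal.N_RECORDS / cal.N_COWS,
) -> StudyDesign:
    """A study design emulating the recording scheme of the calibrated study.

    At ``scale=1`` this is 3266 cows in 309 herds sired by 128 bulls inside a
    1254-bull pedigree, with a zero-truncated-Poisson number of records per
    cow (mean ~2.69).  ``scale`` shrinks every count proportionally.  Cows are
    allocated to herds round-robin (balanced, no empty herds) and each herd
    draws its sires from a small overlapping pool so herd and sire effects
    stay separable.
    """
    if scale <= 0:
        raise InputError("scale must be positive")
    n_cows = max(20, int(round(cal.N_COWS * scale)))
    n_herds = max(4, int(round(cal.N_HERDS * scale)))
    n_sires = max(4, int(round(cal.N_SIRES * scale)))
    n_ped = max(n_sires + 5, int(round(cal.N_PEDIGREE * scale)))

    ss = np.random.SeedSequence(seed)
    rng_ped, rng_design = [np.random.default_rng(s) for s in ss.spawn(2)]

    pedigree, sire_rows = random_pedigree(n_ped, n_sires, rng_ped)

    # Balanced herd allocation: shuffled round-robin.
    reps = int(np.ceil(n_cows / n_herds))
    cow_herd = np.tile(np.arange(n_herds), reps)[:n_cows]
    rng_design.shuffle(cow_herd)

    # Each herd uses an overlapping pool of sires.
    pool_size = min(max(2, sires_per_herd), n_sires)
    herd_pools = [
        rng_design.choice(n_sires, size=pool_size, replace=False)
        for _ in range(n_herds)
    ]
    cow_sire_local = np.array(
        [herd_pools[h][rng_design.integers(pool_size)] for h in cow_herd]
    )
    cow_sire = sire_rows[cow_sire_local]

    mu = _truncated_poisson_mu(mean_records)
    n_rec = rng_design.poisson(mu, size=n_cows)
    n_rec = np.where(n_rec == 0, 1, n_rec)

    record_cow = np.repeat(np.arange(n_cows), n_rec)
    # Monthly recording: each cow starts in a random early class and moves up
    # one class per subsequent test day, capped at the last class.
    start = rng_design.integers(1, 5, size=n_cows)
    within = np.concatenate([np.arange(k) for k in n_rec])
    dim_class = np.minimum(start[record_cow] + within, 4)

    return StudyDesign(
        n_cows=n_cows, n_herds=n_herds, n_sires=n_sires,
        cow_herd=cow_herd, cow_sire=cow_sire,
        record_cow=record_cow, dim_class=dim_class,
        pedigree=pedigree, sire_rows=sire_rows, scale=scale, seed=seed,
    )


def dim_design_matrix(dim_class: np.ndarray) -> np.ndarray:
    """Fixed-effect design: intercept plus indicators for classes 1-3.

    Class 4 is the reference (corner constraint), keeping the intercept and
    stage-of-lactation effects jointly identifiable.
    """
    n = len(dim_class)
    X = np.zeros((n, 4))
    X[:, 0] = 1.0
    for c in (1, 2, 3):
        X[dim_class == c, c] = 1.0
    return X


def simulate(
    design: StudyDesign, truth: TrueParameters, seed: int
) -> SimulationResult:
    """Draw a complete record table from the reduced-form model.

    The seed governs named substreams (sire, herd, permanent environment,
    residual) so each random source can be varied independently; output is
    bit-reproducible for a fixed seed.
    """
    traits = truth.traits.labels
    T = len(traits)
    n = design.n_records
    q = design.pedigree.n

    ss = np.random.SeedSequence(seed)
    rng_s, rng_h, rng_p, rng_e = [np.random.default_rng(s) for s in ss.spawn(4)]

    A = build_A_sire_mgs(design.pedigree).A
    L_A = np.linalg.cholesky(A)
    s_eff = L_A @ rng_s.standard_normal((q, T)) @ np.linalg.cholesky(truth.G).T
    h_eff = rng_h.standard_normal((design.n_herds, T)) @ np.linalg.cholesky(truth.H).T
    p_eff = rng_p.standard_normal((design.n_cows, T)) @ np.linalg.cholesky(truth.P).T
    e = rng_e.standard_normal((n, T)) @ np.linalg.cholesky(truth.R).T

    X = dim_design_matrix(design.dim_class)
    herd_of_rec = design.cow_herd[design.record_cow]
    sire_of_rec = design.cow_sire[design.record_cow]
    u = (
        X @ truth.b
        + h_eff[herd_of_rec]
        + p_eff[design.record_cow]
        + s_eff[sire_of_rec]
        + e
    )
    Binv = identity_minus_lambda_inverse(truth.Lambda)
    y = u @ Binv.T

    cow_ids = design.cow_ids()
    herd_ids = design.herd_ids()
    ped_ids = design.pedigree.ids
    records = pd.DataFrame(
        {
            "record": np.arange(1, n + 1),
            "cow": [cow_ids[c] for c in design.record_cow],
            "herd": [herd_ids[h] for h in herd_of_rec],
            "sire": [ped_ids[s] for s in sire_of_rec],
            "dim_class": design.dim_class,
        }
    )
    for t, label in enumerate(traits):
        records[label] = y[:, t]

    effects = {
        "sire": s_eff, "herd": h_eff, "cow": p_eff,
        "residual": e, "structural": u, "fixed": X @ truth.b,
    }
    return SimulationResult(records=records, design=design, truth=truth,
                            effects=effects)


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth_audit(result: SimulationResult, directory: str | Path) -> None:
    """Dump realized effects and true parameters as delimited text."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    truth = result.truth
    labels = truth.traits.labels
    for name in ("G", "P", "H", "R", "Lambda"):
        pd.DataFrame(getattr(truth, name), index=labels, columns=labels).to_csv(
            directory / f"true_{name}.tsv", sep="\t"
        )
    pd.DataFrame(truth.b, columns=labels).to_csv(
        directory / "true_b.tsv", sep="\t", index=False
    )
    for name, arr in result.effects.items():
        pd.DataFrame(arr, columns=labels).to_csv(
            directory / f"effects_{name}.tsv", sep="\t", index=False,
            float_format="%.8f",
        )
    write_pedigree(result.design.pedigree, directory / "pedigree.tsv")
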
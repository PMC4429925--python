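"""Metropolis-Hastings-within-Gibbs sampler for recursive SEM sire models.

The model for each test-day record is

    y = Lambda y + X b + Z_h h + Z_p p + Z_s s + e,

with sire effects ``s ~ N(0, G (x) A)`` over a sire-MGS pedigree, herd
``h ~ N(0, H (x) I)``, cow permanent environment ``p ~ N(0, P (x) I)`` and
residuals ``e ~ N(0, R (x) I)``.  When the causal structure has edges the
residual covariance is forced diagonal (required to identify the structural
coefficients); the empty structure is the plain multi-trait model with full R.

The sampler works on the reduced responses ``y* = (I - Lambda) y``, which
follow the ordinary multi-trait likelihood, so every location and dispersion
block is conjugate and Gibbs-sampled; the structural coefficients are updated
by per-coefficient Gaussian random-walk Metropolis steps (no Jacobian is
needed because det(I - Lambda) = 1 for an acyclic system).  Proposal step
sizes adapt toward a target acceptance rate during burn-in only and are
frozen afterwards, preserving detailed balance of the retained chain.

Priors follow the package defaults: N(0, tau2) on each structural
coefficient, N(0, c) on fixed effects, inverse-Wishart(nu, S) on G, P, H (and
on full R in the multi-trait model) and per-trait scaled inverse chi-square
on the diagonal R of the SEM.  The inverse-Wishart scales are derived from
the observed phenotypic variances unless overridden.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, solve_triangular
from scipy.stats import invwishart

from .exceptions import InputError, NumericalError
from .pedigree import RelationshipMatrix, SireMgsPedigree, build_A_sire_mgs
from .structure import CausalStructure, make_structure

log = logging.getLogger("sirsem")

ALL_COMPONENTS = ("herd", "pe", "sire")


@dataclass
class PriorSpec:
    """Hyperparameters of every prior in the model.

    ``lambda0``/``tau2`` are the normal prior mean/variance of structural
    coefficients; ``fixed_effect_variance`` the normal prior variance of fixed
    effects; ``nu`` the degrees of freedom shared by all covariance priors.
    The scale matrices default to weakly informative values centred on half
    the observed phenotypic variance split equally across the four variance
    components; see :meth:`resolve`.
    """

    lambda0: float = 0.0
    tau2: float = 10_000.0
    fixed_effect_variance: float = 10_000.0
    nu: float = 6.0
    scale_G: np.ndarray | None = None
    scale_P: np.ndarray | None = None
    scale_H: np.ndarray | None = None
    scale_R: np.ndarray | None = None  # full matrix (MTM)
    residual_scale: np.ndarray | None = None  # per-trait chi-square scale (SEM)

    def resolve(self, trait_variances: np.ndarray) -> "ResolvedPriors":
        T = len(trait_variances)
        if self.tau2 <= 0:
            raise InputError("tau2 must be positive")
        if self.nu <= T + 1:
            raise InputError(
                f"nu must exceed n_traits + 1 = {T + 1} for a proper "
                "inverse-Wishart mean"
            )
        # Prior mean target: half the phenotypic variance split equally over
        # the four components (sire, PE, herd, residual).
        target = 0.5 * np.asarray(trait_variances, float) / 4.0
        default_S = (self.nu - T - 1) * np.diag(target)

        def pick(given, default):
            if given is None:
                return default.copy()
            m = np.asarray(given, float)
            if m.shape != default.shape:
                raise InputError(f"prior scale has shape {m.shape}, want {default.shape}")
            return m

        # Scaled-inverse-chi-square with df nu and scale s2 has mean
        # nu*s2/(nu-2); match the same target per trait.
        default_r = target * (self.nu - 2.0) / self.nu
        r_scale = (
            np.asarray(self.residual_scale, float)
            if self.residual_scale is not None
            else default_r
        )
        if np.any(r_scale <= 0):
            raise InputError("residual chi-square scales must be positive")
        return ResolvedPriors(
            lambda0=self.lambda0,
            tau2=self.tau2,
            fixed_effect_variance=self.fixed_effect_variance,
            nu=self.nu,
            S_G=pick(self.scale_G, default_S),
            S_P=pick(self.scale_P, default_S),
            S_H=pick(self.scale_H, default_S),
            S_R=pick(self.scale_R, default_S),
            r_scale=r_scale,
        )


@dataclass(frozen=True)
class ResolvedPriors:
    lambda0: float
    tau2: float
    fixed_effect_variance: float
    nu: float
    S_G: np.ndarray
    S_P: np.ndarray
    S_H: np.ndarray
    S_R: np.ndarray
    r_scale: np.ndarray


@dataclass
class ChainConfig:
    """Chain protocol: length, burn-in, thinning and proposal tuning."""

    n_iter: int = 120_000
    burn_in: int = 20_000
    thin: int = 10
    seed: int = 0
    initial_step: float = 0.05
    target_accept: float = 0.30
    adapt_interval: int = 50

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise InputError("burn_in must be in [0, n_iter)")
        if self.thin < 1:
            raise InputError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        """Number of stored samples: iterations >= burn_in, one every thin."""
        return len(range(self.burn_in, self.n_iter, self.thin))


@dataclass
class ModelState:
    """Current values of every sampled parameter."""

    b: np.ndarray  # (k, T)
    h: np.ndarray  # (n_herds, T)
    p: np.ndarray  # (n_cows, T)
    s: np.ndarray  # (n_ped, T)
    lam: np.ndarray  # (n_edges,)
    G: np.ndarray
    P: np.ndarray
    H: np.ndarray
    R: np.ndarray

    def lambda_matrix(self, structure: CausalStructure) -> np.ndarray:
        return structure.lambda_matrix(self.lam)


@dataclass(frozen=True)
class PreparedData:
    """Design information precomputed once per fit."""

    Y: np.ndarray  # (n, T) raw responses
    X: np.ndarray  # (n, k)
    XtX: np.ndarray
    herd_idx: np.ndarray
    cow_idx: np.ndarray
    sire_idx: np.ndarray  # pedigree row per record
    n_herds: int
    n_cows: int
    relationship: RelationshipMatrix | None
    structure: CausalStructure
    components: tuple[str, ...]
    edge_pos: np.ndarray  # (n_edges, 2) (row y, col x)

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def T(self) -> int:
        return self.Y.shape[1]

    @property
    def n_ped(self) -> int:
        return self.relationship.A.shape[0] if self.relationship is not None else 0


def reduce_records(Y: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Transformed responses y* = (I - Lambda) y, row-wise over records."""
    T = lam.shape[0]
    return np.asarray(Y) @ (np.eye(T) - lam).T


def prepare_data(
    records: pd.DataFrame,
    structure: CausalStructure,
    pedigree: SireMgsPedigree | RelationshipMatrix | None = None,
    components: Sequence[str] = ALL_COMPONENTS,
) -> PreparedData:
    """Assemble design matrices and index vectors from a record table.

    ``records`` needs a ``dim_class`` column plus one column per trait; herd,
    cow and sire columns are required only for the components in use.
    """
    from .simulate import dim_design_matrix  # local import to avoid a cycle

    components = tuple(components)
    unknown = set(components) - set(ALL_COMPONENTS)
    if unknown:
        raise InputError(f"unknown model components {sorted(unknown)}")
    traits = structure.traits.labels
    missing = [t for t in traits if t not in records.columns]
    if missing:
        raise InputError(f"record table lacks trait columns {missing}")
    Y = records.loc[:, list(traits)].to_numpy(float)
    if np.isnan(Y).any():
        raise InputError("missing trait values; only complete records are supported")
    X = dim_design_matrix(records["dim_class"].to_numpy(int))

    def codes(col: str) -> tuple[np.ndarray, int]:
        c, uniques = pd.factorize(records[col], sort=True)
        return c.astype(int), len(uniques)

    herd_idx = np.zeros(len(records), int)
    cow_idx = np.zeros(len(records), int)
    n_herds = n_cows = 0
    if "herd" in components:
        herd_idx, n_herds = codes("herd")
    if "pe" in components:
        cow_idx, n_cows = codes("cow")

    rel = None
    sire_idx = np.zeros(len(records), int)
    if "sire" in components:
        if pedigree is None:
            raise InputError("sire component requires a pedigree")
        rel = (
            pedigree
            if isinstance(pedigree, RelationshipMatrix)
            else build_A_sire_mgs(pedigree)
        )
        sire_idx = rel.rows_for(records["sire"])

    return PreparedData(
        Y=Y, X=X, XtX=X.T @ X,
        herd_idx=herd_idx, cow_idx=cow_idx, sire_idx=sire_idx,
        n_herds=n_herds, n_cows=n_cows,
        relationship=rel, structure=structure, components=components,
        edge_pos=structure.edge_positions(),
    )


def _symmetric_inverse(m: np.ndarray, name: str) -> np.ndarray:
    try:
        L = np.linalg.cholesky(m)
    except np.linalg.LinAlgError:
        raise NumericalError(f"{name} is not positive definite") from None
    inv = cho_solve((L, True), np.eye(m.shape[0]))
    return 0.5 * (inv + inv.T)


def _grouped_normal_draws(
    sums: np.ndarray,
    counts: np.ndarray,
    Rinv: np.ndarray,
    Cinv: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw independent T-variate normals with precision n_j R^-1 + C^-1.

    Levels with equal record counts share a precision matrix, so one Cholesky
    factorisation serves the whole group.
    """
    m, T = sums.shape
    out = np.empty((m, T))
    for c in np.unique(counts):
        idx = np.flatnonzero(counts == c)
        prec = c * Rinv + Cinv
        try:
            L = np.linalg.cholesky(prec)
        except np.linalg.LinAlgError:
            raise NumericalError("singular conditional precision in a level block") from None
        rhs = (sums[idx] @ Rinv).T  # (T, g)
        mean = cho_solve((L, True), rhs)
        z = rng.standard_normal((T, len(idx)))
        out[idx] = (mean + solve_triangular(L, z, lower=True, trans="T")).T
    return out


def gibbs_location(
    state: ModelState,
    data: PreparedData,
    priors: ResolvedPriors,
    rng: np.random.Generator,
) -> None:
    """Draw b, herd, permanent-environment and sire blocks from their full
    conditionals (in that order), updating ``state`` in place."""
    T = data.T
    ystar = reduce_records(data.Y, state.lambda_matrix(data.structure))
    Rinv = _symmetric_inverse(state.R, "R")

    he = state.h[data.herd_idx] if "herd" in data.components else 0.0
    pe = state.p[data.cow_idx] if "pe" in data.components else 0.0
    se = state.s[data.sire_idx] if "sire" in data.components else 0.0

    # --- fixed effects: joint k*T-variate normal -------------------------
    k = data.X.shape[1]
    E0 = ystar - he - pe - se
    prec = np.kron(Rinv, data.XtX) + np.eye(k * T) / priors.fixed_effect_variance
    rhs = (data.X.T @ E0 @ Rinv).ravel(order="F")
    try:
        L = np.linalg.cholesky(prec)
    except np.linalg.LinAlgError:
        raise NumericalError("singular conditional precision in the fixed-effect block") from None
    mean = cho_solve((L, True), rhs)
    vec = mean + solve_triangular(L, rng.standard_normal(k * T), lower=True, trans="T")
    state.b = vec.reshape((k, T), order="F")
    fx = data.X @ state.b

    # --- herd block ------------------------------------------------------
    if "herd" in data.components:
        r0 = ystar - fx - pe - se
        sums = np.zeros((data.n_herds, T))
        np.add.at(sums, data.herd_idx, r0)
        counts = np.bincount(data.herd_idx, minlength=data.n_herds)
        Hinv = _symmetric_inverse(state.H, "H")
        state.h = _grouped_normal_draws(sums, counts, Rinv, Hinv, rng)
        he = state.h[data.herd_idx]

    # --- permanent environment block -------------------------------------
    if "pe" in data.components:
        r0 = ystar - fx - he - se
        sums = np.zeros((data.n_cows, T))
        np.add.at(sums, data.cow_idx, r0)
        counts = np.bincount(data.cow_idx, minlength=data.n_cows)
        Pinv = _symmetric_inverse(state.P, "P")
        state.p = _grouped_normal_draws(sums, counts, Rinv, Pinv, rng)
        pe = state.p[data.cow_idx]

    # --- sire block: single-site Gibbs through G^-1 (x) A^-1 --------------
    if "sire" in data.components:
        q = data.n_ped
        Ainv = data.relationship.A_inv
        Ginv = _symmetric_inverse(state.G, "G")
        r0 = ystar - fx - he - pe
        sums = np.zeros((q, T))
        np.add.at(sums, data.sire_idx, r0)
        counts = np.bincount(data.sire_idx, minlength=q)
        s = state.s
        for j in range(q):
            aj = Ainv[j]
            cross = aj @ s - aj[j] * s[j]
            rhs_j = Rinv @ sums[j] - Ginv @ cross
            prec_j = counts[j] * Rinv + aj[j] * Ginv
            try:
                Lj = np.linalg.cholesky(prec_j)
            except np.linalg.LinAlgError:
                raise NumericalError(
                    f"singular conditional precision in the sire block (row {j})"
                ) from None
            mean_j = cho_solve((Lj, True), rhs_j)
            s[j] = mean_j + solve_triangular(
                Lj, rng.standard_normal(T), lower=True, trans="T"
            )


def gibbs_covariances(
    state: ModelState,
    data: PreparedData,
    priors: ResolvedPriors,
    rng: np.random.Generator,
) -> None:
    """Draw G, P, H and R from their conjugate full conditionals."""
    nu = priors.nu
    if "sire" in data.components:
        Sc = state.s.T @ data.relationship.A_inv @ state.s
        state.G = _invwishart_draw(nu + data.n_ped, priors.S_G + Sc, rng)
    if "pe" in data.components:
        state.P = _invwishart_draw(nu + data.n_cows, priors.S_P + state.p.T @ state.p, rng)
    if "herd" in data.components:
        state.H = _invwishart_draw(nu + data.n_herds, priors.S_H + state.h.T @ state.h, rng)

    ystar = reduce_records(data.Y, state.lambda_matrix(data.structure))
    resid = ystar - data.X @ state.b
    if "herd" in data.components:
        resid = resid - state.h[data.herd_idx]
    if "pe" in data.components:
        resid = resid - state.p[data.cow_idx]
    if "sire" in data.components:
        resid = resid - state.s[data.sire_idx]
    n = data.n
    if data.structure.has_edges:
        # Diagonal R: independent scaled inverse chi-square per trait.
        ee = np.einsum("ij,ij->j", resid, resid)
        draws = (nu * priors.r_scale + ee) / rng.chisquare(nu + n, size=data.T)
        state.R = np.diag(draws)
    else:
        state.R = _invwishart_draw(nu + n, priors.S_R + resid.T @ resid, rng)


def _invwishart_draw(df: float, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    scale = 0.5 * (scale + scale.T)
    if np.linalg.eigvalsh(scale).min() <= 0:
        raise NumericalError("inverse-Wishart posterior scale is not positive definite")
    draw = invwishart.rvs(df=df, scale=scale, random_state=rng)
    return np.atleast_2d(draw)


def mh_structural(
    state: ModelState,
    data: PreparedData,
    priors: ResolvedPriors,
    steps: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One random-walk Metropolis sweep over the structural coefficients.

    Each coefficient is proposed from a Gaussian step; the acceptance ratio is
    the diagonal-R Gaussian likelihood of the reduced residuals times the
    N(lambda0, tau2) prior (det(I - Lambda) = 1, so no Jacobian enters).
    Returns a boolean acceptance flag per edge.
    """
    if not data.structure.has_edges:
        return np.zeros(0, bool)
    ystar = reduce_records(data.Y, state.lambda_matrix(data.structure))
    mean = data.X @ state.b
    if "herd" in data.components:
        mean = mean + state.h[data.herd_idx]
    if "pe" in data.components:
        mean = mean + state.p[data.cow_idx]
    if "sire" in data.components:
        mean = mean + state.s[data.sire_idx]

    accepted = np.zeros(data.structure.n_edges, bool)
    for k, (row, col) in enumerate(data.edge_pos):
        resid = ystar[:, row] - mean[:, row]
        prop = state.lam[k] + steps[k] * rng.standard_normal()
        delta = prop - state.lam[k]
        resid_prop = resid - delta * data.Y[:, col]
        r_y = state.R[row, row]
        loglik = -0.5 * (resid_prop @ resid_prop - resid @ resid) / r_y
        logprior = (
            -0.5
            * ((prop - priors.lambda0) ** 2 - (state.lam[k] - priors.lambda0) ** 2)
            / priors.tau2
        )
        if np.log(rng.random()) < loglik + logprior:
            state.lam[k] = prop
            ystar[:, row] = resid_prop + mean[:, row]
            accepted[k] = True
    return accepted


@dataclass
class PosteriorChain:
    """Thinned post-burn-in samples of every model parameter."""

    structure: CausalStructure
    config: ChainConfig
    lambda_samples: np.ndarray  # (m, n_edges)
    b_samples: np.ndarray  # (m, k, T)
    G_samples: np.ndarray  # (m, T, T)
    P_samples: np.ndarray
    H_samples: np.ndarray
    R_samples: np.ndarray
    acceptance: dict[str, float]
    components: tuple[str, ...] = ALL_COMPONENTS
    effect_samples: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def n_samples(self) -> int:
        return self.G_samples.shape[0]

    @property
    def traits(self) -> tuple[str, ...]:
        return self.structure.traits.labels

    def lambda_matrices(self) -> np.ndarray:
        """(m, T, T) structural coefficient matrix per retained sample."""
        m = self.n_samples
        T = len(self.traits)
        out = np.zeros((m, T, T))
        pos = self.structure.edge_positions()
        for k, (row, col) in enumerate(pos):
            out[:, row, col] = self.lambda_samples[:, k]
        return out

    def save(self, directory: str | Path) -> None:
        """Write one delimited samples file per block plus run metadata."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        traits = self.traits
        pd.DataFrame(self.lambda_samples, columns=self.structure.edge_labels()).to_csv(
            directory / "lambda.tsv", sep="\t", index=False
        )
        k = self.b_samples.shape[1]
        bcols = [f"b{i}.{t}" for t in traits for i in range(k)]
        pd.DataFrame(
            self.b_samples.reshape(self.n_samples, -1, order="F"), columns=bcols
        ).to_csv(directory / "b.tsv", sep="\t", index=False)
        covcols = [f"{a}.{b}" for a in traits for b in traits]
        for name in ("G", "P", "H", "R"):
            arr = getattr(self, f"{name}_samples").reshape(self.n_samples, -1)
            pd.DataFrame(arr, columns=covcols).to_csv(
                directory / f"{name}.tsv", sep="\t", index=False
            )
        meta = {
            "traits": list(traits),
            "edges": [list(e) for e in self.structure.edges],
            "components": list(self.components),
            "config": {
                "n_iter": self.config.n_iter,
                "burn_in": self.config.burn_in,
                "thin": self.config.thin,
                "seed": self.config.seed,
                "initial_step": self.config.initial_step,
                "target_accept": self.config.target_accept,
                "adapt_interval": self.config.adapt_interval,
            },
            "acceptance": self.acceptance,
        }
        (directory / "metadata.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "PosteriorChain":
        directory = Path(directory)
        meta = json.loads((directory / "metadata.json").read_text())
        structure = make_structure(
            [tuple(e) for e in meta["edges"]], traits=tuple(meta["traits"])
        )
        config = ChainConfig(**meta["config"])
        T = len(meta["traits"])

        def grab(name):
            return pd.read_csv(directory / f"{name}.tsv", sep="\t").to_numpy(float)

        lam = grab("lambda") if structure.has_edges else np.zeros((0, 0))
        b_flat = grab("b")
        m = b_flat.shape[0]
        if not structure.has_edges:
            lam = np.zeros((m, 0))
        k = b_flat.shape[1] // T
        covs = {name: grab(name).reshape(m, T, T) for name in ("G", "P", "H", "R")}
        return cls(
            structure=structure,
            config=config,
            lambda_samples=lam,
            b_samples=b_flat.reshape(m, k, T, order="F"),
            G_samples=covs["G"],
            P_samples=covs["P"],
            H_samples=covs["H"],
            R_samples=covs["R"],
            acceptance=meta["acceptance"],
            components=tuple(meta["components"]),
        )


def _initial_state(data: PreparedData, priors: ResolvedPriors) -> ModelState:
    T = data.T
    k = data.X.shape[1]
    b = np.zeros((k, T))
    if data.n:
        b[0] = data.Y.mean(axis=0)
    denom = priors.nu - T - 1
    start_cov = lambda S: S / denom if denom > 0 else S.copy()  # noqa: E731
    R0 = start_cov(priors.S_R)
    if data.structure.has_edges:
        R0 = np.diag(priors.nu * priors.r_scale / (priors.nu - 2.0))
    return ModelState(
        b=b,
        h=np.zeros((max(data.n_herds, 1), T)),
        p=np.zeros((max(data.n_cows, 1), T)),
        s=np.zeros((max(data.n_ped, 1), T)),
        lam=np.zeros(data.structure.n_edges),
        G=start_cov(priors.S_G),
        P=start_cov(priors.S_P),
        H=start_cov(priors.S_H),
        R=R0,
    )


def run_chain(
    records: pd.DataFrame,
    structure: CausalStructure,
    pedigree: SireMgsPedigree | RelationshipMatrix | None = None,
    priors: PriorSpec | None = None,
    config: ChainConfig | None = None,
    components: Sequence[str] = ALL_COMPONENTS,
    store_effects: bool = False,
) -> PosteriorChain:
    """Fit the model by MH-within-Gibbs and return the thinned chain.

    Each iteration sweeps the location blocks, the covariance blocks and (for
    structures with edges) the structural coefficients.  Retained samples are
    the post-burn-in iterations, one every ``thin``.  Fixed seed gives a
    bit-identical chain.
    """
    priors = priors or PriorSpec()
    config = config or ChainConfig()
    data = prepare_data(records, structure, pedigree, components)
    resolved = priors.resolve(data.Y.var(axis=0, ddof=1))
    rng = np.random.default_rng(config.seed)
    state = _initial_state(data, resolved)

    n_edges = data.structure.n_edges
    steps = np.full(n_edges, config.initial_step)
    window_acc = np.zeros(n_edges)
    post_acc = np.zeros(n_edges)
    n_post = 0

    m = config.n_retained
    T = data.T
    k = data.X.shape[1]
    out = PosteriorChain(
        structure=data.structure,
        config=config,
        lambda_samples=np.empty((m, n_edges)),
        b_samples=np.empty((m, k, T)),
        G_samples=np.empty((m, T, T)),
        P_samples=np.empty((m, T, T)),
        H_samples=np.empty((m, T, T)),
        R_samples=np.empty((m, T, T)),
        acceptance={},
        components=tuple(components),
    )
    if store_effects:
        out.effect_samples = {
            "h": np.empty((m, state.h.shape[0], T)),
            "p": np.empty((m, state.p.shape[0], T)),
            "s": np.empty((m, state.s.shape[0], T)),
        }

    stored = 0
    try:
        for it in range(config.n_iter):
            gibbs_location(state, data, resolved, rng)
            gibbs_covariances(state, data, resolved, rng)
            if n_edges:
                accepted = mh_structural(state, data, resolved, steps, rng)
                window_acc += accepted
                if it >= config.burn_in:
                    post_acc += accepted
                    n_post += 1
                elif (it + 1) % config.adapt_interval == 0:
                    rate = window_acc / config.adapt_interval
                    steps *= np.exp(0.5 * (rate - config.target_accept))
                    steps = np.clip(steps, 1e-8, 1e3)
                    window_acc[:] = 0.0
            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                out.lambda_samples[stored] = state.lam
                out.b_samples[stored] = state.b
                out.G_samples[stored] = state.G
                out.P_samples[stored] = state.P
                out.H_samples[stored] = state.H
                out.R_samples[stored] = state.R
                if store_effects:
                    out.effect_samples["h"][stored] = state.h
                    out.effect_samples["p"][stored] = state.p
                    out.effect_samples["s"][stored] = state.s
                stored += 1
            if (it + 1) % 1000 == 0:
                msg = f"iteration {it + 1}/{config.n_iter}"
                if n_edges and n_post:
                    msg += f", MH acceptance {np.round(post_acc / n_post, 3)}"
                log.info(msg)
    except NumericalError as exc:
        raise NumericalError(f"iteration {it}: {exc}") from exc

    assert stored == m
    labels = data.structure.edge_labels()
    rates = post_acc / max(n_post, 1)
    out.acceptance = {lab: float(r) for lab, r in zip(labels, rates)}
    return out
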
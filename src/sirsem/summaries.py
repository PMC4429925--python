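"""Posterior summaries: multi-trait-scale transforms and derived genetics.

Dispersion parameters of a recursive SEM describe only the *direct* (not
phenotype-mediated) part of each random effect.  To compare them with a
standard multi-trait model they are mapped through the congruence transform

    M* = (I - Lambda)^-1 M (I - Lambda)'^-1        for M in {G, P, H, R},

which preserves positive semi-definiteness.  From the transformed draws the
usual quantities follow: sire-model heritability h^2 = 4 s2_s / (s2_s + s2_p
+ s2_h + s2_e), genetic correlations from G*, phenotypic correlations from
G* + P* + H* + R*, causal coefficients in phenotypic-SD units, and the
percentage of a variance component lost relative to the no-causal-path
baseline.  Every derived scalar is computed per retained draw and then
summarised (posterior mean and highest-posterior-density interval); the
variance-loss table is additionally reported as plain point-estimate
arithmetic on posterior means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InputError
from .sampler import PosteriorChain
from .structure import identity_minus_lambda_inverse


@dataclass(frozen=True)
class TransformedDraw:
    """One posterior draw of all covariance matrices on the multi-trait scale."""

    G: np.ndarray
    P: np.ndarray
    H: np.ndarray
    R: np.ndarray

    @property
    def total(self) -> np.ndarray:
        """Phenotypic covariance: elementwise sum of the four components."""
        return self.G + self.P + self.H + self.R


def to_mtm_scale(
    G: np.ndarray, P: np.ndarray, H: np.ndarray, R: np.ndarray, lam: np.ndarray
) -> TransformedDraw:
    """Map SEM-scale covariance matrices to the multi-trait scale."""
    Binv = identity_minus_lambda_inverse(np.asarray(lam, float))
    f = lambda M: Binv @ np.asarray(M, float) @ Binv.T  # noqa: E731
    return TransformedDraw(G=f(G), P=f(P), H=f(H), R=f(R))


def heritability(draw: TransformedDraw, trait: int) -> float:
    """Sire-model heritability of one trait from a transformed draw."""
    s2s = draw.G[trait, trait]
    total = draw.total[trait, trait]
    return 4.0 * s2s / total


def correlations(draw: TransformedDraw) -> tuple[np.ndarray, np.ndarray]:
    """Genetic (from G*) and phenotypic (from the component sum) correlations."""
    def corr(m: np.ndarray) -> np.ndarray:
        d = np.sqrt(np.diag(m))
        return m / np.outer(d, d)

    return corr(draw.G), corr(draw.total)


def sd_units(lambda_yx: float, sd_x: float, sd_y: float) -> float:
    """Causal coefficient in phenotypic-SD units: lambda * sd(x) / sd(y)."""
    if sd_y <= 0:
        raise InputError("sd of the dependent trait must be positive")
    return lambda_yx * sd_x / sd_y


def variance_loss(value_m0: float, value_mk: float) -> float:
    """Percent of a baseline variance component absorbed by causal paths."""
    if value_m0 <= 0:
        raise InputError("baseline variance must be positive")
    return 100.0 * (value_m0 - value_mk) / value_m0


def hpd_interval(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the samples.

    Sorted-sample shortest-window method; ties broken toward the lower
    interval start.
    """
    x = np.sort(np.asarray(samples, float).ravel())
    n = x.size
    if n < 2:
        return (float(x[0]), float(x[0])) if n else (np.nan, np.nan)
    keep = int(np.ceil(mass * n))
    keep = min(max(keep, 1), n)
    if keep == n:
        return float(x[0]), float(x[-1])
    widths = x[keep:] - x[: n - keep]
    start = int(np.argmin(widths))  # argmin takes the first (lowest) minimum
    return float(x[start]), float(x[start + keep])


def autocorrelation(x: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Sample autocorrelation function via FFT, lags 0..max_lag."""
    x = np.asarray(x, float).ravel()
    n = x.size
    if max_lag is None:
        max_lag = min(n - 1, 1000)
    xc = x - x.mean()
    var = xc @ xc
    if var == 0:
        return np.full(max_lag + 1, np.nan)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f))[: max_lag + 1]
    return acov / var


def effective_sample_size(x: np.ndarray) -> float:
    """ESS by truncating the autocorrelation sum at the first non-positive lag.

    For an AR(1) chain with coefficient rho this recovers
    n (1 - rho) / (1 + rho).  A constant chain has no information and
    returns ``nan`` with a warning.
    """
    x = np.asarray(x, float).ravel()
    n = x.size
    rho = autocorrelation(x)
    if np.isnan(rho).all():
        warnings.warn("constant chain: effective sample size is undefined",
                      stacklevel=2)
        return np.nan
    s = 0.0
    for r in rho[1:]:
        if r <= 0:
            break
        s += r
    return n / (1.0 + 2.0 * s)


def running_mean(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, float).ravel()
    return np.cumsum(x) / np.arange(1, x.size + 1)


def diagnostics(samples: dict[str, np.ndarray] | pd.DataFrame) -> pd.DataFrame:
    """Per-parameter MCMC diagnostics: mean, sd, 95% HPD, ESS, lag-1 ACF."""
    if isinstance(samples, pd.DataFrame):
        samples = {c: samples[c].to_numpy() for c in samples.columns}
    rows = []
    for name, x in samples.items():
        x = np.asarray(x, float).ravel()
        lo, hi = hpd_interval(x)
        rho = autocorrelation(x, max_lag=1)
        rows.append(
            {
                "parameter": name,
                "mean": x.mean(),
                "sd": x.std(ddof=1) if x.size > 1 else 0.0,
                "hpd_low": lo,
                "hpd_high": hi,
                "ess": effective_sample_size(x),
                "acf_lag1": rho[1] if rho.size > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def trace_series(chain: PosteriorChain) -> dict[str, np.ndarray]:
    """Plot-ready per-parameter traces (structural coefficients, variances)."""
    out: dict[str, np.ndarray] = {}
    for k, lab in enumerate(chain.structure.edge_labels()):
        out[f"lambda[{lab}]"] = chain.lambda_samples[:, k]
    for t, lab in enumerate(chain.traits):
        out[f"sigma2_s[{lab}]"] = chain.G_samples[:, t, t]
        out[f"sigma2_e[{lab}]"] = chain.R_samples[:, t, t]
    return out


def plot_traces(chain: PosteriorChain, path: str | Path) -> None:
    """Trace + running-mean figure for the main parameters (needs matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    series = trace_series(chain)
    fig, axes = plt.subplots(len(series), 1, figsize=(8, 2 * len(series)),
                             squeeze=False)
    for ax, (name, x) in zip(axes[:, 0], series.items()):
        ax.plot(x, lw=0.4, label="trace")
        ax.plot(running_mean(x), lw=1.2, label="running mean")
        ax.set_ylabel(name, fontsize=7)
    axes[0, 0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class GeneticSummary:
    """Every derived quantity of a fitted chain, with 95% HPD bounds."""

    traits: tuple[str, ...]
    heritability_table: pd.DataFrame
    variance_components: pd.DataFrame
    genetic_correlation: pd.DataFrame
    phenotypic_correlation: pd.DataFrame
    causal_effects: pd.DataFrame
    variance_loss_table: pd.DataFrame | None = None
    samples: dict[str, np.ndarray] = field(default_factory=dict, repr=False)


def _summary_row(x: np.ndarray, mass: float = 0.95) -> tuple[float, float, float]:
    lo, hi = hpd_interval(x, mass)
    return float(np.mean(x)), lo, hi


def transformed_draws(chain: PosteriorChain) -> list[TransformedDraw]:
    lams = chain.lambda_matrices()
    return [
        to_mtm_scale(chain.G_samples[i], chain.P_samples[i],
                     chain.H_samples[i], chain.R_samples[i], lams[i])
        for i in range(chain.n_samples)
    ]


def summarize_chain(
    chain: PosteriorChain,
    data_sds: dict[str, float] | None = None,
    baseline: PosteriorChain | None = None,
    mass: float = 0.95,
) -> GeneticSummary:
    """Compute the full genetic summary of a chain.

    ``data_sds`` (observed phenotypic SDs per trait) enable the SD-unit
    transform of causal coefficients.  ``baseline`` is a fitted no-causal-path
    chain; when given, variance-loss percentages for the terminal trait are
    reported both per-draw (draws paired by index) and as point-estimate
    arithmetic on the posterior means.  The loss compares the *direct*
    (structural-scale, pre-transformation) components of the causal model —
    the dispersion that would remain if the upstream phenotypes were held
    fixed by intervention — against the baseline components, and also reports
    the heritability implied by the direct components.
    """
    traits = chain.traits
    T = len(traits)
    m = chain.n_samples
    draws = transformed_draws(chain)

    h2 = np.array([[heritability(d, t) for t in range(T)] for d in draws])
    comp = {
        name: np.array([np.diag(getattr(d, name)) for d in draws])
        for name in ("G", "P", "H", "R")
    }
    total = comp["G"] + comp["P"] + comp["H"] + comp["R"]
    gcorr = np.array([correlations(d)[0] for d in draws])
    pcorr = np.array([correlations(d)[1] for d in draws])

    h2_rows = []
    vc_rows = []
    for t, lab in enumerate(traits):
        mean, lo, hi = _summary_row(h2[:, t], mass)
        h2_rows.append({"trait": lab, "h2": mean, "hpd_low": lo, "hpd_high": hi})
        row = {"trait": lab}
        for name, sym in (("G", "sigma2_s"), ("P", "sigma2_p"),
                          ("H", "sigma2_h"), ("R", "sigma2_e")):
            mu, lo, hi = _summary_row(comp[name][:, t], mass)
            row.update({sym: mu, f"{sym}_low": lo, f"{sym}_high": hi})
        mu, lo, hi = _summary_row(total[:, t], mass)
        row.update({"sigma2_y": mu, "sigma2_y_low": lo, "sigma2_y_high": hi})
        vc_rows.append(row)

    def corr_frame(arr: np.ndarray) -> pd.DataFrame:
        mean = arr.mean(axis=0)
        return pd.DataFrame(mean, index=traits, columns=traits)

    ce_rows = []
    for k, (x, y) in enumerate(chain.structure.edges):
        lam_k = chain.lambda_samples[:, k]
        mean, lo, hi = _summary_row(lam_k, mass)
        row = {"effect": f"{x}->{y}", "estimate": mean,
               "hpd_low": lo, "hpd_high": hi}
        if data_sds is not None:
            row["sd_units"] = sd_units(mean, data_sds[x], data_sds[y])
        ce_rows.append(row)
    ce = pd.DataFrame(
        ce_rows,
        columns=["effect", "estimate", "hpd_low", "hpd_high"]
        + (["sd_units"] if data_sds is not None else []),
    )

    loss = None
    samples = {
        "h2": h2, "sigma2_s": comp["G"], "sigma2_y": total,
        "lambda": chain.lambda_samples,
    }
    if baseline is not None:
        if baseline.n_samples != m:
            raise InputError(
                "baseline chain must have the same number of retained samples"
            )
        t = T - 1  # the terminal trait of the causal network
        # Direct (structural-scale) components: the baseline has no edges, so
        # its direct and transformed components coincide.
        idx = np.arange(T)
        direct_s = chain.G_samples[:, idx, idx]
        direct_y = (
            chain.G_samples + chain.P_samples + chain.H_samples + chain.R_samples
        )[:, idx, idx]
        b_s = baseline.G_samples[:, idx, idx]
        b_y = (
            baseline.G_samples + baseline.P_samples
            + baseline.H_samples + baseline.R_samples
        )[:, idx, idx]
        rows = []
        for label, cur, base in (
            ("sigma2_s", direct_s[:, t], b_s[:, t]),
            ("sigma2_y", direct_y[:, t], b_y[:, t]),
        ):
            per_draw = 100.0 * (base - cur) / base
            mu, lo, hi = _summary_row(per_draw, mass)
            rows.append(
                {
                    "component": label,
                    "loss_pct_point": variance_loss(base.mean(), cur.mean()),
                    "loss_pct_mean": mu,
                    "hpd_low": lo,
                    "hpd_high": hi,
                }
            )
        h2_direct = 4.0 * direct_s[:, t] / direct_y[:, t]
        mu, lo, hi = _summary_row(h2_direct, mass)
        rows.append(
            {
                "component": "h2_direct",
                "loss_pct_point": 4.0 * direct_s[:, t].mean() / direct_y[:, t].mean(),
                "loss_pct_mean": mu,
                "hpd_low": lo,
                "hpd_high": hi,
            }
        )
        loss = pd.DataFrame(rows)
        samples["direct_sigma2_s"] = direct_s
        samples["direct_sigma2_y"] = direct_y
        samples["baseline_sigma2_s"] = b_s
        samples["baseline_sigma2_y"] = b_y

    return GeneticSummary(
        traits=traits,
        heritability_table=pd.DataFrame(h2_rows),
        variance_components=pd.DataFrame(vc_rows),
        genetic_correlation=corr_frame(gcorr),
        phenotypic_correlation=corr_frame(pcorr),
        causal_effects=ce,
        variance_loss_table=loss,
        samples=samples,
    )


def write_summary_tables(summary: GeneticSummary, directory: str | Path) -> None:
    """Emit the report tables as delimited text files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    summary.heritability_table.to_csv(directory / "heritability.tsv", sep="\t",
                                      index=False, float_format="%.4f")
    summary.variance_components.to_csv(directory / "variance_components.tsv",
                                       sep="\t", index=False, float_format="%.4f")
    summary.genetic_correlation.to_csv(directory / "genetic_correlation.tsv",
                                       sep="\t", float_format="%.4f")
    summary.phenotypic_correlation.to_csv(
        directory / "phenotypic_correlation.tsv", sep="\t", float_format="%.4f"
    )
    summary.causal_effects.to_csv(directory / "causal_effects.tsv", sep="\t",
                                  index=False, float_format="%.4f")
    if summary.variance_loss_table is not None:
        summary.variance_loss_table.to_csv(directory / "variance_loss.tsv",
                                           sep="\t", index=False,
                                           float_format="%.4f")
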
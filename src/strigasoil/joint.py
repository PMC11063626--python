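"""Joint Bayesian multivariate regression of taxa and traits.

CLR-transformed taxa abundances and host traits are stacked into one response
matrix Y (n x q) and regressed on the factorial design

    Y = X B + E,    rows of E ~ N(0, Sigma),

with X = [intercept, soil_natural, striga_infected, interaction].  A Gibbs
sampler alternates exact conjugate draws:

* B | Sigma   ~ matrix-normal around the ridge solution
  (X'X + tau I)^-1 X'Y with row covariance (X'X + tau I)^-1 and column
  covariance Sigma;
* Sigma | B   ~ inverse-Wishart(nu0 + n, S0 + E'E), E = Y - X B.

The estimand of interest is the *residual correlation* matrix: the
correlation between responses after the treatment effects are removed, the
model's proxy for biotic association between taxa and Striga-suppression
traits.  Treatment contrasts answer two questions per response: H1, is there
a Striga effect within each soil; H2, is there a soil effect within each
Striga treatment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, cholesky, solve_triangular

from .datasets import TaxaCountTable, TraitTable

DESIGN_COLUMNS = ("intercept", "soil_natural", "striga_infected", "interaction")


@dataclass
class DesignMatrix:
    """Treatment-coded design: sterilized/control is the reference cell."""

    x: pd.DataFrame
    coding: dict[str, str] = field(
        default_factory=lambda: {"soil": "natural=1", "striga": "infected=1"}
    )

    @property
    def values(self) -> np.ndarray:
        return self.x.to_numpy(float)


def build_design(metadata: pd.DataFrame) -> DesignMatrix:
    """0/1 design with an interaction column from soil and striga factors."""
    unknown_soil = set(metadata["soil"]) - {"natural", "sterilized"}
    unknown_striga = set(metadata["striga"]) - {"infected", "control"}
    if unknown_soil or unknown_striga:
        raise ValueError(
            f"unknown factor level(s): soil={sorted(unknown_soil)}, "
            f"striga={sorted(unknown_striga)}"
        )
    soil = (metadata["soil"] == "natural").astype(float)
    striga = (metadata["striga"] == "infected").astype(float)
    x = pd.DataFrame(
        {
            "intercept": 1.0,
            "soil_natural": soil,
            "striga_infected": striga,
            "interaction": soil * striga,
        },
        index=metadata.index,
    )
    return DesignMatrix(x=x)


def clr_transform(counts, pseudocount: float = 0.5):
    """Centered log-ratio transform of count rows.

    x_i = ln((c_i + pseudocount) / g), with g the geometric mean of the
    shifted row, so each output row sums to zero.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    is_frame = isinstance(counts, pd.DataFrame)
    values = counts.to_numpy(float) if is_frame else np.asarray(counts, float)
    one_dim = values.ndim == 1
    if one_dim:
        values = values[None, :]
    logs = np.log(values + pseudocount)
    out = logs - logs.mean(axis=1, keepdims=True)
    if is_frame:
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out[0] if one_dim else out


def filter_taxa(
    table: TaxaCountTable, min_prevalence: float = 0.2, max_taxa: int = 100
) -> TaxaCountTable:
    """Prevalence filter, then top ``max_taxa`` by mean relative abundance.

    Ties at the abundance cutoff break lexicographically by taxon id (the
    smaller id is kept), so the result is deterministic.
    """
    counts = table.counts
    prevalence = (counts > 0).mean(axis=0)
    kept = prevalence[prevalence >= min_prevalence].index
    if len(kept) == 0:
        raise ValueError("no taxa pass the prevalence filter")
    rel = counts[kept].div(counts.sum(axis=1).replace(0, 1), axis=0)
    mean_abundance = rel.mean(axis=0)
    order = sorted(kept, key=lambda t: (-mean_abundance[t], t))
    chosen = set(order[:max_taxa])
    final = [t for t in counts.columns if t in chosen]
    return TaxaCountTable(
        counts=counts[final].copy(),
        metadata=table.metadata,
        taxonomy=table.taxonomy,
    )


@dataclass
class Prior:
    """Ridge precision on B and inverse-Wishart(nu0, s0) on Sigma.

    ``nu0`` defaults to q + 2 and ``s0`` to the identity, set at fit time.
    """

    tau: float = 1.0e-3
    nu0: int | None = None
    s0: np.ndarray | None = None


@dataclass
class McmcSettings:
    n_iter: int = 10_000
    burn_in: int = 2_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class JointFit:
    """Retained posterior draws and derived summaries."""

    b_draws: np.ndarray  # (n_draws, p, q)
    sigma_draws: np.ndarray  # (n_draws, q, q)
    responses: list[str]
    design_columns: list[str]
    column_roles: dict[str, str]  # response id -> "taxon" | "trait"
    mcmc: McmcSettings
    geweke_z: dict[str, float]

    @property
    def n_draws(self) -> int:
        return self.b_draws.shape[0]

    @property
    def posterior_mean_b(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.b_draws.mean(axis=0), index=self.design_columns, columns=self.responses
        )

    @property
    def resid_corr(self) -> pd.DataFrame:
        return residual_correlations(self)


def _inverse_wishart_draw(
    rng: np.random.Generator, df: int, scale_chol: np.ndarray
) -> np.ndarray:
    """Draw from IW(df, S) given the lower Cholesky factor of S (Bartlett)."""
    q = scale_chol.shape[0]
    t = np.zeros((q, q))
    idx = np.tril_indices(q, k=-1)
    t[idx] = rng.standard_normal(len(idx[0]))
    t[np.diag_indices(q)] = np.sqrt(rng.chisquare(df - np.arange(q)))
    # Sigma = L T^-T T^-1 L'  with  S = L L'
    w = solve_triangular(t, scale_chol.T, lower=True)
    return w.T @ w


def _geweke_z(series: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    n = len(series)
    a = series[: max(int(first * n), 2)]
    b = series[-max(int(last * n), 2):]
    denom = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def gibbs_fit(
    y: pd.DataFrame,
    x: DesignMatrix | pd.DataFrame,
    prior: Prior | None = None,
    mcmc: McmcSettings | None = None,
    column_roles: dict[str, str] | None = None,
) -> JointFit:
    """Sample the joint posterior of (B, Sigma) by blocked Gibbs.

    Draws after ``burn_in``, thinned by ``thin``, are retained.  Identical
    seeds give identical chains.
    """
    prior = prior or Prior()
    mcmc = mcmc or McmcSettings()
    x_frame = x.x if isinstance(x, DesignMatrix) else x
    xv = x_frame.to_numpy(float)
    yv = y.to_numpy(float)
    n, p = xv.shape
    q = yv.shape[1]
    if q < 2:
        raise ValueError("need at least two response columns")
    if n <= p:
        raise ValueError(
            f"n ({n}) must exceed the number of design columns ({p}); "
            "filter taxa more aggressively or add samples"
        )
    if not np.isfinite(yv).all():
        raise ValueError("response matrix contains non-finite values")

    nu0 = prior.nu0 if prior.nu0 is not None else q + 2
    s0 = prior.s0 if prior.s0 is not None else np.eye(q)
    rng = np.random.default_rng(mcmc.seed)

    gram = xv.T @ xv + prior.tau * np.eye(p)
    gram_chol = cholesky(gram, lower=True)
    b_hat = cho_solve((gram_chol, True), xv.T @ yv)  # ridge posterior mean of B
    # row-covariance factor A with A A' = (X'X + tau I)^-1
    a_factor = solve_triangular(gram_chol, np.eye(p), lower=True).T

    n_retained = (mcmc.n_iter - mcmc.burn_in + mcmc.thin - 1) // mcmc.thin
    b_draws = np.empty((n_retained, p, q))
    sigma_draws = np.empty((n_retained, q, q))

    sigma = np.eye(q)
    kept = 0
    for it in range(mcmc.n_iter):
        sigma_chol = cholesky(sigma, lower=True)
        b = b_hat + a_factor @ rng.standard_normal((p, q)) @ sigma_chol.T
        resid = yv - xv @ b
        scale = s0 + resid.T @ resid
        sigma = _inverse_wishart_draw(rng, nu0 + n, cholesky(scale, lower=True))
        if not np.isfinite(sigma).all():
            raise RuntimeError(
                f"non-finite Sigma draw at iteration {it}; check response scaling"
            )
        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            b_draws[kept] = b
            sigma_draws[kept] = sigma
            kept += 1
    b_draws = b_draws[:kept]
    sigma_draws = sigma_draws[:kept]

    # Geweke diagnostics on the log-determinant and a few Sigma entries
    monitor: dict[str, np.ndarray] = {
        "log_det_sigma": np.linalg.slogdet(sigma_draws)[1]
    }
    diag_rng = np.random.default_rng(mcmc.seed + 1)
    for _ in range(min(10, q * (q - 1) // 2)):
        i = int(diag_rng.integers(q))
        j = int(diag_rng.integers(q))
        monitor[f"sigma[{i},{j}]"] = sigma_draws[:, i, j]
    geweke = {name: _geweke_z(series) for name, series in monitor.items()}
    bad = {k: v for k, v in geweke.items() if abs(v) > 2}
    if bad:
        warnings.warn(f"Geweke |z| > 2 for {sorted(bad)}: chain may not have converged",
                      stacklevel=2)

    roles = column_roles or {c: "trait" for c in y.columns}
    return JointFit(
        b_draws=b_draws,
        sigma_draws=sigma_draws,
        responses=list(y.columns),
        design_columns=list(x_frame.columns),
        column_roles=roles,
        mcmc=mcmc,
        geweke_z=geweke,
    )


def residual_correlations(fit: JointFit) -> pd.DataFrame:
    """Posterior-mean residual correlation matrix (unit diagonal, symmetric).

    Each Sigma draw is converted to a correlation matrix before averaging.
    """
    if fit.n_draws < 100:
        raise ValueError(f"need >= 100 retained draws, have {fit.n_draws}")
    sd = np.sqrt(np.diagonal(fit.sigma_draws, axis1=1, axis2=2))
    corr = fit.sigma_draws / (sd[:, :, None] * sd[:, None, :])
    mean_corr = corr.mean(axis=0)
    mean_corr = (mean_corr + mean_corr.T) / 2.0
    np.fill_diagonal(mean_corr, 1.0)
    return pd.DataFrame(mean_corr, index=fit.responses, columns=fit.responses)


CONTRASTS = {
    # name -> coefficient weights over (soil_natural, striga_infected, interaction)
    "h1_striga_in_sterilized": (0.0, 1.0, 0.0),
    "h1_striga_in_natural": (0.0, 1.0, 1.0),
    "h2_soil_in_control": (1.0, 0.0, 0.0),
    "h2_soil_in_infected": (1.0, 0.0, 1.0),
}


def contrast_h1_h2(fit: JointFit) -> pd.DataFrame:
    """Per-response treatment contrasts with 95% credible intervals.

    H1: the Striga effect within each soil type.  H2: the soil effect within
    each Striga treatment.  Under the 0/1 coding these are sums of the
    marginal and interaction coefficients.
    """
    cols = fit.design_columns
    idx = {name: cols.index(name) for name in ("soil_natural", "striga_infected", "interaction")}
    rows = []
    for name, (w_soil, w_striga, w_int) in CONTRASTS.items():
        effect = (
            w_soil * fit.b_draws[:, idx["soil_natural"], :]
            + w_striga * fit.b_draws[:, idx["striga_infected"], :]
            + w_int * fit.b_draws[:, idx["interaction"], :]
        )  # (n_draws, q)
        lo, hi = np.percentile(effect, [2.5, 97.5], axis=0)
        for j, response in enumerate(fit.responses):
            rows.append(
                {
                    "response": response,
                    "contrast": name,
                    "mean": float(effect[:, j].mean()),
                    "ci_lower": float(lo[j]),
                    "ci_upper": float(hi[j]),
                    "p_positive": float((effect[:, j] > 0).mean()),
                }
            )
    return pd.DataFrame(rows)


def fit_bundle(
    taxa_table: TaxaCountTable,
    trait_table: TraitTable,
    sub_category: str,
    timepoint: str,
    traits: list[str],
    prior: Prior | None = None,
    mcmc: McmcSettings | None = None,
    min_prevalence: float = 0.2,
    max_taxa: int = 100,
    pseudocount: float = 0.5,
) -> JointFit:
    """Fit one sub-category x timepoint bundle on CLR taxa plus given traits."""
    taxa_sub = filter_taxa(
        taxa_table.subset(sub_category, timepoint), min_prevalence, max_taxa
    )
    traits_sub = trait_table.subset(sub_category, timepoint)
    missing = [t for t in traits if t not in traits_sub.values.columns]
    if missing:
        raise ValueError(
            f"traits {missing} not measured in {sub_category}/{timepoint}"
        )
    clr = clr_transform(taxa_sub.counts, pseudocount=pseudocount)
    trait_values = traits_sub.values[traits].loc[clr.index]
    y = pd.concat([clr, trait_values], axis=1)
    roles = {c: "taxon" for c in clr.columns}
    roles.update({t: "trait" for t in traits})
    design = build_design(taxa_sub.metadata)
    return gibbs_fit(y, design, prior=prior, mcmc=mcmc, column_roles=roles)
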
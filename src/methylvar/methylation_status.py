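"""Classify genes as methylated vs unmethylated, by two routes.

Route A clusters gene-level weighted methylation with a two-component
Gaussian mixture (on the logit scale by default) and requires the
methylated call to hold in at least 85% of samples with data.

Route B follows the propensity approach used for invertebrate methylomes:
binarize each CpG x sample methylation fraction with 2-state kmeans, fit a
logistic random-intercept model (state ~ 1 + (1|gene)) to the binary
states, and call a gene methylated when its conditional-mode intercept u_g
exceeds 2.5 on the log-odds scale.  Applied per population, this yields the
FC and NC methylated gene sets and their population-specific differences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

log = logging.getLogger("methylvar")

KMEANS_SEED = 42


def _safe_logit(w: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    # logit((w + eps) / (1 + 2 eps)): defined on the closed interval [0, 1]
    z = (np.asarray(w, dtype=float) + eps) / (1.0 + 2.0 * eps)
    return special.logit(z)


# ---------------------------------------------------------------------------
# Route A: Gaussian mixture on gene-level weighted methylation
# ---------------------------------------------------------------------------


@dataclass
class MixtureFit:
    """Two-component 1-D Gaussian mixture; component 1 is the higher mean."""

    means: np.ndarray          # sorted ascending, shape (2,)
    sds: np.ndarray
    weights: np.ndarray
    use_logit: bool
    eps: float
    degenerate: bool = False
    threshold: float = field(default=np.nan)  # midpoint fallback, fit scale

    def _transform(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        return _safe_logit(values, self.eps) if self.use_logit else values

    def responsibilities(self, values) -> np.ndarray:
        """Posterior probabilities of (low, high) components, rows sum to 1."""
        x = self._transform(values)
        if self.degenerate:
            hi = (x > self.threshold).astype(float)
            return np.column_stack([1.0 - hi, hi])
        logp = (np.log(self.weights)
                + stats.norm.logpdf(x[:, None], self.means, self.sds))
        logp -= special.logsumexp(logp, axis=1, keepdims=True)
        return np.exp(logp)

    def posterior_methylated(self, values) -> np.ndarray:
        return self.responsibilities(values)[:, 1]


def fit_methylation_mixture(values, n_restarts: int = 5, tol: float = 1e-8,
                            max_iter: int = 500, use_logit: bool = True,
                            eps: float = 1e-3, seed: int = 0) -> MixtureFit:
    """EM fit of a two-component Gaussian mixture to methylation values.

    Values are logit-transformed by default (raw scale available via
    ``use_logit=False``).  Best of ``n_restarts`` EM runs; a fit with a
    vanishing component weight or coincident means falls back to a
    midpoint-threshold rule with a warning.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 20:
        raise ValueError("need at least 20 finite values to fit the mixture")
    x = _safe_logit(values, eps) if use_logit else values
    gm = GaussianMixture(n_components=2, covariance_type="spherical",
                         n_init=n_restarts, tol=tol, max_iter=max_iter,
                         random_state=seed, reg_covar=1e-10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm.fit(x[:, None])
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    weights = gm.weights_[order]
    fit = MixtureFit(means=means, sds=sds, weights=weights,
                     use_logit=use_logit, eps=eps)
    if weights.min() < 1e-3 or (means[1] - means[0]) < 1e-6:
        log.warning("degenerate mixture fit; falling back to midpoint threshold")
        fit.degenerate = True
        fit.threshold = float(means.mean())
    return fit


def call_methylated_genes_mixture(W: pd.DataFrame, consistency: float = 0.85,
                                  fit: MixtureFit | None = None,
                                  population: str = "pooled",
                                  **fit_kwargs) -> pd.DataFrame:
    """Mixture-based per-gene methylation calls with a consistency rule.

    The mixture is fitted on all finite gene x sample values pooled; a gene
    is methylated iff its posterior exceeds 0.5 in at least
    ceil(consistency * n_samples_with_data) samples.
    """
    vals = W.to_numpy(dtype=float)
    finite = np.isfinite(vals)
    if fit is None:
        fit = fit_methylation_mixture(vals[finite], **fit_kwargs)
    post = np.full(vals.shape, np.nan)
    post[finite] = fit.posterior_methylated(vals[finite])
    n_data = finite.sum(axis=1)
    n_meth = np.nansum(post > 0.5, axis=1).astype(int)
    needed = np.ceil(consistency * n_data).astype(int)
    call = (n_data > 0) & (n_meth >= np.maximum(needed, 1))
    with np.errstate(invalid="ignore"):
        score = np.nanmean(np.where(finite, post, np.nan), axis=1)
    return pd.DataFrame({
        "gene_id": W.index,
        "method": "mixture",
        "population": population,
        "score": score,
        "call": np.where(call, "methylated", "unmethylated"),
    }).set_index("gene_id")


# ---------------------------------------------------------------------------
# Route B: kmeans binarization + logistic random-intercept model
# ---------------------------------------------------------------------------


def binarize_cpgs_kmeans(percent_meth, seed: int = KMEANS_SEED,
                         n_init: int = 10) -> np.ndarray:
    """2-state kmeans on CpG methylation fractions; high cluster -> 1."""
    x = np.asarray(percent_meth, dtype=float)
    if np.isnan(x).any():
        raise ValueError("binarize_cpgs_kmeans requires finite values")
    if len(np.unique(x)) < 2:
        log.warning("all CpG fractions identical; returning all-unmethylated")
        return np.zeros(len(x), dtype=np.int8)
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed)
    labels = km.fit_predict(x[:, None])
    hi = int(np.argmax(km.cluster_centers_.ravel()))
    return (labels == hi).astype(np.int8)


@dataclass
class RandomInterceptFit:
    """Logistic random-intercept fit: state ~ 1 + (1|gene).

    ``u`` holds per-gene conditional modes (log-odds deviations from the
    global intercept), estimated with the marginal likelihood integrated by
    Gauss-Hermite quadrature.
    """

    u: pd.Series
    intercept: float
    sigma: float
    loglik: float
    converged: bool


def _glmm_neg_loglik(params, k, n, nodes, weights):
    beta0, log_sigma = params
    sigma = np.exp(log_sigma)
    eta = beta0 + np.sqrt(2.0) * sigma * nodes[None, :]  # (1, q)
    ll_obs = (k[:, None] * special.log_expit(eta)
              + (n - k)[:, None] * special.log_expit(-eta))
    lw = np.log(weights / np.sqrt(np.pi))
    return -float(np.sum(special.logsumexp(ll_obs + lw[None, :], axis=1)))


def fit_random_intercept_model(states, gene_labels, n_quad: int = 25,
                               max_newton: int = 100) -> RandomInterceptFit:
    """Fit state ~ 1 + (1|gene) to pooled binary CpG x sample observations.

    The binomial likelihood factorizes over genes given (beta0, sigma), so
    the marginal likelihood is a product of one-dimensional integrals,
    evaluated by Gauss-Hermite quadrature and maximized numerically.
    Conditional modes u_g then come from per-gene Newton steps.
    """
    states = np.asarray(states)
    if not np.isin(states, (0, 1)).all():
        raise ValueError("states must be binary")
    gene_labels = np.asarray(gene_labels)
    genes, codes = np.unique(gene_labels, return_inverse=True)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to fit a random intercept")
    k = np.bincount(codes, weights=states).astype(float)
    n = np.bincount(codes).astype(float)

    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    pbar = np.clip(states.mean(), 1e-6, 1 - 1e-6)
    x0 = np.array([special.logit(pbar), 0.0])
    # Bounds keep the fit identifiable when gene groups are perfectly
    # separated (all-0 vs all-1 states), where beta0 and sigma otherwise
    # run away together without changing the conditional modes' ordering.
    res = optimize.minimize(_glmm_neg_loglik, x0,
                            args=(k, n, nodes, weights),
                            method="L-BFGS-B",
                            bounds=[(-15.0, 15.0), (np.log(0.05), np.log(8.0))],
                            options={"maxiter": 500})
    if not res.success:
        raise RuntimeError(f"random-intercept fit did not converge: {res.message}")
    beta0, sigma = res.x[0], float(np.exp(res.x[1]))

    # Conditional modes: maximize k*log mu + (n-k)*log(1-mu) - u^2/(2 sigma^2)
    u = np.zeros(len(genes))
    for _ in range(max_newton):
        mu = special.expit(beta0 + u)
        grad = k - n * mu - u / sigma**2
        hess = -n * mu * (1 - mu) - 1.0 / sigma**2
        step = np.clip(grad / hess, -4.0, 4.0)  # damped: plain Newton can
        u -= step                               # overshoot on flat logistic tails
        if np.max(np.abs(step)) < 1e-10:
            break
    return RandomInterceptFit(
        u=pd.Series(u, index=pd.Index(genes, name="gene_id"), name="u"),
        intercept=float(beta0), sigma=sigma,
        loglik=-res.fun, converged=bool(res.success))


def call_methylated_genes_intercept(u: pd.Series, threshold: float = 2.5,
                                    population: str = "pooled") -> pd.DataFrame:
    """Call a gene methylated iff its random intercept u_g > threshold."""
    u = u.astype(float)
    if not np.isfinite(u.to_numpy()).all():
        raise ValueError("non-finite intercepts")
    return pd.DataFrame({
        "gene_id": u.index,
        "method": "random_intercept",
        "population": population,
        "score": u.to_numpy(),
        "call": np.where(u.to_numpy() > threshold, "methylated",
                         "unmethylated"),
    }).set_index("gene_id")


def methylated_set(calls: pd.DataFrame) -> set:
    return set(calls.index[calls["call"] == "methylated"])


def intercept_calls_per_population(matrix, mapping, design,
                                   threshold: float = 2.5,
                                   kmeans_seed: int = KMEANS_SEED) -> dict:
    """Run binarization + random-intercept classification per population.

    Binary observations are CpG x sample methylation fractions of that
    population's WGBS samples, pooled across environments and blocks.
    Returns {population: calls frame} plus the fits under key "_fits".
    """
    frac = matrix.fractions()
    site_idx = mapping["site_idx"].to_numpy()
    gene_ids = mapping["gene_id"].to_numpy()
    out: dict = {"_fits": {}}
    wgbs = design[design["assay"] == "WGBS"]
    for pop, sub in wgbs.groupby("population"):
        cols = [matrix.samples.index(s) for s in sub["sample_id"]]
        f = frac[np.ix_(site_idx, cols)]          # (n_obs_sites, n_samples)
        genes_rep = np.repeat(gene_ids, len(cols))
        f_flat = f.ravel()
        keep = np.isfinite(f_flat)
        states = binarize_cpgs_kmeans(f_flat[keep], seed=kmeans_seed)
        fit = fit_random_intercept_model(states, genes_rep[keep])
        out["_fits"][pop] = fit
        out[pop] = call_methylated_genes_intercept(fit.u, threshold,
                                                   population=pop)
    return out


def population_specific_sets(fc_calls: set, nc_calls: set,
                             universe: set) -> dict:
    """Partition the gene universe into shared / FC_only / NC_only / neither."""
    fc_calls, nc_calls, universe = set(fc_calls), set(nc_calls), set(universe)
    if not fc_calls <= universe or not nc_calls <= universe:
        raise ValueError("call sets extend beyond the shared gene universe")
    shared = fc_calls & nc_calls
    return {
        "shared": shared,
        "FC_only": fc_calls - nc_calls,
        "NC_only": nc_calls - fc_calls,
        "neither": universe - (fc_calls | nc_calls),
    }
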
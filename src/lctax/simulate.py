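"""Synthetic data generators: prototypical taxonic / dimensional indicator
matrices and latent-class datasets with covariate-driven membership.

Two latent structures are emulated. The taxonic generator draws a two-group
mixture with a stated base rate ``P`` and a standardized between-group
separation ``d`` on every indicator; the dimensional generator draws a
one-factor model with common loading ``lambda``. Both are discretized to
ordered categories with equal-frequency thresholds computed on the pooled
sample, so the two structures share marginal shapes — the property the
comparison-data logic of taxometric analysis relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import CategoricalDataset, IndicatorMatrix


@dataclass
class TaxonicSpec:
    """Two-group mixture spec: N, base rate, #indicators, separation d,
    within-group equicorrelation, and ordered category count."""

    n_cases: int = 600
    base_rate: float = 0.5
    n_indicators: int = 4
    separation: float = 2.0
    within_r: float = 0.0
    n_categories: int = 4
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.base_rate < 1:
            raise ValueError("base_rate must be in (0, 1)")
        if self.separation < 0:
            raise ValueError("separation d must be >= 0")
        if not 0 <= self.within_r <= 0.95:
            raise ValueError("within_r must be in [0, 0.95]")
        if self.n_categories < 2:
            raise ValueError("need at least 2 ordered categories")
        if self.n_indicators < 2:
            raise ValueError("need at least 2 indicators")


@dataclass
class DimensionalSpec:
    """One-factor spec: N, #indicators, common loading, ordered category count."""

    n_cases: int = 600
    n_indicators: int = 4
    loading: float = 0.7
    n_categories: int = 4
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.loading < 1:
            raise ValueError("loading must be in [0, 1)")
        if self.n_categories < 2:
            raise ValueError("need at least 2 ordered categories")

    @property
    def implied_correlation(self) -> float:
        return self.loading**2


@dataclass
class LCAGenSpec:
    """Latent-class generator spec: either fixed class proportions or a
    multinomial-logit covariate model for class membership."""

    n_cases: int
    n_classes: int
    item_probs: np.ndarray  # (C, K, M_max), padded rows sum to 1 over valid cats
    n_categories: np.ndarray  # (K,)
    class_probs: np.ndarray | None = None  # (C,)
    logit_intercepts: np.ndarray | None = None  # (C-1,) vs reference last class
    logit_slopes: np.ndarray | None = None  # (C-1, P)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.item_probs = np.asarray(self.item_probs, dtype=float)
        self.n_categories = np.asarray(self.n_categories, dtype=np.int64)
        has_pi = self.class_probs is not None
        has_logit = self.logit_intercepts is not None
        if has_pi == has_logit:
            raise ValueError("give exactly one of class_probs or a covariate model")
        if has_pi:
            self.class_probs = np.asarray(self.class_probs, dtype=float)
            if abs(self.class_probs.sum() - 1) > 1e-8:
                raise ValueError("class_probs must sum to 1")
        else:
            self.logit_intercepts = np.atleast_1d(
                np.asarray(self.logit_intercepts, dtype=float))
            self.logit_slopes = np.atleast_2d(
                np.asarray(self.logit_slopes, dtype=float))


def _equicorr_cholesky(k: int, r: float) -> np.ndarray:
    cov = np.full((k, k), r)
    np.fill_diagonal(cov, 1.0)
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"equicorrelation {r} is infeasible for k={k}") from exc


def _discretize_equal_frequency(latent: np.ndarray, n_categories: int) -> np.ndarray:
    """Pooled equal-frequency discretization to codes 1..C_ord, per column."""
    n, k = latent.shape
    qs = np.linspace(0, 1, n_categories + 1)[1:-1]
    out = np.empty((n, k), dtype=np.int64)
    for j in range(k):
        cuts = np.quantile(latent[:, j], qs)
        out[:, j] = 1 + np.searchsorted(cuts, latent[:, j], side="left")
    return out


def make_taxonic(
    spec: TaxonicSpec, return_latent: bool = False
) -> tuple[IndicatorMatrix, np.ndarray] | tuple[IndicatorMatrix, np.ndarray, np.ndarray]:
    """Generate prototypical taxonic (two-group mixture) ordinal indicators.

    Returns the indicator matrix and the true group labels (1 = taxon); labels
    (and, on request, the pre-discretization latent scores) are for validation
    only and never feed back into any analysis.
    """
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_cases, spec.n_indicators
    groups = (rng.random(n) < spec.base_rate).astype(np.int64)
    chol = _equicorr_cholesky(k, spec.within_r)
    latent = rng.standard_normal((n, k)) @ chol.T
    latent += spec.separation * groups[:, None]
    codes = _discretize_equal_frequency(latent, spec.n_categories)
    mat = IndicatorMatrix(codes.astype(float))
    if return_latent:
        return mat, groups, latent
    return mat, groups


def make_dimensional(spec: DimensionalSpec) -> IndicatorMatrix:
    """Generate prototypical dimensional (one-factor) ordinal indicators."""
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_cases, spec.n_indicators
    f = rng.standard_normal(n)
    e = rng.standard_normal((n, k))
    latent = spec.loading * f[:, None] + np.sqrt(1 - spec.loading**2) * e
    codes = _discretize_equal_frequency(latent, spec.n_categories)
    return IndicatorMatrix(codes.astype(float))


def discretization_attenuation(n_categories: int) -> float:
    """Linearized attenuation of a bivariate-normal correlation under
    equal-frequency discretization to ``n_categories`` ordered codes.

    The category code is a step function of the latent normal score; to first
    order in r the code correlation is the latent correlation times
    ``(sum of the normal density at the thresholds)^2 / var(code)``.
    (About 0.86 for four categories; tends to 1 as categories grow fine.)
    """
    from scipy.stats import norm

    qs = np.linspace(0, 1, n_categories + 1)[1:-1]
    var_code = (n_categories**2 - 1) / 12.0
    return float(norm.pdf(norm.ppf(qs)).sum() ** 2 / var_code)


def match_dimensional_to_taxonic(tax: IndicatorMatrix,
                                 seed: int | None = None) -> DimensionalSpec:
    """Spec for one-factor data whose realized average inter-indicator
    correlation matches the taxonic dataset's observed average correlation.

    Under a common loading ``lambda`` the latent correlation is ``lambda**2``;
    because both datasets are discretized to equal-frequency categories, the
    loading is inflated by the discretization attenuation factor so the
    *discretized* correlations, not just the latent ones, line up.
    """
    r = tax.correlation_matrix()
    k = r.shape[0]
    off = r[~np.eye(k, dtype=bool)]
    mean_r = float(off.mean())
    if mean_r <= 0:
        raise ValueError("taxonic data show no positive average correlation to match")
    n_categories = int(np.max([np.unique(tax.scores[:, j]).size
                               for j in range(k)]))
    latent_r = min(mean_r / discretization_attenuation(n_categories), 0.95)
    return DimensionalSpec(
        n_cases=tax.n_cases,
        n_indicators=k,
        loading=float(np.sqrt(latent_r)),
        n_categories=n_categories,
        seed=seed,
    )


def make_lca_data(spec: LCAGenSpec) -> tuple[CategoricalDataset, np.ndarray]:
    """Generate categorical responses from a latent class model.

    With a covariate model, one standard-normal covariate per slope column is
    drawn and class membership follows a multinomial logit (last class is the
    reference); otherwise membership is drawn from fixed class proportions.
    Returns the dataset and the true class labels (0-based).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cases
    c = spec.n_classes
    covariates = None
    if spec.class_probs is not None:
        classes = rng.choice(c, size=n, p=spec.class_probs)
    else:
        p_cov = spec.logit_slopes.shape[1]
        covariates = rng.standard_normal((n, p_cov))
        eta = np.zeros((n, c))
        eta[:, :-1] = spec.logit_intercepts[None, :] + covariates @ spec.logit_slopes.T
        eta -= eta.max(axis=1, keepdims=True)
        probs = np.exp(eta)
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng.random(n)
        classes = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
    k = spec.item_probs.shape[1]
    responses = np.empty((n, k), dtype=np.int64)
    u = rng.random((n, k))
    for j in range(k):
        m = int(spec.n_categories[j])
        cdf = np.cumsum(spec.item_probs[:, j, :m], axis=1)
        responses[:, j] = 1 + (u[:, j, None] > cdf[classes]).sum(axis=1)
    np.clip(responses, 1, spec.n_categories[None, :], out=responses)
    data = CategoricalDataset(responses, covariates=covariates)
    return data, classes


def binary_item_probs(theta_high: float, theta_low: float, n_items: int) -> np.ndarray:
    """Convenience: 2-class binary-item profile array, class 1 endorsing high."""
    theta = np.zeros((2, n_items, 2))
    theta[0, :, 0] = theta_high
    theta[0, :, 1] = 1 - theta_high
    theta[1, :, 0] = theta_low
    theta[1, :, 1] = 1 - theta_low
    return theta
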
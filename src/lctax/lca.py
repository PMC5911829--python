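"""Latent class measurement model: EM estimation, posteriors, classification.

The model is an unrestricted finite mixture for categorical items: a case in
class ``c`` answers item ``k`` with category ``m`` with probability
``theta[c, k, m]``, items independent given the class (local independence).
Estimation is maximum likelihood by EM on the table of unique response
patterns; multiple random starts are run simultaneously as one batched
computation, and the same batching is reused to refit models on hundreds of
parametric-bootstrap replicates at once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .datasets import CategoricalDataset

log = logging.getLogger(__name__)

PROB_FLOOR = 1e-10


@dataclass
class LCAParameters:
    """Mixture parameters: class proportions and class-specific item profiles.

    ``item_probs`` is stored padded to the largest category count; entries for
    categories an item does not have are zero and carry no probability mass.
    """

    n_classes: int
    class_probs: np.ndarray  # (C,)
    item_probs: np.ndarray  # (C, K, M_max)
    n_categories: np.ndarray  # (K,)

    def __post_init__(self) -> None:
        self.class_probs = np.asarray(self.class_probs, dtype=float)
        self.item_probs = np.asarray(self.item_probs, dtype=float)
        self.n_categories = np.asarray(self.n_categories, dtype=np.int64)
        if abs(self.class_probs.sum() - 1.0) > 1e-8:
            raise ValueError("class probabilities must sum to 1")
        for k, m in enumerate(self.n_categories):
            rows = self.item_probs[:, k, :m]
            if np.any(np.abs(rows.sum(axis=1) - 1.0) > 1e-8):
                raise ValueError(f"item {k} conditional probabilities must sum to 1")


@dataclass
class ClassificationErrorMatrix:
    """D[c, s] = p(assigned class W = s | true class X = c), plus the overall error."""

    D: np.ndarray
    overall_error: float


@dataclass
class LCAFit:
    parameters: LCAParameters
    log_likelihood: float
    n_params: int
    bic: float
    l2: float
    entropy_r2: float
    posteriors: np.ndarray  # (N, C)
    converged: bool
    n_starts_used: int
    seed: int | None
    n_cases: int
    n_iter: int = 0
    ll_history: np.ndarray | None = field(default=None, repr=False)


def _onehot_patterns(patterns: np.ndarray, n_categories: np.ndarray) -> np.ndarray:
    """Encode unique patterns (P, K) of 1-based codes as one-hot (P, K, M_max)."""
    p, k = patterns.shape
    m_max = int(n_categories.max())
    out = np.zeros((p, k, m_max))
    rows = np.arange(p)[:, None]
    cols = np.arange(k)[None, :]
    out[rows, cols, patterns - 1] = 1.0
    return out


def _init_params(rng: np.random.Generator, b: int, s: int, c: int,
                 n_categories: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Dirichlet(1) random starts for class and item probabilities."""
    k = len(n_categories)
    m_max = int(n_categories.max())
    pi = rng.dirichlet(np.ones(c), size=(b, s))
    theta = np.zeros((b, s, c, k, m_max))
    for j, m in enumerate(n_categories):
        draw = rng.dirichlet(np.ones(int(m)), size=(b, s, c))
        theta[:, :, :, j, : int(m)] = draw
    return pi, theta


def _em_batch(
    onehot: np.ndarray,
    counts: np.ndarray,
    n_classes: int,
    n_starts: int,
    n_categories: np.ndarray,
    rng: np.random.Generator,
    tol: float = 1e-8,
    max_iter: int = 5000,
    record_history: bool = False,
) -> dict:
    """Run EM from ``n_starts`` random starts on a batch of count vectors.

    ``counts`` has shape (B, P): B datasets sharing one pattern space. All
    B*n_starts chains advance together in vectorized numpy operations, so
    bootstrap refits cost little more than a single fit.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    b, p = counts.shape
    c = n_classes
    n_per = counts.sum(axis=1)  # (B,)
    valid = np.zeros(onehot.shape[1:], dtype=bool)  # (K, M_max)
    for j, m in enumerate(n_categories):
        valid[j, : int(m)] = True

    pi, theta = _init_params(rng, b, n_starts, c, n_categories)
    log_theta = np.where(theta > 0, np.log(np.maximum(theta, PROB_FLOOR)), 0.0)

    ll = np.full((b, n_starts), -np.inf)
    converged = np.zeros((b, n_starts), dtype=bool)
    history: list[np.ndarray] = []
    it = 0
    for it in range(1, max_iter + 1):
        # E-step in log space
        logdens = np.einsum("pkm,bsckm->bscp", onehot, log_theta)
        joint = logdens + np.log(np.maximum(pi, PROB_FLOOR))[..., None]  # (B,S,C,P)
        ll_pat = logsumexp(joint, axis=2)  # (B, S, P)
        new_ll = np.einsum("bp,bsp->bs", counts, ll_pat)
        z = np.exp(joint - ll_pat[:, :, None, :])  # posterior (B,S,C,P)
        if record_history:
            history.append(new_ll.copy())
        with np.errstate(invalid="ignore"):
            rel = np.where(np.isfinite(ll),
                           np.abs(new_ll - ll) / (np.abs(ll) + 1.0), np.inf)
        converged = rel < tol
        ll = new_ll
        if converged.all():
            break
        # M-step
        nz = z * counts[:, None, None, :]  # expected pattern counts per class
        class_tot = nz.sum(axis=3)  # (B, S, C)
        pi = class_tot / n_per[:, None, None]
        theta = np.einsum("bscp,pkm->bsckm", nz, onehot)
        theta = np.maximum(theta, PROB_FLOOR) * valid  # smooth, keep padding at 0
        theta = theta / np.maximum(theta.sum(axis=4, keepdims=True), PROB_FLOOR)
        log_theta = np.where(theta > 0, np.log(np.maximum(theta, PROB_FLOOR)), 0.0)

    best = np.argmax(ll, axis=1)  # (B,)
    rows = np.arange(b)
    return {
        "class_probs": pi[rows, best],
        "item_probs": theta[rows, best],
        "log_likelihood": ll[rows, best],
        "converged": converged[rows, best],
        "n_iter": it,
        "ll_history": np.stack(history, axis=-1) if history else None,
    }


def _canonical_order(class_probs: np.ndarray, item_probs: np.ndarray) -> np.ndarray:
    """Sort classes by descending size; break ties on item 1 category 1 probability."""
    order = np.lexsort((-item_probs[:, 0, 0], -np.round(class_probs, 12)))
    return order


def fit_lca(
    data: CategoricalDataset,
    n_classes: int,
    n_starts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 5000,
    seed: int | None = None,
) -> LCAFit:
    """Fit a C-class latent class model by multi-start EM.

    Returns the best start by final log-likelihood with classes relabeled into
    canonical order (largest first). A fit in which no start converged is
    flagged ``converged=False`` but still returned.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    patterns, counts, index = data.pattern_table()
    if n_classes > patterns.shape[0]:
        raise ValueError("model not identifiable: more classes than distinct patterns")
    n_categories = data.n_categories
    onehot = _onehot_patterns(patterns, n_categories)
    rng = np.random.default_rng(seed)

    if n_classes == 1:
        # closed form: marginal category frequencies
        m_max = int(n_categories.max())
        theta = np.zeros((1, data.n_items, m_max))
        freq = np.einsum("p,pkm->km", counts.astype(float), onehot) / data.n_cases
        theta[0] = np.maximum(freq, 0.0)
        theta[0] = theta[0] / np.maximum(theta[0].sum(axis=1, keepdims=True), PROB_FLOOR)
        log_theta = np.where(theta > 0, np.log(theta), 0.0)
        ll = float(np.einsum("p,pkm,km->", counts.astype(float), onehot, log_theta[0]))
        params = LCAParameters(1, np.array([1.0]), theta, n_categories)
        post = np.ones((data.n_cases, 1))
        npar = int(np.sum(n_categories - 1))
        fit = LCAFit(
            parameters=params,
            log_likelihood=ll,
            n_params=npar,
            bic=-2 * ll + npar * np.log(data.n_cases),
            l2=0.0,
            entropy_r2=1.0,
            posteriors=post,
            converged=True,
            n_starts_used=1,
            seed=seed,
            n_cases=data.n_cases,
        )
        fit.l2 = l2_statistic(fit, data)
        return fit

    res = _em_batch(
        onehot, counts[None, :], n_classes, n_starts, n_categories, rng,
        tol=tol, max_iter=max_iter,
    )
    pi = res["class_probs"][0]
    theta = res["item_probs"][0]
    order = _canonical_order(pi, theta)
    pi, theta = pi[order], theta[order]
    params = LCAParameters(n_classes, pi, theta, n_categories)
    post_pat = _posterior_patterns(params, onehot)
    post = post_pat[index]
    npar = int((n_classes - 1) + n_classes * np.sum(n_categories - 1))
    ll = float(res["log_likelihood"][0])
    fit = LCAFit(
        parameters=params,
        log_likelihood=ll,
        n_params=npar,
        bic=-2 * ll + npar * np.log(data.n_cases),
        l2=0.0,
        entropy_r2=entropy_r2(post, pi),
        posteriors=post,
        converged=bool(res["converged"][0]),
        n_starts_used=n_starts,
        seed=seed,
        n_cases=data.n_cases,
        n_iter=res["n_iter"],
    )
    if not fit.converged:
        log.warning("no EM start converged within %d iterations", max_iter)
    fit.l2 = l2_statistic(fit, data)
    return fit


def _log_pattern_density(params: LCAParameters, onehot: np.ndarray) -> np.ndarray:
    """log p(pattern | class) for each unique pattern: (P, C)."""
    log_theta = np.where(params.item_probs > 0,
                         np.log(np.maximum(params.item_probs, PROB_FLOOR)), 0.0)
    return np.einsum("pkm,ckm->pc", onehot, log_theta)


def _posterior_patterns(params: LCAParameters, onehot: np.ndarray) -> np.ndarray:
    logdens = _log_pattern_density(params, onehot)
    joint = logdens + np.log(np.maximum(params.class_probs, PROB_FLOOR))
    tot = logsumexp(joint, axis=1, keepdims=True)
    if not np.isfinite(tot).all():
        raise ValueError("pattern has zero likelihood")
    return np.exp(joint - tot)


def posterior(params: LCAParameters, data: CategoricalDataset) -> np.ndarray:
    """Posterior class-membership probabilities p(X=c | Y=y_i), one row per case."""
    if data.n_items != params.item_probs.shape[1]:
        raise ValueError("item count mismatch between parameters and data")
    if np.any(data.n_categories > params.n_categories):
        raise ValueError("data contain category codes outside the model's range")
    patterns, _, index = data.pattern_table()
    onehot = _onehot_patterns(patterns, params.n_categories)
    return _posterior_patterns(params, onehot)[index]


def assign(posteriors: np.ndarray, method: str = "modal") -> np.ndarray:
    """Turn posteriors into class-assignment weights.

    ``modal`` gives one-hot rows at the largest posterior (ties to the lowest
    class index); ``proportional`` keeps the posterior weights (soft
    partitioning).
    """
    posteriors = np.asarray(posteriors, dtype=float)
    if method == "proportional":
        return posteriors.copy()
    if method == "modal":
        w = np.zeros_like(posteriors)
        w[np.arange(len(posteriors)), np.argmax(posteriors, axis=1)] = 1.0
        return w
    raise ValueError(f"unknown assignment method: {method!r}")


def classification_error(
    posteriors: np.ndarray, assignment: np.ndarray, class_probs: np.ndarray
) -> ClassificationErrorMatrix:
    """Misclassification probabilities D[c,s] = p(W=s | X=c) and the overall CE.

    Averages posterior-weighted assignment weights over cases and conditions on
    the class size; the overall error is one minus the class-probability-
    weighted trace of D.
    """
    posteriors = np.asarray(posteriors, dtype=float)
    assignment = np.asarray(assignment, dtype=float)
    class_probs = np.asarray(class_probs, dtype=float)
    if posteriors.shape != assignment.shape:
        raise ValueError("posteriors and assignment shapes differ")
    if np.any(class_probs < 1e-12):
        raise ValueError("empty class")
    n = posteriors.shape[0]
    d = (posteriors.T @ assignment) / (n * class_probs[:, None])
    ce = 1.0 - float(np.sum(class_probs * np.diag(d)))
    return ClassificationErrorMatrix(D=d, overall_error=ce)


def entropy_r2(posteriors: np.ndarray, class_probs: np.ndarray) -> float:
    """Entropy pseudo-R²: proportional reduction in classification entropy.

    1 minus the mean posterior entropy over cases divided by the entropy of
    the marginal class distribution; natural log, with 0*log(0) = 0.
    """
    posteriors = np.asarray(posteriors, dtype=float)
    class_probs = np.asarray(class_probs, dtype=float)
    if len(class_probs) == 1:
        log.warning("entropy R² is degenerate for a one-class model; returning 1.0")
        return 1.0

    def _ent(p: np.ndarray) -> np.ndarray:
        terms = np.where(p > 0, p * np.log(np.maximum(p, 1e-300)), 0.0)
        return -terms.sum(axis=-1)

    prior = _ent(class_probs)
    if prior <= 0:
        return 1.0
    return float(1.0 - _ent(posteriors).mean() / prior)


def l2_statistic(fit: LCAFit, data: CategoricalDataset) -> float:
    """Likelihood-ratio chi-square of the fit against the saturated pattern table."""
    patterns, counts, _ = data.pattern_table()
    onehot = _onehot_patterns(patterns, fit.parameters.n_categories)
    logdens = _log_pattern_density(fit.parameters, onehot)
    logp = logsumexp(
        logdens + np.log(np.maximum(fit.parameters.class_probs, PROB_FLOOR)), axis=1
    )
    n = data.n_cases
    l2 = 2.0 * float(np.sum(counts * (np.log(counts / n) - logp)))
    return max(l2, 0.0)


def simulate_from_params(
    params: LCAParameters, n_cases: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw an (N, K) response matrix from fitted mixture parameters."""
    c = params.n_classes
    classes = rng.choice(c, size=n_cases, p=params.class_probs)
    k = params.item_probs.shape[1]
    out = np.empty((n_cases, k), dtype=np.int64)
    u = rng.random((n_cases, k))
    for j in range(k):
        m = int(params.n_categories[j])
        cdf = np.cumsum(params.item_probs[:, j, :m], axis=1)  # (C, m)
        out[:, j] = 1 + (u[:, j, None] > cdf[classes]).sum(axis=1)
    np.clip(out, 1, params.n_categories[None, :], out=out)
    return out


def bootstrap_lrt(
    data: CategoricalDataset,
    c_null: int,
    c_alt: int,
    n_boot: int = 99,
    seed: int | None = None,
    n_starts: int = 8,
    boot_n_starts: int = 4,
    tol: float = 1e-7,
    max_iter: int = 1000,
) -> dict:
    """Parametric (conditional) bootstrap test of C vs C+1 classes.

    The observed statistic is the drop in L² (equivalently twice the gain in
    log-likelihood) from adding one class. ``n_boot`` datasets are simulated
    from the fitted null model, both models are refit on each, and the p-value
    is ``(1 + #{boot >= observed}) / (n_kept + 1)``.
    """
    if c_alt != c_null + 1:
        raise ValueError("bootstrap LRT is defined for c_alt = c_null + 1")
    if n_boot < 19:
        raise ValueError("need at least 19 bootstrap replicates")
    rng = np.random.default_rng(seed)
    fit0 = fit_lca(data, c_null, n_starts=n_starts, tol=tol, max_iter=max_iter,
                   seed=int(rng.integers(2**31)))
    fit1 = fit_lca(data, c_alt, n_starts=n_starts, tol=tol, max_iter=max_iter,
                   seed=int(rng.integers(2**31)))
    observed = 2.0 * (fit1.log_likelihood - fit0.log_likelihood)

    # simulate all replicates, express them in one shared pattern space
    n = data.n_cases
    sims = [simulate_from_params(fit0.parameters, n, rng) for _ in range(n_boot)]
    all_rows = np.vstack(sims)
    patterns, inverse = np.unique(all_rows, axis=0, return_inverse=True)
    inverse = inverse.reshape(n_boot, n)
    p = patterns.shape[0]
    counts = np.zeros((n_boot, p))
    for b in range(n_boot):
        counts[b] = np.bincount(inverse[b], minlength=p)
    n_categories = np.maximum(data.n_categories, patterns.max(axis=0))
    onehot = _onehot_patterns(patterns, n_categories)

    stats = np.full(n_boot, np.nan)
    ok = np.zeros(n_boot, dtype=bool)
    if c_null == 1:
        # closed form for the null refit
        freq = counts @ onehot.reshape(p, -1)
        freq = freq.reshape(n_boot, *onehot.shape[1:])
        theta = freq / n
        log_theta = np.where(theta > 0, np.log(np.maximum(theta, PROB_FLOOR)), 0.0)
        ll0 = np.einsum("bp,pkm,bkm->b", counts, onehot, log_theta)
        ok0 = np.ones(n_boot, dtype=bool)
    else:
        res0 = _em_batch(onehot, counts, c_null, boot_n_starts, n_categories, rng,
                         tol=tol, max_iter=max_iter)
        ll0 = res0["log_likelihood"]
        ok0 = res0["converged"]
    res1 = _em_batch(onehot, counts, c_alt, boot_n_starts, n_categories, rng,
                     tol=tol, max_iter=max_iter)
    stats = 2.0 * (res1["log_likelihood"] - ll0)
    ok = ok0 & res1["converged"]

    n_dropped = int((~ok).sum())
    if n_dropped > 0.2 * n_boot:
        log.warning("%d/%d bootstrap replicates did not converge", n_dropped, n_boot)
    kept = stats[ok]
    pval = (1.0 + float(np.sum(kept >= observed - 1e-12))) / (len(kept) + 1.0)
    return {
        "p_value": pval,
        "observed": observed,
        "bootstrap_stats": kept,
        "n_dropped": n_dropped,
        "fit_null": fit0,
        "fit_alt": fit1,
    }


def select_model(
    data: CategoricalDataset,
    c_range: list[int],
    n_starts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 5000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fit a sweep of class counts under one protocol and tabulate fit statistics."""
    rng = np.random.default_rng(seed)
    rows = []
    for c in sorted(c_range):
        sub_seed = int(rng.integers(2**31))
        try:
            fit = fit_lca(data, c, n_starts=n_starts, tol=tol, max_iter=max_iter,
                          seed=sub_seed)
            w = assign(fit.posteriors, "modal")
            ce = classification_error(fit.posteriors, w, fit.parameters.class_probs)
            rows.append({
                "n_classes": c,
                "log_likelihood": fit.log_likelihood,
                "n_params": fit.n_params,
                "bic": fit.bic,
                "l2": fit.l2,
                "entropy_r2": fit.entropy_r2,
                "classification_error": ce.overall_error,
                "converged": fit.converged,
                "error": "",
            })
        except ValueError as exc:
            rows.append({"n_classes": c, "error": str(exc)})
    return pd.DataFrame(rows)
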
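"""Relating latent class membership to covariates: one-step and three-step
estimation with BCH and ML corrections.

The three-step workflow fits the measurement model first, assigns cases to
classes (modally or proportionally), then regresses the assigned class on
covariates. The naive third step is downward-biased because assignment error
attenuates the class-covariate association. Two corrections are provided:

* BCH — reweight each case's class-assignment weights by the inverse of the
  classification-error matrix D, then run the same weighted multinomial logit
  on the corrected (possibly negative) weights with a sandwich variance.
* ML — treat the assigned class W as a single fallible indicator of the true
  class X with known error probabilities p(W=s|X=c) = D[c,s], and maximize the
  resulting marginal likelihood over the logit coefficients by EM.

The weighted multinomial logit is written in-house because the BCH weights can
be negative and the sandwich estimator must aggregate scores per case, which
off-the-shelf GLM routines do not support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import CategoricalDataset
from .lca import (
    LCAFit,
    LCAParameters,
    _onehot_patterns,
    assign,
    classification_error,
    entropy_r2,
    fit_lca,
    l2_statistic,
    posterior,
)

log = logging.getLogger(__name__)

COEF_CAP = 40.0


@dataclass
class StructuralModel:
    """Multinomial-logit coefficients for class membership given covariates.

    Coefficients are on the log-odds scale versus the reference class; the
    reference class's coefficients are identically zero and not stored. Rows
    of ``coefficients`` index the non-reference classes in order, columns are
    (intercept, covariate 1, ..., covariate P).
    """

    reference_class: int
    class_indices: list[int]  # non-reference classes, in coefficient row order
    coefficients: np.ndarray  # (C-1, P+1)
    se: np.ndarray  # (C-1, P+1)
    method: str
    se_type: str  # "model" | "sandwich"
    converged: bool
    separation: bool = False
    n_iter: int = 0
    covariate_labels: list[str] = field(default_factory=list)

    @property
    def z_values(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.se > 0, self.coefficients / self.se, np.nan)

    def tidy(self) -> pd.DataFrame:
        rows = []
        labels = ["intercept"] + (
            self.covariate_labels
            or [f"psi{j + 1}" for j in range(self.coefficients.shape[1] - 1)]
        )
        z = self.z_values
        for r, c in enumerate(self.class_indices):
            for j, lab in enumerate(labels):
                rows.append({
                    "class": c,
                    "covariate": lab,
                    "mean": self.coefficients[r, j],
                    "se": self.se[r, j],
                    "z": z[r, j],
                })
        return pd.DataFrame(rows)


def _design(covariates: np.ndarray) -> np.ndarray:
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.shape[0] == 1 and covariates.shape[1] > 1:
        covariates = covariates.T
    return np.column_stack([np.ones(covariates.shape[0]), covariates])


def _softmax_probs(xt: np.ndarray, b_full: np.ndarray) -> np.ndarray:
    eta = xt @ b_full.T  # (N, C)
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    return p


def _expand_b(b: np.ndarray, c: int, reference_class: int) -> np.ndarray:
    """Insert the zero row of the reference class: (C-1, q) -> (C, q)."""
    q = b.shape[1]
    full = np.zeros((c, q))
    rows = [i for i in range(c) if i != reference_class]
    full[rows] = b
    return full


def _fit_weighted_mnlogit(
    weights: np.ndarray,
    covariates: np.ndarray,
    reference_class: int = -1,
    max_iter: int = 200,
    tol: float = 1e-10,
    b_init: np.ndarray | None = None,
) -> dict:
    """Damped-Newton fit of the weighted multinomial logit.

    Maximizes sum_i sum_c w_ic log p(c | x_i). Weights may be negative (BCH);
    as long as each case's weights sum to ~1 the Hessian is the standard
    multinomial information and stays negative definite. Coefficients are
    capped at |40| and a separation flag raised if the cap binds.
    """
    weights = np.asarray(weights, dtype=float)
    n, c = weights.shape
    if reference_class < 0:
        reference_class = c + reference_class
    xt = _design(covariates)
    if xt.shape[0] != n:
        raise ValueError("assignment and covariates must be row-aligned")
    q = xt.shape[1]
    nonref = [i for i in range(c) if i != reference_class]
    eff = weights.sum(axis=0)
    if np.any(eff < q):
        raise ValueError("insufficient effective cases in a class")
    wplus = weights.sum(axis=1)  # ~1 per case

    b = np.zeros((c - 1, q)) if b_init is None else b_init.copy()

    def loglik(bmat: np.ndarray) -> tuple[float, np.ndarray]:
        p = _softmax_probs(xt, _expand_b(bmat, c, reference_class))
        ll = float(np.sum(weights * np.log(np.maximum(p, 1e-300))))
        return ll, p

    ll, p = loglik(b)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        resid = weights - wplus[:, None] * p  # (N, C)
        grad = (xt.T @ resid[:, nonref]).T.ravel()  # (C-1)*q
        # block Hessian of the negative log-likelihood
        h = np.zeros(((c - 1) * q, (c - 1) * q))
        for a, ca in enumerate(nonref):
            for d, cd in enumerate(nonref):
                wab = wplus * p[:, ca] * ((ca == cd) - p[:, cd])
                h[a * q:(a + 1) * q, d * q:(d + 1) * q] = xt.T @ (wab[:, None] * xt)
        ridge = 1e-10 * np.trace(h) / h.shape[0] + 1e-12
        try:
            delta = np.linalg.solve(h + ridge * np.eye(h.shape[0]), grad)
        except np.linalg.LinAlgError:
            delta = grad / (np.trace(h) / h.shape[0] + 1.0)
        step = 1.0
        for _ in range(30):
            b_new = np.clip(b + step * delta.reshape(c - 1, q), -COEF_CAP, COEF_CAP)
            ll_new, p_new = loglik(b_new)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        improved = ll_new - ll
        b, ll, p = b_new, ll_new, p_new
        if abs(improved) < tol * (abs(ll) + 1.0) and np.linalg.norm(grad) < 1e-5 * n:
            converged = True
            break
    separation = bool(np.any(np.abs(b) >= COEF_CAP - 1e-9))
    if separation:
        log.warning("separation detected: coefficients hit the %.0f cap", COEF_CAP)

    # information pieces at the solution
    resid = weights - wplus[:, None] * p
    h = np.zeros(((c - 1) * q, (c - 1) * q))
    for a, ca in enumerate(nonref):
        for d, cd in enumerate(nonref):
            wab = wplus * p[:, ca] * ((ca == cd) - p[:, cd])
            h[a * q:(a + 1) * q, d * q:(d + 1) * q] = xt.T @ (wab[:, None] * xt)
    scores = np.einsum("nc,nq->ncq", resid[:, nonref], xt).reshape(n, -1)
    return {
        "b": b,
        "loglik": ll,
        "hessian": h,  # observed information (negative Hessian of LL)
        "scores": scores,  # per-case score contributions
        "probs": p,
        "converged": converged,
        "separation": separation,
        "n_iter": it,
        "nonref": nonref,
        "reference_class": reference_class,
        "n_predictors": q - 1,
    }


def _se_from_fit(res: dict, sandwich: bool) -> np.ndarray:
    h = res["hessian"]
    hinv = np.linalg.pinv(h)
    if sandwich:
        meat = res["scores"].T @ res["scores"]
        cov = hinv @ meat @ hinv
    else:
        cov = hinv
    q = res["b"].shape[1]
    se = np.sqrt(np.maximum(np.diag(cov), 0.0)).reshape(-1, q)
    return se


def _structural_from_fit(res: dict, method: str, se_type: str,
                         covariate_labels: list[str] | None = None) -> StructuralModel:
    se = _se_from_fit(res, sandwich=(se_type == "sandwich"))
    return StructuralModel(
        reference_class=res["reference_class"],
        class_indices=res["nonref"],
        coefficients=res["b"],
        se=se,
        method=method,
        se_type=se_type,
        converged=res["converged"],
        separation=res["separation"],
        n_iter=res["n_iter"],
        covariate_labels=list(covariate_labels or []),
    )


def step3_naive(
    assignment: np.ndarray,
    covariates: np.ndarray,
    reference_class: int = -1,
    method_tag: str = "naive",
    covariate_labels: list[str] | None = None,
) -> StructuralModel:
    """Uncorrected third step: weighted multinomial logit of assigned class on
    covariates, case i contributing weight w_is to outcome s. Downward-biased
    when classification is imperfect."""
    res = _fit_weighted_mnlogit(assignment, covariates, reference_class)
    return _structural_from_fit(res, method_tag, "model", covariate_labels)


def bch_weights(assignment: np.ndarray, D: np.ndarray) -> np.ndarray:
    """BCH-corrected weights w*_ic = sum_s w_is (D^-1)[s,c].

    D[c,s] = p(W=s | X=c). Rows of the result sum to 1 (they inherit the row
    sums of the assignment through the inverse); entries may be negative.
    """
    assignment = np.asarray(assignment, dtype=float)
    D = np.asarray(D, dtype=float)
    if np.linalg.cond(D) > 1e8:
        raise ValueError("classification too poor for BCH inversion")
    return assignment @ np.linalg.inv(D)


def step3_bch(
    assignment: np.ndarray,
    D: np.ndarray,
    covariates: np.ndarray,
    reference_class: int = -1,
    method_tag: str = "bch",
    covariate_labels: list[str] | None = None,
) -> StructuralModel:
    """BCH-corrected third step with sandwich standard errors."""
    wstar = bch_weights(assignment, D)
    res = _fit_weighted_mnlogit(wstar, covariates, reference_class)
    if not res["converged"]:
        log.warning("BCH third step did not fully converge (negative weights); "
                    "final gradient norm reported in diagnostics")
    return _structural_from_fit(res, method_tag, "sandwich", covariate_labels)


def step3_ml(
    assignment: np.ndarray,
    D: np.ndarray,
    covariates: np.ndarray,
    reference_class: int = -1,
    max_iter: int = 500,
    tol: float = 1e-9,
    method_tag: str = "ml",
    covariate_labels: list[str] | None = None,
) -> StructuralModel:
    """ML-corrected third step.

    Treats the assigned class W as a single indicator of the true class X with
    fixed error probabilities p(W=s|X=c) = D[c,s] and maximizes the marginal
    likelihood sum_i sum_s w_is log sum_c p(X=c|psi_i) D[c,s] by EM; standard
    errors come from the observed information of this marginal likelihood.
    """
    assignment = np.asarray(assignment, dtype=float)
    D = np.asarray(D, dtype=float)
    n, c = assignment.shape
    if np.any(np.diag(D) <= 0):
        raise ValueError("class never correctly assigned")
    if reference_class < 0:
        reference_class = c + reference_class
    xt = _design(covariates)
    q = xt.shape[1]

    def marginal_ll_and_v(b: np.ndarray) -> tuple[float, np.ndarray]:
        p = _softmax_probs(xt, _expand_b(b, c, reference_class))  # p(X=c|psi)
        den = p @ D  # (N, S): p(W=s|psi)
        ll = float(np.sum(assignment * np.log(np.maximum(den, 1e-300))))
        # E-step responsibilities folded over observed W weights
        ratio = assignment / np.maximum(den, 1e-300)  # (N, S)
        v = p * (ratio @ D.T)  # (N, C): effective class weights
        return ll, v

    b = np.zeros((c - 1, q))
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll, v = marginal_ll_and_v(b)
        if abs(ll - ll_old) < tol * (abs(ll) + 1.0):
            converged = True
            break
        ll_old = ll
        inner = _fit_weighted_mnlogit(v, covariates, reference_class, b_init=b,
                                      max_iter=50)
        b = inner["b"]

    # observed information of the marginal likelihood by finite differences of
    # the analytic gradient v -> grad
    def grad_at(bvec: np.ndarray) -> np.ndarray:
        bb = bvec.reshape(c - 1, q)
        _, v = marginal_ll_and_v(bb)
        p = _softmax_probs(xt, _expand_b(bb, c, reference_class))
        resid = v - v.sum(axis=1, keepdims=True) * p
        nonref = [i for i in range(c) if i != reference_class]
        return (xt.T @ resid[:, nonref]).T.ravel()

    bvec = b.ravel()
    dim = bvec.size
    h = np.zeros((dim, dim))
    eps = 1e-5
    for j in range(dim):
        bp, bm = bvec.copy(), bvec.copy()
        bp[j] += eps
        bm[j] -= eps
        h[:, j] = (grad_at(bm) - grad_at(bp)) / (2 * eps)  # negative Hessian
    h = 0.5 * (h + h.T)
    cov = np.linalg.pinv(h)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0)).reshape(c - 1, q)
    nonref = [i for i in range(c) if i != reference_class]
    return StructuralModel(
        reference_class=reference_class,
        class_indices=nonref,
        coefficients=b,
        se=se,
        method=method_tag,
        se_type="model",
        converged=converged,
        separation=bool(np.any(np.abs(b) >= COEF_CAP - 1e-9)),
        n_iter=it,
        covariate_labels=list(covariate_labels or []),
    )


def fit_one_step(
    data: CategoricalDataset,
    n_classes: int,
    n_starts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 2000,
    seed: int | None = None,
    reference_class: int = -1,
) -> tuple[LCAFit, StructuralModel | None]:
    """Joint (one-step) estimation: class membership follows a multinomial
    logit in the covariates while the measurement model is fit simultaneously.

    Structural standard errors are taken from the observed information of the
    marginal likelihood with the measurement parameters held at their joint
    estimates (a profile approximation, noted in the methods documentation).
    """
    if n_classes == 1:
        return fit_lca(data, 1, seed=seed), None
    if data.covariates is None:
        raise ValueError("one-step estimation needs covariates")
    rng = np.random.default_rng(seed)
    patterns, counts, index = data.pattern_table()
    if n_classes > patterns.shape[0]:
        raise ValueError("model not identifiable: more classes than distinct patterns")
    n_categories = data.n_categories
    onehot_pat = _onehot_patterns(patterns, n_categories)
    onehot = onehot_pat[index]  # (N, K, M)
    n = data.n_cases
    c = n_classes
    xt = _design(data.covariates)
    q = xt.shape[1]
    if reference_class < 0:
        reference_class = c + reference_class
    valid = np.zeros(onehot.shape[1:], dtype=bool)
    for j, m in enumerate(n_categories):
        valid[j, : int(m)] = True

    best = None
    for _ in range(n_starts):
        theta = np.zeros((c,) + onehot.shape[1:])
        for j, m in enumerate(n_categories):
            theta[:, j, : int(m)] = rng.dirichlet(np.ones(int(m)), size=c)
        b = np.zeros((c - 1, q))
        ll_old = -np.inf
        conv = False
        for _ in range(max_iter):
            log_theta = np.where(theta > 0,
                                 np.log(np.maximum(theta, 1e-300)), 0.0)
            logdens = np.einsum("nkm,ckm->nc", onehot, log_theta)
            prior = _softmax_probs(xt, _expand_b(b, c, reference_class))
            joint = logdens + np.log(np.maximum(prior, 1e-300))
            mx = joint.max(axis=1, keepdims=True)
            dens = np.exp(joint - mx)
            tot = dens.sum(axis=1, keepdims=True)
            ll = float(np.sum(mx) + np.sum(np.log(tot)))
            z = dens / tot  # posteriors (N, C)
            if abs(ll - ll_old) < tol * (abs(ll) + 1.0):
                conv = True
                break
            ll_old = ll
            theta = np.einsum("nc,nkm->ckm", z, onehot)
            theta = np.maximum(theta, 1e-10) * valid
            theta /= np.maximum(theta.sum(axis=2, keepdims=True), 1e-300)
            inner = _fit_weighted_mnlogit(z, data.covariates, reference_class,
                                          b_init=b, max_iter=30)
            b = inner["b"]
        if best is None or ll > best["ll"]:
            best = {"ll": ll, "theta": theta, "b": b, "z": z, "conv": conv}

    # canonical label order by class size (mean posterior), ties by item 1 cat 1
    sizes = best["z"].mean(axis=0)
    order = np.lexsort((-best["theta"][:, 0, 0], -np.round(sizes, 12)))
    theta = best["theta"][order]
    z = best["z"][:, order]
    sizes = sizes[order]
    # re-express logit coefficients in the permuted labels with the same
    # reference position (last class after reordering)
    b_full = _expand_b(best["b"], c, reference_class)[order]
    b_full = b_full - b_full[reference_class]
    b = np.delete(b_full, reference_class, axis=0)

    params = LCAParameters(c, sizes / sizes.sum(), theta, n_categories)
    npar = int((c - 1) * q + c * np.sum(n_categories - 1))
    fit = LCAFit(
        parameters=params,
        log_likelihood=best["ll"],
        n_params=npar,
        bic=-2 * best["ll"] + npar * np.log(n),
        l2=0.0,
        entropy_r2=entropy_r2(z, sizes / sizes.sum()),
        posteriors=z,
        converged=best["conv"],
        n_starts_used=n_starts,
        seed=seed,
        n_cases=n,
    )

    # structural SEs: observed information of the marginal LL in the logit
    # coefficients, measurement part fixed
    log_theta = np.where(theta > 0, np.log(np.maximum(theta, 1e-300)), 0.0)
    logdens = np.einsum("nkm,ckm->nc", onehot, log_theta)
    dens = np.exp(logdens - logdens.max(axis=1, keepdims=True))

    def grad_at(bvec: np.ndarray) -> np.ndarray:
        bb = bvec.reshape(c - 1, q)
        prior = _softmax_probs(xt, _expand_b(bb, c, reference_class))
        num = prior * dens
        zz = num / np.maximum(num.sum(axis=1, keepdims=True), 1e-300)
        resid = zz - prior
        nonref = [i for i in range(c) if i != reference_class]
        return (xt.T @ resid[:, nonref]).T.ravel()

    bvec = b.ravel()
    dim = bvec.size
    h = np.zeros((dim, dim))
    eps = 1e-5
    for j in range(dim):
        bp, bm = bvec.copy(), bvec.copy()
        bp[j] += eps
        bm[j] -= eps
        h[:, j] = (grad_at(bm) - grad_at(bp)) / (2 * eps)
    h = 0.5 * (h + h.T)
    cov = np.linalg.pinv(h)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0)).reshape(c - 1, q)
    nonref = [i for i in range(c) if i != reference_class]
    structural = StructuralModel(
        reference_class=reference_class,
        class_indices=nonref,
        coefficients=b,
        se=se,
        method="one_step",
        se_type="model",
        converged=best["conv"],
        separation=bool(np.any(np.abs(b) >= COEF_CAP - 1e-9)),
        covariate_labels=list(data.covariate_labels or []),
    )
    return fit, structural


METHOD_ORDER = [
    "one_step", "proportional", "proportional_ml", "proportional_bch",
    "modal", "modal_ml", "modal_bch",
]


def compare_methods(
    data: CategoricalDataset,
    n_classes: int,
    n_starts: int = 20,
    seed: int | None = None,
    reference_class: int = -1,
    methods: list[str] | None = None,
) -> pd.DataFrame:
    """Run the seven estimators (one-step; naive / ML / BCH under proportional
    and modal assignment) on one dataset and tabulate coefficient, se, z.

    Covariate labels are prefixed with the class index when the model has more
    than one non-reference class, keeping the schema fixed at
    (method, covariate, mean, se, z).
    """
    if data.covariates is None:
        raise ValueError("compare_methods needs covariates")
    methods = methods or METHOD_ORDER
    rng = np.random.default_rng(seed)
    fit = fit_lca(data, n_classes, n_starts=n_starts, seed=int(rng.integers(2**31)))
    rows: list[dict] = []

    def add(method: str, model: StructuralModel | None, error: str = "") -> None:
        if model is None:
            rows.append({"method": method, "covariate": "", "mean": np.nan,
                         "se": np.nan, "z": np.nan, "error": error})
            return
        tdy = model.tidy()
        tdy = tdy[tdy["covariate"] != "intercept"]
        multi = len(model.class_indices) > 1
        for _, r in tdy.iterrows():
            label = f"class{int(r['class']) + 1}:{r['covariate']}" if multi else r["covariate"]
            rows.append({"method": method, "covariate": label,
                         "mean": r["mean"], "se": r["se"], "z": r["z"]})

    labels = data.covariate_labels
    for method in methods:
        try:
            if method == "one_step":
                _, model = fit_one_step(data, n_classes, n_starts=max(5, n_starts // 2),
                                        seed=int(rng.integers(2**31)),
                                        reference_class=reference_class)
                add(method, model)
                continue
            style = "proportional" if method.startswith("proportional") else "modal"
            w = assign(fit.posteriors, style)
            if method in ("proportional", "modal"):
                add(method, step3_naive(w, data.covariates, reference_class,
                                        method_tag=f"naive_{style}",
                                        covariate_labels=labels))
            else:
                ce = classification_error(fit.posteriors, w,
                                          fit.parameters.class_probs)
                if method.endswith("bch"):
                    add(method, step3_bch(w, ce.D, data.covariates, reference_class,
                                          method_tag=f"bch_{style}",
                                          covariate_labels=labels))
                else:
                    add(method, step3_ml(w, ce.D, data.covariates, reference_class,
                                         method_tag=f"ml_{style}",
                                         covariate_labels=labels))
        except Exception as exc:  # per-row failure must not abort the sweep
            log.warning("method %s failed: %s", method, exc)
            add(method, None, error=str(exc))
    df = pd.DataFrame(rows)
    if "error" in df.columns and df["error"].isna().all():
        df = df.drop(columns=["error"])
    return df[[col for col in ["method", "covariate", "mean", "se", "z", "error"]
               if col in df.columns]]
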
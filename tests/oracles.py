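"""Independent brute-force reference implementations used only by the tests.

These deliberately re-derive each statistic with naive loops or exhaustive
enumeration, independent of the package's vectorized code paths.
"""

import numpy as np


def naive_posterior(class_probs, item_probs, n_categories, responses):
    """Direct Bayes-rule evaluation, one case and one class at a time."""
    n, k = responses.shape
    c = len(class_probs)
    out = np.zeros((n, c))
    for i in range(n):
        for cc in range(c):
            dens = class_probs[cc]
            for kk in range(k):
                dens *= item_probs[cc, kk, responses[i, kk] - 1]
            out[i, cc] = dens
        out[i] /= out[i].sum()
    return out


def naive_classification_error(posteriors, assignment, class_probs):
    """Double-loop evaluation of D[c,s] = (1/N) sum_i post_ic w_is / pi_c."""
    n, c = posteriors.shape
    d = np.zeros((c, c))
    for cc in range(c):
        for s in range(c):
            acc = 0.0
            for i in range(n):
                acc += posteriors[i, cc] * assignment[i, s]
            d[cc, s] = acc / (n * class_probs[cc])
    return d


def naive_entropy_r2(posteriors, class_probs):
    def ent(p):
        return -sum(pi * np.log(pi) for pi in p if pi > 0)

    mean_post = np.mean([ent(row) for row in posteriors])
    return 1.0 - mean_post / ent(class_probs)


def grid_search_2class_binary_ll(responses, resolution=0.05):
    """Exhaustive grid maximum of the 2-class binary-item log-likelihood.

    Enumerates (pi, theta_1c.., theta_Kc..) on a regular grid placed at cell
    midpoints, for K <= 3 binary items; feasible because the likelihood only
    depends on the pattern counts.
    """
    patterns, counts = np.unique(responses, axis=0, return_counts=True)
    k = responses.shape[1]
    vals = np.arange(resolution / 2, 1.0, resolution)
    g = len(vals)
    # per-item, per-class likelihood factors for each pattern, on the grid
    best = -np.inf
    pi = vals.reshape(-1, *([1] * (2 * k)))
    shapes1 = []
    shapes2 = []
    for j in range(k):
        s1 = [1] * (1 + 2 * k)
        s1[1 + j] = g
        shapes1.append(tuple(s1))
        s2 = [1] * (1 + 2 * k)
        s2[1 + k + j] = g
        shapes2.append(tuple(s2))
    ll = 0.0
    for pat, cnt in zip(patterns, counts):
        f1 = np.array(1.0)
        f2 = np.array(1.0)
        for j in range(k):
            th = vals if pat[j] == 1 else 1 - vals
            f1 = f1 * th.reshape(shapes1[j])
            f2 = f2 * th.reshape(shapes2[j])
        p = pi * f1 + (1 - pi) * f2
        ll = ll + cnt * np.log(p)
    return float(ll.max())


def naive_mambac_point(scores, input_idx, output_idx, cut_rank, order):
    """Mean above minus mean below one cut, by explicit slicing."""
    out = scores[order, output_idx]
    return out[cut_rank:].mean() - out[:cut_rank].mean()


def naive_window_cov(window_scores, j, l):
    """Two-pass sample covariance within one window."""
    a = window_scores[:, j]
    b = window_scores[:, l]
    am, bm = a.mean(), b.mean()
    return float(np.sum((a - am) * (b - bm)) / (len(a) - 1))


def naive_rmsr(y1, y2):
    acc = 0.0
    for a, b in zip(y1, y2):
        acc += (a - b) ** 2
    return float(np.sqrt(acc / len(y1)))
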
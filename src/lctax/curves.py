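"""Coherent-cut-kinetics taxometric procedures: MAMBAC, MAXCOV, MAXEIG, L-Mode.

Each procedure slides cuts or windows along a sorted *input* indicator and
tracks a statistic of the *output* indicators. Taxonic (two-group) data
produce peaked curves; dimensional (common-factor) data produce flat or
bowl-shaped curves. Curves from all input/output pairings of one procedure
form a panel whose pointwise average is the quantity compared against
bootstrapped comparison data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations, permutations

import numpy as np
from scipy import stats

from .datasets import IndicatorMatrix

log = logging.getLogger(__name__)

DEFAULT_N_CUTS = 50
DEFAULT_END_BUFFER = 25
DEFAULT_N_WINDOWS = 50
DEFAULT_OVERLAP = 0.90
LMODE_GRID_SIZE = 512
LMODE_GRID_SPAN = 3.0


@dataclass
class TaxometricCurve:
    """One x-y series from a coherent-cut procedure.

    ``grid`` is the alignment axis (cut ranks, window indices, or the fixed
    factor-score grid) shared by construction across datasets analyzed under
    the same settings; ``x`` is the descriptive axis for plotting (case rank,
    window mean of the input, or factor score).
    """

    procedure: str
    x: np.ndarray
    y: np.ndarray
    grid: np.ndarray
    input_label: str = ""
    output_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float)
        if len(self.x) != len(self.y) or len(self.grid) != len(self.y):
            raise ValueError("x, y and grid must have equal length")
        if not (np.isfinite(self.y).all() and np.isfinite(self.x).all()):
            raise ValueError("curve contains non-finite values")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("curve grid must be strictly increasing")


@dataclass
class CurvePanel:
    """All curves of one procedure on one dataset plus their pointwise mean."""

    procedure: str
    curves: list[TaxometricCurve]
    averaged: TaxometricCurve = field(init=False)

    def __post_init__(self) -> None:
        self.averaged = average_curves(self.curves, self.procedure)


@dataclass
class LModeResult:
    factor_scores: np.ndarray
    density_curve: TaxometricCurve
    left_mode: float
    right_mode: float
    base_rate_estimate: float
    clear_bimodality: bool
    loadings: np.ndarray


def average_curves(curves: list[TaxometricCurve], procedure: str | None = None) -> TaxometricCurve:
    """Pointwise mean of a panel's y values on the common grid."""
    if not curves:
        raise ValueError("cannot average an empty panel")
    grid = curves[0].grid
    for c in curves[1:]:
        if len(c.grid) != len(grid) or not np.array_equal(c.grid, grid):
            raise ValueError("curves do not share a common grid")
    y = np.mean([c.y for c in curves], axis=0)
    x = np.mean([c.x for c in curves], axis=0)
    return TaxometricCurve(procedure or curves[0].procedure, x, y, grid,
                           input_label="average")


def _sort_order(scores: np.ndarray, input_idx: int) -> np.ndarray:
    """Sort cases on the input indicator; ties broken by the sum of the
    remaining indicators, then by case index (stable lexsort)."""
    inp = scores[:, input_idx]
    others = scores.sum(axis=1) - inp
    return np.lexsort((others, inp))


def mambac_curves(
    data: IndicatorMatrix,
    n_cuts: int = DEFAULT_N_CUTS,
    end_buffer: int = DEFAULT_END_BUFFER,
) -> CurvePanel:
    """Mean-above-minus-below-a-cut curves for all k(k-1) ordered pairings.

    For each (input, output) pair the cases are sorted on the input, cuts are
    placed at evenly spaced ranks between ``end_buffer`` and ``N-end_buffer``,
    and the curve value at a cut is mean(output above) - mean(output below).
    """
    n, k = data.scores.shape
    if n <= 2 * end_buffer + 1:
        raise ValueError("too few cases for the requested end buffer")
    ranks = np.unique(np.round(np.linspace(end_buffer, n - end_buffer, n_cuts))
                      .astype(int))
    if len(ranks) < n_cuts:
        log.warning("cut ranks collapsed to %d distinct positions", len(ranks))
    grid = ranks.astype(float)
    curves = []
    for i, j in permutations(range(k), 2):
        order = _sort_order(data.scores, i)
        out = data.scores[order, j]
        csum = np.concatenate([[0.0], np.cumsum(out)])
        total = csum[-1]
        below = csum[ranks] / ranks
        above = (total - csum[ranks]) / (n - ranks)
        curves.append(TaxometricCurve(
            "mambac", grid, above - below, grid,
            input_label=data.labels[i], output_labels=(data.labels[j],),
        ))
    return CurvePanel("mambac", curves)


def _window_slices(n: int, n_windows: int, overlap: float) -> list[slice]:
    """Overlapping ordered windows covering the sorted sample.

    Window width w satisfies n = w + (n_windows - 1) * w * (1 - overlap); the
    starts are evenly spaced so the last window ends at the last case.
    """
    w = int(round(n / (1 + (n_windows - 1) * (1 - overlap))))
    w = max(w, 1)
    if n_windows == 1:
        return [slice(0, n)]
    starts = np.round(np.linspace(0, n - w, n_windows)).astype(int)
    return [slice(s, s + w) for s in starts]


def maxcov_curves(
    data: IndicatorMatrix,
    n_windows: int = DEFAULT_N_WINDOWS,
    overlap: float = DEFAULT_OVERLAP,
) -> CurvePanel:
    """Within-window covariance of output pairs along each input indicator.

    Produces the k(k-1)(k-2)/2 curves of all (input; unordered output pair)
    triplets; x is the window mean of the input, the alignment grid is the
    window index.
    """
    n, k = data.scores.shape
    if k < 3:
        raise ValueError("MAXCOV needs at least 3 indicators")
    slices = _window_slices(n, n_windows, overlap)
    curves = []
    for i in range(k):
        order = _sort_order(data.scores, i)
        s = data.scores[order]
        for j, l in combinations([m for m in range(k) if m != i], 2):
            xs, ys, gs = [], [], []
            for widx, sl in enumerate(slices):
                win = s[sl]
                if win.shape[0] < 3:
                    log.warning("window %d has fewer than 3 cases; dropped", widx)
                    continue
                xs.append(win[:, i].mean())
                ys.append(float(np.cov(win[:, j], win[:, l], ddof=1)[0, 1]))
                gs.append(widx + 1)
            curves.append(TaxometricCurve(
                "maxcov", np.asarray(xs), np.asarray(ys), np.asarray(gs, float),
                input_label=data.labels[i],
                output_labels=(data.labels[j], data.labels[l]),
            ))
    return CurvePanel("maxcov", curves)


def maxeig_curves(
    data: IndicatorMatrix,
    n_windows: int = DEFAULT_N_WINDOWS,
    overlap: float = DEFAULT_OVERLAP,
) -> CurvePanel:
    """Largest eigenvalue of the zero-diagonal output covariance matrix within
    overlapping windows along each input indicator; k curves.

    Zeroing the diagonal removes the variances so the leading eigenvalue
    reflects covariation only; for k=3 it equals |cov| of the two outputs.
    """
    n, k = data.scores.shape
    if k < 3:
        raise ValueError("MAXEIG needs at least 3 indicators")
    slices = _window_slices(n, n_windows, overlap)
    curves = []
    for i in range(k):
        order = _sort_order(data.scores, i)
        s = data.scores[order]
        outputs = [m for m in range(k) if m != i]
        xs, ys, gs = [], [], []
        for widx, sl in enumerate(slices):
            win = s[sl]
            if win.shape[0] < 3:
                log.warning("window %d has fewer than 3 cases; dropped", widx)
                continue
            cov = np.cov(win[:, outputs], rowvar=False, ddof=1)
            np.fill_diagonal(cov, 0.0)
            ys.append(float(np.linalg.eigvalsh(cov)[-1]))
            xs.append(win[:, i].mean())
            gs.append(widx + 1)
        curves.append(TaxometricCurve(
            "maxeig", np.asarray(xs), np.asarray(ys), np.asarray(gs, float),
            input_label=data.labels[i],
            output_labels=tuple(data.labels[m] for m in outputs),
        ))
    return CurvePanel("maxeig", curves)


def _principal_axis_loadings(r: np.ndarray, max_iter: int = 25) -> np.ndarray:
    """First-factor loadings by principal-axis factoring with SMC initial
    communalities."""
    k = r.shape[0]
    try:
        rinv = np.linalg.inv(r)
        h2 = 1.0 - 1.0 / np.diag(rinv)
    except np.linalg.LinAlgError:
        h2 = np.full(k, 0.5)
    h2 = np.clip(h2, 0.01, 0.99)
    loadings = np.zeros(k)
    for _ in range(max_iter):
        rr = r.copy()
        np.fill_diagonal(rr, h2)
        vals, vecs = np.linalg.eigh(rr)
        lead = vals[-1]
        if lead <= 0:
            raise ValueError("factor extraction failed: no positive leading eigenvalue")
        loadings = np.sqrt(lead) * vecs[:, -1]
        if loadings.sum() < 0:
            loadings = -loadings
        h2_new = np.clip(loadings**2, 0.0, 0.995)
        if np.max(np.abs(h2_new - h2)) < 1e-6:
            h2 = h2_new
            break
        h2 = h2_new
    return loadings


def lmode(data: IndicatorMatrix) -> LModeResult:
    """L-Mode analysis: density of first-factor Bartlett scores.

    Bimodality of the score density indicates a taxon; the mode locations
    estimate the base rate. With standardized scores a two-point mixture
    satisfies P*M_R + (1-P)*M_L = 0, giving P = M_L / (M_L - M_R).
    """
    if data.n_indicators < 3:
        raise ValueError("L-Mode needs at least 3 indicators")
    z = (data.scores - data.scores.mean(axis=0)) / data.scores.std(axis=0, ddof=1)
    r = np.corrcoef(z, rowvar=False)
    loadings = _principal_axis_loadings(r)
    psi = np.clip(1.0 - loadings**2, 1e-3, None)
    lam_psi = loadings / psi
    denom = float(loadings @ lam_psi)
    if denom <= 0:
        raise ValueError("factor extraction failed: degenerate loadings")
    scores = (z @ lam_psi) / denom  # Bartlett weighted least squares
    scores = (scores - scores.mean()) / scores.std(ddof=1)
    grid = np.linspace(-LMODE_GRID_SPAN, LMODE_GRID_SPAN, LMODE_GRID_SIZE)
    kde = stats.gaussian_kde(scores, bw_method="silverman")
    density = kde(grid)
    # mode locations: the highest interior local maximum on each side of zero;
    # a side with no local peak (density merely decaying across it) falls back
    # to the plain argmax so the locations are always defined
    interior = (density[1:-1] > density[:-2]) & (density[1:-1] >= density[2:])
    peak_locs = grid[1:-1][interior]
    peak_hts = density[1:-1][interior]

    def _side_mode(mask_side: np.ndarray, side_peaks: np.ndarray) -> float:
        if side_peaks.any():
            hts = peak_hts[side_peaks]
            return float(peak_locs[side_peaks][np.argmax(hts)])
        return float(grid[mask_side][np.argmax(density[mask_side])])

    left = grid < 0
    right = grid > 0
    ml = _side_mode(left, peak_locs < 0)
    mr = _side_mode(right, peak_locs > 0)
    # clear bimodality requires two comparable mode heights AND a genuine dip
    # between them; without the dip condition, KDE ripples on coarse ordinal
    # scores or a single peak straddling zero would count as bimodal
    il = int(np.argmin(np.abs(grid - ml)))
    ir = int(np.argmin(np.abs(grid - mr)))
    h_l, h_r = density[il], density[ir]
    dip = density[min(il, ir):max(il, ir) + 1].min()
    clear = (min(h_l, h_r) >= 0.5 * max(h_l, h_r)
             and dip < 0.75 * min(h_l, h_r))
    base_rate = ml / (ml - mr)
    curve = TaxometricCurve("lmode", grid, density, grid, input_label="factor score")
    return LModeResult(
        factor_scores=scores,
        density_curve=curve,
        left_mode=ml,
        right_mode=mr,
        base_rate_estimate=float(np.clip(base_rate, 1e-6, 1 - 1e-6)),
        clear_bimodality=bool(clear),
        loadings=loadings,
    )


def lmode_panel(data: IndicatorMatrix) -> CurvePanel:
    """The L-Mode density as a one-curve panel, for uniform suite handling."""
    return CurvePanel("lmode", [lmode(data).density_curve])


def check_suitability(
    data: IndicatorMatrix, assumed_base_rate: float | None = None
) -> dict:
    """Screen the data against the conventional taxometric requirements.

    Checks sample size (N >= 300), indicator count (k >= 2), ordered categories
    per indicator (>= 4), between-group validity (d >= 1.25) and within-group
    correlations (r <= 0.30), the latter two from a provisional split of the
    cases at the assumed base rate on the total score. The report warns but
    never blocks: a few violations or borderline values are tolerated.
    """
    s = data.scores
    n, k = s.shape
    p = assumed_base_rate if assumed_base_rate is not None else 0.5
    total = s.sum(axis=1)
    n_taxon = int(np.ceil(p * n))
    order = np.argsort(-total, kind="stable")
    taxon_mask = np.zeros(n, dtype=bool)
    taxon_mask[order[:n_taxon]] = True
    g1, g0 = s[taxon_mask], s[~taxon_mask]

    d_values = []
    for j in range(k):
        v1, v0 = g1[:, j].var(ddof=1), g0[:, j].var(ddof=1)
        pooled = np.sqrt(((len(g1) - 1) * v1 + (len(g0) - 1) * v0) / (n - 2))
        d_values.append((g1[:, j].mean() - g0[:, j].mean()) / pooled
                        if pooled > 0 else 0.0)
    d_values = np.asarray(d_values)

    def _mean_within_r(g: np.ndarray) -> float:
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(g, rowvar=False)
        off = r[~np.eye(k, dtype=bool)]
        off = off[np.isfinite(off)]
        return float(np.abs(off).mean()) if off.size else 0.0

    within_r = 0.5 * (_mean_within_r(g1) + _mean_within_r(g0))
    n_cats = np.array([np.unique(s[:, j]).size for j in range(k)])
    report = {
        "n_cases": n,
        "n_indicators": k,
        "sample_size_ok": n >= 300,
        "n_indicators_ok": k >= 2,
        "categories_per_indicator": n_cats.tolist(),
        "categories_ok": bool(np.all(n_cats >= 4)),
        "validity_d": d_values.tolist(),
        "validity_ok": bool(np.all(d_values >= 1.25)),
        "within_group_r": within_r,
        "within_r_ok": within_r <= 0.30,
        "assumed_base_rate": p,
    }
    report["all_ok"] = all(report[key] for key in
                           ["sample_size_ok", "n_indicators_ok", "categories_ok",
                            "validity_ok", "within_r_ok"])
    if not report["all_ok"]:
        log.warning("suitability screen found violations: %s",
                    {key: report[key] for key in report if key.endswith("_ok")})
    return report


PANEL_BUILDERS = {
    "mambac": mambac_curves,
    "maxcov": maxcov_curves,
    "maxeig": maxeig_curves,
    "lmode": lmode_panel,
}


def expected_curve_count(procedure: str, k: int) -> int:
    """Combinatorial panel sizes: k(k-1), k(k-1)(k-2)/2, k, and 1."""
    return {
        "mambac": k * (k - 1),
        "maxcov": k * (k - 1) * (k - 2) // 2,
        "maxeig": k,
        "lmode": 1,
    }[procedure]
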
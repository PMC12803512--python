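"""Dose-response modelling of trans genes against cis-gene dosage.

Each trans gene's log2 fold change is modelled as a function of its cis
regulator's log2 fold change across guide perturbations, with three
models:

* linear (ordinary least squares),
* a four-parameter logistic (4PL) sigmoid

      y = c + (d - c) / (1 + exp(b (x - a)))

  where ``c``/``d`` are the lower/upper asymptotes, ``a`` the x-location
  of the inflection and ``b`` a shape parameter (under this convention a
  *negative* b encodes an increasing curve; the true slope at the
  inflection is -b (d - c) / 4),
* LOESS (local polynomial regression with tricube weights) for
  non-monotonic responses.

Nonlinearity is scored by dAIC = AIC(linear) - AIC(sigmoid) (positive
favours the sigmoid).  A 10-fold cross-validation scheme yields parameter
means/SDs for z-test-based responsiveness calls, and the within-network
top-5% of dRMSE = RMSE(sigmoid) - RMSE(LOESS) flags non-monotonic
candidates confirmed by an interior-extremum prominence rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._stats import bh_fdr
from .simdata import ConfigurationError

RSS_FLOOR = 1e-12
DEFAULT_GRID = (-1.83, 0.51, 101)
#: dAIC above this counts a response as nonlinear
DELTA_AIC_NONLINEAR = 2.0
#: dAIC above this enters enrichment contrasts
DELTA_AIC_ENRICHMENT = 0.0
DEFAULT_RESTRICTED_BOUNDS = (-1.0, 0.585)  # one copy lost .. one gained
MIN_POINTS = 6


def sigmoid(x, a, b, c, d):
    """Four-parameter logistic: c + (d - c) / (1 + exp(b (x - a)))."""
    z = np.clip(b * (np.asarray(x, dtype=float) - a), -500, 500)
    return c + (d - c) / (1.0 + np.exp(z))


@dataclass
class LinearFit:
    slope: float
    intercept: float
    rss: float
    aic: float
    rmse: float
    n: int
    defined: bool = True

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass
class SigmoidFit:
    a: float
    b: float
    c: float
    d: float
    rss: float
    aic: float
    rmse: float
    n: int
    converged: bool
    rss_floored: bool = False
    cv_param_mean: dict | None = None
    cv_param_sd: dict | None = None
    cv_folds_used: int = 0
    heldout_pearson_r: float = np.nan

    def predict(self, x):
        return sigmoid(x, self.a, self.b, self.c, self.d)


@dataclass
class LoessFit:
    span: float
    degree: int
    x: np.ndarray
    fitted: np.ndarray
    rmse: float

    def predict(self, x_new, extrapolation_flags: bool = False):
        """Predict by local refit inside the observed x-range, flat beyond."""
        x_new = np.asarray(x_new, dtype=float)
        lo, hi = float(self.x.min()), float(self.x.max())
        clipped = np.clip(x_new, lo, hi)
        y = _loess_predict(self.x, self._y, clipped, self.span, self.degree)
        if extrapolation_flags:
            return y, (x_new < lo) | (x_new > hi)
        return y

    _y: np.ndarray = field(default=None, repr=False)


def assemble_dose_points(effects: pd.DataFrame, cis_gene: str,
                         trans_gene: str) -> pd.DataFrame:
    """Pair cis and trans fold changes per targeting guide of ``cis_gene``.

    Both modalities are pooled on the common fold-change axis; NTC guides
    contribute no points (the effects table only holds targeting guides).
    Fewer than 6 points flags the gene unfittable (``fittable`` attr).
    """
    mask = effects["target_cis_gene"] == cis_gene
    if "undefined" in effects.columns:
        mask &= ~effects["undefined"].astype(bool)
    sub = effects[mask]
    x = sub[sub["gene_id"] == cis_gene].set_index(["guide_id", "modality"])
    y = sub[sub["gene_id"] == trans_gene].set_index(["guide_id", "modality"])
    idx = x.index.intersection(y.index)
    pts = pd.DataFrame({
        "guide_id": [i[0] for i in idx],
        "modality": [i[1] for i in idx],
        "x": x.loc[idx, "log2fc"].to_numpy(),
        "y": y.loc[idx, "log2fc"].to_numpy(),
    })
    pts = pts[np.isfinite(pts["x"]) & np.isfinite(pts["y"])]
    pts = pts.reset_index(drop=True)
    pts.attrs["fittable"] = len(pts) >= MIN_POINTS
    return pts


def compute_aic(rss: float, n: int, k_mean: int) -> tuple[float, bool]:
    """Gaussian maximum-likelihood AIC from a residual sum of squares.

    AIC = n (ln(2 pi rss / n) + 1) + 2 (k_mean + 1), the +1 counting the
    estimated residual variance.  ``rss`` is floored at 1e-12 (flagged) to
    guard the degenerate perfect-fit case.

    Returns ``(aic, rss_floored)``.
    """
    if n <= k_mean:
        raise ValueError("n must exceed k_mean")
    floored = rss < RSS_FLOOR
    rss = max(rss, RSS_FLOOR)
    return float(n * (np.log(2 * np.pi * rss / n) + 1) + 2 * (k_mean + 1)), floored


def fit_linear(points: pd.DataFrame) -> LinearFit:
    """Ordinary least squares of y on x."""
    x = points["x"].to_numpy(dtype=float)
    y = points["y"].to_numpy(dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 points")
    if np.ptp(x) == 0:
        return LinearFit(np.nan, float(y.mean()), np.nan, np.nan, np.nan,
                         n, defined=False)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    rss = float(resid @ resid)
    aic, _ = compute_aic(rss, n, 2)
    return LinearFit(float(slope), float(intercept), rss, aic,
                     float(np.sqrt(rss / n)), n)


def _sigmoid_residual_jac(params, x, y):
    a, b, c, d = params
    z = np.clip(b * (x - a), -500, 500)
    e = np.exp(z)
    s = 1.0 / (1.0 + e)
    r = c + (d - c) * s - y
    # ds/dz = -e / (1+e)^2 = -s (1 - s)
    dsdz = -s * (1.0 - s)
    jac = np.empty((len(x), 4))
    jac[:, 0] = (d - c) * dsdz * (-b)          # d r / d a
    jac[:, 1] = (d - c) * dsdz * (x - a)       # d r / d b
    jac[:, 2] = 1.0 - s                        # d r / d c
    jac[:, 3] = s                              # d r / d d
    return r, jac


def _canonicalize(a, b, c, d):
    if c > d:
        return a, -b, d, c
    return a, b, c, d


def fit_sigmoid(points: pd.DataFrame, max_abs_b: float = 50.0,
                extra_starts=None, n_quantile_starts: int = 7,
                min_starts: int = 3) -> SigmoidFit:
    """Fit the 4PL by bounded nonlinear least squares with multi-start.

    Seven starts are built from data quantiles (a from x quantiles, c/d
    from y quantiles in both orientations, b at moderate/steep values).
    Parameters are canonicalized post-fit so that d >= c (swapping c and d
    and negating b leaves the model invariant).  If no start converges the
    fit is returned with ``converged=False`` and the caller is expected to
    fall back to the linear model.

    Multi-start stops early once ``min_starts`` starts have run and the
    best fit still explains less than 2% of the variance around the mean:
    such data are flat and additional starts only polish an uninformative
    optimum (the optimizer crawls slowly through the degenerate
    large-|b|, tiny-range valley there).
    """
    x = points["x"].to_numpy(dtype=float)
    y = points["y"].to_numpy(dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError("need >= 5 points")
    yr = max(np.ptp(y), 1e-6)
    lo = [x.min() - 1.0, -max_abs_b, y.min() - yr, y.min() - yr]
    hi = [x.max() + 1.0, max_abs_b, y.max() + yr, y.max() + yr]

    xq = np.quantile(x, [0.25, 0.5, 0.75])
    yq = np.quantile(y, [0.05, 0.95])
    starts = [
        (xq[1], -4.0, yq[0], yq[1]),
        (xq[1], 4.0, yq[0], yq[1]),
        (xq[0], -8.0, yq[0], yq[1]),
        (xq[2], -8.0, yq[0], yq[1]),
        (xq[0], 8.0, yq[0], yq[1]),
        (xq[2], 8.0, yq[0], yq[1]),
        (xq[1], -1.0, y.mean() - yr, y.mean() + yr),
    ][:n_quantile_starts]
    if extra_starts is not None:
        starts = list(extra_starts) + starts
    best = None
    tss = float(((y - y.mean()) ** 2).sum())
    for k, s0 in enumerate(starts):
        if (best is not None and k >= min_starts
                and best[0] >= 0.98 * tss):
            break
        p0 = np.clip(s0, lo, hi)
        try:
            res = optimize.least_squares(
                lambda p: _sigmoid_residual_jac(p, x, y)[0], p0,
                jac=lambda p: _sigmoid_residual_jac(p, x, y)[1],
                bounds=(lo, hi), method="trf",
                xtol=1e-8, ftol=1e-8, gtol=1e-8, max_nfev=100)
        except Exception:
            continue
        if not res.success or not np.all(np.isfinite(res.x)):
            continue
        rss = float(2 * res.cost)
        if best is None or rss < best[0]:
            best = (rss, res.x)
    if best is None:
        return SigmoidFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                          np.nan, n, converged=False)
    rss, params = best
    a, b, c, d = _canonicalize(*params)
    aic, floored = compute_aic(rss, n, 4)
    return SigmoidFit(float(a), float(b), float(c), float(d), rss, aic,
                      float(np.sqrt(rss / n)), n, converged=True,
                      rss_floored=floored)


def delta_aic(linear: LinearFit, sig: SigmoidFit) -> float:
    """AIC(linear) - AIC(sigmoid); NaN when the sigmoid did not converge."""
    if not sig.converged or not linear.defined:
        return np.nan
    return float(linear.aic - sig.aic)


# ---------------------------------------------------------------------------
# LOESS


def _loess_predict(x, y, x0, span, degree):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    n = len(x)
    k = int(np.ceil(span * n))
    if k < degree + 1:
        raise ConfigurationError(
            f"span {span} gives a window of {k} points at n={n}; the "
            f"degree-{degree} local fit needs at least {degree + 1} "
            f"(minimum span {(degree + 1) / n:.3f})")
    k = min(k, n)
    out = np.empty(len(x0))
    for i, xi in enumerate(x0):
        dist = np.abs(x - xi)
        h = np.sort(dist)[k - 1]
        if h == 0:
            h = max(dist.max(), 1e-12)
            w = np.where(dist == 0, 1.0, 0.0)
            if w.sum() >= degree + 1:
                out[i] = y[dist == 0].mean()
                continue
        w = np.clip(1 - (dist / h) ** 3, 0, None) ** 3
        use = w > 0
        if use.sum() < degree + 1:
            use = dist <= np.sort(dist)[degree]
            w = np.maximum(w, 1e-9 * use)
        X = np.vander(x[use] - xi, degree + 1, increasing=True)
        W = w[use]
        beta, *_ = np.linalg.lstsq(X * np.sqrt(W)[:, None],
                                   y[use] * np.sqrt(W), rcond=None)
        out[i] = beta[0]
    return out


def fit_loess(points: pd.DataFrame, span: float = 0.75,
              degree: int = 2) -> LoessFit:
    """Local polynomial regression with tricube weights.

    ``span`` is the fraction of points in each local window (window size
    ``ceil(span * n)``, which must be at least ``degree + 1``).
    """
    if not 0 < span <= 1:
        raise ConfigurationError("span must be in (0, 1]")
    if degree not in (1, 2):
        raise ConfigurationError("degree must be 1 or 2")
    x = points["x"].to_numpy(dtype=float)
    y = points["y"].to_numpy(dtype=float)
    fitted = _loess_predict(x, y, x, span, degree)
    resid = y - fitted
    fit = LoessFit(span=span, degree=degree, x=x, fitted=fitted,
                   rmse=float(np.sqrt(resid @ resid / len(x))))
    fit._y = y
    return fit


# ---------------------------------------------------------------------------
# cross-validation and classification


#: a fold fit whose |b| lands this close to the optimizer bound is a
#: degenerate step (the inflection shape is unidentified) and is dropped
DEGENERATE_B_FRACTION = 0.99


def crossvalidate_sigmoid(points: pd.DataFrame, folds: int = 10,
                          rng_seed: int = 0) -> SigmoidFit:
    """10-fold CV of the sigmoid fit; summaries attached to the full fit.

    The points are randomly partitioned into ``folds`` groups; each fold's
    model is trained on the complement and predicts the held-out points.
    Parameter means/SDs are taken over the per-fold fits (canonicalized
    before averaging); ``heldout_pearson_r`` correlates the pooled
    held-out predictions with the observations.  Folds whose fit fails
    or degenerates to a boundary step (|b| at the optimizer bound) are
    dropped (surviving count recorded in ``cv_folds_used``).  Fold fits
    use their own reduced multi-start so that folds stay independent --
    warm-starting every fold from the full-data optimum would couple
    them and deflate the CV parameter SDs that the responsiveness
    z-tests rely on.
    """
    n = len(points)
    if n < folds:
        raise ValueError(f"need n >= folds ({n} < {folds})")
    fit = fit_sigmoid(points)
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(n)
    groups = np.array_split(perm, folds)
    params, preds, obs = [], [], []
    for g in groups:
        train = points.iloc[np.setdiff1d(perm, g, assume_unique=False)]
        try:
            f = fit_sigmoid(train, n_quantile_starts=3, min_starts=2)
        except Exception:
            continue
        if not f.converged or abs(f.b) >= DEGENERATE_B_FRACTION * 50.0:
            continue
        params.append((f.a, f.b, f.c, f.d))
        preds.append(f.predict(points.iloc[g]["x"].to_numpy()))
        obs.append(points.iloc[g]["y"].to_numpy())
    if params:
        arr = np.array(params)
        names = ("a", "b", "c", "d")
        fit.cv_param_mean = dict(zip(names, arr.mean(axis=0)))
        fit.cv_param_sd = dict(
            zip(names, arr.std(axis=0, ddof=1) if len(arr) > 1
                else np.zeros(4)))
        rng_vals = arr[:, 3] - arr[:, 2]
        fit.cv_param_mean["range"] = float(rng_vals.mean())
        fit.cv_param_sd["range"] = float(
            rng_vals.std(ddof=1) if len(arr) > 1 else 0.0)
        fit.cv_folds_used = len(params)
        pooled_pred = np.concatenate(preds)
        pooled_obs = np.concatenate(obs)
        if np.std(pooled_pred) > 0 and np.std(pooled_obs) > 0:
            fit.heldout_pearson_r = float(
                stats.pearsonr(pooled_pred, pooled_obs)[0])
    return fit


def _z_to_p(mean, sd, two_sided=True, shift=0.0):
    """p-value of a z statistic with the documented degenerate handling."""
    if sd == 0:
        return 1.0 if mean - shift == 0 else 0.0
    z = (mean - shift) / sd
    if two_sided:
        return float(2 * stats.norm.sf(abs(z)))
    return float(stats.norm.sf(z))


def classify_responsive(fits: dict, range_threshold: float = 0.05,
                        fdr_cutoff: float = 0.05) -> pd.DataFrame:
    """Responsive / unresponsive calls over one cis-gene network.

    ``fits`` maps trans gene -> cross-validated SigmoidFit.  Per gene, a
    two-sided z-test of the CV-mean shape parameter b against 0 and a
    one-sided z-test of the CV-mean asymptote range (d - c) against
    ``range_threshold``, each using the SD of the fold estimates; both
    p-value families are BH-adjusted across the network's trans genes and
    a gene is responsive iff both adjusted p-values fall below
    ``fdr_cutoff``.  Genes with fewer than 3 surviving (identifiable)
    fold fits cannot be tested and are unresponsive by default.
    """
    rows = []
    for gene, fit in fits.items():
        if fit.cv_param_mean is None or fit.cv_folds_used < 3:
            rows.append({"trans_gene": gene, "slope_p": np.nan,
                         "range_p": np.nan})
            continue
        slope_p = _z_to_p(fit.cv_param_mean["b"], fit.cv_param_sd["b"])
        range_p = _z_to_p(fit.cv_param_mean["range"], fit.cv_param_sd["range"],
                          two_sided=False, shift=range_threshold)
        rows.append({"trans_gene": gene, "slope_p": slope_p,
                     "range_p": range_p})
    out = pd.DataFrame(rows)
    out["slope_z_fdr"] = bh_fdr(out["slope_p"].to_numpy())
    out["range_z_fdr"] = bh_fdr(out["range_p"].to_numpy())
    out["responsive"] = ((out["slope_z_fdr"] < fdr_cutoff)
                         & (out["range_z_fdr"] < fdr_cutoff)).fillna(False)
    return out


def classify_nonmonotonic(sig_rmse: dict, loess_fits: dict,
                          quantile: float = 0.95,
                          prominence: float = 0.05,
                          noise_scale: float = 2.0,
                          grid_size: int = 101) -> pd.DataFrame:
    """Flag non-monotonic responses by the top-5% dRMSE rule.

    dRMSE = RMSE(sigmoid) - RMSE(LOESS) per gene; genes at or above the
    within-network ``quantile`` of dRMSE are candidates.  A candidate is
    confirmed non-monotonic -- the automated stand-in for visual curve
    validation -- when both hold:

    * the LOESS curve has an interior extremum whose prominence is at
      least ``max(prominence, noise_scale * loess rmse)`` log2 units
      (the noise-scaled floor demands the peak rise clearly above the
      smoother's own wiggle on noisy plateaus), and
    * the raw points support the reversal: the observations in a window
      around the extremum differ from those on *each* side by at least
      ``prominence`` in the reversing direction, with rank-sum p < 0.05
      on both sides.

    Confirmed genes should be predicted from the LOESS model.
    """
    genes = list(sig_rmse)
    drmse = np.array([sig_rmse[g] - loess_fits[g].rmse for g in genes])
    finite = np.isfinite(drmse)
    cut = np.quantile(drmse[finite], quantile) if finite.sum() else np.inf
    candidates = finite & (drmse >= cut)
    confirmed = np.zeros(len(genes), dtype=bool)
    for i, g in enumerate(genes):
        if not candidates[i]:
            continue
        confirmed[i] = _confirmed_reversal(
            loess_fits[g], prominence, noise_scale, grid_size)
    return pd.DataFrame({
        "trans_gene": genes, "delta_rmse": drmse,
        "candidate": candidates, "nonmonotonic": confirmed,
    })


def _confirmed_reversal(lf: LoessFit, prominence: float,
                        noise_scale: float, grid_size: int) -> bool:
    from ._stats import rank_sum_test
    x, y = lf.x, lf._y
    grid = np.linspace(x.min(), x.max(), grid_size)
    yv = lf.predict(grid)
    threshold = max(prominence, noise_scale * lf.rmse)
    half_window = (x.max() - x.min()) / 8.0
    for sign in (1.0, -1.0):
        v = sign * yv
        j = int(np.argmax(v))
        if not 0 < j < len(v) - 1:
            continue
        prom = min(v[j] - v[:j].min(), v[j] - v[j + 1:].min())
        if prom < threshold:
            continue
        x_star = grid[j]
        peak = np.abs(x - x_star) <= half_window
        left = x < x_star - half_window
        right = x > x_star + half_window
        if min(peak.sum(), left.sum(), right.sum()) < 5:
            continue
        y_p, y_l, y_r = sign * y[peak], sign * y[left], sign * y[right]
        if (y_p.mean() - y_l.mean() >= prominence
                and y_p.mean() - y_r.mean() >= prominence
                and rank_sum_test(y_p, y_l)[1] < 0.05
                and rank_sum_test(y_p, y_r)[1] < 0.05):
            return True
    return False


def _has_interior_extremum(y: np.ndarray, prominence: float) -> bool:
    for sign in (1.0, -1.0):
        v = sign * y
        i = int(np.argmax(v))
        if 0 < i < len(v) - 1:
            prom = min(v[i] - v[:i].min(), v[i] - v[i + 1:].min())
            if prom >= prominence:
                return True
    return False


def predict_response_grid(fit, x_grid=None, observed_x=None):
    """Evaluate a fit on a dosage grid (default 101 points on [-1.83, 0.51]).

    Sigmoid and linear fits evaluate analytically; LOESS fits refit
    locally inside the observed x-range and extrapolate flat beyond it.
    Returns ``(y, extrapolated mask)`` where the mask marks grid points
    more than 0.5 log2 units outside the observed x-range (always for the
    flat LOESS extension).
    """
    if x_grid is None:
        x_grid = np.linspace(DEFAULT_GRID[0], DEFAULT_GRID[1], DEFAULT_GRID[2])
    x_grid = np.asarray(x_grid, dtype=float)
    if isinstance(fit, LoessFit):
        y, extra = fit.predict(x_grid, extrapolation_flags=True)
        return y, extra
    if isinstance(fit, SigmoidFit) and not fit.converged:
        raise ValueError("cannot predict from a non-converged sigmoid fit")
    y = fit.predict(x_grid)
    if observed_x is not None:
        ox = np.asarray(observed_x, dtype=float)
        extra = (x_grid < ox.min() - 0.5) | (x_grid > ox.max() + 0.5)
    else:
        extra = np.zeros_like(x_grid, dtype=bool)
    return y, extra


def refit_restricted(points: pd.DataFrame,
                     x_bounds: tuple = DEFAULT_RESTRICTED_BOUNDS):
    """Re-run the linear + sigmoid comparison on a restricted dosage window.

    Default window [-1.0, +0.585] spans one hypothetical copy lost
    (log2 1/2) to one gained (log2 3/2).  Returns
    ``(linear, sigmoid, dAIC, n_used)`` or ``(None, None, nan, n_used)``
    when fewer than 5 points survive.
    """
    lo, hi = x_bounds
    sub = points[(points["x"] >= lo) & (points["x"] <= hi)].reset_index(drop=True)
    if len(sub) < 5:
        return None, None, np.nan, len(sub)
    lin = fit_linear(sub)
    sig = fit_sigmoid(sub)
    return lin, sig, delta_aic(lin, sig), len(sub)


# ---------------------------------------------------------------------------
# network driver


def fit_network(effects: pd.DataFrame, cis_gene: str, trans_genes,
                folds: int = 10, rng_seed: int = 0,
                range_threshold: float = 0.05, fdr_cutoff: float = 0.05,
                loess_span: float = 0.75, loess_degree: int = 2,
                nonmono_quantile: float = 0.95,
                nonmono_prominence: float = 0.05,
                ) -> tuple[pd.DataFrame, dict]:
    """Fit and classify every trans gene of one cis-gene network.

    Returns ``(table, fits)`` where the table holds one row per trans gene
    (parameters, AICs, dAIC, dRMSE, responsiveness and monotonicity
    flags) and ``fits`` maps gene -> (points, LinearFit, SigmoidFit,
    LoessFit) for downstream prediction.
    """
    ss = np.random.SeedSequence(rng_seed)
    seeds = {g: int(c.generate_state(1)[0] % 2**31)
             for g, c in zip(trans_genes, ss.spawn(len(trans_genes)))}
    sig_fits, loess_fits, lin_fits, all_points = {}, {}, {}, {}
    rows = {}
    for gene in trans_genes:
        pts = assemble_dose_points(effects, cis_gene, gene)
        all_points[gene] = pts
        if not pts.attrs["fittable"]:
            rows[gene] = {"fittable": False}
            continue
        lin = fit_linear(pts)
        sig = crossvalidate_sigmoid(pts, folds=min(folds, len(pts)),
                                    rng_seed=seeds[gene])
        lo = fit_loess(pts, span=loess_span, degree=loess_degree)
        lin_fits[gene], sig_fits[gene], loess_fits[gene] = lin, sig, lo
        rows[gene] = {"fittable": True}

    fitted = [g for g in trans_genes if rows[g].get("fittable")]
    resp = classify_responsive(
        {g: sig_fits[g] for g in fitted},
        range_threshold=range_threshold, fdr_cutoff=fdr_cutoff,
    ).set_index("trans_gene") if fitted else pd.DataFrame()
    nonmono = classify_nonmonotonic(
        {g: sig_fits[g].rmse for g in fitted},
        {g: loess_fits[g] for g in fitted},
        quantile=nonmono_quantile, prominence=nonmono_prominence,
    ).set_index("trans_gene") if fitted else pd.DataFrame()

    out = []
    for gene in trans_genes:
        row = {"cis_gene": cis_gene, "trans_gene": gene,
               "fittable": rows[gene].get("fittable", False)}
        if row["fittable"]:
            lin, sig, lo = lin_fits[gene], sig_fits[gene], loess_fits[gene]
            row.update(
                n_points=lin.n, slope=lin.slope, intercept=lin.intercept,
                aic_linear=lin.aic, rmse_linear=lin.rmse,
                a=sig.a, b=sig.b, c=sig.c, d=sig.d,
                aic_sigmoid=sig.aic, rmse_sigmoid=sig.rmse,
                sigmoid_converged=sig.converged,
                heldout_pearson_r=sig.heldout_pearson_r,
                cv_folds_used=sig.cv_folds_used,
                delta_aic=delta_aic(lin, sig),
                rmse_loess=lo.rmse,
                slope_z_fdr=resp.loc[gene, "slope_z_fdr"],
                range_z_fdr=resp.loc[gene, "range_z_fdr"],
                responsive=bool(resp.loc[gene, "responsive"]),
                delta_rmse=nonmono.loc[gene, "delta_rmse"],
                nonmonotonic=bool(nonmono.loc[gene, "nonmonotonic"]),
            )
            for p in ("a", "b", "c", "d", "range"):
                if sig.cv_param_mean is not None:
                    row[f"cv_mean_{p}"] = sig.cv_param_mean[p]
                    row[f"cv_sd_{p}"] = sig.cv_param_sd[p]
            row["nonlinear"] = (np.isfinite(row["delta_aic"])
                                and row["delta_aic"] > DELTA_AIC_NONLINEAR)
        out.append(row)
    table = pd.DataFrame(out)
    fits = {g: (all_points[g], lin_fits.get(g), sig_fits.get(g),
                loess_fits.get(g)) for g in trans_genes}
    return table, fits


def network_predictions(table: pd.DataFrame, fits: dict,
                        x_grid=None) -> pd.DataFrame:
    """Predicted responses on the dosage grid, per trans gene.

    Non-monotonic genes are predicted from the LOESS model, all other
    fittable genes from the sigmoid (linear fallback when the sigmoid did
    not converge).
    """
    if x_grid is None:
        x_grid = np.linspace(DEFAULT_GRID[0], DEFAULT_GRID[1], DEFAULT_GRID[2])
    recs = {}
    for _, row in table.iterrows():
        gene = row["trans_gene"]
        if not row["fittable"]:
            continue
        pts, lin, sig, lo = fits[gene]
        if row.get("nonmonotonic", False):
            y, _ = predict_response_grid(lo, x_grid)
        elif sig.converged:
            y, _ = predict_response_grid(sig, x_grid, observed_x=pts["x"])
        else:
            y = lin.predict(x_grid)
        recs[gene] = y
    out = pd.DataFrame(recs, index=np.asarray(x_grid)).T
    out.index.name = "trans_gene"
    return out
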
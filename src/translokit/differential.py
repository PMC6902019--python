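"""Donor-paired differential abundance with PSM-count-moderated variance.

Per fraction and contrast, the model is the paired t-test on within-donor
log2 differences.  With 3 donors the residual degrees of freedom are 2, so
the per-gene variance is pooled empirical-Bayes style toward a prior that
depends on the gene's PSM count: proteins quantified from more spectra are
measured more precisely, and the prior variance trend captures that.  The
estimator is the classic scaled-F moment fit — per-gene variances are
modelled as s² ~ s0²(count)·F(d, d0) — with the prior trend obtained by a
lowess smooth of log-variances on log PSM count and d0 from the spread of
the residuals via the trigamma inverse.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .design import FRACTIONS, DesignContrast, ExperimentDesign
from .quant import ProteinQuantMatrix

#: Prior df at (or above) this value are treated as effectively infinite.
D0_CAP = 1e6


@dataclass
class VarianceTrend:
    """Prior variance as a function of PSM count, plus prior df d0.

    ``log_counts``/``log_s0_sq`` tabulate the fitted trend on the observed
    count range; evaluation interpolates linearly in log-log space with
    constant extrapolation outside the range.
    """

    log_counts: np.ndarray
    log_s0_sq: np.ndarray
    d0: float

    def s0_sq(self, counts) -> np.ndarray:
        counts = np.asarray(counts, dtype=float)
        lc = np.log(np.maximum(counts, 1.0))
        return np.exp(np.interp(lc, self.log_counts, self.log_s0_sq))


def fit_paired_model(
    matrix: ProteinQuantMatrix,
    design: ExperimentDesign,
    contrast: DesignContrast,
) -> pd.DataFrame:
    """Within-donor paired differences for one fraction and contrast.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (mean of
    within-donor differences), ``s2`` (their sample variance), ``df``
    (donors − 1) and ``psm_count`` (median across sets).  Genes with fewer
    than 2 complete donor pairs are excluded (untestable).
    """
    samples = design.sample_table()
    sel = samples[samples["fraction"] == contrast.fraction]
    base = sel[sel["timepoint_min"] == contrast.baseline].set_index("donor")["sample_id"]
    treat = sel[sel["timepoint_min"] == contrast.treatment].set_index("donor")["sample_id"]
    donors = sorted(set(base.index) & set(treat.index))
    if len(donors) < 2:
        raise ValueError("need >= 2 donors with both timepoints in the design")
    missing = [s for d in donors for s in (base[d], treat[d]) if s not in matrix.values.columns]
    if missing:
        raise KeyError(f"sample columns absent from matrix: {missing}")
    deltas = pd.DataFrame(
        {d: matrix.values[treat[d]] - matrix.values[base[d]] for d in donors}
    )
    n = deltas.notna().sum(axis=1)
    testable = n >= 2
    deltas = deltas.loc[testable]
    n = n.loc[testable]
    log2fc = deltas.mean(axis=1)
    s2 = deltas.var(axis=1, ddof=1)
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "s2": s2,
            "df": (n - 1).astype(float),
            "n_pairs": n.astype(int),
            "psm_count": matrix.median_psm_count.reindex(deltas.index),
        }
    )
    out.index.name = "gene"
    return out


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on 1/trigamma, Smyth-style)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_trend(
    fits: pd.DataFrame,
    min_genes: int = 20,
    lowess_frac: float = 0.75,
) -> VarianceTrend:
    """Fit the PSM-count-dependent prior variance and prior df.

    Works on e = log s² − digamma(d/2) + log(d/2), the unbiased log-scale
    variance statistic: its lowess trend on log count gives the prior
    location, and the excess of var(e − trend) over the sampling variance
    trigamma(d/2) gives d0 through the trigamma inverse.  Zero variances
    are floored at 1e-3 × the smallest positive s².  Fewer than
    ``min_genes`` testable genes, or a single distinct PSM count, falls
    back to a constant trend.
    """
    fits = fits.dropna(subset=["s2", "df", "psm_count"])
    s2 = fits["s2"].to_numpy(dtype=float)
    d = fits["df"].to_numpy(dtype=float)
    counts = np.maximum(fits["psm_count"].to_numpy(dtype=float), 1.0)
    if len(s2) == 0:
        raise ValueError("no testable genes")
    positive = s2[s2 > 0]
    if len(positive) == 0:
        # degenerate: every gene has zero residual variance
        return VarianceTrend(np.array([0.0]), np.array([-50.0]), D0_CAP)
    floor = positive.min() * 1e-3
    s2 = np.maximum(s2, floor)

    e = np.log(s2) - special.digamma(d / 2.0) + np.log(d / 2.0)
    log_c = np.log(counts)
    distinct = np.unique(log_c)
    if len(s2) < min_genes or len(distinct) < 2:
        e_trend = np.full_like(e, e.mean())
        grid_x = np.array([log_c.min() - 1.0, log_c.max() + 1.0])
        grid_y = np.full(2, e.mean())
    else:
        # it=0: the scaled-F moment model calibrates the *mean* of e; robust
        # iterations would drift toward the median of the left-skewed
        # log-chi-square statistic and bias the prior variance low
        sm = lowess(e, log_c, frac=lowess_frac, it=0, return_sorted=True)
        grid_x, idx = np.unique(sm[:, 0], return_index=True)
        grid_y = sm[idx, 1]
        e_trend = np.interp(log_c, grid_x, grid_y)

    resid = e - e_trend
    evar = float(np.var(resid, ddof=1)) if len(resid) > 1 else 0.0
    evar -= float(np.mean(special.polygamma(1, d / 2.0)))
    if evar > 0:
        d0 = min(2.0 * _trigamma_inverse(evar), D0_CAP)
    else:
        d0 = D0_CAP
    # back-transform trend location to the s0^2 scale
    if np.isfinite(d0) and d0 < D0_CAP:
        offset = float(special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        offset = 0.0
    log_s0 = grid_y + resid.mean() + offset
    return VarianceTrend(log_counts=grid_x, log_s0_sq=log_s0, d0=float(d0))


def moderate_statistics(fits: pd.DataFrame, trend: VarianceTrend) -> pd.DataFrame:
    """Moderated t-test: squeeze per-gene variances toward the count trend.

    Posterior variance (d0·s0² + d·s²)/(d0 + d); t = log2FC/(s̃/√n) on
    d0 + d degrees of freedom; two-sided P, uncorrected.
    """
    d0 = trend.d0
    d = fits["df"].to_numpy(dtype=float)
    if np.any(d0 + d <= 0):
        raise ValueError("non-positive total degrees of freedom")
    s2 = fits["s2"].to_numpy(dtype=float)
    n = fits["n_pairs"].to_numpy(dtype=float)
    s0 = trend.s0_sq(fits["psm_count"].to_numpy())
    if d0 >= D0_CAP:
        post = s0
        df_total = np.full_like(d, np.inf)
    else:
        post = (d0 * s0 + d * s2) / (d0 + d)
        df_total = d0 + d
    se = np.sqrt(post / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, fits["log2fc"].to_numpy() / se, 0.0)
    finite_df = np.isfinite(df_total)
    p = np.empty_like(t)
    p[finite_df] = 2.0 * stats.t.sf(np.abs(t[finite_df]), df_total[finite_df])
    p[~finite_df] = 2.0 * stats.norm.sf(np.abs(t[~finite_df]))
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    out = fits.copy()
    out["posterior_var"] = post
    out["t"] = t
    out["pvalue"] = p
    out["df_total"] = df_total
    return out


def compute_differential(
    matrix: ProteinQuantMatrix,
    design: ExperimentDesign,
    treatment: int,
    baseline: int = 0,
    per_fraction_trend: bool = False,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Differential statistics for one contrast across all three fractions.

    By default the variance trend is pooled across fractions (one trend per
    contrast); ``per_fraction_trend=True`` fits one per fraction.
    ``d0_override`` forces the prior df (0 disables moderation entirely).
    Returns a long DataFrame: gene, fraction, contrast, log2fc, t, pvalue,
    posterior_var, psm_count.
    """
    per_fraction = {}
    for fraction in FRACTIONS:
        contrast = DesignContrast(fraction=fraction, treatment=treatment, baseline=baseline)
        per_fraction[fraction] = fit_paired_model(matrix, design, contrast)
    if per_fraction_trend:
        trends = {f: fit_variance_trend(fits) for f, fits in per_fraction.items()}
    else:
        pooled = pd.concat(per_fraction.values(), ignore_index=True)
        shared = fit_variance_trend(pooled)
        trends = {f: shared for f in FRACTIONS}
    if d0_override is not None:
        trends = {
            f: VarianceTrend(t.log_counts, t.log_s0_sq, float(d0_override))
            for f, t in trends.items()
        }
    frames = []
    for fraction, fits in per_fraction.items():
        stats_f = moderate_statistics(fits, trends[fraction]).reset_index()
        stats_f.insert(1, "fraction", fraction)
        stats_f.insert(2, "contrast", f"{treatment}min_vs_{baseline}min")
        frames.append(stats_f)
    return pd.concat(frames, ignore_index=True)
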
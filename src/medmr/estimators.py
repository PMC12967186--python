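"""The five two-sample MR estimators.

All estimators consume a :class:`~medmr.gwas_io.HarmonizedSet` and return
an :class:`MREstimate` on the log odds-ratio scale (for a binary outcome)
or the outcome's own scale otherwise. The building block is the per-SNP
Wald ratio r_j = beta_y_j / beta_x_j with first-order standard error
s_j = se_y_j / |beta_x_j| and inverse-variance weight w_j = 1 / s_j^2.

* ``ivw`` — inverse-variance-weighted meta-analysis of the ratios,
  equivalent to weighted least squares of beta_y on beta_x through the
  origin with weights 1/se_y^2. The default variance model inflates the
  fixed-effect SE by max(1, sqrt(Q/(k-1))) (multiplicative random
  effects).
* ``egger`` — the same regression with an unconstrained intercept after
  orienting every SNP to a non-negative exposure effect; the intercept
  estimates directional pleiotropy, inference is t-based on k-2 df with
  the residual scale floored at 1.
* ``weighted_median`` — the weighted median of the ratios (consistent
  when valid instruments carry > 50% of the weight), with a parametric
  bootstrap SE.
* ``mode_estimate`` — the mode of a Gaussian kernel density over the
  ratios (simple: equal weights; weighted: IVW weights), bandwidth
  phi * 0.9 * min(sd, IQR/1.349) * k^(-1/5), bootstrap SE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateInstrumentError,
    EmptyInstrumentSetError,
    InsufficientInstrumentsError,
)
from .gwas_io import HarmonizedSet

IVW = "IVW"
EGGER = "Egger"
WEIGHTED_MEDIAN = "WeightedMedian"
SIMPLE_MODE = "SimpleMode"
WEIGHTED_MODE = "WeightedMode"
METHODS = (IVW, EGGER, WEIGHTED_MEDIAN, SIMPLE_MODE, WEIGHTED_MODE)

_MODE_GRID_POINTS = 512


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate on the log-OR scale."""

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    note: str | None = None

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        """Lower 95% CI bound on the OR scale."""
        return float(np.exp(self.beta - 1.96 * self.se))

    @property
    def ci_high(self) -> float:
        """Upper 95% CI bound on the OR scale."""
        return float(np.exp(self.beta + 1.96 * self.se))

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "nsnp": self.n_snp,
            "beta": self.beta,
            "se": self.se,
            "pval": self.pval,
            "or": self.odds_ratio,
            "or_lci95": self.ci_low,
            "or_uci95": self.ci_high,
        }


@dataclass(frozen=True)
class RatioEstimates:
    """Per-SNP Wald ratios with first-order SEs and IVW weights."""

    ratio: np.ndarray
    se: np.ndarray
    weight: np.ndarray

    @property
    def k(self) -> int:
        return len(self.ratio)


def _norm_p(z: float | np.ndarray) -> float | np.ndarray:
    # clip so reported p stays in (0, 1] even when the normal tail underflows
    return np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)


def wald_ratios(hs: HarmonizedSet) -> RatioEstimates:
    """Per-SNP causal estimates r_j = beta_y/beta_x, s_j = se_y/|beta_x|."""
    if hs.k == 0:
        raise EmptyInstrumentSetError("no instruments")
    zero = hs.beta_x == 0
    if np.any(zero):
        bad = ", ".join(map(str, hs.snp_ids[zero]))
        raise DegenerateInstrumentError(f"zero exposure effect for: {bad}")
    r = hs.beta_y / hs.beta_x
    s = hs.se_y / np.abs(hs.beta_x)
    return RatioEstimates(ratio=r, se=s, weight=1.0 / s**2)


def ivw(hs: HarmonizedSet, variance_model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate.

    ``variance_model`` is "fixed" or "multiplicative_random" (default);
    the latter multiplies the fixed-effect SE by max(1, sqrt(Q/(k-1))).
    With a single SNP the Wald ratio itself is returned, flagged.
    """
    if variance_model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown variance model {variance_model!r}")
    re = wald_ratios(hs)
    k = re.k
    if k == 1:
        beta, se = float(re.ratio[0]), float(re.se[0])
        return MREstimate(IVW, beta, se, float(_norm_p(beta / se)), 1, note="single-SNP Wald ratio")
    w = re.weight
    beta = float(np.sum(w * re.ratio) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    se = se_fixed
    if variance_model == "multiplicative_random":
        q = float(np.sum(w * (re.ratio - beta) ** 2))
        se = se_fixed * max(1.0, np.sqrt(q / (k - 1)))
    return MREstimate(IVW, beta, se, float(_norm_p(beta / se)), k)


def egger(hs: HarmonizedSet) -> tuple[MREstimate, float, float, float]:
    """MR-Egger regression.

    Returns ``(slope_estimate, intercept, intercept_se, intercept_p)``.
    SNPs are oriented so every exposure effect is non-negative; the
    regression of beta_y on beta_x (weights 1/se_y^2) then has an
    intercept interpretable as the average directional pleiotropic
    effect. Standard errors carry a residual-scale factor floored at 1
    and p-values use t with k-2 degrees of freedom.
    """
    if hs.k < 3:
        raise InsufficientInstrumentsError(f"Egger needs k >= 3, got {hs.k}")
    flip = np.sign(hs.beta_x)
    flip[flip == 0] = 1.0
    bx = hs.beta_x * flip
    by = hs.beta_y * flip
    w = 1.0 / hs.se_y**2
    x = np.column_stack([np.ones_like(bx), bx])
    xtwx = x.T @ (w[:, None] * x)
    xtwy = x.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - x @ coef
    k = hs.k
    sigma2 = float(np.sum(w * resid**2) / (k - 2))
    cov_unscaled = np.linalg.inv(xtwx)
    scale = max(1.0, np.sqrt(sigma2))
    se_int = float(np.sqrt(cov_unscaled[0, 0]) * scale)
    se_slope = float(np.sqrt(cov_unscaled[1, 1]) * scale)
    tdist = stats.t(df=k - 2)
    slope_p = float(2 * tdist.sf(abs(coef[1] / se_slope)))
    int_p = float(2 * tdist.sf(abs(coef[0] / se_int)))
    est = MREstimate(EGGER, float(coef[1]), se_slope, slope_p, k)
    return est, float(coef[0]), se_int, int_p


def _weighted_median_point(r: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median of ratios ``r`` with weights ``w``."""
    order = np.argsort(r, kind="stable")
    r_s, w_s = r[order], w[order]
    cum = np.cumsum(w_s)
    total = cum[-1]
    p = (cum - w_s / 2.0) / total
    return float(np.interp(0.5, p, r_s))


def _bootstrap_se(
    hs: HarmonizedSet,
    point_fn,
    n_boot: int,
    rng: np.random.Generator,
) -> float:
    """Parametric bootstrap SE: resample beta_x, beta_y from their sampling
    distributions, recompute ratios/weights, re-apply ``point_fn``."""
    k = hs.k
    bx = rng.normal(hs.beta_x, hs.se_x, size=(n_boot, k))
    by = rng.normal(hs.beta_y, hs.se_y, size=(n_boot, k))
    bx[bx == 0] = np.finfo(float).tiny  # Wald ratio undefined at exactly zero
    ratios = by / bx
    weights = bx**2 / hs.se_y**2  # = 1 / (se_y/|bx|)^2
    ests = np.array([point_fn(ratios[b], weights[b]) for b in range(n_boot)])
    return float(np.std(ests, ddof=1))


def weighted_median(
    hs: HarmonizedSet, n_boot: int = 1000, seed: int | None = None
) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE."""
    if hs.k < 3:
        raise InsufficientInstrumentsError(f"weighted median needs k >= 3, got {hs.k}")
    re = wald_ratios(hs)
    beta = _weighted_median_point(re.ratio, re.weight)
    rng = np.random.default_rng(seed)
    se = _bootstrap_se(hs, lambda r, w: _weighted_median_point(r, w), n_boot, rng)
    se = max(se, np.finfo(float).tiny)
    return MREstimate(WEIGHTED_MEDIAN, beta, se, float(_norm_p(beta / se)), hs.k)


def _mode_point(r: np.ndarray, w: np.ndarray, weighted: bool, phi: float) -> float:
    """Argmax of the (optionally weighted) Gaussian KDE over the ratios."""
    k = len(r)
    sd = np.std(r, ddof=1) if k > 1 else 0.0
    iqr = np.subtract(*np.percentile(r, [75, 25]))
    band = min(sd, iqr / 1.349)
    if band <= 0:  # ties collapse the IQR; fall back to the sd alone
        band = sd
    h = phi * 0.9 * band * k ** (-1 / 5)
    if h <= 0:  # all ratios identical
        return float(r[0])
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, _MODE_GRID_POINTS)
    wts = (w / w.sum()) if weighted else np.full(k, 1.0 / k)
    dens = np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2) @ wts
    return float(grid[np.argmax(dens)])


def mode_estimate(
    hs: HarmonizedSet,
    weighted: bool,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Mode-based estimate (simple or weighted) with bootstrap SE."""
    if hs.k < 3:
        raise InsufficientInstrumentsError(f"mode estimate needs k >= 3, got {hs.k}")
    re = wald_ratios(hs)
    beta = _mode_point(re.ratio, re.weight, weighted, phi)
    rng = np.random.default_rng(seed)
    se = _bootstrap_se(hs, lambda r, w: _mode_point(r, w, weighted, phi), n_boot, rng)
    se = max(se, np.finfo(float).tiny)
    method = WEIGHTED_MODE if weighted else SIMPLE_MODE
    return MREstimate(method, beta, se, float(_norm_p(beta / se)), hs.k)


def run_all(
    hs: HarmonizedSet,
    seed: int | None = None,
    n_boot: int = 1000,
    variance_model: str = "multiplicative_random",
    phi: float = 1.0,
) -> dict[str, MREstimate]:
    """Run every estimator whose precondition holds.

    Returns a dict keyed by method name; with k < 3 only IVW is present.
    The bootstrap-based methods draw independent streams derived from the
    shared ``seed``, so results are reproducible.
    """
    if hs.k == 0:
        raise EmptyInstrumentSetError("no instruments")
    out: dict[str, MREstimate] = {IVW: ivw(hs, variance_model=variance_model)}
    if hs.k >= 3:
        seeds = np.random.SeedSequence(seed).spawn(3)
        out[EGGER] = egger(hs)[0]
        out[WEIGHTED_MEDIAN] = weighted_median(hs, n_boot=n_boot, seed=seeds[0])
        out[SIMPLE_MODE] = mode_estimate(hs, weighted=False, phi=phi, n_boot=n_boot, seed=seeds[1])
        out[WEIGHTED_MODE] = mode_estimate(hs, weighted=True, phi=phi, n_boot=n_boot, seed=seeds[2])
    return out
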
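"""Heterogeneity, pleiotropy and influence diagnostics.

Every causal claim reported by the screening layer is gated on these:
Cochran's Q over the per-SNP Wald ratios (heterogeneity), the MR-Egger
intercept (directional pleiotropy), and leave-one-out / single-SNP tables
for influence inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, egger, ivw, wald_ratios
from .exceptions import InsufficientInstrumentsError
from .gwas_io import HarmonizedSet


@dataclass(frozen=True)
class QTest:
    """Cochran's Q heterogeneity test over per-SNP Wald ratios."""

    Q: float
    df: int
    pval: float


def cochran_q(hs: HarmonizedSet) -> QTest:
    """Q = sum_j w_j (r_j - beta_fixed)^2, chi-square with k-1 df.

    Computed about the fixed-effect IVW estimate. A small p indicates the
    per-SNP causal estimates disagree beyond sampling noise.
    """
    if hs.k < 2:
        raise InsufficientInstrumentsError(f"Cochran's Q needs k >= 2, got {hs.k}")
    re = wald_ratios(hs)
    beta_fixed = np.sum(re.weight * re.ratio) / np.sum(re.weight)
    q = float(np.sum(re.weight * (re.ratio - beta_fixed) ** 2))
    df = hs.k - 1
    return QTest(Q=q, df=df, pval=float(stats.chi2.sf(q, df)))


def egger_intercept_test(hs: HarmonizedSet) -> tuple[float, float, float]:
    """(intercept, SE, p) from the MR-Egger regression; p from t(k-2)."""
    if hs.k < 3:
        raise InsufficientInstrumentsError(f"Egger intercept needs k >= 3, got {hs.k}")
    _, intercept, se, pval = egger(hs)
    return intercept, se, pval


def leave_one_out(hs: HarmonizedSet, variance_model: str = "multiplicative_random") -> pd.DataFrame:
    """IVW re-fit omitting each SNP in turn.

    Columns: snp_left_out, nsnp, beta, se, pval, sign_flip, crosses_alpha.
    The flags mark SNPs whose omission flips the sign of the estimate or
    moves its p-value across 0.05 relative to the full fit; they are
    reporting aids, not screening gates.
    """
    if hs.k < 3:
        raise InsufficientInstrumentsError(f"leave-one-out needs k >= 3, got {hs.k}")
    full = ivw(hs, variance_model=variance_model)
    rows = []
    for i in range(hs.k):
        mask = np.ones(hs.k, dtype=bool)
        mask[i] = False
        est = ivw(hs.subset(mask), variance_model=variance_model)
        rows.append(
            {
                "snp_left_out": hs.snp_ids[i],
                "nsnp": est.n_snp,
                "beta": est.beta,
                "se": est.se,
                "pval": est.pval,
                "sign_flip": bool(np.sign(est.beta) * np.sign(full.beta) < 0),
                "crosses_alpha": bool((est.pval < 0.05) != (full.pval < 0.05)),
            }
        )
    return pd.DataFrame(rows)


def single_snp(hs: HarmonizedSet) -> pd.DataFrame:
    """Per-SNP Wald ratios with SE and two-sided normal p (columns snp, beta, se, pval)."""
    re = wald_ratios(hs)
    pvals = 2.0 * stats.norm.sf(np.abs(re.ratio / re.se))
    return pd.DataFrame(
        {"snp": hs.snp_ids, "beta": re.ratio, "se": re.se, "pval": pvals}
    )


def scatter_data(hs: HarmonizedSet, estimates: dict[str, MREstimate]) -> pd.DataFrame:
    """Plot-ready table for the exposure-vs-outcome effect scatter.

    One "point" row per SNP (beta_x, beta_y, se_x, se_y) and one "line"
    row per method with its slope and intercept (zero except MR-Egger,
    whose fitted intercept is used).
    """
    rows = [
        {
            "kind": "point",
            "label": hs.snp_ids[i],
            "beta_x": hs.beta_x[i],
            "beta_y": hs.beta_y[i],
            "se_x": hs.se_x[i],
            "se_y": hs.se_y[i],
            "slope": np.nan,
            "intercept": np.nan,
        }
        for i in range(hs.k)
    ]
    egger_intercept = 0.0
    if "Egger" in estimates and hs.k >= 3:
        egger_intercept = egger(hs)[1]
    for method, est in estimates.items():
        rows.append(
            {
                "kind": "line",
                "label": method,
                "beta_x": np.nan,
                "beta_y": np.nan,
                "se_x": np.nan,
                "se_y": np.nan,
                "slope": est.beta,
                "intercept": egger_intercept if method == "Egger" else 0.0,
            }
        )
    return pd.DataFrame(rows)
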
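"""Replicated simulation studies validating the pipeline end to end.

Each study generates synthetic GWAS triplets with
:func:`~medmr.simulate.simulate_triplet`, pushes them through the same
code path a user would run (selection, clumping, harmonization, F
filtering, estimation, gating), and summarizes the result across
replicates. They back both the test suite and the reproducibility
script.

Replicate counts are parameters; the defaults (2000 null sets for test
calibration, 500 triplets for effect recovery, 200 for the pleiotropy
robustness contrast, 2000 pairs for the null screen) keep every study
runnable in minutes on one core while leaving Monte-Carlo error well
below the effects being checked.
"""

from __future__ import annotations

import numpy as np

from . import gwas_io
from .estimators import ivw, weighted_median
from .gwas_io import exclude_snps, f_filter, harmonize, select_instruments
from .mediation import two_step_mediation
from .screening import PipelineConfig, screen_pair
from .sensitivity import cochran_q, egger_intercept_test
from .simulate import SimConfig, simulate_triplet


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    """n reproducible 31-bit child seeds derived from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def qtest_calibration(n_rep: int = 2000, k: int = 10, seed: int = 1) -> float:
    """Type-I error of Cochran's Q at nominal 0.05 on null homogeneous sets.

    Exposure instruments are real (nonzero gamma) but the outcome is
    unrelated, so the per-SNP ratios are homogeneous around zero and Q is
    exactly chi-square(k-1).
    """
    seeds = _spawn_seeds(seed, n_rep)
    rejections = 0
    for s in seeds:
        t = simulate_triplet(SimConfig(m_snps=k, seed=int(s)))
        hs = harmonize(t.exposure, t.outcome)
        rejections += cochran_q(hs).pval < 0.05
    return rejections / n_rep


def intercept_calibration(n_rep: int = 2000, k: int = 10, seed: int = 2) -> float:
    """Type-I error of the Egger intercept test under balanced pleiotropy.

    Every instrument carries a direct outcome effect drawn from
    N(0, 0.02^2) — zero mean (no directional pleiotropy, so the intercept
    truly is zero) with spread comparable to the outcome sampling SE. The
    variance regime matters: with pleiotropy far smaller than sampling
    noise the residual-scale floor at 1 makes the test conservative by
    construction.
    """
    seeds = _spawn_seeds(seed, n_rep)
    rejections = 0
    for s in seeds:
        t = simulate_triplet(
            SimConfig(
                m_snps=k, invalid_fraction=0.99, pleiotropy_mean=0.0,
                pleiotropy_sd=0.02, seed=int(s),
            )
        )
        hs = harmonize(t.exposure, t.outcome)
        rejections += egger_intercept_test(hs)[2] < 0.05
    return rejections / n_rep


def recovery_study(
    n_rep: int = 500,
    seed: int = 3,
    theta1: float = 0.3,
    theta2: float = -0.5,
    theta_direct: float = -0.1,
    m_snps: int = 130,
) -> dict:
    """Total-effect and mediated-proportion recovery through the full pipeline.

    Each replicate simulates a triplet (~100 exposure instruments surviving
    selection and filtering from ``m_snps`` candidates, plus as many
    mediator-specific loci), runs the three univariable MR fits and the
    mediation decomposition, and compares the averages against the
    generative truth. Mediator instruments exclude exposure-associated
    SNPs so the mediator-on-outcome step does not leak the direct path.
    """
    seeds = _spawn_seeds(seed, n_rep)
    totals, props, ks = [], [], []
    for s in seeds:
        cfg = SimConfig(
            m_snps=m_snps, m_mediator_snps=m_snps,
            theta1=theta1, theta2=theta2, theta_direct=theta_direct, seed=int(s),
        )
        t = simulate_triplet(cfg)

        def fit(exposure, outcome):
            iv = select_instruments(exposure)
            iv = gwas_io.clump(iv, t.ld)
            return ivw(f_filter(harmonize(iv, outcome)))

        total = fit(t.exposure, t.outcome)
        b1 = fit(t.exposure, t.mediator)
        exposure_snps = set(select_instruments(t.exposure).df["snp_id"])
        b2 = fit(exclude_snps(t.mediator, exposure_snps), t.outcome)
        res = two_step_mediation(b1.beta, b1.se, b2.beta, b2.se, total.beta, total.se)
        totals.append(total.beta)
        props.append(res.proportion_pct)
        ks.append(total.n_snp)
    totals, props = np.array(totals), np.array(props)
    truth_total = theta1 * theta2 + theta_direct
    return {
        "truth_total": truth_total,
        "truth_proportion_pct": 100.0 * theta1 * theta2 / truth_total,
        "total_mean": float(totals.mean()),
        "total_mcse": float(totals.std(ddof=1) / np.sqrt(n_rep)),
        "proportion_mean": float(props.mean()),
        "proportion_mcse": float(props.std(ddof=1) / np.sqrt(n_rep)),
        "mean_n_instruments": float(np.mean(ks)),
        "n_rep": n_rep,
    }


def pleiotropy_robustness(
    n_rep: int = 200,
    seed: int = 4,
    theta_direct: float = -0.25,
    m_snps: int = 60,
) -> dict:
    """Weighted median vs IVW under 40% invalid weight, directional pleiotropy.

    Exposure effects are one-sided (instruments aligned to the
    exposure-increasing allele) and 40% of instruments carry a positive
    direct outcome effect N(0.1, 0.05^2), so every invalid ratio is
    pushed the same way and IVW is systematically biased. The weighted
    median, with a majority of the weight on valid instruments, stays
    close to the truth (its residual bias is the finite-noise quantile
    shift, vanishing as the sampling SEs shrink).
    """
    seeds = _spawn_seeds(seed, n_rep)
    wm, iv_est = [], []
    for i, s in enumerate(seeds):
        cfg = SimConfig(
            m_snps=m_snps, theta_direct=theta_direct, invalid_fraction=0.4,
            pleiotropy_mean=0.1, pleiotropy_sd=0.05, one_sided_effects=True, seed=int(s),
        )
        t = simulate_triplet(cfg)
        hs = f_filter(harmonize(select_instruments(t.exposure), t.outcome))
        iv_est.append(ivw(hs).beta)
        wm.append(weighted_median(hs, n_boot=50, seed=int(s)).beta)
    wm, iv_est = np.array(wm), np.array(iv_est)
    return {
        "truth": theta_direct,
        "wm_mean": float(wm.mean()),
        "wm_bias": float(wm.mean() - theta_direct),
        "ivw_mean": float(iv_est.mean()),
        "ivw_bias": float(iv_est.mean() - theta_direct),
        "n_rep": n_rep,
    }


def null_screen_study(n_pairs: int = 2000, k: int = 10, seed: int = 5) -> dict:
    """Pass rates on a pure-null screen: compound criterion vs IVW-only.

    Every exposure has real instruments but no effect on the outcome and
    no pleiotropy. The compound criterion (IVW p, five-method direction
    concordance, heterogeneity and pleiotropy gates) must be stricter
    than the IVW p < 0.05 rule alone.
    """
    seeds = _spawn_seeds(seed, n_pairs)
    config = PipelineConfig(n_boot=100)
    compound = 0
    ivw_only = 0
    evaluated = 0
    for s in seeds:
        t = simulate_triplet(SimConfig(m_snps=k, seed=int(s)))
        res = screen_pair(t.exposure, t.outcome, t.ld, config=config, seed=int(s))
        if res is None:
            continue
        evaluated += 1
        compound += res.passed
        ivw_only += res.ivw.pval < 0.05
    return {
        "n_evaluated": evaluated,
        "compound_pass_rate": compound / evaluated,
        "ivw_only_pass_rate": ivw_only / evaluated,
    }
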
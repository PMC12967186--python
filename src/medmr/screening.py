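"""Screening many exposure-outcome pairs with a compound significance rule.

A pair "passes" only if (i) the IVW p-value is below 0.05, (ii) the odds
ratios of all five methods lie strictly on the same side of 1, and
(iii) there is no evidence of heterogeneity (Cochran's Q p > 0.05) or
directional pleiotropy (Egger intercept p > 0.05). A passing pair is
additionally "starred" when at least three of the five method p-values
are below 0.05.

No multiple-testing correction enters the pass/fail decision; Bonferroni
and Benjamini-Hochberg adjusted IVW p-values are emitted alongside for
context.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import gwas_io
from .estimators import METHODS, MREstimate, run_all
from .exceptions import MedMRError
from .gwas_io import HarmonizedSet, LDProvider, SummaryStats
from .sensitivity import QTest, cochran_q, egger_intercept_test

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreeningCriteria:
    """Thresholds of the compound significance rule."""

    ivw_p_max: float = 0.05
    require_direction_concordance: bool = True
    q_p_min: float = 0.05
    intercept_p_min: float = 0.05
    star_methods_min: int = 3

    def __post_init__(self) -> None:
        for name in ("ivw_p_max", "q_p_min", "intercept_p_min"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass(frozen=True)
class PipelineConfig:
    """Instrument-selection and estimation settings shared across a screen."""

    p_threshold: float = 1e-5
    r2_threshold: float = 0.001
    window_kb: int = 1000
    f_min: float = 10.0
    n_boot: int = 1000
    variance_model: str = "multiplicative_random"
    phi: float = 1.0


@dataclass
class ScreeningResult:
    """Verdict for one exposure-outcome pair."""

    exposure_id: str
    outcome_id: str
    estimates: dict[str, MREstimate]
    qtest: QTest | None
    intercept: tuple[float, float, float] | None  # (value, se, p)
    passed: bool = False
    fail_reasons: list[str] = field(default_factory=list)
    starred: bool = False

    @property
    def ivw(self) -> MREstimate | None:
        return self.estimates.get("IVW")


def evaluate_pair(
    estimates: dict[str, MREstimate],
    qtest: QTest | None,
    intercept: tuple[float, float, float] | None,
    criteria: ScreeningCriteria = ScreeningCriteria(),
    exposure_id: str = "",
    outcome_id: str = "",
) -> ScreeningResult:
    """Apply the compound criterion to one pair's estimates and diagnostics.

    Every input yields a result; pairs lacking any of the five methods
    (or the diagnostics) auto-fail with reason ``insufficient_methods``.
    """
    res = ScreeningResult(exposure_id, outcome_id, estimates, qtest, intercept)
    reasons = res.fail_reasons
    if any(m not in estimates for m in METHODS) or qtest is None or intercept is None:
        reasons.append("insufficient_methods")
        return res
    ivw_est = estimates["IVW"]
    if not ivw_est.pval < criteria.ivw_p_max:
        reasons.append("ivw_not_significant")
    if criteria.require_direction_concordance:
        ors = np.array([estimates[m].odds_ratio for m in METHODS])
        if not (np.all(ors > 1.0) or np.all(ors < 1.0)):  # OR exactly 1 is discordant
            reasons.append("direction_discordant")
    if not qtest.pval > criteria.q_p_min:
        reasons.append("heterogeneity")
    if not intercept[2] > criteria.intercept_p_min:
        reasons.append("pleiotropy")
    res.passed = not reasons
    if res.passed:
        n_sig = sum(estimates[m].pval < 0.05 for m in METHODS)
        res.starred = n_sig >= criteria.star_methods_min
    return res


def screen_pair(
    exposure: SummaryStats,
    outcome: SummaryStats,
    ld: LDProvider | None = None,
    criteria: ScreeningCriteria = ScreeningCriteria(),
    config: PipelineConfig = PipelineConfig(),
    seed: int | None = None,
) -> ScreeningResult | None:
    """Full per-pair pipeline: select, clump, harmonize, filter, estimate, gate.

    Returns ``None`` when no instruments survive (the pair is "skipped",
    not failed).
    """
    ld = ld or LDProvider.independent()
    iv = gwas_io.select_instruments(exposure, p_threshold=config.p_threshold)
    if len(iv) == 0:
        return None
    iv = gwas_io.clump(iv, ld, r2_threshold=config.r2_threshold, window_kb=config.window_kb)
    hs = gwas_io.harmonize(iv, outcome)
    if hs.k == 0:
        return None
    hs = gwas_io.f_filter(hs, f_threshold=config.f_min)
    if hs.k == 0:
        return None
    estimates = run_all(
        hs,
        seed=seed,
        n_boot=config.n_boot,
        variance_model=config.variance_model,
        phi=config.phi,
    )
    qtest = cochran_q(hs) if hs.k >= 2 else None
    intercept = egger_intercept_test(hs) if hs.k >= 3 else None
    return evaluate_pair(
        estimates, qtest, intercept, criteria,
        exposure_id=exposure.trait_id, outcome_id=outcome.trait_id,
    )


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def results_table(results: Sequence[ScreeningResult]) -> pd.DataFrame:
    """Flatten screening results into the forest-plot-ready table, sorted by IVW p."""
    rows = []
    for r in results:
        row: dict = {
            "exposure": r.exposure_id,
            "outcome": r.outcome_id,
            "passed": r.passed,
            "starred": r.starred,
            "fail_reasons": ";".join(r.fail_reasons),
        }
        for m in METHODS:
            est = r.estimates.get(m)
            prefix = m.lower()
            if est is None:
                row.update({f"{prefix}_{c}": np.nan for c in ("nsnp", "beta", "se", "pval", "or", "or_lci95", "or_uci95")})
            else:
                row.update({f"{prefix}_{c}": v for c, v in est.as_dict().items() if c != "method"})
        row["q"] = r.qtest.Q if r.qtest else np.nan
        row["q_pval"] = r.qtest.pval if r.qtest else np.nan
        row["egger_intercept"] = r.intercept[0] if r.intercept else np.nan
        row["egger_intercept_pval"] = r.intercept[2] if r.intercept else np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        p = df["ivw_pval"].to_numpy(float)
        df["ivw_p_bonferroni"] = np.minimum(p * len(p), 1.0)
        df["ivw_p_bh"] = _bh_adjust(p)
        df = df.sort_values("ivw_pval", kind="stable").reset_index(drop=True)
    return df


def screen_many(
    exposure_files: Iterable[str | Path],
    outcome_file: str | Path,
    criteria: ScreeningCriteria = ScreeningCriteria(),
    config: PipelineConfig = PipelineConfig(),
    seed: int | None = None,
    ld: LDProvider | None = None,
    outcome_trait_type: str = "binary",
) -> tuple[list[ScreeningResult], pd.DataFrame, pd.DataFrame]:
    """Screen many exposure files against one outcome file.

    Returns ``(results, all_pairs_table, skipped_table)``. Per-exposure
    seeds are derived deterministically from ``seed``, so the same call
    reproduces the same tables. Unreadable files are recorded in the
    skipped table and the run continues.
    """
    outcome = gwas_io.read_sumstats(outcome_file, trait_type=outcome_trait_type)
    results: list[ScreeningResult] = []
    skipped: list[dict] = []
    root = np.random.SeedSequence(seed)
    exposure_files = list(exposure_files)
    child_seeds = root.spawn(len(exposure_files))
    for path, child in zip(exposure_files, child_seeds):
        try:
            exposure = gwas_io.read_sumstats(path)
        except (MedMRError, OSError) as exc:
            skipped.append({"exposure": str(path), "reason": f"read_error: {exc}"})
            continue
        pair_seed = int(child.generate_state(1)[0] % (2**31))
        try:
            res = screen_pair(exposure, outcome, ld, criteria, config, seed=pair_seed)
        except MedMRError as exc:
            skipped.append({"exposure": exposure.trait_id, "reason": str(exc)})
            continue
        if res is None:
            skipped.append({"exposure": exposure.trait_id, "reason": "no_surviving_instruments"})
        else:
            results.append(res)
    table = results_table(results)
    skipped_df = pd.DataFrame(skipped, columns=["exposure", "reason"])
    return results, table, skipped_df


def criteria_from_yaml(path: str | Path) -> tuple[ScreeningCriteria, PipelineConfig]:
    """Load screening thresholds and pipeline settings from a YAML file.

    Recognized top-level keys: ``criteria`` and ``pipeline``; unknown
    keys raise so typos do not silently fall back to defaults.
    """
    data = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(data) - {"criteria", "pipeline"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return (
        ScreeningCriteria(**(data.get("criteria") or {})),
        PipelineConfig(**(data.get("pipeline") or {})),
    )
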
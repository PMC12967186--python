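"""Two-step MR mediation: decomposing a total causal effect into direct
and mediated components.

For an exposure X, mediator M and outcome Y, three univariable MR fits
supply beta1 (X -> M), beta2 (M -> Y) and the total effect (X -> Y). The
mediated (indirect) effect is the product beta1 * beta2; its standard
error uses the first-order delta (Sobel) formula

    se_med = sqrt(beta1^2 * se2^2 + beta2^2 * se1^2)

(the Aroian variant adds the se1^2 * se2^2 term and is available behind
a flag). Significance is a Z-test of mediated / se_med. The mediated
proportion is 100 * mediated / total; its CI is obtained by dividing the
mediated-effect CI endpoints by the total effect, so when total and
mediated have opposite signs the proportion (and its CI) is negative —
the mediator partially offsets the exposure's effect.

Note beta2 here is the univariable mediator-on-outcome estimate, not a
multivariable estimate adjusted for the exposure; with a genetically
correlated exposure and mediator this can bias the decomposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate
from .screening import ScreeningResult

logger = logging.getLogger(__name__)


def proportion_pct(mediated: float, total: float) -> float:
    """Mediated proportion as a percentage of the total effect."""
    return 100.0 * mediated / total


def proportion_ci_pct(ci_low: float, ci_high: float, total: float) -> tuple[float, float]:
    """Map the mediated-effect CI endpoints to proportion-of-total scale.

    Endpoints are divided by the total effect and returned in the same
    order, so a negative total yields a descending (negative) pair.
    """
    return 100.0 * ci_low / total, 100.0 * ci_high / total


@dataclass(frozen=True)
class MediationResult:
    """Decomposition of one exposure -> mediator -> outcome pathway."""

    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta1: float
    se1: float
    beta2: float
    se2: float
    total: float
    se_total: float
    mediated: float
    se_mediated: float
    ci_mediated: tuple[float, float]
    z: float
    pval: float
    direct: float
    proportion_pct: float | None
    proportion_ci_pct: tuple[float, float] | None

    def as_dict(self) -> dict:
        d = {
            "exposure": self.exposure_id,
            "mediator": self.mediator_id,
            "outcome": self.outcome_id,
            "beta1": self.beta1,
            "se1": self.se1,
            "beta2": self.beta2,
            "se2": self.se2,
            "total": self.total,
            "mediated": self.mediated,
            "se_mediated": self.se_mediated,
            "ci_low": self.ci_mediated[0],
            "ci_high": self.ci_mediated[1],
            "z": self.z,
            "p": self.pval,
            "direct": self.direct,
            "proportion_pct": np.nan if self.proportion_pct is None else self.proportion_pct,
            "prop_ci_low_pct": np.nan if self.proportion_ci_pct is None else self.proportion_ci_pct[0],
            "prop_ci_high_pct": np.nan if self.proportion_ci_pct is None else self.proportion_ci_pct[1],
        }
        return d


def two_step_mediation(
    beta1: float,
    se1: float,
    beta2: float,
    se2: float,
    total: float,
    se_total: float,
    exposure_id: str = "exposure",
    mediator_id: str = "mediator",
    outcome_id: str = "outcome",
    aroian: bool = False,
) -> MediationResult:
    """Product-of-coefficients mediation from three MR effect estimates.

    ``beta1``: exposure -> mediator, ``beta2``: mediator -> outcome,
    ``total``: exposure -> outcome. With ``total == 0`` the proportion is
    reported as undefined (None); all other fields are still returned.
    """
    # se1/se2 may be exactly zero (a coefficient treated as known), in which
    # case the Sobel SE degenerates to |other beta| * its se
    for name, se in (("se1", se1), ("se2", se2)):
        if se < 0:
            raise ValueError(f"{name} must be non-negative")
    if not se_total > 0:
        raise ValueError("se_total must be positive")
    mediated = beta1 * beta2
    var = beta1**2 * se2**2 + beta2**2 * se1**2
    if aroian:
        var += se1**2 * se2**2
    se_med = float(np.sqrt(var))
    if se_med > 0:
        z = mediated / se_med
        pval = float(2 * stats.norm.sf(abs(z)))
    else:
        z, pval = 0.0, 1.0
    ci = (mediated - 1.96 * se_med, mediated + 1.96 * se_med)
    if total != 0:
        prop = proportion_pct(mediated, total)
        prop_ci = proportion_ci_pct(ci[0], ci[1], total)
    else:
        prop, prop_ci = None, None
    return MediationResult(
        exposure_id=exposure_id,
        mediator_id=mediator_id,
        outcome_id=outcome_id,
        beta1=beta1,
        se1=se1,
        beta2=beta2,
        se2=se2,
        total=total,
        se_total=se_total,
        mediated=mediated,
        se_mediated=se_med,
        ci_mediated=ci,
        z=float(z),
        pval=pval,
        direct=total - mediated,
        proportion_pct=prop,
        proportion_ci_pct=prop_ci,
    )


def mediate_pathways(
    cyto_metab_results: Sequence[ScreeningResult],
    metab_outcome: Mapping[str, MREstimate],
    cyto_outcome: Mapping[str, MREstimate],
    outcome_id: str = "outcome",
    passed_only: bool = True,
) -> list[MediationResult]:
    """Decompose every exposure -> mediator -> outcome pathway.

    ``cyto_metab_results`` supplies beta1 per (exposure, mediator) pair
    (IVW estimates of the exposure-on-mediator screen); ``metab_outcome``
    and ``cyto_outcome`` map mediator / exposure ids to their IVW
    estimates on the outcome. Pathways missing an upstream estimate are
    skipped with a logged reason; output is sorted by mediation p-value.
    """
    results: list[MediationResult] = []
    for pair in cyto_metab_results:
        if passed_only and not pair.passed:
            continue
        b1 = pair.ivw
        if b1 is None:
            logger.info("skip %s->%s: no IVW estimate", pair.exposure_id, pair.outcome_id)
            continue
        mediator_id = pair.outcome_id
        b2 = metab_outcome.get(mediator_id)
        tot = cyto_outcome.get(pair.exposure_id)
        if b2 is None or tot is None:
            logger.info(
                "skip %s->%s->%s: missing %s estimate",
                pair.exposure_id, mediator_id, outcome_id,
                "mediator-outcome" if b2 is None else "total",
            )
            continue
        results.append(
            two_step_mediation(
                beta1=b1.beta, se1=b1.se,
                beta2=b2.beta, se2=b2.se,
                total=tot.beta, se_total=tot.se,
                exposure_id=pair.exposure_id,
                mediator_id=mediator_id,
                outcome_id=outcome_id,
            )
        )
    results.sort(key=lambda r: r.pval)
    return results


def mediation_table(results: Sequence[MediationResult]) -> pd.DataFrame:
    cols = [
        "exposure", "mediator", "outcome", "beta1", "se1", "beta2", "se2",
        "total", "mediated", "se_mediated", "ci_low", "ci_high", "z", "p",
        "direct", "proportion_pct", "prop_ci_low_pct", "prop_ci_high_pct",
    ]
    return pd.DataFrame([r.as_dict() for r in results], columns=cols)
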
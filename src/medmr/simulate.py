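"""Synthetic GWAS summary statistics with known causal structure.

Generates exposure / mediator / binary-outcome summary-statistics triplets
directly at the summary level (no individual genotypes): each instrument
SNP j gets a true exposure effect gamma_j ~ N(0, effect_sd^2); the
mediator effect is theta1 * gamma_j and the outcome effect is
theta2 * theta1 * gamma_j + theta_direct * gamma_j + alpha_j, where
alpha_j is a direct (pleiotropic) outcome effect carried by a configured
fraction of "invalid" instruments. Observed estimates are the true
effects plus Gaussian sampling noise with

    se = 1 / sqrt(2 p (1 - p) n)

for a standardized continuous trait at minor-allele frequency p, using
the effective sample size n_eff = 4 / (1/n_cases + 1/n_controls) for the
case-control outcome. The exclusion restriction therefore holds exactly
when ``invalid_fraction = 0`` and the true total effect is
theta1 * theta2 + theta_direct by construction.

LD is modelled at the level the pipeline consumes: optional blocks of tag
SNPs whose true effects are attenuated by rho = sqrt(r2) and whose
sampling noise is correlated with the index SNP at rho, together with an
explicit pairwise r^2 table for the clumping step. Default sample sizes
mirror a cytokine-GWAS-sized exposure (14,824), a metabolite-GWAS-sized
mediator (8,299) and a biobank case-control outcome (2,846 cases /
450,887 controls).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import LDProvider, SummaryStats

_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]
_PALINDROME_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class SimConfig:
    """Generative settings for one exposure/mediator/outcome triplet.

    ``effect_sd`` is the SD of per-SNP true effects in trait-SD units per
    allele; 0.2 emulates the strong cis-acting protein/metabolite QTLs
    that dominate cytokine and metabolite instrument sets (mean
    instrument F of order 10^2 at the default sample sizes), while still
    leaving a minority of SNPs below the p < 1e-5 selection threshold.

    ``m_mediator_snps`` adds SNPs that act on the mediator directly
    (zero exposure effect), mirroring the mediator trait having its own
    GWAS-significant loci; without them every mediator instrument would
    act through the exposure and the mediator-on-outcome step of a
    two-step mediation analysis would be unidentifiable.
    """

    m_snps: int = 100
    m_mediator_snps: int = 0
    n_exposure: int = 14824
    n_mediator: int = 8299
    n_cases: int = 2846
    n_controls: int = 450887
    maf_range: tuple[float, float] = (0.05, 0.5)
    effect_sd: float = 0.2
    theta1: float = 0.0
    theta2: float = 0.0
    theta_direct: float = 0.0
    invalid_fraction: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    ld_blocks: tuple[tuple[int, float], ...] = ()
    one_sided_effects: bool = False
    palindrome_fraction: float = 0.0
    duplicate_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.m_snps < 1:
            problems.append("m_snps must be >= 1")
        if self.m_mediator_snps < 0:
            problems.append("m_mediator_snps must be >= 0")
        for name in ("n_exposure", "n_mediator", "n_cases", "n_controls"):
            if getattr(self, name) < 2:
                problems.append(f"{name} must be >= 2")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            problems.append("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0 <= self.invalid_fraction < 1:
            problems.append("invalid_fraction must be in [0, 1)")
        if self.effect_sd <= 0:
            problems.append("effect_sd must be positive")
        for name in ("palindrome_fraction", "duplicate_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                problems.append(f"{name} must be in [0, 1]")
        for size, r2 in self.ld_blocks:
            if size < 2 or not 0 <= r2 <= 1:
                problems.append(f"bad LD block ({size}, {r2})")
        if sum(1 for _ in self.ld_blocks) > self.m_snps:
            problems.append("more LD blocks than index SNPs")
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))


@dataclass
class SimTruth:
    """Ground truth behind a simulated triplet."""

    theta1: float
    theta2: float
    theta_direct: float
    snp_ids: list[str]
    gamma: np.ndarray  # true SNP -> exposure effects
    mu: np.ndarray  # true SNP -> mediator effects
    delta: np.ndarray  # true SNP -> outcome effects (incl. pleiotropy)
    alpha: np.ndarray  # direct pleiotropic outcome effects
    invalid: np.ndarray  # boolean mask of invalid instruments
    total: float = field(init=False)
    mediated: float = field(init=False)
    mediated_proportion_pct: float | None = field(init=False)

    def __post_init__(self) -> None:
        self.mediated = self.theta1 * self.theta2
        self.total = self.mediated + self.theta_direct
        self.mediated_proportion_pct = (
            100.0 * self.mediated / self.total if self.total != 0 else None
        )

    def as_dict(self) -> dict:
        return {
            "theta1": self.theta1,
            "theta2": self.theta2,
            "theta_direct": self.theta_direct,
            "total": self.total,
            "mediated": self.mediated,
            "mediated_proportion_pct": self.mediated_proportion_pct,
            "snp_ids": list(self.snp_ids),
            "gamma": self.gamma.tolist(),
            "mu": self.mu.tolist(),
            "delta": self.delta.tolist(),
            "alpha": self.alpha.tolist(),
            "invalid": self.invalid.astype(bool).tolist(),
        }


@dataclass
class SimTriplet:
    exposure: SummaryStats
    mediator: SummaryStats
    outcome: SummaryStats
    ld: LDProvider
    truth: SimTruth


def _continuous_se(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def simulate_triplet(cfg: SimConfig) -> SimTriplet:
    """Draw one deterministic triplet of summary-statistics tables."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    m = cfg.m_snps + cfg.m_mediator_snps  # index SNPs before LD expansion

    # --- true effects on the index SNPs ---------------------------------
    # exposure instruments carry gamma; mediator-specific SNPs carry eta
    gamma = np.zeros(m)
    gamma[: cfg.m_snps] = rng.normal(0.0, cfg.effect_sd, size=cfg.m_snps)
    if cfg.one_sided_effects:  # effects aligned to the exposure-increasing allele
        gamma = np.abs(gamma)
    eta = np.zeros(m)
    if cfg.m_mediator_snps:
        eta[cfg.m_snps:] = rng.normal(0.0, cfg.effect_sd, size=cfg.m_mediator_snps)
    # invalid (pleiotropic) instruments are drawn among the exposure SNPs
    n_invalid = int(round(cfg.invalid_fraction * cfg.m_snps))
    invalid = np.zeros(m, dtype=bool)
    if n_invalid:
        invalid[rng.choice(cfg.m_snps, size=n_invalid, replace=False)] = True
    alpha = np.where(invalid, rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=m), 0.0)
    mu = cfg.theta1 * gamma + eta
    delta = cfg.theta2 * mu + cfg.theta_direct * gamma + alpha

    # --- expand LD blocks: tags attenuate truth by rho and share noise ---
    rho_of = np.ones(m)
    parent = np.arange(m)
    ids = [f"rs{i + 1:06d}" for i in range(m)]
    chrom = [str((i % 22) + 1) for i in range(m)]
    pos = [10_000_000 + 5_000_000 * (i // 22) for i in range(m)]
    ld = LDProvider()
    block_members: list[list[int]] = []
    for b, (size, r2) in enumerate(cfg.ld_blocks):
        idx = b  # block b anchors on index SNP b
        members = [idx]
        rho = np.sqrt(r2)
        for t in range(size - 1):
            j = len(ids)
            ids.append(f"rs{idx + 1:06d}_tag{t + 1}")
            chrom.append(chrom[idx])
            pos.append(pos[idx] + 10_000 * (t + 1))
            rho_of = np.append(rho_of, rho)
            parent = np.append(parent, idx)
            members.append(j)
        for a in members:
            for bb in members:
                if a < bb:
                    ld.set_r2(ids[a], ids[bb], r2)
        block_members.append(members)
    n_total = len(ids)

    gamma_all = gamma[parent] * rho_of
    mu_all = mu[parent] * rho_of
    delta_all = delta[parent] * rho_of

    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=n_total)
    se_x = _continuous_se(maf, cfg.n_exposure)
    se_m = _continuous_se(maf, cfg.n_mediator)
    n_eff = 4.0 / (1.0 / cfg.n_cases + 1.0 / cfg.n_controls)
    se_y = _continuous_se(maf, int(round(n_eff)))

    # sampling noise; tags correlate with their index SNP at rho per trait
    def correlated_noise() -> np.ndarray:
        z = rng.standard_normal(n_total)
        out = z.copy()
        for j in range(m, n_total):
            p = parent[j]
            out[j] = rho_of[j] * z[p] + np.sqrt(1.0 - rho_of[j] ** 2) * z[j]
        return out

    beta_x = gamma_all + se_x * correlated_noise()
    beta_m = mu_all + se_m * correlated_noise()
    beta_y = delta_all + se_y * correlated_noise()

    # --- alleles ---------------------------------------------------------
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n_total)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx], dtype=object)
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx], dtype=object)
    if cfg.palindrome_fraction:
        n_pal = int(round(cfg.palindrome_fraction * n_total))
        chosen = rng.choice(n_total, size=n_pal, replace=False)
        pal_idx = rng.integers(0, len(_PALINDROME_PAIRS), size=n_pal)
        for c, pi in zip(chosen, pal_idx):
            ea[c], oa[c] = _PALINDROME_PAIRS[pi]

    def make_ss(trait_id: str, trait_type: str, beta: np.ndarray, se: np.ndarray, n: int) -> SummaryStats:
        pval = np.clip(2.0 * stats.norm.sf(np.abs(beta / se)), np.finfo(float).tiny, 1.0)
        df = pd.DataFrame(
            {
                "snp_id": ids,
                "chrom": chrom,
                "pos": pos,
                "effect_allele": ea,
                "other_allele": oa,
                "eaf": maf,
                "beta": beta,
                "se": se,
                "pval": pval,
                "n": n,
            }
        )
        if cfg.duplicate_fraction and trait_id == "exposure":
            n_dup = int(round(cfg.duplicate_fraction * n_total))
            dup_rows = df.iloc[rng.choice(n_total, size=n_dup, replace=False)]
            df = pd.concat([df, dup_rows], ignore_index=True)
        return SummaryStats(trait_id=trait_id, trait_type=trait_type, df=df)

    truth = SimTruth(
        theta1=cfg.theta1,
        theta2=cfg.theta2,
        theta_direct=cfg.theta_direct,
        snp_ids=ids,
        gamma=gamma_all,
        mu=mu_all,
        delta=delta_all,
        alpha=np.concatenate([alpha, alpha[parent[m:]] * rho_of[m:]]) if n_total > m else alpha,
        invalid=np.concatenate([invalid, invalid[parent[m:]]]) if n_total > m else invalid,
    )
    return SimTriplet(
        exposure=make_ss("exposure", "continuous", beta_x, se_x, cfg.n_exposure),
        mediator=make_ss("mediator", "continuous", beta_m, se_m, cfg.n_mediator),
        outcome=make_ss("outcome", "binary", beta_y, se_y, cfg.n_cases + cfg.n_controls),
        ld=ld,
        truth=truth,
    )


def write_triplet(triplet: SimTriplet, out_dir: str | Path) -> None:
    """Write exposure.tsv, mediator.tsv, outcome.tsv, ld.tsv and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    triplet.exposure.to_tsv(out / "exposure.tsv")
    triplet.mediator.to_tsv(out / "mediator.tsv")
    triplet.outcome.to_tsv(out / "outcome.tsv")
    triplet.ld.to_frame().to_csv(out / "ld.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(json.dumps(triplet.truth.as_dict(), indent=1))


#: the named fixture battery used by the unit tests
FIXTURE_CONFIGS: dict[str, SimConfig] = {
    "clean_causal": SimConfig(m_snps=50, theta1=0.3, theta2=-0.5, theta_direct=-0.1, seed=101),
    "null": SimConfig(m_snps=50, seed=102),
    "pleiotropic": SimConfig(
        m_snps=50, theta1=0.3, theta2=-0.5, theta_direct=-0.1,
        invalid_fraction=0.3, pleiotropy_mean=0.08, pleiotropy_sd=0.02, seed=103,
    ),
    "heterogeneous": SimConfig(
        m_snps=50, theta_direct=0.2,
        invalid_fraction=0.8, pleiotropy_mean=0.0, pleiotropy_sd=0.15, seed=104,
    ),
    "ld_blocked": SimConfig(
        m_snps=20, theta_direct=0.2, ld_blocks=((3, 0.8), (2, 0.5)), seed=105,
    ),
    "palindrome": SimConfig(m_snps=50, theta_direct=0.2, palindrome_fraction=0.3, seed=106),
    "duplicate": SimConfig(m_snps=50, theta_direct=0.2, duplicate_fraction=0.2, seed=107),
}


def write_fixture_suite(out_dir: str | Path) -> dict[str, Path]:
    """Emit the deterministic fixture battery plus a manifest; returns name -> dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    manifest = {}
    for name, cfg in FIXTURE_CONFIGS.items():
        d = out / name
        write_triplet(simulate_triplet(cfg), d)
        written[name] = d
        manifest[name] = {
            "seed": cfg.seed,
            "m_snps": cfg.m_snps,
            "theta1": cfg.theta1,
            "theta2": cfg.theta2,
            "theta_direct": cfg.theta_direct,
            "invalid_fraction": cfg.invalid_fraction,
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return written
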
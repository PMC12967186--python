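"""Reading, instrument selection, LD clumping and allele harmonization of
GWAS summary statistics.

The unit of data is one trait's summary-statistics table (one row per SNP,
with effect/other allele, beta, SE, p). Exposure and outcome tables are
joined on SNP id and harmonized so both effects refer to the same effect
allele; the resulting :class:`HarmonizedSet` carries the aligned effect
vectors consumed by every causal estimator.

Conventions implemented here:

* instrument selection keeps SNPs with p strictly below the threshold
  (default 1e-5);
* LD clumping is the standard greedy procedure: visit SNPs by ascending
  p-value and keep each unless it lies within the window of an
  already-kept SNP on the same chromosome with r^2 at or above the
  threshold (defaults r^2 < 0.001, +/-1000 kb);
* palindromic (A/T, C/G) and duplicated SNP ids are removed outright;
* per-SNP instrument strength is F = (beta/se)^2, the squared marginal
  z-score, and instruments with F at or below 10 are dropped by default.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError, SumstatsFormatError

logger = logging.getLogger(__name__)

#: default header names of the TSV dialect -> internal field names
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "SNP": "snp_id",
    "CHR": "chrom",
    "POS": "pos",
    "EA": "effect_allele",
    "OA": "other_allele",
    "EAF": "eaf",
    "BETA": "beta",
    "SE": "se",
    "P": "pval",
    "N": "n",
}

_MANDATORY = ("snp_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "pval")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass(frozen=True)
class VariantAssoc:
    """One SNP's association with one trait."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if not self.se > 0:
            raise ValueError(f"{self.snp_id}: se must be positive")
        if not 0 < self.pval <= 1:
            raise ValueError(f"{self.snp_id}: pval outside (0, 1]")


@dataclass
class SummaryStats:
    """Summary statistics for one trait, one row per SNP.

    ``df`` columns: snp_id, chrom, pos, effect_allele, other_allele, eaf,
    beta, se, pval, n. Row order is meaningful (selection preserves it,
    clumping re-sorts by genomic position).
    """

    trait_id: str
    trait_type: str  # "continuous" | "binary"
    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        missing = [c for c in _MANDATORY if c not in self.df.columns]
        if missing:
            raise SumstatsFormatError(f"missing columns: {', '.join(missing)}")
        for opt in ("eaf", "n"):
            if opt not in self.df.columns:
                self.df[opt] = np.nan

    def __len__(self) -> int:
        return len(self.df)

    @property
    def records(self) -> list[VariantAssoc]:
        out = []
        for row in self.df.itertuples(index=False):
            out.append(
                VariantAssoc(
                    snp_id=row.snp_id,
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    effect_allele=row.effect_allele,
                    other_allele=row.other_allele,
                    beta=float(row.beta),
                    se=float(row.se),
                    pval=float(row.pval),
                    eaf=None if pd.isna(row.eaf) else float(row.eaf),
                    n=None if pd.isna(row.n) else int(row.n),
                )
            )
        return out

    @classmethod
    def from_records(
        cls, trait_id: str, trait_type: str, records: Iterable[VariantAssoc]
    ) -> "SummaryStats":
        rows = [
            {
                "snp_id": r.snp_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": np.nan if r.eaf is None else r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pval": r.pval,
                "n": np.nan if r.n is None else r.n,
            }
            for r in records
        ]
        df = pd.DataFrame(rows, columns=list(DEFAULT_COLUMN_MAP.values()))
        return cls(trait_id=trait_id, trait_type=trait_type, df=df)

    def to_tsv(self, path: str | Path) -> None:
        out = self.df.rename(columns={v: k for k, v in DEFAULT_COLUMN_MAP.items()})
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")


class LDProvider:
    """Pairwise r^2 lookup. Pairs not in the table have r^2 = 0; r^2(a, a) = 1."""

    def __init__(self, table: Mapping[tuple[str, str], float] | None = None):
        self._r2: dict[frozenset, float] = {}
        if table:
            for (a, b), r2 in table.items():
                self.set_r2(a, b, r2)

    def set_r2(self, a: str, b: str, r2: float) -> None:
        if not 0 <= r2 <= 1:
            raise ValueError(f"r2({a},{b})={r2} outside [0,1]")
        if a != b:
            self._r2[frozenset((a, b))] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    @classmethod
    def independent(cls) -> "LDProvider":
        """All pairs independent (r^2 = 0)."""
        return cls()

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LDProvider":
        """Build from a table with columns SNP_A, SNP_B, R2."""
        prov = cls()
        for row in df.itertuples(index=False):
            prov.set_r2(str(row.SNP_A), str(row.SNP_B), float(row.R2))
        return prov

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LDProvider":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"SNP_A": a, "SNP_B": b, "R2": r2}
            for pair, r2 in sorted(self._r2.items(), key=lambda kv: sorted(kv[0]))
            for a, b in [sorted(pair)]
        ]
        return pd.DataFrame(rows, columns=["SNP_A", "SNP_B", "R2"])


@dataclass
class HarmonizeAudit:
    """Bookkeeping of what harmonization did to the SNP intersection."""

    n_input: int = 0
    n_palindromic_dropped: int = 0
    n_unmatched: int = 0
    n_duplicate_dropped: int = 0
    n_flipped: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


@dataclass
class HarmonizedSet:
    """Exposure/outcome effects aligned to a common effect allele, one row per SNP."""

    exposure_id: str
    outcome_id: str
    snp_ids: np.ndarray
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    effect_allele: np.ndarray | None = None
    other_allele: np.ndarray | None = None
    audit: HarmonizeAudit = field(default_factory=HarmonizeAudit)

    def __post_init__(self) -> None:
        arrays = [self.snp_ids, self.beta_x, self.se_x, self.beta_y, self.se_y]
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.beta_x = np.asarray(self.beta_x, dtype=float)
        self.se_x = np.asarray(self.se_x, dtype=float)
        self.beta_y = np.asarray(self.beta_y, dtype=float)
        self.se_y = np.asarray(self.se_y, dtype=float)
        k = len(self.snp_ids)
        if any(len(a) != k for a in arrays):
            raise ValueError("harmonized vectors must share one length")
        if k and (np.any(self.se_x <= 0) or np.any(self.se_y <= 0)):
            raise ValueError("all standard errors must be positive")

    @property
    def k(self) -> int:
        return len(self.snp_ids)

    def __len__(self) -> int:
        return self.k

    @property
    def f_stats(self) -> np.ndarray:
        """Per-SNP instrument strength F = (beta_x / se_x)^2."""
        return (self.beta_x / self.se_x) ** 2

    def subset(self, mask: np.ndarray) -> "HarmonizedSet":
        def take(a):
            return None if a is None else np.asarray(a)[mask]

        return replace(
            self,
            snp_ids=self.snp_ids[mask],
            beta_x=self.beta_x[mask],
            se_x=self.se_x[mask],
            beta_y=self.beta_y[mask],
            se_y=self.se_y[mask],
            chrom=take(self.chrom),
            pos=take(self.pos),
            effect_allele=take(self.effect_allele),
            other_allele=take(self.other_allele),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "SNP": self.snp_ids,
                "CHR": self.chrom if self.chrom is not None else "",
                "POS": self.pos if self.pos is not None else -1,
                "EA": self.effect_allele if self.effect_allele is not None else "",
                "OA": self.other_allele if self.other_allele is not None else "",
                "BETA_X": self.beta_x,
                "SE_X": self.se_x,
                "BETA_Y": self.beta_y,
                "SE_Y": self.se_y,
                "F": self.f_stats if self.k else np.array([]),
            }
        )
        return df

    def to_tsv(self, path: str | Path, audit_sidecar: bool = True) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
        if audit_sidecar:
            sidecar = path.with_suffix(path.suffix + ".audit.json")
            sidecar.write_text(json.dumps(self.audit.as_dict(), indent=1))

    @classmethod
    def from_tsv(
        cls, path: str | Path, exposure_id: str = "exposure", outcome_id: str = "outcome"
    ) -> "HarmonizedSet":
        df = pd.read_csv(path, sep="\t")
        return cls(
            exposure_id=exposure_id,
            outcome_id=outcome_id,
            snp_ids=df["SNP"].astype(str).to_numpy(dtype=object),
            beta_x=df["BETA_X"].to_numpy(float),
            se_x=df["SE_X"].to_numpy(float),
            beta_y=df["BETA_Y"].to_numpy(float),
            se_y=df["SE_Y"].to_numpy(float),
            chrom=df["CHR"].astype(str).to_numpy(dtype=object) if "CHR" in df else None,
            pos=df["POS"].to_numpy(int) if "POS" in df else None,
        )


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    trait_type: str = "continuous",
) -> SummaryStats:
    """Read one trait's summary statistics from a headered TSV.

    ``column_map`` maps file header names to the internal field names
    (defaults to the SNP/CHR/POS/EA/OA/EAF/BETA/SE/P/N dialect). Rows with
    missing beta, SE or alleles are dropped with a logged count; alleles
    are uppercased.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(column_map or DEFAULT_COLUMN_MAP)
    try:
        raw = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty") from None
    missing = [src for src, dst in cmap.items() if dst in _MANDATORY and src not in raw.columns]
    if missing:
        raise SumstatsFormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    df = raw.rename(columns=cmap)
    df = df[[c for c in DEFAULT_COLUMN_MAP.values() if c in df.columns]].copy()
    n_before = len(df)
    if n_before == 0:
        raise EmptyInputError(f"{path}: no data rows")
    df = df.dropna(subset=["beta", "se", "effect_allele", "other_allele"])
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("%s: dropped %d row(s) with missing beta/se/alleles", path, n_dropped)
    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    return SummaryStats(
        trait_id=trait_id or path.stem, trait_type=trait_type, df=df.reset_index(drop=True)
    )


def exclude_snps(ss: SummaryStats, snp_ids: Iterable[str]) -> SummaryStats:
    """Remove the listed SNP ids (e.g. exposure-associated variants when
    building a mediator instrument set), preserving row order."""
    drop = set(snp_ids)
    kept = ss.df[~ss.df["snp_id"].isin(drop)].reset_index(drop=True)
    return SummaryStats(trait_id=ss.trait_id, trait_type=ss.trait_type, df=kept)


def select_instruments(ss: SummaryStats, p_threshold: float = 1e-5) -> SummaryStats:
    """Keep SNPs with p strictly below ``p_threshold``, preserving row order."""
    if not 0 < p_threshold <= 1:
        raise ValueError("p_threshold must be in (0, 1]")
    kept = ss.df[ss.df["pval"] < p_threshold].reset_index(drop=True)
    if kept.empty:
        logger.warning("%s: no instruments at p < %g", ss.trait_id, p_threshold)
    return SummaryStats(trait_id=ss.trait_id, trait_type=ss.trait_type, df=kept)


def clump(
    ss: SummaryStats,
    ld: LDProvider,
    r2_threshold: float = 0.001,
    window_kb: int = 1000,
) -> SummaryStats:
    """Greedy LD clumping.

    Visit SNPs by ascending p-value; keep a SNP unless it lies within
    ``window_kb`` (inclusive, either side) of an already-kept SNP on the
    same chromosome with r^2 >= ``r2_threshold``. Output sorted by
    (chrom, pos).
    """
    df = ss.df
    if df.empty:
        return SummaryStats(trait_id=ss.trait_id, trait_type=ss.trait_type, df=df.copy())
    order = df["pval"].to_numpy().argsort(kind="stable")
    snp = df["snp_id"].to_numpy(dtype=object)
    chrom = df["chrom"].to_numpy(dtype=object)
    pos = df["pos"].to_numpy(dtype=np.int64)
    window_bp = window_kb * 1000
    kept: list[int] = []
    for i in order:
        independent = True
        for j in kept:
            if chrom[j] != chrom[i]:
                continue
            if abs(int(pos[j]) - int(pos[i])) > window_bp:
                continue
            if ld.r2(snp[i], snp[j]) >= r2_threshold:
                independent = False
                break
        if independent:
            kept.append(i)
    out = df.iloc[kept].sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return SummaryStats(trait_id=ss.trait_id, trait_type=ss.trait_type, df=out)


def _classify_alleles(
    ea_x: str, oa_x: str, ea_y: str, oa_y: str
) -> str:
    """Classify an exposure/outcome allele pairing.

    Returns one of "palindromic", "same", "swap", or "unmatched". Strand
    complements are reconciled before declaring a mismatch; a pair that is
    palindromic in either trait cannot be resolved and is dropped.
    """
    if (ea_x, oa_x) in _PALINDROMIC or (ea_y, oa_y) in _PALINDROMIC:
        return "palindromic"
    if (ea_y, oa_y) == (ea_x, oa_x):
        return "same"
    if (ea_y, oa_y) == (oa_x, ea_x):
        return "swap"
    try:
        cea, coa = _COMPLEMENT[ea_y], _COMPLEMENT[oa_y]
    except KeyError:
        return "unmatched"
    if (cea, coa) == (ea_x, oa_x):
        return "same"
    if (cea, coa) == (oa_x, ea_x):
        return "swap"
    return "unmatched"


def harmonize(exposure: SummaryStats, outcome: SummaryStats) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect alleles.

    SNPs present in both traits are kept if the allele pairs agree
    directly, after swapping effect/other (outcome beta negated, EAF
    complemented), or after strand complementation. Palindromic pairs and
    SNP ids duplicated in either file are removed. The returned set may be
    empty; consumers treat k = 0 as "pair skipped".
    """
    if exposure.df.empty or outcome.df.empty:
        raise EmptyInputError("harmonize requires non-empty exposure and outcome")
    audit = HarmonizeAudit(n_input=len(exposure.df))

    dup_x = set(exposure.df.loc[exposure.df["snp_id"].duplicated(keep=False), "snp_id"])
    dup_y = set(outcome.df.loc[outcome.df["snp_id"].duplicated(keep=False), "snp_id"])
    dup = dup_x | dup_y
    out_by_id = {
        r.snp_id: r for r in outcome.df.itertuples(index=False) if r.snp_id not in dup
    }

    rows: list[dict] = []
    for r in exposure.df.itertuples(index=False):
        if r.snp_id in dup:
            audit.n_duplicate_dropped += 1
            continue
        o = out_by_id.get(r.snp_id)
        if o is None:
            audit.n_unmatched += 1
            continue
        kind = _classify_alleles(
            r.effect_allele, r.other_allele, o.effect_allele, o.other_allele
        )
        if kind == "palindromic":
            audit.n_palindromic_dropped += 1
            continue
        if kind == "unmatched":
            audit.n_unmatched += 1
            continue
        beta_y = float(o.beta)
        if kind == "swap":
            beta_y = -beta_y
            audit.n_flipped += 1
        rows.append(
            {
                "snp_id": r.snp_id,
                "chrom": str(r.chrom),
                "pos": int(r.pos),
                "ea": r.effect_allele,
                "oa": r.other_allele,
                "beta_x": float(r.beta),
                "se_x": float(r.se),
                "beta_y": beta_y,
                "se_y": float(o.se),
            }
        )
    # duplicates only in the exposure file are already counted; duplicates only
    # in the outcome file surface as unmatched exposure SNPs, which keeps the
    # audit identity n_input = k + palindromic + unmatched + duplicate intact
    hs = HarmonizedSet(
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        snp_ids=np.array([r["snp_id"] for r in rows], dtype=object),
        beta_x=np.array([r["beta_x"] for r in rows]),
        se_x=np.array([r["se_x"] for r in rows]),
        beta_y=np.array([r["beta_y"] for r in rows]),
        se_y=np.array([r["se_y"] for r in rows]),
        chrom=np.array([r["chrom"] for r in rows], dtype=object),
        pos=np.array([r["pos"] for r in rows], dtype=int),
        effect_allele=np.array([r["ea"] for r in rows], dtype=object),
        other_allele=np.array([r["oa"] for r in rows], dtype=object),
        audit=audit,
    )
    if hs.k == 0:
        logger.warning(
            "%s ~ %s: no SNPs survived harmonization", exposure.trait_id, outcome.trait_id
        )
    return hs


def f_filter(hs: HarmonizedSet, f_threshold: float = 10.0) -> HarmonizedSet:
    """Drop weak instruments: keep SNPs with F = (beta_x/se_x)^2 strictly above the threshold."""
    mask = hs.f_stats > f_threshold
    out = hs.subset(mask)
    out.audit = hs.audit
    if out.k == 0:
        logger.warning("%s ~ %s: all instruments weak (F <= %g)", hs.exposure_id, hs.outcome_id, f_threshold)
    return out
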
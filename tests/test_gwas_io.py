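"""Reading, instrument selection, clumping, harmonization, F filtering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from medmr import (
    LDProvider,
    SummaryStats,
    clump,
    f_filter,
    harmonize,
    read_sumstats,
    select_instruments,
    simulate_triplet,
    SimConfig,
)
from medmr.exceptions import EmptyInputError, SumstatsFormatError
from medmr.gwas_io import exclude_snps

from conftest import make_hs

HEADER = "SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tP\tN"


def write_tsv(path, rows):
    path.write_text(HEADER + "\n" + "\n".join(rows) + "\n")
    return path


def var_row(snp="rs1", chrom="1", pos=100, ea="A", oa="G", eaf=0.3, beta=0.1, se=0.02, p=1e-6, n=10000):
    return f"{snp}\t{chrom}\t{pos}\t{ea}\t{oa}\t{eaf}\t{beta}\t{se}\t{p}\t{n}"


class TestReadSumstats:
    def test_well_formed_file_round_trips(self, tmp_path):
        rows = [var_row(snp=f"rs{i}", pos=100 * i) for i in range(1, 6)]
        ss = read_sumstats(write_tsv(tmp_path / "x.tsv", rows))
        assert len(ss) == 5
        assert ss.records[0].snp_id == "rs1"
        assert ss.trait_id == "x"

    def test_row_with_missing_se_is_dropped(self, tmp_path):
        rows = [var_row(snp=f"rs{i}") for i in range(1, 5)]
        rows.append("rs5\t1\t500\tA\tG\t0.3\t0.1\t\t1e-6\t10000")
        ss = read_sumstats(write_tsv(tmp_path / "x.tsv", rows))
        assert len(ss) == 4
        assert "rs5" not in set(ss.df["snp_id"])

    def test_lowercase_alleles_are_uppercased(self, tmp_path):
        ss = read_sumstats(write_tsv(tmp_path / "x.tsv", [var_row(ea="a", oa="g")]))
        rec = ss.records[0]
        assert (rec.effect_allele, rec.other_allele) == ("A", "G")

    def test_missing_mandatory_column_names_it(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("SNP\tCHR\tPOS\tEA\tOA\tEAF\tSE\tP\tN\nrs1\t1\t1\tA\tG\t0.3\t0.02\t1e-6\t1\n")
        with pytest.raises(SumstatsFormatError, match="BETA"):
            read_sumstats(p)

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.raises(EmptyInputError):
            read_sumstats(p)


class TestSelectInstruments:
    def test_strict_threshold(self, tmp_path):
        rows = [var_row(snp="rs1", p=1e-6), var_row(snp="rs2", pos=200, p=1e-4)]
        ss = read_sumstats(write_tsv(tmp_path / "x.tsv", rows))
        kept = select_instruments(ss, 1e-5)
        assert list(kept.df["snp_id"]) == ["rs1"]

    def test_threshold_one_keeps_everything(self, tmp_path):
        rows = [var_row(snp=f"rs{i}", pos=100 * i, p=0.5) for i in range(1, 4)]
        ss = read_sumstats(write_tsv(tmp_path / "x.tsv", rows))
        assert len(select_instruments(ss, 1.0)) == 3

    def test_null_snps_essentially_never_survive(self):
        # 100 SNPs with true effect 0: expected survivors 100 * 1e-5
        rng = np.random.default_rng(0)
        z = rng.standard_normal(100)
        pvals = 2 * stats.norm.sf(np.abs(z))
        ss = SummaryStats(
            trait_id="null",
            trait_type="continuous",
            df=pd.DataFrame(
                {
                    "snp_id": [f"rs{i}" for i in range(100)],
                    "chrom": "1",
                    "pos": np.arange(100) * 100,
                    "effect_allele": "A",
                    "other_allele": "G",
                    "beta": z * 0.01,
                    "se": 0.01,
                    "pval": pvals,
                }
            ),
        )
        # binomial(100, 1e-5): P(any survivor) ~ 1e-3
        assert len(select_instruments(ss, 1e-5)) == 0

    def test_exclude_snps(self, tmp_path):
        rows = [var_row(snp=f"rs{i}", pos=100 * i) for i in range(1, 4)]
        ss = read_sumstats(write_tsv(tmp_path / "x.tsv", rows))
        assert list(exclude_snps(ss, {"rs2"}).df["snp_id"]) == ["rs1", "rs3"]


def _brute_force_clump(df, ld, r2_threshold, window_bp):
    """Re-derive every kept/dropped decision straight from the rule."""
    order = df["pval"].to_numpy().argsort(kind="stable")
    kept = []
    for i in order:
        blocked = any(
            df.iloc[j]["chrom"] == df.iloc[i]["chrom"]
            and abs(int(df.iloc[j]["pos"]) - int(df.iloc[i]["pos"])) <= window_bp
            and ld.r2(df.iloc[i]["snp_id"], df.iloc[j]["snp_id"]) >= r2_threshold
            for j in kept
        )
        if not blocked:
            kept.append(i)
    return sorted(df.iloc[i]["snp_id"] for i in kept)


class TestClump:
    def two_snp_ss(self, pos2, p1=1e-8, p2=1e-6):
        df = pd.DataFrame(
            {
                "snp_id": ["rs1", "rs2"],
                "chrom": ["1", "1"],
                "pos": [1_000_000, pos2],
                "effect_allele": "A",
                "other_allele": "G",
                "beta": [0.1, 0.1],
                "se": [0.01, 0.01],
                "pval": [p1, p2],
            }
        )
        return SummaryStats("x", "continuous", df)

    def test_correlated_neighbour_is_pruned(self):
        ss = self.two_snp_ss(pos2=1_500_000)
        ld = LDProvider({("rs1", "rs2"): 0.5})
        kept = clump(ss, ld)
        assert list(kept.df["snp_id"]) == ["rs1"]

    def test_outside_window_both_kept(self):
        ss = self.two_snp_ss(pos2=3_000_001)  # 2000 kb away
        ld = LDProvider({("rs1", "rs2"): 0.5})
        assert len(clump(ss, ld)) == 2

    def test_matches_brute_force_on_ld_block_fixture(self):
        rng = np.random.default_rng(3)
        n = 10
        df = pd.DataFrame(
            {
                "snp_id": [f"rs{i}" for i in range(n)],
                "chrom": ["1"] * 6 + ["2"] * 4,
                "pos": [1e6, 1.2e6, 1.4e6, 5e6, 5.1e6, 9e6, 1e6, 1.3e6, 4e6, 4.2e6],
                "effect_allele": "A",
                "other_allele": "G",
                "beta": 0.1,
                "se": 0.01,
                "pval": rng.uniform(1e-9, 1e-5, n),
            }
        )
        df["pos"] = df["pos"].astype(int)
        ld = LDProvider(
            {("rs0", "rs1"): 0.9, ("rs0", "rs2"): 0.7, ("rs1", "rs2"): 0.8,
             ("rs3", "rs4"): 0.4, ("rs6", "rs7"): 0.0005, ("rs8", "rs9"): 0.2}
        )
        ss = SummaryStats("x", "continuous", df)
        kept = sorted(clump(ss, ld).df["snp_id"])
        assert kept == _brute_force_clump(df, ld, 0.001, 1_000_000)

    def test_output_is_independent_at_threshold(self):
        rng = np.random.default_rng(11)
        t = simulate_triplet(SimConfig(m_snps=15, ld_blocks=((4, 0.9), (3, 0.5)), seed=5))
        kept = clump(t.exposure, t.ld)
        ids = list(kept.df["snp_id"])
        pos = dict(zip(kept.df["snp_id"], kept.df["pos"]))
        chrom = dict(zip(kept.df["snp_id"], kept.df["chrom"]))
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if chrom[a] == chrom[b] and abs(pos[a] - pos[b]) <= 1_000_000:
                    assert t.ld.r2(a, b) < 0.001


def one_snp_ss(trait, ea="A", oa="G", beta=0.1, snp="rs1", **kw):
    df = pd.DataFrame(
        [{
            "snp_id": snp, "chrom": "1", "pos": 100, "effect_allele": ea,
            "other_allele": oa, "beta": beta, "se": kw.get("se", 0.02),
            "pval": 1e-6,
        }]
    )
    return SummaryStats(trait, kw.get("trait_type", "continuous"), df)


class TestHarmonize:
    def test_identical_alleles_kept_unchanged(self):
        hs = harmonize(one_snp_ss("x", beta=0.1), one_snp_ss("y", beta=0.2))
        assert hs.k == 1
        assert hs.beta_y[0] == pytest.approx(0.2)
        assert hs.audit.n_flipped == 0

    def test_swapped_alleles_negate_outcome_beta(self):
        hs = harmonize(one_snp_ss("x", "A", "G", 0.1), one_snp_ss("y", "G", "A", 0.2))
        assert hs.beta_y[0] == pytest.approx(-0.2)
        assert hs.audit.n_flipped == 1

    def test_strand_complement_match(self):
        # exposure A/G vs outcome T/C: same variant on the other strand
        hs = harmonize(one_snp_ss("x", "A", "G", 0.1), one_snp_ss("y", "T", "C", 0.2))
        assert hs.k == 1
        assert hs.beta_y[0] == pytest.approx(0.2)

    def test_palindromic_snp_dropped(self):
        hs = harmonize(one_snp_ss("x", "A", "T"), one_snp_ss("y", "A", "T"))
        assert hs.k == 0
        assert hs.audit.n_palindromic_dropped == 1

    def test_irreconcilable_alleles_unmatched(self):
        hs = harmonize(one_snp_ss("x", "A", "G"), one_snp_ss("y", "A", "C"))
        assert hs.k == 0
        assert hs.audit.n_unmatched == 1

    def test_duplicate_snp_ids_dropped_entirely(self):
        df = pd.concat([one_snp_ss("x").df, one_snp_ss("x").df], ignore_index=True)
        exp = SummaryStats("x", "continuous", df)
        hs = harmonize(exp, one_snp_ss("y"))
        assert hs.k == 0
        assert hs.audit.n_duplicate_dropped == 2

    def test_audit_counts_sum_to_input(self):
        t = simulate_triplet(SimConfig(m_snps=60, palindrome_fraction=0.2, duplicate_fraction=0.1, seed=9))
        hs = harmonize(t.exposure, t.outcome)
        a = hs.audit
        assert a.n_input == hs.k + a.n_palindromic_dropped + a.n_unmatched + a.n_duplicate_dropped

    def test_planted_palindromes_all_counted(self):
        cfg = SimConfig(m_snps=50, palindrome_fraction=0.3, seed=106)
        t = simulate_triplet(cfg)
        planted = sum(
            (ea, oa) in {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
            for ea, oa in zip(t.exposure.df["effect_allele"], t.exposure.df["other_allele"])
        )
        hs = harmonize(t.exposure, t.outcome)
        assert hs.audit.n_palindromic_dropped == planted == round(0.3 * 50)

    def test_idempotent(self):
        t = simulate_triplet(SimConfig(m_snps=30, seed=2))
        hs1 = harmonize(t.exposure, t.outcome)
        # re-harmonize the harmonized exposure against the harmonized outcome
        exp2 = SummaryStats(
            "x", "continuous",
            pd.DataFrame({
                "snp_id": hs1.snp_ids, "chrom": hs1.chrom, "pos": hs1.pos,
                "effect_allele": hs1.effect_allele, "other_allele": hs1.other_allele,
                "beta": hs1.beta_x, "se": hs1.se_x, "pval": 1e-6,
            }),
        )
        out2 = SummaryStats(
            "y", "binary",
            pd.DataFrame({
                "snp_id": hs1.snp_ids, "chrom": hs1.chrom, "pos": hs1.pos,
                "effect_allele": hs1.effect_allele, "other_allele": hs1.other_allele,
                "beta": hs1.beta_y, "se": hs1.se_y, "pval": 0.5,
            }),
        )
        hs2 = harmonize(exp2, out2)
        assert hs2.k == hs1.k
        np.testing.assert_allclose(hs2.beta_y, hs1.beta_y)
        assert hs2.audit.n_flipped == 0

    def test_swap_then_swap_restores_beta(self):
        # outcome reported on swapped alleles, then swapped again -> original
        first = harmonize(one_snp_ss("x", "A", "G", 0.1), one_snp_ss("y", "G", "A", 0.2))
        assert first.beta_y[0] == pytest.approx(-0.2)
        back = harmonize(
            one_snp_ss("x", "G", "A", 0.1),  # exposure itself reported swapped
            one_snp_ss("y", "A", "G", first.beta_y[0]),
        )
        assert back.beta_y[0] == pytest.approx(0.2)


class TestFFilter:
    def test_strong_instrument_kept(self):
        hs = make_hs([0.1], [0.01], [0.05], [0.01])
        assert f_filter(hs).k == 1  # F = 100

    def test_weak_instrument_dropped(self):
        hs = make_hs([0.03], [0.01], [0.05], [0.01])
        assert f_filter(hs).k == 0  # F = 9

    def test_mixed_set_matches_hand_rule(self):
        beta_x = np.array([0.1, 0.03, 0.05, 0.2])
        se_x = np.array([0.01, 0.01, 0.02, 0.1])
        hs = make_hs(beta_x, se_x, [0.1] * 4, [0.02] * 4)
        expected = [f"rs{i + 1}" for i in range(4) if (beta_x[i] / se_x[i]) ** 2 > 10]
        assert list(f_filter(hs).snp_ids) == expected

    def test_zero_threshold_is_identity(self, homogeneous_hs):
        out = f_filter(homogeneous_hs, f_threshold=0.0)
        assert out.k == homogeneous_hs.k

    def test_never_increases_k(self, homogeneous_hs):
        assert f_filter(homogeneous_hs, f_threshold=1e6).k <= homogeneous_hs.k
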
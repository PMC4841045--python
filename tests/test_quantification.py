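import numpy as np
import pandas as pd
import pytest

from taxopep.database import ProteinRecord, SequenceDatabase
from taxopep.digestion import DigestionParams, build_peptide_index
from taxopep.quantification import (
    EvidenceTable,
    GenusAbundanceTable,
    GenusQuantParams,
    bacterial_fraction_by_rank,
    core_membership_histogram,
    cumulative_abundance_fraction,
    fold_change_between_states,
    genus_abundance_topn,
    genus_pools,
    pairwise_log_r2,
    read_evidence,
    zscore_within_sample,
)

from oracles import brute_force_topn

MC0 = DigestionParams(max_missed_cleavages=0)

# 17 distinct single-fragment tryptic peptides
PEPS = [c * 6 + "K" for c in "ACDEFGHILMNQSTVWY"]


def strep_db(n_peptides, taxon="s_mitis"):
    db = SequenceDatabase()
    db.add(ProteinRecord("prot1", "".join(PEPS[:n_peptides]), taxon), "src")
    return db


def evidence_of(intensities: dict[str, dict[str, float]]) -> EvidenceTable:
    df = pd.DataFrame(intensities).fillna(0.0)  # columns = samples
    return EvidenceTable(df)


class TestReadEvidence:
    def write(self, tmp_path, text):
        p = tmp_path / "evidence.tsv"
        p.write_text(text)
        return p

    def test_reverse_rows_removed_and_counted(self, tmp_path):
        path = self.write(
            tmp_path,
            "Sequence\tReverse\tIntensity s1\n"
            "AAAAAAK\t\t10\nCCCCCCK\t+\t5\nDDDDDDK\t\t1\n"
            "EEEEEEK\t\t2\nFFFFFFK\t\t3\n",
        )
        table, report = read_evidence(path)
        assert report["reverse"] == 1
        assert len(table.peptides) == 4
        assert "CCCCCCK" not in table.peptides

    def test_missing_flag_columns_is_warning_not_error(self, tmp_path, caplog):
        path = self.write(tmp_path, "Sequence\tIntensity s1\nAAAAAAK\t10\n")
        with caplog.at_level("WARNING"):
            table, report = read_evidence(path)
        assert len(table.peptides) == 1
        assert report == {"reverse": 0, "contaminant": 0}
        assert any("filter skipped" in m for m in caplog.messages)

    def test_negative_intensity_rejected(self, tmp_path):
        path = self.write(tmp_path, "Sequence\tIntensity s1\nAAAAAAK\t-3\n")
        with pytest.raises(ValueError, match="negative intensity"):
            read_evidence(path)

    def test_missing_sequence_column_rejected(self, tmp_path):
        path = self.write(tmp_path, "Pep\tIntensity s1\nAAAAAAK\t3\n")
        with pytest.raises(ValueError, match="sequence column"):
            read_evidence(path)

    def test_duplicate_peptide_rows_are_summed(self, tmp_path):
        path = self.write(
            tmp_path,
            "Sequence\tIntensity s1\nAAAAAAK\t10\nAAAAAAK\t5\n",
        )
        table, _ = read_evidence(path)
        assert table.intensities.at["AAAAAAK", "s1"] == 15.0


class TestGenusAbundanceTopN:
    def test_twelve_peptides_intensities_1_to_12_gives_75(self, toy_tree):
        db = strep_db(12)
        index = build_peptide_index(db, MC0)
        ev = evidence_of({"s1": {p: float(i + 1) for i, p in enumerate(PEPS[:12])}})
        table = genus_abundance_topn(ev, index, toy_tree)
        assert table.abundance.at["strep", "s1"] == 75.0  # 78 - (1 + 2)

    def test_pool_of_exactly_ten_sums_everything(self, toy_tree):
        db = strep_db(10)
        index = build_peptide_index(db, MC0)
        ev = evidence_of({"s1": {p: float(i + 1) for i, p in enumerate(PEPS[:10])}})
        table = genus_abundance_topn(ev, index, toy_tree)
        assert table.abundance.at["strep", "s1"] == 55.0

    def test_pool_of_nine_is_excluded(self, toy_tree):
        db = strep_db(9)
        index = build_peptide_index(db, MC0)
        ev = evidence_of({"s1": {p: 1.0 for p in PEPS[:9]}})
        table = genus_abundance_topn(ev, index, toy_tree)
        assert "strep" not in table.abundance.index
        assert "strep" in table.excluded_genera
        assert "9" in table.excluded_genera["strep"]

    def test_zeros_never_occupy_topn_slots(self, toy_tree):
        db = strep_db(12)
        index = build_peptide_index(db, MC0)
        vals = {p: 0.0 for p in PEPS[:12]}
        vals[PEPS[0]] = 4.0
        vals[PEPS[1]] = 2.0
        ev = evidence_of({"s1": vals})
        table = genus_abundance_topn(ev, index, toy_tree)
        assert table.abundance.at["strep", "s1"] == 6.0

    def test_global_median_mode_fixes_selection_across_samples(self, toy_tree):
        db = strep_db(12)
        index = build_peptide_index(db, MC0)
        # peptide i has median i+1; top-10 by median = PEPS[2..11]
        ev = evidence_of(
            {
                "s1": {p: float(i + 1) for i, p in enumerate(PEPS[:12])},
                "s2": {p: float(i + 1) for i, p in enumerate(PEPS[:12])},
            }
        )
        params = GenusQuantParams(mode="global-median")
        table = genus_abundance_topn(ev, index, toy_tree, params)
        assert table.abundance.at["strep", "s1"] == 75.0
        assert table.abundance.at["strep", "s2"] == 75.0

    def test_matches_full_sort_oracle_on_random_tables(self, small_dataset):
        ds = small_dataset
        index = build_peptide_index(ds.database, ds.config.digestion)
        pools = genus_pools(ds.evidence, index, ds.tree)
        rng = np.random.default_rng(3)
        samples = ds.evidence.samples
        peptides = ds.evidence.peptides
        for _ in range(10):
            mat = rng.uniform(0, 100, size=(len(peptides), len(samples)))
            mat[rng.random(mat.shape) < 0.3] = 0.0
            ev = EvidenceTable(pd.DataFrame(mat, index=peptides, columns=samples))
            table = genus_abundance_topn(ev, index, ds.tree)
            expected = brute_force_topn(ev, pools, 10)
            assert set(table.abundance.index) == set(expected)
            for g, row in expected.items():
                for s in samples:
                    assert table.abundance.at[g, s] == pytest.approx(row[s])

    def test_scale_equivariance(self, small_dataset):
        ds = small_dataset
        index = build_peptide_index(ds.database, ds.config.digestion)
        base = genus_abundance_topn(ds.evidence, index, ds.tree)
        for c in (0.5, 3.0):
            scaled = genus_abundance_topn(ds.evidence.scaled(c), index, ds.tree)
            pd.testing.assert_frame_equal(scaled.abundance, base.abundance * c)

    def test_adding_pool_peptide_never_decreases_abundance(self, toy_tree):
        index12 = build_peptide_index(strep_db(12), MC0)
        index13 = build_peptide_index(strep_db(13), MC0)
        vals = {p: float(i + 1) for i, p in enumerate(PEPS[:13])}
        ev = evidence_of({"s1": vals})
        a12 = genus_abundance_topn(ev, index12, toy_tree).abundance.at["strep", "s1"]
        a13 = genus_abundance_topn(ev, index13, toy_tree).abundance.at["strep", "s1"]
        assert a13 >= a12


def quant_table(values: dict[str, dict[str, float]]) -> GenusAbundanceTable:
    df = pd.DataFrame(values).T  # rows = genera
    return GenusAbundanceTable(
        abundance=df,
        n_peptides_in_pool=pd.Series({g: 10 for g in df.index}),
        excluded_genera={},
        params=GenusQuantParams(),
    )


class TestFoldChange:
    def test_identical_states_give_ratio_one(self):
        q = quant_table({"g1": {"s1": 5.0, "s2": 7.0}, "g2": {"s1": 1.0, "s2": 3.0}})
        table, summary = fold_change_between_states(q, q)
        assert (table["ratio"] == 1.0).all()
        assert summary["median_fold_change"] == 1.0

    def test_halved_state_b_gives_ratio_two(self):
        qa = quant_table({"g1": {"s1": 5.0}, "g2": {"s1": 8.0}})
        qb = quant_table({"g1": {"s2": 2.5}, "g2": {"s2": 4.0}})
        table, _ = fold_change_between_states(qa, qb)
        assert (table["ratio"] == 2.0).all()

    def test_genus_missing_in_one_state_not_evaluable(self):
        qa = quant_table({"g1": {"s1": 5.0}, "g2": {"s1": 8.0}})
        qb = quant_table({"g1": {"s2": 2.5}})
        table, summary = fold_change_between_states(qa, qb)
        assert not table.loc["g2", "evaluable"]
        assert np.isnan(table.loc["g2", "ratio"])
        assert summary["n_evaluable"] == 1

    def test_grouping_splits_one_table_into_states(self):
        q = quant_table({"g1": {"a1": 4.0, "a2": 6.0, "b1": 2.0, "b2": 3.0}})
        table, _ = fold_change_between_states(
            q, q, grouping={"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        )
        assert table.loc["g1", "ratio"] == 2.0

    def test_empty_state_rejected(self):
        q = quant_table({"g1": {"s1": 1.0}})
        with pytest.raises(ValueError, match="exactly 2 states"):
            fold_change_between_states(q, q, grouping={"s1": "A"})


class TestCoreMembership:
    def test_single_donor_puts_everything_in_bin_one(self):
        presence = pd.DataFrame([[True, True, False]], index=["d1"],
                                columns=["p1", "p2", "p3"])
        hist, core, pct = core_membership_histogram(presence)
        assert hist == {1: 2}
        assert core == {"p1", "p2"}

    def test_two_donor_enumeration(self):
        presence = pd.DataFrame(
            {"p1": [True, True], "p2": [True, False], "p3": [False, True]},
            index=["d1", "d2"],
        )
        hist, core, pct = core_membership_histogram(presence)
        assert hist == {1: 2, 2: 1}
        assert core == {"p1"}
        assert pct[2] == pytest.approx(100.0 / 3)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            core_membership_histogram(pd.DataFrame())


class TestCumulativeAbundance:
    def test_equal_abundances_give_k_over_n(self):
        ab = {f"p{i}": 2.0 for i in range(8)}
        assert cumulative_abundance_fraction(ab, 3) == pytest.approx(3 / 8)

    def test_dominant_protein(self):
        assert cumulative_abundance_fraction({"a": 8.0, "b": 1.0, "c": 1.0}, 1) == 0.8

    def test_k_at_least_n_returns_exactly_one(self):
        ab = {"a": 1.0, "b": 5.0}
        assert cumulative_abundance_fraction(ab, 2) == 1.0
        assert cumulative_abundance_fraction(ab, 99) == 1.0

    def test_non_decreasing_in_k(self):
        rng = np.random.default_rng(8)
        ab = {f"p{i}": float(v) for i, v in enumerate(rng.uniform(0, 10, 20))}
        fracs = [cumulative_abundance_fraction(ab, k) for k in range(1, 21)]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cumulative_abundance_fraction({"a": 0.0}, 1)


class TestBacterialFraction:
    def test_all_human_is_zero_everywhere(self):
        df = bacterial_fraction_by_rank([(f"p{i}", "human") for i in range(20)])
        assert (df["cumulative_pct_bacterial"] == 0.0).all()

    def test_all_bacterial_is_hundred_everywhere(self):
        df = bacterial_fraction_by_rank([(f"p{i}", "bacterial") for i in range(20)])
        assert (df["cumulative_pct_bacterial"] == 100.0).all()

    def test_strict_alternation_hits_fifty_at_even_ranks(self):
        ranked = [
            (f"p{i}", "human" if i % 2 == 0 else "bacterial") for i in range(10)
        ]
        df = bacterial_fraction_by_rank(ranked)
        even = df[df["rank"] % 2 == 0]
        assert (even["cumulative_pct_bacterial"] == 50.0).all()

    def test_unknown_origin_rejected(self):
        with pytest.raises(ValueError, match="unknown origin"):
            bacterial_fraction_by_rank([("p1", "viral")])


class TestZscore:
    def test_two_point_column(self):
        out = zscore_within_sample(pd.DataFrame({"s1": [1.0, 3.0]}))
        assert list(out["s1"]) == [-1.0, 1.0]

    def test_columns_standardized(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.uniform(0, 50, size=(30, 4)), columns=list("abcd"))
        out = zscore_within_sample(df)
        assert np.allclose(out.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(out.std(axis=0, ddof=0), 1.0, atol=1e-12)

    def test_idempotent_on_standardized_input(self):
        df = pd.DataFrame({"s1": [-1.0, 0.0, 1.0] * 2})
        df["s1"] = (df["s1"] - df["s1"].mean()) / df["s1"].std(ddof=0)
        out = zscore_within_sample(df)
        assert np.allclose(out["s1"], df["s1"], atol=1e-12)

    def test_constant_column_error_names_sample(self):
        df = pd.DataFrame({"good": [1.0, 2.0], "flat": [3.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            zscore_within_sample(df)


class TestPairwiseLogR2:
    def test_identical_vectors(self):
        a = pd.Series([1.0, 10.0, 100.0], index=list("xyz"))
        assert pairwise_log_r2(a, a).r2 == pytest.approx(1.0)

    def test_global_scaling_is_perfect_fit(self):
        a = pd.Series([1.0, 10.0, 100.0, 1000.0], index=list("wxyz"))
        assert pairwise_log_r2(a, 2 * a).r2 == pytest.approx(1.0)

    def test_three_point_closed_form(self):
        a = pd.Series([1.0, 10.0, 100.0], index=list("xyz"))
        b = pd.Series([1.0, 100.0, 10.0], index=list("xyz"))
        # logs: x=(0,1,2), y=(0,2,1) -> r = (1/3)/(2/3) = 0.5 -> R^2 = 0.25
        assert pairwise_log_r2(a, b).r2 == pytest.approx(0.25)

    def test_nonpositive_entries_dropped_and_counted(self):
        a = pd.Series([1.0, 10.0, 100.0, 0.0], index=list("wxyz"))
        b = pd.Series([2.0, 20.0, 200.0, 5.0], index=list("wxyz"))
        res = pairwise_log_r2(a, b)
        assert res.n_used == 3 and res.n_dropped == 1

    def test_too_few_shared_positive_entries(self):
        a = pd.Series([1.0, 0.0, 3.0], index=list("xyz"))
        b = pd.Series([1.0, 2.0, 0.0], index=list("xyz"))
        with pytest.raises(ValueError, match="need >= 3"):
            pairwise_log_r2(a, b)
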
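"""Ground-truth properties of the synthetic generator.

The generator's observation model is fully known (normal fold-change noise
with standard error tau = residual_sd * sqrt(2/n)), so its behaviour is
checked against closed forms: uniform p-values under the null, the normal
power formula at the p < 0.05 gate, a self-consistent fixed point for the
Benjamini-Hochberg gate, binomial counts for reference-set construction.
"""

import io

import numpy as np
import pytest
from scipy import stats

from sigcross import (
    GenerativeConfig,
    ProgramSpec,
    ValidationError,
    extract_signature,
    pair_fold_changes,
    simulate_comparison_bank,
    simulate_de_study,
    simulate_pair,
    simulate_reference_sets,
    spearman_rho,
)
from sigcross.io import write_de_table


def null_config(n_genes=10000, seed=0, **kw):
    return GenerativeConfig(n_genes=n_genes, programs=[], seed=seed, **kw)


def one_program_config(seed=0, **kw):
    defaults = dict(n_genes=2000,
                    programs=[ProgramSpec("prog", 100, 2.0)],
                    residual_sd=1.0, n_replicates_per_group=4)
    defaults.update(kw)
    return GenerativeConfig(seed=seed, **defaults)


class TestConfigValidation:
    def test_program_sizes_must_fit(self):
        with pytest.raises(ValidationError):
            GenerativeConfig(n_genes=50, programs=[ProgramSpec("p", 100, 2.0)])

    def test_up_program_needs_positive_effect(self):
        with pytest.raises(ValidationError):
            ProgramSpec("p", 10, -1.0, direction="up")

    def test_fraction_ranges(self):
        with pytest.raises(ValidationError):
            GenerativeConfig(ortholog_coverage=0.0)
        with pytest.raises(ValidationError):
            GenerativeConfig(refset_precision=1.5)


class TestSimulateDEStudy:
    def test_deterministic_and_byte_identical(self):
        cfg = one_program_config(seed=123)
        t1, _ = simulate_de_study(cfg)
        t2, _ = simulate_de_study(cfg)
        buf1, buf2 = io.StringIO(), io.StringIO()
        t1.data.to_csv(buf1, sep="\t", index=False, float_format="%.12g")
        t2.data.to_csv(buf2, sep="\t", index=False, float_format="%.12g")
        assert buf1.getvalue() == buf2.getvalue()

    def test_null_pvalues_uniform(self):
        table, _ = simulate_de_study(null_config(seed=4))
        frac = (table.data["pvalue"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 10000)
        assert frac == pytest.approx(0.05, abs=3 * se)

    def test_noiseless_limit_recovers_effect(self):
        cfg = one_program_config(residual_sd=1e-9, seed=1)
        table, truth = simulate_de_study(cfg)
        members = truth.index[truth.is_member]
        lfc = table.data.set_index("gene").loc[members, "log2fc"]
        np.testing.assert_allclose(lfc, 2.0, atol=1e-6)
        assert (table.data.set_index("gene").loc[members, "pvalue"] < 1e-10).all()

    def test_member_power_matches_closed_form(self):
        # tau = sqrt(2/4); p < 0.05 gate power = Phi(z - 1.96) + Phi(-z - 1.96)
        tau = np.sqrt(2 / 4)
        z = 2.0 / tau
        crit = stats.norm.isf(0.025)
        closed = stats.norm.cdf(z - crit) + stats.norm.cdf(-z - crit)
        hits = []
        for seed in range(200):
            table, truth = simulate_de_study(one_program_config(seed=seed))
            members = truth.index[truth.is_member]
            hits.append(
                (table.data.set_index("gene").loc[members, "pvalue"] < 0.05).mean()
            )
        assert np.mean(hits) == pytest.approx(closed, abs=0.02)

    def test_truth_bookkeeping(self):
        _, truth = simulate_de_study(one_program_config(seed=9))
        assert (truth.loc[truth.is_member, "beta"] != 0).all()
        assert (truth.loc[~truth.is_member, "beta"] == 0).all()

    def test_down_program_is_negative(self):
        cfg = GenerativeConfig(
            n_genes=500, programs=[ProgramSpec("d", 50, 2.0, direction="down")],
            seed=3,
        )
        _, truth = simulate_de_study(cfg)
        assert (truth.loc[truth.is_member, "beta"] < 0).all()

    def test_membership_overlap_shares_genes(self):
        cfg = GenerativeConfig(
            n_genes=500,
            programs=[ProgramSpec("p1", 100, 2.0), ProgramSpec("p2", 100, 2.0)],
            program_membership_overlap=0.2, seed=0,
        )
        _, truth = simulate_de_study(cfg)
        both = truth["programs"].str.contains(";").sum()
        assert both == 20

    def test_bh_null_false_discovery_proportion(self):
        # all-null tables: realized FDP averaged over 100 seeds stays near
        # the nominal 0.1 level
        fdps = []
        for seed in range(100):
            table, _ = simulate_de_study(null_config(n_genes=2000, seed=seed))
            n_sel = (table.data["fdr"] <= 0.1).sum()
            fdps.append(1.0 if n_sel > 0 else 0.0)  # every discovery is false
        assert np.mean(fdps) <= 0.15


class TestSimulatePair:
    def test_symbols_differ_by_case_and_map_links_them(self):
        pair = simulate_pair(GenerativeConfig(n_genes=100, seed=0,
                                              ortholog_coverage=1.0))
        a, b = pair.ortholog_map.pairs[0]
        assert b == a.upper()
        assert a in pair.table_a.genes and b in pair.table_b.genes

    def test_unshared_pair_rho_near_zero(self):
        rhos = []
        for seed in range(50):
            cfg = GenerativeConfig(n_genes=5000, seed=seed,
                                   programs=[ProgramSpec("p", 100, 2.0)])
            pair = simulate_pair(cfg, shared_programs=[])
            pv = pair_fold_changes(pair.table_a, pair.table_b,
                                   pair.ortholog_map)
            rhos.append(spearman_rho(pv))
        assert abs(np.mean(rhos)) < 0.05

    def test_shared_member_mean_fold_change(self):
        # planted members' mean observed log2fc within 3*tau/sqrt(size) of 2
        cfg = one_program_config(seed=2)
        tol = 3 * cfg.tau / np.sqrt(100)
        pair = simulate_pair(cfg)
        members_a = pair.truth.index[pair.truth.shared_member]
        members_b = pair.truth.loc[members_a, "gene_b"]
        mean_a = pair.table_a.data.set_index("gene").loc[members_a, "log2fc"].mean()
        mean_b = pair.table_b.data.set_index("gene").loc[members_b, "log2fc"].mean()
        assert mean_a == pytest.approx(2.0, abs=tol)
        assert mean_b == pytest.approx(2.0, abs=tol)

    def test_truth_covers_every_gene(self):
        pair = simulate_pair(GenerativeConfig(n_genes=300, seed=1))
        assert set(pair.truth.index) == pair.table_a.genes
        assert set(pair.truth.gene_b) == pair.table_b.genes

    def test_reference_members_exist_in_universe(self):
        pair = simulate_pair(GenerativeConfig(n_genes=300, seed=1))
        assert pair.reference_sets.all_members() <= pair.table_a.genes

    def test_ambiguous_entries_added(self):
        cfg = GenerativeConfig(n_genes=200, ortholog_coverage=1.0,
                               one_to_many_fraction=0.1, seed=0)
        pair = simulate_pair(cfg)
        counts = pair.ortholog_map.multiplicity_counts()
        assert counts["one_to_many"] == 20
        assert counts["one_to_one"] == 180

    def test_byte_identical_written_tables(self, tmp_path):
        cfg = one_program_config(seed=77)
        for name in ("x", "y"):
            pair = simulate_pair(cfg)
            write_de_table(pair.table_a, tmp_path / f"{name}_a.tsv")
            write_de_table(pair.table_b, tmp_path / f"{name}_b.tsv")
        assert (tmp_path / "x_a.tsv").read_bytes() == \
            (tmp_path / "y_a.tsv").read_bytes()
        assert (tmp_path / "x_b.tsv").read_bytes() == \
            (tmp_path / "y_b.tsv").read_bytes()


class TestReferenceSets:
    def test_perfect_sensitivity_precision_equals_membership(self):
        cfg = one_program_config(seed=5)
        _, truth = simulate_de_study(cfg)
        coll = simulate_reference_sets(truth, sensitivity=1.0, precision=1.0,
                                       seed=0)
        members = set(truth.index[truth.is_member])
        assert coll["prog"].members == members

    def test_expected_true_member_count_binomial(self):
        cfg = one_program_config(seed=5)
        _, truth = simulate_de_study(cfg)
        members = set(truth.index[truth.is_member])
        counts = []
        for seed in range(100):
            coll = simulate_reference_sets(truth, sensitivity=0.8,
                                           precision=1.0, seed=seed)
            counts.append(len(coll["prog"].members & members))
        se = np.sqrt(100 * 0.8 * 0.2)
        assert np.mean(counts) == pytest.approx(80, abs=3 * se / np.sqrt(100))

    def test_precision_padding(self):
        cfg = one_program_config(seed=5)
        _, truth = simulate_de_study(cfg)
        members = set(truth.index[truth.is_member])
        coll = simulate_reference_sets(truth, sensitivity=1.0, precision=0.8,
                                       seed=1)
        refset = coll["prog"].members
        assert len(refset - members) == 25  # 100 * (1/0.8 - 1)

    def test_decoys_avoid_program_members(self):
        cfg = one_program_config(seed=5)
        _, truth = simulate_de_study(cfg)
        members = set(truth.index[truth.is_member])
        coll = simulate_reference_sets(truth, sensitivity=0.8, precision=0.8,
                                       seed=2)
        assert not coll["decoy_prog_1"].members & members

    def test_invalid_sensitivity(self):
        cfg = one_program_config(seed=5)
        _, truth = simulate_de_study(cfg)
        with pytest.raises(ValidationError):
            simulate_reference_sets(truth, sensitivity=0.0, precision=0.5)


class TestComparisonBank:
    def test_sharing_comparisons_correlate_stronger(self):
        cfg = one_program_config(seed=8)
        table_a, omap, comparisons = simulate_comparison_bank(cfg, 3, 3)
        rhos = {}
        for cid, table_b, shares in comparisons:
            pv = pair_fold_changes(table_a, table_b, omap)
            rhos[cid] = (spearman_rho(pv), shares)
        sharing = [r for r, s in rhos.values() if s]
        nulls = [r for r, s in rhos.values() if not s]
        assert min(sharing) > max(nulls)

    def test_signature_recovery_at_bh_gate_matches_fixed_point_oracle(self):
        # self-consistent BH threshold: k = R(0.1 k / m) with
        # R(t) = m0 t + m1 [Phi(z - z_{t/2}) + Phi(-z - z_{t/2})]
        m, m1 = 2000, 100
        z = 2.0 / np.sqrt(2 / 4)

        def rejections(t):
            zq = stats.norm.isf(t / 2)
            power = stats.norm.cdf(z - zq) + stats.norm.cdf(-z - zq)
            return (m - m1) * t + m1 * power

        k = float(m1)
        for _ in range(200):
            k = rejections(0.1 * k / m)
        zq = stats.norm.isf(0.1 * k / m / 2)
        oracle = stats.norm.cdf(z - zq) + stats.norm.cdf(-z - zq)

        recovered = []
        for seed in range(100):
            table, truth = simulate_de_study(one_program_config(seed=seed))
            sig = extract_signature(table)
            members = set(truth.index[truth.is_member])
            recovered.append(len(sig.up & members) / 100)
        assert np.mean(recovered) == pytest.approx(oracle, abs=0.05)
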
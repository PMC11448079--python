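"""TPM normalization, Welch contrasts, BH adjustment and the overlay."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mobilome import expression_overlay as xo
from mobilome import genome_diff as gd
from mobilome import impact_annotator as ia
from mobilome import synthetic_data as sd


class TestTPM:
    def test_closed_form(self):
        tpm = xo.tpm_from_counts([10, 10], [1000, 2000])
        assert tpm[0] == pytest.approx(666666.67, abs=0.01)
        assert tpm[1] == pytest.approx(333333.33, abs=0.01)

    def test_single_gene(self):
        assert xo.tpm_from_counts([5], [700])[0] == pytest.approx(1e6)

    def test_normalization_identity(self, rng):
        counts = rng.integers(0, 1000, size=200)
        lengths = rng.integers(300, 3000, size=200)
        assert xo.tpm_from_counts(counts, lengths).sum() == pytest.approx(1e6, abs=1e-3)

    def test_all_zero_counts(self):
        assert (xo.tpm_from_counts([0, 0], [100, 100]) == 0).all()

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            xo.tpm_from_counts([1], [0])


class TestWelch:
    def test_hand_computed_example(self):
        t, df, p = xo.welch_t([10, 12], [20, 22])
        assert t == pytest.approx(-7.071, abs=1e-3)
        assert df == pytest.approx(2.0)

    def test_identical_groups(self):
        t, df, p = xo.welch_t([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert t == 0.0 and p == 1.0

    def test_swap_flips_sign_keeps_p(self):
        t1, _, p1 = xo.welch_t([1.0, 2.0, 4.0], [8.0, 9.0, 11.0])
        t2, _, p2 = xo.welch_t([8.0, 9.0, 11.0], [1.0, 2.0, 4.0])
        assert t1 == -t2 and p1 == pytest.approx(p2)

    def test_zero_variance_unequal_means_uses_floor(self):
        t, df, p = xo.welch_t([10.0, 10.0], [20.0, 20.0])
        assert np.isfinite(t) and 0 <= p < 1e-6

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError):
            xo.welch_t([1.0], [2.0, 3.0])

    def test_matches_scipy(self, rng):
        for _ in range(30):
            a = rng.normal(10, 2, size=int(rng.integers(2, 8)))
            b = rng.normal(12, 3, size=int(rng.integers(2, 8)))
            t, df, p = xo.welch_t(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)


def _bh_oracle(p):
    """Step-up adjustment written out longhand."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


class TestBH:
    def test_hand_computed_step_up(self):
        q = xo.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert xo.bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_permutation_invariance_per_gene(self, rng):
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        assert np.allclose(xo.bh_fdr(p)[perm], xo.bh_fdr(p[perm]))

    def test_nan_passthrough(self):
        q = xo.bh_fdr([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and not np.isnan(q[0])

    def test_matches_longhand_oracle(self, rng):
        for _ in range(20):
            p = rng.uniform(size=int(rng.integers(1, 50)))
            assert np.allclose(xo.bh_fdr(p), _bh_oracle(p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            xo.bh_fdr([1.5])


def _make_table(rng, n_genes, effect_genes=(), effect=1.0, n_rep=2, cv=0.1,
                timepoints=("T1",)):
    sigma = np.sqrt(np.log1p(cv**2))
    base = np.exp(rng.normal(3.5, 1.0, size=n_genes))
    rows = []
    for strain, mult_map in (("wildtype", {}), ("mutant", dict.fromkeys(effect_genes, effect))):
        for tp in timepoints:
            for rep in range(n_rep):
                noise = np.exp(rng.normal(0, sigma, size=n_genes))
                for i in range(n_genes):
                    rows.append(
                        {
                            "gene_id": f"g{i:04d}",
                            "strain": strain,
                            "timepoint": tp,
                            "replicate": rep,
                            "tpm": base[i] * mult_map.get(f"g{i:04d}", 1.0) * noise[i],
                        }
                    )
    return pd.DataFrame(rows)


class TestFlagDE:
    def test_identical_strains_nothing_significant(self, rng):
        table = _make_table(rng, 80)
        de = xo.flag_de(table, ("wildtype", "mutant"))
        assert not de["significant"].any()

    def test_inclusive_thresholds(self):
        assert xo._is_significant(2.0, 0.05, 2.0, 0.05)
        assert not xo._is_significant(1.999, 0.01, 2.0, 0.05)
        assert not xo._is_significant(4.0, 0.0501, 2.0, 0.05)

    def test_q_at_least_p_and_monotone_significance(self, rng):
        table = _make_table(rng, 60, effect_genes=[f"g{i:04d}" for i in range(10)],
                            effect=5.0, n_rep=4)
        de = xo.flag_de(table, ("wildtype", "mutant"))
        assert (de["q"] >= de["p"] - 1e-12).all()
        stricter = xo.flag_de(table, ("wildtype", "mutant"), q_threshold=0.01)
        assert set(stricter[stricter.significant].gene_id) <= set(
            de[de.significant].gene_id
        )

    def test_missing_replicates_skipped(self, rng):
        table = _make_table(rng, 10)
        table = table[~((table.gene_id == "g0000") & (table.strain == "mutant"))]
        de = xo.flag_de(table, ("wildtype", "mutant"))
        assert "g0000" not in set(de.gene_id)

    def test_fixture_recovers_planted_effect_genes(self, small_sim):
        expr = sd.simulate_expression(small_sim)  # n=5 replicates
        de = xo.flag_de(expr, ("wildtype", "mutant"))
        flagged = set(de[de.significant].gene_id)
        assert flagged == set(small_sim.truth_effects.gene_id)


@pytest.fixture(scope="module")
def pieces(small_sim, small_catalogs):
    diff = gd.diff_genomes(
        small_sim.genome_a, small_sim.genome_b, catalogs=small_catalogs
    )
    impacts = [
        ia.classify_insertion(
            d, small_sim.features_a if d.carrier == "B" else small_sim.features_b
        )
        for d in diff.insertions
    ]
    expr = sd.simulate_expression(small_sim)
    de = xo.flag_de(expr, ("wildtype", "mutant"))
    return impacts, de


class TestOverlay:
    def test_silenced_operon_rows_flagged(self, small_sim, pieces):
        impacts, de = pieces
        rows = xo.overlay(impacts, de, small_sim.features_a)
        is1634 = rows[rows.gene_id.isin(["lipo", "duf1995", "samMT"])]
        assert set(is1634.gene_id) == {"lipo", "duf1995", "samMT"}
        assert is1634.groupby("gene_id")["significant"].any().all()

    def test_intragenic_hit_gene_always_included(self, small_sim, pieces):
        impacts, de = pieces
        rows = xo.overlay(impacts, de, small_sim.features_a, window_nt=1)
        intragenic = [r for r in impacts if r.context == "intragenic"]
        for rep in intragenic:
            assert rep.hit_gene in set(rows[rows.relation == "hit"].gene_id)

    def test_no_genes_in_window_yields_no_rows(self, rng):
        d = gd.InsertionDiff("B", 100, (100, 300), "A" * 200)
        rep = ia.classify_insertion(d, [])
        rows = xo.overlay([rep], pd.DataFrame(columns=xo.REQUIRED_COLUMNS), [])
        assert len(rows) == 0


class TestReadExpression:
    def test_round_trip_and_validation(self, tmp_path, rng):
        table = _make_table(rng, 5)
        p = tmp_path / "expr.tsv"
        table.to_csv(p, sep="\t", index=False)
        back = xo.read_expression(p)
        assert len(back) == len(table)
        bad = table.copy()
        bad.loc[0, "tpm"] = -1
        bad.to_csv(p, sep="\t", index=False)
        with pytest.raises(ValueError):
            xo.read_expression(p)
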
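"""Negative-binomial exact tests, common dispersion, and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from cagedyn.diffexpr import (
    Dispersion,
    _exact_test_from_totals,
    bh_adjust,
    estimate_common_dispersion,
    nb_exact_test,
    pairwise_de,
)
from cagedyn.io import CountMatrix, ValidationError
from cagedyn.simulate import SynthConfig, simulate_timecourse


def _sim_counts(rng, mu, phi, n):
    if phi == 0:
        return rng.poisson(mu[:, None], (len(mu), n))
    lam = rng.gamma(1 / phi, mu[:, None] * phi, size=(len(mu), n))
    return rng.poisson(lam)


def _count_matrix(arr):
    return CountMatrix(
        pd.DataFrame(
            np.asarray(arr, dtype=np.int64),
            index=[f"p{i}" for i in range(len(arr))],
            columns=[f"s{j}" for j in range(np.asarray(arr).shape[1])],
        )
    )


class TestExactTest:
    def test_balanced_split_gives_p_one(self):
        p = nb_exact_test([5], [5], [1e6], [1e6], phi=0.1)
        assert p == 1.0

    def test_phi_zero_matches_binomial_enumeration(self):
        # full enumeration oracle: two-sided binomial(n, 1/2) minimum-likelihood
        for a, b in [(0, 10), (3, 7), (2, 2), (1, 15)]:
            n = a + b
            pmf = binom.pmf(np.arange(n + 1), n, 0.5)
            expected = pmf[pmf <= pmf[a] * (1 + 1e-12)].sum()
            got = nb_exact_test([a], [b], [1e6], [1e6], phi=0.0)
            assert got == pytest.approx(expected, rel=1e-9), (a, b)

    def test_extreme_binomial_closed_form(self):
        assert nb_exact_test([0], [10], [1e6], [1e6], 0.0) == pytest.approx(2 * 0.5**10)

    def test_degenerate_zero_totals(self):
        assert nb_exact_test([0], [0], [1e6], [1e6], 0.1) == 1.0

    def test_negative_phi_rejected(self):
        with pytest.raises(ValidationError):
            nb_exact_test([1], [1], [1e6], [1e6], -0.1)

    def test_zero_library_rejected(self):
        with pytest.raises(ValidationError):
            nb_exact_test([1], [1], [0.0], [1e6], 0.1)

    @given(
        st.integers(0, 50),
        st.integers(0, 50),
        st.floats(0.0, 2.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_symmetry_under_group_exchange(self, a, b, phi):
        p_ab = nb_exact_test([a], [b], [1e6], [1e6], phi)
        p_ba = nb_exact_test([b], [a], [1e6], [1e6], phi)
        assert p_ab == pytest.approx(p_ba, rel=1e-9)

    def test_monotone_in_imbalance_at_fixed_total(self):
        for phi in (0.0, 0.1, 0.5):
            ps = [_exact_test_from_totals(a, 40, 3, 3, phi) for a in range(20, -1, -1)]
            assert all(ps[i + 1] <= ps[i] + 1e-12 for i in range(len(ps) - 1)), phi

    def test_library_scaling_shifts_the_null(self):
        # same counts, but group b sequenced twice as deep: a=10 vs b=20 is balanced
        p = nb_exact_test([10], [20], [1e6], [2e6], phi=0.0)
        assert p > 0.5


class TestCalibration:
    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(123)
        phi = 0.1
        mu = rng.lognormal(np.log(100), 0.7, 4000)
        ya = _sim_counts(rng, mu, phi, 3)
        yb = _sim_counts(rng, mu, phi, 3)
        ps = np.array(
            [
                _exact_test_from_totals(int(a), int(a + b), 3, 3, phi)
                for a, b in zip(ya.sum(1), yb.sum(1))
            ]
        )
        assert 0.035 <= (ps <= 0.05).mean() <= 0.065


class TestDispersion:
    def test_recovery_from_replicated_groups(self):
        rng = np.random.default_rng(5)
        mu = rng.lognormal(np.log(100), 0.7, 3000)
        y = np.hstack([_sim_counts(rng, mu, 0.1, 4), _sim_counts(rng, mu, 0.1, 4)])
        cm = _count_matrix(y)
        groups = {"a": [f"s{j}" for j in range(4)], "b": [f"s{j}" for j in range(4, 8)]}
        d = estimate_common_dispersion(cm, groups)
        assert d.method == "profile_cml"
        assert abs(d.phi - 0.1) / 0.1 < 0.15

    def test_poisson_data_hits_boundary(self):
        rng = np.random.default_rng(6)
        mu = rng.lognormal(np.log(100), 0.7, 3000)
        y = np.hstack([_sim_counts(rng, mu, 0.0, 4), _sim_counts(rng, mu, 0.0, 4)])
        d = estimate_common_dispersion(_count_matrix(y), {"a": [f"s{j}" for j in range(4)],
                                                          "b": [f"s{j}" for j in range(4, 8)]})
        assert d.phi <= 0.01

    def test_no_replication_errors(self):
        cm = _count_matrix([[5, 6], [7, 8]])
        with pytest.raises(ValidationError, match="fixed"):
            estimate_common_dispersion(cm, {"a": ["s0"], "b": ["s1"]})

    def test_negative_phi_invalid(self):
        with pytest.raises(ValidationError):
            Dispersion(phi=-0.1, method="fixed", n_promoters_used=0)


class TestBH:
    def test_hand_worked_stepup(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @staticmethod
    def _brute_force(p):
        # literal step-up definition: q_i = min over j with p_j >= p_i of p_j * m / rank_j
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        q = np.empty(m)
        for pos in range(m):
            cands = [p[order[j]] * m / (j + 1) for j in range(pos, m)]
            q[order[pos]] = min(1.0, min(cands))
        return q

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_brute_force_definition(self, ps):
        assert np.allclose(bh_adjust(ps), self._brute_force(ps), atol=1e-12)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        p = rng.uniform(size=500)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_adjust(p), q_sm, atol=1e-12)


class TestPairwiseDE:
    def test_three_timepoints_three_families(self):
        cfg = SynthConfig(n_promoters=100, seed=3,
                          time_points_fgf2=(0, 15, 30), time_points_il1b=(0, 15, 30),
                          responder_fractions={"FGF2": {}, "IL1B": {}})
        counts, meta, _ = simulate_timecourse(cfg)
        de = pairwise_de(counts, meta, "FGF2")
        fams = set(map(tuple, de[["time_a", "time_b"]].drop_duplicates().to_numpy()))
        assert fams == {(0, 15), (0, 30), (15, 30)}

    def test_alpha_validation(self, small_course):
        _, counts, meta, _ = small_course
        with pytest.raises(ValidationError):
            pairwise_de(counts, meta, "FGF2", alpha=1.5)

    def test_q_at_least_p_and_flag_consistency(self, small_course):
        _, counts, meta, _ = small_course
        de = pairwise_de(counts, meta, "IL1B")
        assert (de["q_value"] >= de["p_value"] - 1e-12).all()
        assert (de["significant"] == (de["q_value"] < 0.05)).all()

    def test_null_course_respects_alpha(self):
        cfg = SynthConfig(n_promoters=1500, seed=9,
                          responder_fractions={"FGF2": {}, "IL1B": {}})
        counts, meta, _ = simulate_timecourse(cfg)
        de = pairwise_de(counts, meta, "FGF2")
        frac = de.groupby("region_id")["significant"].any().mean()
        assert frac <= 0.05 + 0.02


class TestEdgeRCrossCheck:
    """edgeR (Bioconductor) as an independent oracle on a small dataset.

    The estimator here deliberately simplifies edgeR's qCML equalization, so
    agreement is checked loosely: dispersion within 30% and strongly
    rank-correlated exact-test p-values.
    """

    def test_against_edger_exact_test(self, tmp_path):
        import subprocess

        rng = np.random.default_rng(21)
        mu = rng.lognormal(np.log(80), 0.8, 300)
        phi = 0.12
        fc = np.ones(300)
        fc[:30] = 4.0
        ya = _sim_counts(rng, mu, phi, 3)
        yb = _sim_counts(rng, mu * fc, phi, 3)
        y = np.hstack([ya, yb])
        cm = _count_matrix(y)
        counts_path = tmp_path / "counts.tsv"
        cm.data.to_csv(counts_path, sep="\t")

        script = tmp_path / "edger.R"
        script.write_text(
            """
            suppressMessages(library(edgeR))
            args <- commandArgs(trailingOnly=TRUE)
            x <- read.delim(args[1], row.names=1)
            group <- factor(c(1,1,1,2,2,2))
            d <- DGEList(counts=x, group=group)
            d <- estimateCommonDisp(d)
            et <- exactTest(d)
            out <- data.frame(id=rownames(et$table), p=et$table$PValue)
            write.table(data.frame(disp=d$common.dispersion), args[2], sep="\t", row.names=FALSE)
            write.table(out, args[3], sep="\t", row.names=FALSE, quote=FALSE)
            """
        )
        disp_path, p_path = tmp_path / "disp.tsv", tmp_path / "p.tsv"
        subprocess.run(
            ["Rscript", str(script), str(counts_path), str(disp_path), str(p_path)],
            check=True, capture_output=True,
        )
        edger_disp = float(pd.read_csv(disp_path, sep="\t")["disp"].iloc[0])
        edger_p = pd.read_csv(p_path, sep="\t").set_index("id")["p"]

        groups = {"a": [f"s{j}" for j in range(3)], "b": [f"s{j}" for j in range(3, 6)]}
        mine = estimate_common_dispersion(cm, groups)
        assert abs(mine.phi - edger_disp) / edger_disp < 0.30

        libs = cm.library_sizes()
        la = libs[groups["a"]].to_numpy(float)
        lb = libs[groups["b"]].to_numpy(float)
        my_p = np.array(
            [
                nb_exact_test(cm.data.loc[i, groups["a"]], cm.data.loc[i, groups["b"]],
                              la, lb, mine.phi)
                for i in cm.promoter_ids
            ]
        )
        rho = pd.Series(my_p, index=cm.promoter_ids).corr(edger_p, method="spearman")
        assert rho >= 0.95
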
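"""LD clumping, LD-panel validation and instrument-strength statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sexmr.instruments import (
    InstrumentSet,
    LdPanel,
    LdPanelError,
    NoInstrumentsError,
    clump,
    f_statistics,
    mean_f_statistic,
    read_ld_panel,
    select_instruments,
    write_ld_panel,
)

from conftest import build_stats, snp_row


def _panel(rsids, pairs=None):
    """Identity panel with selected symmetric correlations."""
    r = np.eye(len(rsids))
    idx = {s: i for i, s in enumerate(rsids)}
    for a, b, v in pairs or []:
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = v
    return LdPanel(rsids=list(rsids), r=r)


def _stats(pvalues, **kw):
    rows = [
        snp_row(rsid=f"s{i + 1}", pos=1000 * (i + 1), pvalue=p) for i, p in enumerate(pvalues)
    ]
    return build_stats(rows, **kw)


class TestClump:
    def test_greedy_hand_trace(self):
        # s3 (best p) removes s1 via r2 = 0.25 > 0.001; s2 remains
        stats = _stats([1e-10, 1e-9, 1e-20])
        panel = _panel(["s1", "s2", "s3"], [("s1", "s3", 0.5)])
        kept = clump(stats, panel, r2_threshold=0.001, p_threshold=5e-8)
        assert sorted(kept.df["rsid"]) == ["s2", "s3"]

    def test_uncorrelated_all_kept(self):
        stats = _stats([1e-10, 1e-9, 1e-20, 1e-12])
        panel = _panel(["s1", "s2", "s3", "s4"])
        assert clump(stats, panel).n_snps == 4

    def test_tied_pvalues_broken_by_rsid(self):
        stats = _stats([1e-10, 1e-10, 1e-10])
        panel = _panel(["s1", "s2", "s3"], [("s1", "s2", 0.9), ("s1", "s3", 0.9), ("s2", "s3", 0.9)])
        for perm in itertools.permutations(range(3)):
            shuffled = stats.with_df(stats.df.iloc[list(perm)])
            kept = clump(shuffled, panel, r2_threshold=0.001)
            assert list(kept.df["rsid"]) == ["s1"]

    def test_row_order_invariance_random_instance(self, rng):
        k = 20
        rsids = [f"s{i:02d}" for i in range(k)]
        a = rng.normal(size=(k, k // 2))
        cov = a @ a.T
        d = np.sqrt(np.diag(cov))
        panel = LdPanel(rsids=rsids, r=cov / np.outer(d, d))
        pvals = 10.0 ** rng.uniform(-30, -9, size=k)
        rows = [snp_row(rsid=r, pos=1000 + i, pvalue=p) for i, (r, p) in enumerate(zip(rsids, pvals))]
        stats = build_stats(rows)
        baseline = sorted(clump(stats, panel, r2_threshold=0.1).df["rsid"])
        for seed in range(3):
            shuffled = stats.with_df(stats.df.sample(frac=1.0, random_state=seed))
            assert sorted(clump(shuffled, panel, r2_threshold=0.1).df["rsid"]) == baseline

    def test_output_pairs_below_threshold_and_pruned_dominated(self, rng):
        k = 15
        rsids = [f"s{i:02d}" for i in range(k)]
        a = rng.normal(size=(k, 5))
        cov = a @ a.T
        d = np.sqrt(np.diag(cov))
        panel = LdPanel(rsids=rsids, r=cov / np.outer(d, d))
        pvals = 10.0 ** rng.uniform(-30, -9, size=k)
        stats = build_stats(
            [snp_row(rsid=r, pos=1000 + i, pvalue=p) for i, (r, p) in enumerate(zip(rsids, pvals))]
        )
        thr = 0.2
        kept = clump(stats, panel, r2_threshold=thr)
        kept_ids = list(kept.df["rsid"])
        sub = panel.submatrix(kept_ids) ** 2
        off = sub[~np.eye(len(kept_ids), dtype=bool)]
        assert (off <= thr).all()
        # every removed SNP is correlated above threshold with a retained SNP
        # of smaller-or-equal p-value
        pmap = dict(zip(stats.df["rsid"], stats.df["pvalue"]))
        for removed in set(rsids) - set(kept_ids):
            r2s = panel.submatrix([removed] + kept_ids)[0, 1:] ** 2
            dominating = [
                kid
                for kid, r2 in zip(kept_ids, r2s)
                if r2 > thr and pmap[kid] <= pmap[removed]
            ]
            assert dominating, f"{removed} was pruned by no retained SNP"

    def test_snps_absent_from_panel_dropped_with_warning(self):
        stats = _stats([1e-10, 1e-9])
        panel = _panel(["s1"])
        with pytest.warns(UserWarning, match="absent"):
            kept = clump(stats, panel)
        assert list(kept.df["rsid"]) == ["s1"]

    def test_snps_absent_treated_independent_when_configured(self):
        stats = _stats([1e-10, 1e-9])
        panel = _panel(["s1"])
        kept = clump(stats, panel, absent="independent")
        assert sorted(kept.df["rsid"]) == ["s1", "s2"]

    def test_no_instruments_error_names_trait_and_sex(self):
        stats = _stats([0.5, 0.9], trait="glucose", sex="male")
        panel = _panel(["s1", "s2"])
        with pytest.raises(NoInstrumentsError, match="glucose.*male"):
            clump(stats, panel)


class TestFStatistic:
    def test_single_snp(self):
        stats = build_stats([snp_row(beta=0.1, se=0.01)])
        assert mean_f_statistic(stats) == pytest.approx(100.0)

    def test_mean_of_two(self):
        stats = build_stats(
            [
                snp_row(rsid="s1", beta=0.1, se=0.01),
                snp_row(rsid="s2", pos=2000, beta=np.sqrt(44.0) * 0.02, se=0.02),
            ]
        )
        assert mean_f_statistic(stats) == pytest.approx(72.0)

    def test_empty_input_raises(self):
        stats = build_stats([snp_row()])
        with pytest.raises(ValueError):
            mean_f_statistic(filter_empty(stats))

    def test_mean_matches_noncentral_chisquare(self, rng):
        # beta ~ N(b, se^2) makes (beta/se)^2 noncentral chi-square(1, nc),
        # mean 1 + nc; choose nc = 39 so E[F] = 40
        k, nc = 200, 39.0
        se = 1.0
        betas = rng.normal(np.sqrt(nc) * se, se, size=k)
        stats = build_stats(
            [snp_row(rsid=f"s{i}", pos=1000 + i, beta=b, se=se) for i, b in enumerate(betas)]
        )
        se_mean = np.sqrt(2 * (1 + 2 * nc) / k)
        assert abs(mean_f_statistic(stats) - 40.0) < 3 * se_mean
        assert f_statistics(stats).shape == (k,)


def filter_empty(stats):
    return stats.with_df(stats.df.iloc[0:0])


class TestSelectInstruments:
    def test_weak_instrument_warning(self):
        stats = build_stats([snp_row(beta=0.02, se=0.01, pvalue=1e-9)])
        panel = _panel(["rs1"])
        with pytest.warns(UserWarning, match="weak instruments"):
            iset = select_instruments(stats, panel)
        assert iset.is_weak and iset.mean_f == pytest.approx(4.0)

    def test_strong_instruments_no_warning(self, recwarn):
        stats = build_stats([snp_row(beta=0.1, se=0.01, pvalue=1e-9)])
        iset = select_instruments(stats, _panel(["rs1"]))
        assert not iset.is_weak
        assert iset.n_snps == 1
        assert not any("weak" in str(w.message) for w in recwarn.list)

    def test_maf_filter_applied(self):
        stats = build_stats(
            [
                snp_row(rsid="rs1", eaf=0.01, pvalue=1e-9),
                snp_row(rsid="rs2", pos=2000, eaf=0.3, pvalue=1e-9),
            ]
        )
        iset = select_instruments(stats, _panel(["rs1", "rs2"]), min_maf=0.05)
        assert [r.rsid for r in iset.stats.records] == ["rs2"]


class TestLdPanel:
    def test_roundtrip(self, tmp_path, rng):
        a = rng.normal(size=(4, 4))
        cov = a @ a.T
        d = np.sqrt(np.diag(cov))
        panel = LdPanel(rsids=["a", "b", "c", "d"], r=cov / np.outer(d, d))
        p = tmp_path / "panel.tsv"
        write_ld_panel(panel, p)
        back = read_ld_panel(p)
        assert back.rsids == panel.rsids
        np.testing.assert_allclose(back.r, panel.r, atol=1e-12)

    def test_asymmetric_rejected(self):
        r = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(LdPanelError, match="symmetric"):
            LdPanel(rsids=["a", "b"], r=r)

    def test_bad_diagonal_rejected(self):
        r = np.array([[1.0, 0.1], [0.1, 0.9]])
        with pytest.raises(LdPanelError, match="diagonal"):
            LdPanel(rsids=["a", "b"], r=r)

    def test_tiny_asymmetry_symmetrized(self):
        r = np.array([[1.0, 0.5 + 4e-9], [0.5, 1.0]])
        panel = LdPanel(rsids=["a", "b"], r=r)
        assert panel.r[0, 1] == panel.r[1, 0]

    def test_instrument_set_consistency_checked(self):
        stats = build_stats([snp_row()])
        with pytest.raises(ValueError):
            InstrumentSet(stats=stats, mean_f=100.0, n_snps=2)
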
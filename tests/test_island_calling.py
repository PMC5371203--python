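import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cimpscan.island_calling import (
    CallParameters,
    bh_adjust,
    call_island_dm,
    paired_signed_rank,
    scan_delta_threshold,
    signed_rank_p,
    tumour_call_counts,
)
from cimpscan.preprocess import BetaMatrix, SampleSheet
from cimpscan.subtyping import CimpAssignment

from _oracles import bh_stepup, signed_rank_p_enumeration


class TestSignedRank:
    def test_all_zero_differences(self):
        assert signed_rank_p(np.zeros(8)) == 1.0

    def test_six_positive_distinct(self):
        # extreme statistic: two-sided p = 2 / 2^6
        p = signed_rank_p(np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6]))
        assert p == pytest.approx(2 / 64)

    def test_matches_enumeration_on_random_vectors(self):
        rng = np.random.default_rng(31)
        for _ in range(40):
            n = int(rng.integers(3, 13))
            d = rng.normal(0.02, 0.1, n)
            assert signed_rank_p(d) == signed_rank_p_enumeration(d)

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(32)
        for _ in range(20):
            d = rng.normal(0, 1, 12)
            expected = stats.wilcoxon(d, method="exact").pvalue
            assert signed_rank_p(d) == pytest.approx(expected)

    def test_approx_path_matches_scipy_with_ties(self):
        rng = np.random.default_rng(33)
        d = np.round(rng.normal(0.1, 0.5, 40), 1)  # rounded -> ties
        d = d[d != 0]
        expected = stats.wilcoxon(d, method="approx", correction=True).pvalue
        assert signed_rank_p(d, exact_limit=25) == pytest.approx(expected, rel=1e-9)

    def test_paired_wrapper_validates_length(self):
        with pytest.raises(ValueError):
            paired_signed_rank(np.ones(3), np.ones(4))

    def test_exact_switch_respects_limit(self):
        rng = np.random.default_rng(34)
        d = rng.normal(0.05, 0.2, 18)  # moderate signal, above a lowered limit
        approx = signed_rank_p(d, exact_limit=10)
        exact = signed_rank_p(d, exact_limit=25)
        assert exact == signed_rank_p_enumeration(d)
        assert approx != exact
        assert approx == pytest.approx(exact, rel=0.2)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.42])[0] == pytest.approx(0.42)

    def test_closed_form_triple(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_textbook_implementation(self):
        rng = np.random.default_rng(35)
        for _ in range(50):
            p = rng.uniform(0, 1, int(rng.integers(1, 200)))
            assert np.allclose(bh_adjust(p), bh_stepup(p))

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(36)
        p = rng.uniform(0, 1, 100)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


def paired_beta(gene_probes, tumour_shift, n_pairs=4, seed=37, noise=0.02):
    """Beta matrix + sheet with per-gene planted tumour shifts."""
    rng = np.random.default_rng(seed)
    probes, rows_t, rows_n = [], [], []
    for gene, (n_probes, shifts) in gene_probes.items():
        for k in range(n_probes):
            probes.append(f"{gene}_p{k}")
    sample_t = [f"S{j}_T" for j in range(n_pairs)]
    sample_n = [f"S{j}_N" for j in range(n_pairs)]
    base = np.clip(rng.normal(0.12, 0.02, (len(probes), n_pairs)), 0.01, 0.9)
    shift = np.zeros_like(base)
    r = 0
    for gene, (n_probes, shifts) in gene_probes.items():
        for k in range(n_probes):
            shift[r] = shifts
            r += 1
    beta_n = np.clip(base + rng.normal(0, noise, base.shape), 0.001, 0.95)
    beta_t = np.clip(base + shift + rng.normal(0, noise, base.shape), 0.001, 0.95)
    frame = pd.DataFrame(
        np.hstack([beta_t, beta_n]), index=probes, columns=sample_t + sample_n
    )
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": sample_t + sample_n,
                "subject_id": [f"S{j}" for j in range(n_pairs)] * 2,
                "tissue": ["tumour"] * n_pairs + ["normal"] * n_pairs,
                "batch": "c1",
            }
        )
    )
    gene_map = {
        g: [f"{g}_p{k}" for k in range(np_)] for g, (np_, _) in gene_probes.items()
    }
    return BetaMatrix(frame), gene_map, sheet


class TestCallIslandDm:
    def test_dual_criterion(self):
        # geneA strongly shifted in tumours 0/1 only; geneB shifted weakly
        # (significant but below delta); geneC null
        genes = {
            "geneA": (14, np.array([0.3, 0.3, 0.0, 0.0])),
            "geneB": (14, np.array([0.05, 0.05, 0.05, 0.05])),
            "geneC": (14, np.zeros(4)),
        }
        beta, gene_map, sheet = paired_beta(genes, None, noise=0.005)
        params = CallParameters(p_adj_max=0.05, delta_min=0.1)
        calls = call_island_dm(beta, gene_map, sheet, params)
        call = calls.call
        assert call.loc["geneA", "S0_T"] == "hyper"
        assert call.loc["geneA", "S2_T"] == "none"
        # geneB is significant but fails the delta criterion
        assert calls.p_adj.loc["geneB", "S0_T"] < 0.05
        assert call.loc["geneB", "S0_T"] == "none"
        assert (call.loc["geneC"] == "none").all()

    def test_hypo_mirrored(self):
        genes = {"geneD": (14, np.array([-0.3, 0.0, 0.0, 0.0]))}
        beta, gene_map, sheet = paired_beta(genes, None, seed=38, noise=0.005)
        # push the baseline up so the hypo shift stays in range
        beta = BetaMatrix(np.clip(beta.beta + 0.3, 0.0, 0.95))
        params = CallParameters(p_adj_max=0.05, delta_min=0.1)
        calls = call_island_dm(beta, gene_map, sheet, params)
        assert calls.call.loc["geneD", "S0_T"] == "hypo"

    def test_raising_delta_never_adds_calls(self):
        rng = np.random.default_rng(39)
        genes = {
            f"g{i}": (12, rng.uniform(0, 0.3, 4)) for i in range(10)
        }
        beta, gene_map, sheet = paired_beta(genes, None, seed=40)
        calls = call_island_dm(beta, gene_map, sheet, CallParameters(p_adj_max=0.1))
        low = calls.hyper_mask(delta_min=0.05)
        high = calls.hyper_mask(delta_min=0.15)
        assert (high.values <= low.values).all()

    def test_empty_gene_map_rejected(self):
        beta, gene_map, sheet = paired_beta({"g": (6, np.zeros(4))}, None)
        with pytest.raises(ValueError):
            call_island_dm(beta, {}, sheet)


def toy_assignment(labels_dict):
    return CimpAssignment(labels=pd.Series(labels_dict, name="cimp_label"))


class TestCountsAndScan:
    def _calls(self):
        genes = {
            "core1": (14, np.array([0.3, 0.3, 0.3, 0.0])),
            "core2": (14, np.array([0.3, 0.3, 0.0, 0.0])),
            "weak": (14, np.array([0.0, 0.0, 0.0, 0.06])),
        }
        beta, gene_map, sheet = paired_beta(genes, None, seed=41, noise=0.005)
        return call_island_dm(
            beta, gene_map, sheet, CallParameters(p_adj_max=0.05, delta_min=0.1)
        )

    def test_counts_match_manual_tally(self):
        calls = self._calls()
        labels = toy_assignment(
            {"S0_T": "CIMP-H", "S1_T": "CIMP-H", "S2_T": "CIMP-L", "S3_T": "CIMP-N"}
        )
        counts, summary = tumour_call_counts(calls, labels)
        assert counts["S0_T"] == 2 and counts["S1_T"] == 2
        assert counts["S2_T"] == 1 and counts["S3_T"] == 0
        means = dict(zip(summary["group"], summary["mean"]))
        assert means["CIMP-H"] > means["CIMP-L"] > means["CIMP-N"]

    def test_grid_of_one_returns_that_value(self):
        calls = self._calls()
        labels = toy_assignment({"S0_T": "CIMP-H", "S3_T": "CIMP-N"})
        chosen, curve = scan_delta_threshold(calls, [0.2], labels)
        assert chosen == 0.2
        assert len(curve) == 1

    def test_threshold_above_all_effects_gives_zero_objective(self):
        calls = self._calls()
        labels = toy_assignment({"S0_T": "CIMP-H", "S3_T": "CIMP-N"})
        _, curve = scan_delta_threshold(calls, [0.9], labels)
        assert curve["objective"].iloc[0] == 0.0

    def test_missing_group_rejected(self):
        calls = self._calls()
        with pytest.raises(ValueError):
            scan_delta_threshold(calls, [0.1], toy_assignment({"S0_T": "CIMP-H"}))
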
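import numpy as np
import pandas as pd
import pytest

from cimpscan.annotation import ProbeManifest
from cimpscan.preprocess import (
    BetaMatrix,
    IntensityDataset,
    SampleSheet,
    compute_beta,
    filter_probes,
    rescale_to_control_mean,
)


class TestComputeBeta:
    @pytest.mark.parametrize(
        "m,u,expected",
        [(0, 0, 0.0), (100, 0, 0.5), (300, 100, 0.6)],
    )
    def test_known_values(self, m, u, expected):
        assert compute_beta(np.array(m), np.array(u)) == pytest.approx(expected)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(5)
        M = rng.uniform(0, 10000, 500)
        U = rng.uniform(0, 10000, 500)
        beta = compute_beta(M, U)
        assert (beta >= 0).all() and (beta < 1).all()
        assert (compute_beta(M + 10, U) > beta).all()
        assert (compute_beta(M, U + 10) < beta).all()

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            compute_beta(np.array([-1.0]), np.array([5.0]))
        with pytest.raises(ValueError):
            compute_beta(np.array([1.0]), np.array([5.0]), offset=0)


def tiny_dataset():
    probes = ["auto_ok", "auto_fail", "chrX_p", "crossp", "neg1", "int1"]
    samples = ["s1_T", "s1_N"]
    man = pd.DataFrame(
        {
            "probe_id": probes,
            "chromosome": ["chr1", "chr1", "chrX", "chr2", "", ""],
            "position": [100, 200, 300, 400, 0, 0],
            "island_id": [""] * 6,
            "region_class": ["island", "island", "open_sea", "open_sea"] * 1
            + ["open_sea", "open_sea"],
            "gene_symbols": [set(), set(), set(), set(), set(), set()],
            "feature_context": [set()] * 6,
            "cross_reactive": [False, False, False, True, False, False],
            "is_sex_chromosome": [False, False, True, False, False, False],
            "is_negative_control": [False, False, False, False, True, False],
            "is_internal_control": [False, False, False, False, False, True],
        }
    )
    manifest = ProbeManifest(man)
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": samples,
                "subject_id": ["s1", "s1"],
                "tissue": ["tumour", "normal"],
                "batch": ["c1", "c1"],
            }
        )
    )
    mk = lambda vals: pd.DataFrame(vals, index=probes, columns=samples, dtype=float)
    M = mk(np.full((6, 2), 500.0))
    U = mk(np.full((6, 2), 500.0))
    det = mk(np.full((6, 2), 0.001))
    det.loc["auto_fail", "s1_N"] = 0.2  # fails detection in one sample
    return IntensityDataset(M, U, det, sheet), manifest


class TestFilterProbes:
    def test_reasons_and_counts(self):
        ds, manifest = tiny_dataset()
        retained, report = filter_probes(ds, manifest)
        assert retained == ["auto_ok"]
        assert report.removed_detection == 1
        assert report.removed_sex_chromosome == 1
        assert report.removed_cross_reactive == 1
        assert report.removed_control == 2
        assert report.n_input - report.n_retained == (
            report.removed_detection
            + report.removed_sex_chromosome
            + report.removed_cross_reactive
            + report.removed_control
        )

    def test_idempotent(self):
        ds, manifest = tiny_dataset()
        retained, _ = filter_probes(ds, manifest)
        again, report2 = filter_probes(ds.subset_probes(retained), manifest)
        assert again == retained
        assert report2.n_input == report2.n_retained

    def test_failure_fraction_rule(self):
        ds, manifest = tiny_dataset()
        retained, _ = filter_probes(ds, manifest, max_failure_fraction=0.6)
        assert "auto_fail" in retained  # failed in only half the samples

    def test_alpha_validated(self):
        ds, manifest = tiny_dataset()
        with pytest.raises(ValueError):
            filter_probes(ds, manifest, alpha=1.5)


class TestRescale:
    def _dataset(self, control_totals):
        probes = ["p1", "ctl"]
        samples = [f"s{i}_{t}" for i in range(len(control_totals)) for t in ("T",)]
        sheet = SampleSheet(
            pd.DataFrame(
                {
                    "sample_id": samples,
                    "subject_id": [f"s{i}" for i in range(len(samples))],
                    "tissue": ["tumour"] * len(samples),
                    "batch": ["c1"] * len(samples),
                }
            )
        )
        M = pd.DataFrame(
            [np.full(len(samples), 300.0), np.array(control_totals) / 2],
            index=probes, columns=samples,
        )
        U = M.copy()
        det = pd.DataFrame(0.001, index=probes, columns=samples)
        return IntensityDataset(M, U, det, sheet)

    def test_single_sample_unchanged(self):
        ds = self._dataset([1000.0])
        out, factors = rescale_to_control_mean(ds, ["ctl"])
        assert factors.iloc[0] == pytest.approx(1.0)
        pd.testing.assert_frame_equal(out.M, ds.M)

    def test_double_mean_gets_half_factor(self):
        # one sample's control mean is 2x the other's -> grand mean = 1.5x base
        ds = self._dataset([1000.0, 2000.0])
        _, factors = rescale_to_control_mean(ds, ["ctl"])
        assert factors.iloc[0] == pytest.approx(1.5)
        assert factors.iloc[1] == pytest.approx(0.75)

    def test_control_means_equal_afterwards(self):
        ds = self._dataset([800.0, 1700.0, 2400.0])
        out, _ = rescale_to_control_mean(ds, ["ctl"])
        totals = out.M.loc["ctl"] + out.U.loc["ctl"]
        assert totals.std() == pytest.approx(0.0, abs=1e-9)

    def test_zero_control_mean_names_sample(self):
        ds = self._dataset([1000.0, 0.0])
        with pytest.raises(ValueError, match="s1"):
            rescale_to_control_mean(ds, ["ctl"])


class TestSampleSheet:
    def test_duplicate_tissue_rejected(self):
        with pytest.raises(ValueError):
            SampleSheet(
                pd.DataFrame(
                    {
                        "sample_id": ["a", "b"],
                        "subject_id": ["s1", "s1"],
                        "tissue": ["tumour", "tumour"],
                        "batch": ["c", "c"],
                    }
                )
            )

    def test_matched_pairs_require_both_tissues(self):
        sheet = SampleSheet(
            pd.DataFrame(
                {
                    "sample_id": ["a", "b", "c"],
                    "subject_id": ["s1", "s1", "s2"],
                    "tissue": ["tumour", "normal", "tumour"],
                    "batch": ["c", "c", "c"],
                }
            )
        )
        assert sheet.matched_pairs() == [("s1", "a", "b")]


def test_beta_matrix_bounds_enforced():
    frame = pd.DataFrame({"s": [1.0]}, index=["p"])
    with pytest.raises(ValueError):
        BetaMatrix(frame)
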
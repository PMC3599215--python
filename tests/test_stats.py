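"""ROI summaries, deviations, paired tests and the cohort report."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from ivimfit import (
    IvimParams,
    ParameterMap,
    PhantomSpec,
    cohort_report,
    compute_maps,
    deviation,
    deviation_matrix,
    generate_phantom,
    get_scheme,
    paired_compare,
    rank_correlation,
    summarize_roi,
    write_report,
)
from ivimfit.errors import ConfigurationError
from ivimfit.stats import LesionSummary, holm_correction


def exact_wilcoxon_p(diff):
    """Independent oracle: full enumeration of the signed-rank null."""
    diff = np.asarray(diff, dtype=float)
    diff = diff[diff != 0]
    ranks = rankdata(np.abs(diff))
    w = ranks[diff > 0].sum()
    dist = np.array(
        [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([0, 1], repeat=len(diff))
        ]
    )
    p = 2 * min((dist <= w).mean(), (dist >= w).mean())
    return min(p, 1.0)


def _map_from(values, qc=None):
    values = np.asarray(values, dtype=float)
    qc = np.ones_like(values, dtype=bool) if qc is None else qc
    return ParameterMap("B0", "adc", values, qc)


class TestSummarizeRoi:
    def test_constant_field(self):
        pmap = _map_from(np.full((4, 4, 2), 2.5e-3))
        mask = np.zeros((4, 4, 2), dtype=bool)
        mask[1:3, 1:3, :] = True
        s = summarize_roi(pmap, mask, lesion_id=3)
        assert s.median == s.mean == 2.5e-3
        assert s.sd == 0.0
        assert s.n_voxels_used == 8

    def test_hand_computed_three_voxels(self):
        vals = np.full((3, 1, 1), np.nan)
        vals[:, 0, 0] = [1e-3, 2e-3, 10e-3]
        pmap = _map_from(vals)
        mask = np.ones((3, 1, 1), dtype=bool)
        s = summarize_roi(pmap, mask)
        assert s.median == pytest.approx(2e-3)
        assert s.mean == pytest.approx(13e-3 / 3)
        assert (s.min, s.max) == (1e-3, 10e-3)

    def test_qc_excluded_voxels_do_not_contribute(self):
        vals = np.zeros((3, 1, 1))
        vals[:, 0, 0] = [1e-3, 2e-3, 100.0]
        qc = np.ones((3, 1, 1), dtype=bool)
        qc[2] = False
        s = summarize_roi(_map_from(vals, qc), np.ones((3, 1, 1), dtype=bool))
        assert s.max == 2e-3
        assert s.n_voxels_used == 2

    def test_empty_intersection_flagged(self):
        pmap = _map_from(np.ones((2, 2, 2)), qc=np.zeros((2, 2, 2), dtype=bool))
        s = summarize_roi(pmap, np.ones((2, 2, 2), dtype=bool))
        assert not s.usable
        assert np.isnan(s.median)


class TestDeviation:
    def test_identity(self):
        assert deviation(1.04, 1.04) == 0.0

    def test_reciprocal_identity_exact(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            a, b = rng.uniform(0.5, 3.0, 2)
            d1, d2 = deviation(a, b), deviation(b, a)
            assert (1 + d1 / 100) * (1 + d2 / 100) == pytest.approx(1.0, rel=1e-12)

    def test_zero_reference_undefined(self):
        assert np.isnan(deviation(1.0, 0.0))

    @pytest.mark.parametrize("pair", [(-4.7, 4.9), (2.4, -2.3), (23.2, -18.8)])
    def test_reported_breast_cohort_pairs_satisfy_reciprocity(self, pair):
        """Published deviation pairs for this comparison satisfy the
        reciprocal identity within their printed 0.1 % rounding."""
        d1, d2 = pair
        assert (1 + d1 / 100) * (1 + d2 / 100) == pytest.approx(1.0, abs=2e-3)


class TestPairedCompare:
    def test_identical_samples_give_p_one(self):
        x = np.arange(10.0)
        assert paired_compare(x, x) == 1.0

    def test_constant_shift_attains_smallest_p_at_n24(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1.0, 2.0, 24)
        # smallest attainable two-sided exact p for n=24: 2 / 2^24
        assert paired_compare(x + 0.5, x) == pytest.approx(2.0 / 2**24, rel=1e-9)

    @pytest.mark.parametrize("n", [5, 8, 10, 12])
    def test_matches_enumeration_oracle(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(20):
            x = rng.normal(0.0, 1.0, n)
            y = rng.normal(0.2, 1.0, n)
            assert paired_compare(x, y) == pytest.approx(
                exact_wilcoxon_p(x - y), rel=1e-12
            )

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            paired_compare([1.0, 2.0], [2.0, 1.0])


class TestRankCorrelation:
    def test_monotone_gives_plus_one(self):
        x = np.array([1.0, 2.0, 5.0, 7.0, 9.0, 12.0])
        rho, p = rank_correlation(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        assert p < 0.05

    def test_reversed_ranks_give_minus_one(self):
        x = np.array([1.0, 2.0, 5.0, 7.0, 9.0, 12.0])
        rho, _ = rank_correlation(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_constant_input_undefined(self):
        rho, p = rank_correlation(np.ones(6), np.arange(6.0))
        assert np.isnan(rho) and np.isnan(p)


class TestDeviationMatrix:
    def _summaries(self, table, parameter_by_key=None):
        out = []
        for lesion, row in enumerate(table):
            for key, val in row.items():
                param = "d" if key == "B0_biexp" else "adc"
                out.append(
                    LesionSummary(lesion, key, param, val, val, 0.0, val, val, 9)
                )
        return out

    def test_group_median_reciprocity_and_zero_diagonal(self):
        rng = np.random.default_rng(3)
        rows = [
            {"B0": rng.uniform(0.9e-3, 1.3e-3),
             "B1": rng.uniform(0.9e-3, 1.4e-3),
             "B0_biexp": rng.uniform(0.6e-3, 1.0e-3)}
            for _ in range(12)
        ]
        dm = deviation_matrix(
            self._summaries(rows), scheme_keys=["B0", "B1", "B0_biexp"]
        )
        assert np.all(np.diag(dm.deviations) == 0.0)
        for i in range(3):
            for j in range(3):
                prod = (1 + dm.deviations[i, j] / 100) * (
                    1 + dm.deviations[j, i] / 100
                )
                assert prod == pytest.approx(1.0, rel=1e-12)

    def test_per_lesion_variant_differs_but_agrees_in_sign(self):
        rng = np.random.default_rng(4)
        rows = [
            {"B0": 1.0e-3 * (1 + 0.1 * rng.standard_normal()),
             "B0_biexp": 0.8e-3 * (1 + 0.1 * rng.standard_normal())}
            for _ in range(20)
        ]
        g = deviation_matrix(self._summaries(rows),
                             scheme_keys=["B0", "B0_biexp"], method="group_median")
        l = deviation_matrix(self._summaries(rows),
                             scheme_keys=["B0", "B0_biexp"], method="per_lesion")
        assert np.sign(g.deviations[0, 1]) == np.sign(l.deviations[0, 1])
        assert g.deviations[0, 1] != l.deviations[0, 1]

    def test_missing_scheme_rejected(self):
        rows = [{"B0": 1.0}] * 6
        with pytest.raises(ConfigurationError):
            deviation_matrix(self._summaries(rows), scheme_keys=["B0", "B5"])


def test_holm_correction_monotone_and_bounded():
    p = np.array([0.001, 0.02, 0.04, 0.3])
    adj = holm_correction(p)
    assert np.all(adj >= p)
    assert np.all(adj <= 1.0)
    assert np.all(np.diff(adj[np.argsort(p)]) >= 0)


@pytest.fixture(scope="module")
def phantom_report():
    lesion = IvimParams(si0=1000.0, d=0.84e-3, d_star=11.9e-3, fp=0.16)
    ds = generate_phantom(
        PhantomSpec(n_lesions=8, lesion_params=lesion,
                    noise_model="none", seed=2)
    )
    maps = compute_maps(ds)
    summaries = [
        summarize_roi(m, roi, lesion_id=i)
        for i, roi in enumerate(ds.roi_masks)
        for m in maps
    ]
    return ds, cohort_report(summaries)


class TestCohortReport:
    def test_descriptives_cover_all_schemes(self, phantom_report):
        _, report = phantom_report
        desc = report["descriptives"]
        adc_rows = desc[desc.parameter == "adc"]
        assert len(adc_rows) == 13
        assert set(desc.parameter) == {"adc", "d", "d_star", "fp"}

    def test_units_column_uses_display_scale(self, phantom_report):
        _, report = phantom_report
        desc = report["descriptives"]
        row = desc[(desc.scheme == "B0_biexp") & (desc.parameter == "d")].iloc[0]
        assert row.units == "x10^-3 mm^2/s"
        # uniform cohort-median lesions: median D renders as 0.84
        assert row["median"] == pytest.approx(0.84, rel=1e-4)
        fp_row = desc[(desc.scheme == "B0_biexp") & (desc.parameter == "fp")].iloc[0]
        assert fp_row.units == "fraction"
        assert fp_row["median"] == pytest.approx(0.16, rel=1e-4)

    def test_deviation_of_flow_sensitive_adc_vs_d_positive(self, phantom_report):
        _, report = phantom_report
        dm = report["deviation_matrix"]
        i, j = dm.scheme_ids.index("B0"), dm.scheme_ids.index("B0_biexp")
        assert dm.deviations[i, j] > 0

    def test_report_is_pure_function_of_summaries(self, phantom_report):
        ds, report = phantom_report
        maps = compute_maps(ds)
        summaries = [
            summarize_roi(m, roi, lesion_id=i)
            for i, roi in enumerate(ds.roi_masks)
            for m in maps
        ]
        again = cohort_report(summaries)
        assert report["descriptives"].equals(again["descriptives"])
        assert report["deviation"].equals(again["deviation"])

    def test_write_report_emits_csv_json_markdown(self, phantom_report, tmp_path):
        _, report = phantom_report
        write_report(report, tmp_path)
        assert (tmp_path / "descriptives.csv").exists()
        assert (tmp_path / "descriptives.json").exists()
        md = (tmp_path / "report.md").read_text()
        assert "Per-scheme descriptives" in md

    def test_single_scheme_input_degenerate(self, phantom_report):
        ds, _ = phantom_report
        maps = compute_maps(ds, [get_scheme("B0")])
        summaries = [
            summarize_roi(m, roi, lesion_id=i)
            for i, roi in enumerate(ds.roi_masks)
            for m in maps
        ]
        report = cohort_report(summaries)
        assert len(report["descriptives"]) == 1
        assert report["deviation"].empty
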
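"""Biomarker QC: ICC estimator, LOD imputation, normalisation, Gaussianisation."""

import numpy as np
import pytest
from scipy import stats

from renalpanel.qc import (clustered_correlation, gaussianise, icc_duplicates,
                           impute_below_lod, normalise_urine, run_qc)


class TestICC:
    def test_identical_pairs(self):
        assert icc_duplicates([(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)]) == pytest.approx(1.0)

    def test_hand_computed_anova(self):
        # pairs (1,3),(3,1),(2,2): means all 2 -> MSB=0; MSW = (2+2+0)/3
        # ICC = (0 - 4/3) / (0 + 4/3) = -1
        assert icc_duplicates([(1, 3), (3, 1), (2, 2)]) == pytest.approx(-1.0)

    def test_hand_computed_anova_mixed(self):
        # pairs (0,2),(4,6): means 1,5, grand 3; MSB = 2*((1-3)^2+(5-3)^2)/1 = 16
        # MSW = ((0-1)^2+(2-1)^2+(4-5)^2+(6-5)^2)/2 = 2 -> ICC = 14/18
        assert icc_duplicates([(0, 2), (4, 6)]) == pytest.approx(14 / 18)

    def test_independent_pairs_near_zero(self):
        rng = np.random.default_rng(3)
        pairs = rng.standard_normal((1000, 2))
        assert abs(icc_duplicates(pairs)) < 0.1

    def test_requires_two_pairs(self):
        with pytest.raises(ValueError):
            icc_duplicates([(1.0, 2.0)])

    def test_zero_variance_undefined(self):
        assert np.isnan(icc_duplicates([(1.0, 1.0), (1.0, 1.0)]))


class TestLodImputation:
    def test_below_lod_imputed_to_half(self):
        out = impute_below_lod([0.5, 3.0, np.nan], 2.0)
        assert list(out) == [1.0, 3.0, 1.0]

    def test_requires_positive_lod(self):
        with pytest.raises(ValueError):
            impute_below_lod([1.0], 0.0)

    def test_all_below_lod_becomes_constant(self):
        out = impute_below_lod([0.1, 0.2, np.nan, 0.05], 2.0)
        assert np.all(out == 1.0)


class TestUrineNormalisation:
    def test_ratio(self):
        assert normalise_urine([10.0], [5.0])[0] == 2.0

    def test_zero_creatinine_rejected(self):
        with pytest.raises(ValueError):
            normalise_urine([10.0], [0.0])

    def test_missing_creatinine_flagged_missing(self):
        out = normalise_urine([10.0, 10.0], [5.0, np.nan])
        assert out[0] == 2.0 and np.isnan(out[1])


class TestGaussianise:
    def test_mean_zero_unit_sd(self):
        rng = np.random.default_rng(1)
        g = gaussianise(rng.exponential(size=200))
        assert abs(g.mean()) < 1e-10
        assert abs(g.std() - 1.0) < 1e-10

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        assert np.allclose(gaussianise(np.exp(x)), gaussianise(x))

    def test_blom_closed_form_n5(self):
        x = np.array([10.0, 3.0, 7.0, 1.0, 5.0])
        g = gaussianise(x)
        ranks = stats.rankdata(x)
        q = stats.norm.ppf((ranks - 0.375) / 5.25)
        expected = (q - q.mean()) / q.std()
        assert np.allclose(g, expected)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            gaussianise([2.0, 2.0, 2.0, 2.0])

    def test_monotone_in_input(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        g = gaussianise(x)
        order = np.argsort(x)
        assert np.all(np.diff(g[order]) >= 0)


class TestClusteredCorrelation:
    def test_perfectly_correlated_markers_adjacent(self):
        import pandas as pd

        rng = np.random.default_rng(4)
        a = rng.normal(size=100)
        m = pd.DataFrame({"x": rng.normal(size=100), "a": a, "y": rng.normal(size=100),
                          "b": a + 1e-9 * rng.normal(size=100)})
        ordered, order = clustered_correlation(m)
        assert abs(order.index("a") - order.index("b")) == 1
        assert np.allclose(np.diag(ordered), 1.0)

    def test_four_block_structure_recovered(self):
        import pandas as pd
        from scipy.cluster.hierarchy import average, fcluster
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(5)
        n, per = 600, 3
        cols = {}
        for c in range(4):
            base = rng.normal(size=n)
            for j in range(per):
                cols[f"c{c}m{j}"] = base + 0.6 * rng.normal(size=n)
        m = pd.DataFrame(cols)
        ordered, order = clustered_correlation(m)
        r = ordered.to_numpy()
        labels = fcluster(average(squareform(np.clip(1 - r, 0, None), checks=False)),
                          t=4, criterion="maxclust")
        # each true block maps to exactly one recovered cluster
        names = list(ordered.columns)
        for c in range(4):
            got = {labels[names.index(f"c{c}m{j}")] for j in range(per)}
            assert len(got) == 1

    def test_constant_marker_excluded_with_warning(self):
        import pandas as pd

        rng = np.random.default_rng(6)
        m = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50),
                          "k": np.ones(50)})
        with pytest.warns(UserWarning):
            ordered, order = clustered_correlation(m)
        assert "k" not in order


class TestQcDecisions:
    def test_exclusion_rules_on_constructed_panel(self):
        from renalpanel.simulate import BiomarkerPanel

        rng = np.random.default_rng(7)
        n, n_dup = 200, 48
        good = rng.lognormal(1.0, 0.5, n)
        noisy = rng.lognormal(1.0, 0.5, n)  # duplicates will not correlate
        flat = np.full(n, np.nan)  # everything below LOD
        ids = [f"P{i:05d}" for i in range(n)]
        dup_rows = np.arange(n_dup)
        dup = np.column_stack([
            good[dup_rows] * np.exp(rng.normal(0, 0.05, n_dup)),
            rng.lognormal(1.0, 0.5, n_dup),  # independent remeasurement
            np.full(n_dup, np.nan),
        ])
        panel = BiomarkerPanel(
            marker_names=["good", "irreproducible", "below_lod"],
            compartment=["serum"] * 3,
            values=np.column_stack([good, noisy, flat]),
            detection_limit=np.array([0.01, 0.01, 1.0]),
            urinary_creatinine=np.ones(n),
            duplicate_ids=[ids[i] for i in dup_rows],
            duplicate_values=dup,
            participant_ids=ids,
        )
        report, processed = run_qc(panel)
        assert report.included_names == ["good"]
        reasons = {m.name: m.reason for m in report.markers if not m.included}
        assert "ICC" in reasons["irreproducible"]
        assert "identical" in reasons["below_lod"]

    def test_pipeline_order_lod_then_normalise_then_gaussianise(self, small_cohort):
        _, _, panel, _ = small_cohort
        report, processed = run_qc(panel)
        # Gaussianised output: every included column standardized
        assert np.allclose(processed.mean(), 0.0, atol=1e-9)
        assert np.allclose(processed.std(ddof=0), 1.0, atol=1e-9)
        # urine markers were divided by urinary creatinine before the rank
        # transform: ranks differ from the unnormalised ranks
        _, raw = run_qc(panel, gaussianise_output=False)
        j = panel.marker_names.index("U01")
        col = panel.values[:, panel.marker_names.index("U01")]
        imput = impute_below_lod(col, panel.detection_limit[j])
        assert not np.allclose(raw["U01"].to_numpy(), imput)
        assert np.allclose(raw["U01"].to_numpy(),
                           imput / panel.urinary_creatinine)
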
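"""Synthetic cohort generator: determinism, calibration and structure."""

import dataclasses
import json

import numpy as np
import pytest
from scipy import stats

from renalpanel.phenotypes import derive_phenotypes, progression_rate
from renalpanel.qc import icc_duplicates
from renalpanel.simulate import (SimulationConfig, apply_enrichment_sampling,
                                 build_marker_correlation, generate_cohort)


def test_determinism_same_seed(tmp_path):
    cfg = SimulationConfig(n_participants=50, seed=42)
    a = generate_cohort(cfg)
    b = generate_cohort(dataclasses.replace(cfg))
    assert json.dumps(a[2]) == json.dumps(b[2])
    assert np.array_equal(a[1].values, b[1].values, equal_nan=True)
    assert a[0][7].creatinine_series == b[0][7].creatinine_series

    from renalpanel.simulate import write_cohort

    write_cohort(tmp_path / "a", *a)
    write_cohort(tmp_path / "b", *b)
    for name in ("participants.tsv", "labs_long.tsv", "biomarkers.tsv", "truth.json"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_different_seed_differs():
    a = generate_cohort(SimulationConfig(n_participants=50, seed=1))
    b = generate_cohort(SimulationConfig(n_participants=50, seed=2))
    assert not np.array_equal(a[1].values, b[1].values, equal_nan=True)


def test_within_cluster_correlation_monte_carlo():
    cfg = SimulationConfig(n_participants=2000, seed=9, within_cluster_corr=0.8)
    _, _, truth = generate_cohort(cfg)
    z = np.array(truth["marker_scores"])
    # markers 2 and 3 share the first cluster and are not the TNF pair
    r = np.corrcoef(z[:, 2], z[:, 3])[0, 1]
    assert 0.75 <= r <= 0.85


def test_tnf_pair_correlation():
    cfg = SimulationConfig(n_participants=2000, seed=10)
    _, _, truth = generate_cohort(cfg)
    z = np.array(truth["marker_scores"])
    r = np.corrcoef(z[:, 0], z[:, 1])[0, 1]
    assert r == pytest.approx(0.80, abs=0.05)


def test_duplicate_icc_matches_target():
    cfg = SimulationConfig(n_participants=400, seed=12, duplicate_icc_target=0.9)
    _, panel, _ = generate_cohort(cfg)
    assert len(panel.duplicate_ids) == 48
    idx = {pid: i for i, pid in enumerate(panel.participant_ids)}
    iccs = []
    for j in range(len(panel.marker_names)):
        v1 = np.array([panel.values[idx[pid], j] for pid in panel.duplicate_ids])
        v2 = panel.duplicate_values[:, j]
        ok = np.isfinite(v1) & np.isfinite(v2)
        iccs.append(icc_duplicates(np.column_stack([np.log(v1[ok]), np.log(v2[ok])])))
    # per-marker estimates at n=48 scatter around the target
    assert 0.8 <= np.median(iccs) <= 0.96
    assert all(0.7 <= i <= 1.0 for i in iccs)


def test_progression_prevalence_matches_base_rate():
    cfg = SimulationConfig(n_participants=1500, seed=13)
    participants, _, _ = generate_cohort(cfg)
    ph = derive_phenotypes(participants)
    ev, risk, _ = progression_rate(ph["progressed_lt30"])
    p = cfg.progression_base_rate
    sd = np.sqrt(p * (1 - p) * risk)
    assert abs(ev - p * risk) <= 2 * sd


def test_marker_log_normality_before_censoring():
    cfg = SimulationConfig(n_participants=500, seed=14)
    _, _, truth = generate_cohort(cfg)
    logv = np.array(truth["log_values_uncensored"])
    pvals = [stats.shapiro(logv[:, j]).pvalue for j in range(logv.shape[1])]
    # seeded: no marker grossly non-normal on the log scale
    assert min(pvals) > 1e-4


def test_truth_roundtrips_through_json():
    _, _, truth = generate_cohort(SimulationConfig(n_participants=40, seed=15))
    again = json.loads(json.dumps(truth))
    assert again == truth


def test_lod_censoring_fraction():
    cfg = SimulationConfig(n_participants=1000, seed=16, lod_quantile=0.05)
    _, panel, _ = generate_cohort(cfg)
    below = ~np.isfinite(panel.values)
    frac = below.mean(axis=0)
    assert np.all(frac > 0.0) and np.all(frac < 0.12)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(n_participants=5).validate()
    with pytest.raises(ValueError):
        SimulationConfig(within_cluster_corr=1.1).validate()
    with pytest.raises(ValueError):
        SimulationConfig(enrichment_fractions=(0.0, 0.5)).validate()
    with pytest.raises(ValueError):
        SimulationConfig(true_effect_markers=((99, 0.4),)).validate()
    # negative-definite request: impossible cross-cluster correlation
    with pytest.raises(ValueError):
        SimulationConfig(cross_cluster_corr=-0.9).validate()


def test_correlation_matrix_positive_definite_default():
    r = build_marker_correlation(SimulationConfig())
    assert np.linalg.eigvalsh(r).min() > 0
    assert r[0, 1] == 0.80


class TestEnrichment:
    def test_identity_fractions(self, small_cohort):
        _, participants, panel, truth = small_cohort
        sub_p, sub_panel, _ = apply_enrichment_sampling(
            participants, panel, (1.0, 1.0), seed=0, truth=truth)
        assert len(sub_p) == len(participants)
        assert np.array_equal(sub_panel.values, panel.values, equal_nan=True)

    def test_zero_fractions_empty(self, small_cohort):
        _, participants, panel, _ = small_cohort
        sub_p, sub_panel, _ = apply_enrichment_sampling(
            participants, panel, (1e-12, 1e-12), seed=0)
        assert len(sub_p) == 0 and sub_panel.values.shape[0] == 0

    def test_binomial_bounds(self):
        cfg = SimulationConfig(n_participants=4000, seed=17)
        participants, panel, _ = generate_cohort(cfg)
        egfr = np.array([_sd_egfr(p) for p in participants])
        sub_p, _, _ = apply_enrichment_sampling(
            participants, panel, (0.5, 0.25), seed=18, study_day_egfr=egfr)
        n_lo = int((egfr < 75).sum())
        n_hi = len(egfr) - n_lo
        expect = 0.5 * n_lo + 0.25 * n_hi
        sd = np.sqrt(0.25 * n_lo + 0.1875 * n_hi)
        assert abs(len(sub_p) - expect) <= 3 * sd

    def test_reproducible_by_seed(self, small_cohort):
        _, participants, panel, _ = small_cohort
        a, _, _ = apply_enrichment_sampling(participants, panel, (0.5, 0.25), seed=3)
        b, _, _ = apply_enrichment_sampling(participants, panel, (0.5, 0.25), seed=3)
        assert [p.id for p in a] == [p.id for p in b]


def _sd_egfr(p):
    from renalpanel.simulate import _study_day_egfr

    return _study_day_egfr(p)
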
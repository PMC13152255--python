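"""Ground-truth cohort generation and parameter recovery."""

import numpy as np
import pytest
from scipy import stats

from sgecurate import (
    CohortConfig,
    ConfigError,
    aggregate_points,
    run_pipeline,
    recovery_report,
    simulate_cohort,
)
from sgecurate.simulate import CLASS_BANDS, write_cohort


def test_config_validation():
    with pytest.raises(ConfigError):
        CohortConfig(n_variants=0)
    with pytest.raises(ConfigError):
        CohortConfig(class_mix={"PV": 1.0})
    with pytest.raises(ConfigError):
        CohortConfig(sge_discordance_rate=1.5)
    with pytest.raises(ConfigError):
        CohortConfig(lr_lognormal_params={"pathogenic": (-0.5, 0.4), "benign": (-0.6, 0.4)})


def test_same_seed_reproduces_cohort(tmp_path):
    config = CohortConfig(n_variants=60, seed=42)
    a_records, a_truth = simulate_cohort(config)
    b_records, b_truth = simulate_cohort(config)
    assert a_records == b_records
    assert a_truth.equals(b_truth)
    pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_cohort(a_records, pa)
    write_cohort(b_records, pb)
    assert pa.read_bytes() == pb.read_bytes()


def test_evidence_totals_fall_in_true_class_band():
    records, truth = simulate_cohort(CohortConfig(n_variants=300, seed=3))
    for record, true_class in zip(records, truth["true_class"]):
        lo, hi = CLASS_BANDS[true_class]
        assert lo <= aggregate_points(list(record.evidence)) <= hi


def test_discordance_rate_recovered_within_binomial_interval():
    config = CohortConfig(n_variants=500, sge_discordance_rate=0.2, sge_error_rate=0.0, seed=1)
    records, truth = simulate_cohort(config)
    result = run_pipeline(records)
    observed = result.summary["n_discordant"]
    lo = stats.binom.ppf(0.005, 500, 0.2)
    hi = stats.binom.ppf(0.995, 500, 0.2)
    assert lo <= observed <= hi
    # forced-discordant flags agree with observed discordance exactly when
    # per-dataset corruption is off
    assert observed == int(truth["forced_discordant"].sum())


def test_noise_free_cohort_never_moves_against_truth():
    config = CohortConfig(n_variants=200, sge_discordance_rate=0.0, sge_error_rate=0.0, seed=2)
    records, truth = simulate_cohort(config)
    result = run_pipeline(records)
    report = recovery_report(records, truth, result)
    confusion = report["confusion"]
    # definitive truth rows stay on their own side of the scale
    assert confusion.loc["PV"].drop("PV").sum() == 0
    assert confusion.loc["BV"].drop("BV").sum() == 0
    assert confusion.loc["VUS", ["PV", "LPV", "LBV", "BV"]].sum() == 0
    assert report["discordant_fraction"] == 0.0


def test_lr_groups_separate():
    """With log-mean +/-0.6, sd 0.4 and three components, nearly every
    pathogenic-truth variant has combined LR > 1 (normal-tail bound
    1 - Phi(-0.6*3 / (0.4*sqrt(3))) ~ 0.995)."""
    config = CohortConfig(n_variants=1000, seed=4)
    records, truth = simulate_cohort(config)
    report = recovery_report(records, truth, run_pipeline(records))
    assert report["lr_separation"]["pathogenic_gt1"] >= 0.95
    assert report["lr_separation"]["benign_lt1"] >= 0.95


def test_injected_sge_error_rate_recovered():
    config = CohortConfig(
        n_variants=1000,
        class_mix={"PV": 0.5, "LPV": 0.0, "VUS": 0.0, "LBV": 0.0, "BV": 0.5},
        sge_discordance_rate=0.0,
        sge_error_rate=0.1,
        seed=5,
    )
    records, truth = simulate_cohort(config)
    report = recovery_report(records, truth, run_pipeline(records))
    lo = stats.binom.ppf(0.005, 1000, 0.1) / 1000
    hi = stats.binom.ppf(0.995, 1000, 0.1) / 1000
    for dataset in ("hap1_vs_truth", "mes_vs_truth"):
        assert lo <= report[dataset]["major_rate"] <= hi


def test_recovery_report_requires_matching_ids():
    records, truth = simulate_cohort(CohortConfig(n_variants=20, seed=6))
    result = run_pipeline(records)
    shuffled = truth.iloc[::-1].reset_index(drop=True)
    with pytest.raises(Exception):
        recovery_report(records, shuffled, result)


def test_summary_statistics_invariant_under_record_order():
    """Record indices are exchangeable: shuffling the cohort leaves the
    cohort-level summary unchanged."""
    records, _ = simulate_cohort(CohortConfig(n_variants=150, seed=8))
    base = run_pipeline(records).summary
    rng = np.random.default_rng(0)
    shuffled = list(records)
    rng.shuffle(shuffled)
    other = run_pipeline(shuffled).summary
    assert base["transitions"] == other["transitions"]
    assert base["n_discordant"] == other["n_discordant"]
    assert base["discordant_agreement"]["HAP1"] == other["discordant_agreement"]["HAP1"]
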
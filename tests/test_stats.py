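import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import slowave as sw
from slowave import stats
from slowave import synth
from slowave.errors import ValidationError


def rank_oracle(x):
    """Average ranks computed from first principles."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    sx = x[order]
    while i < len(x):
        j = i
        while j < len(x) and sx[j] == sx[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # 1-based average rank
        i = j
    return ranks


def spearman_oracle(x, y):
    rx, ry = rank_oracle(x), rank_oracle(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        rho, p = sw.spearman_correlation(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        assert p < 1e-6

    def test_perfect_antimonotone(self):
        x = np.arange(10.0)
        rho, _ = sw.spearman_correlation(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_ties_match_rank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 8.0])
        y = np.array([3.0, 1.0, 4.0, 4.0, 2.0, 9.0, 9.0, 7.0])
        rho, _ = sw.spearman_correlation(x, y)
        assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            sw.spearman_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            sw.spearman_correlation([1.0, 2.0], [1.0, 2.0])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        rho1, _ = sw.spearman_correlation(x, y)
        rho2, _ = sw.spearman_correlation(np.exp(x), y**3)
        assert rho1 == pytest.approx(rho2, abs=1e-9)


def metrics_from_counts(counts, area_id=1):
    return pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(len(counts))],
            "area_id": area_id,
            "n_events": counts,
            "events_per_min": np.asarray(counts) / 4.0,
        }
    )


def meta_frame(n, group_sizes=None, covariate=None):
    if group_sizes is None:
        groups = ["G1"] * n
    else:
        groups = [g for g, k in group_sizes for _ in range(k)]
    out = pd.DataFrame({"subject_id": [f"S{i}" for i in range(n)], "group": groups})
    if covariate is not None:
        out["covariate"] = covariate
    return out


class TestGroupCompare:
    def test_identical_groups_degenerate(self):
        counts = [2] * 8
        results = sw.group_compare(
            metrics_from_counts(counts),
            meta_frame(8, [("A", 4), ("B", 4)]),
            areas=[1],
        )
        omnibus = results[0]
        assert omnibus.statistic == 0.0
        assert omnibus.p_value == 1.0
        assert len(results) == 1  # no post-hoc when omnibus does not reject

    def test_separated_groups_reject_with_posthoc(self):
        counts = [0, 1, 0, 1, 1, 0, 9, 11, 10, 12, 10, 11]
        results = sw.group_compare(
            metrics_from_counts(counts),
            meta_frame(12, [("A", 6), ("B", 6)]),
            areas=[1],
        )
        assert results[0].p_value < 0.05
        posthoc = [r for r in results if r.test == "rank-sum"]
        assert len(posthoc) == 1
        assert posthoc[0].p_value < 0.05
        assert posthoc[0].correction == "unadjusted (LSD-analog)"

    def test_kruskal_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(3.0, size=12).astype(float)
        meta = meta_frame(12, [("A", 6), ("B", 6)])
        r1 = sw.group_compare(metrics_from_counts(counts), meta, areas=[1])[0]
        r2 = sw.group_compare(metrics_from_counts(np.exp(counts)), meta, areas=[1])[0]
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-9)

    def test_insufficient_group_sizes_rejected(self):
        with pytest.raises(ValidationError):
            sw.group_compare(
                metrics_from_counts([1, 2, 3]),
                meta_frame(3, [("A", 2), ("B", 1)]),
                areas=[1],
            )

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            sw.group_compare(metrics_from_counts([1, 2, 3, 4]), meta_frame(4), areas=[1])


class TestDurationCorrelation:
    def build(self, counts, covariate):
        metrics = metrics_from_counts(counts)
        meta = meta_frame(len(counts), [("PD", len(counts))], covariate=covariate)
        return metrics, meta

    def test_positive_association(self):
        cov = np.arange(12.0)
        counts = (cov * 2 + 1).astype(int)
        metrics, meta = self.build(counts, cov)
        res = sw.duration_correlation(metrics, meta)
        assert res.statistic == pytest.approx(1.0)
        assert res.test == "spearman"

    def test_sum_over_areas(self):
        cov = [1.0, 2.0, 3.0, 4.0]
        m1 = metrics_from_counts([0, 1, 2, 3], area_id=1)
        m2 = metrics_from_counts([0, 2, 4, 6], area_id=2)
        metrics = pd.concat([m1, m2], ignore_index=True)
        meta = meta_frame(4, [("PD", 4)], covariate=cov)
        res = sw.duration_correlation(metrics, meta, scope="all", count_aggregate="sum")
        assert res.statistic == pytest.approx(1.0)

    def test_matches_rank_oracle_on_ties(self):
        cov = [1.0, 1.0, 2.0, 3.0, 3.0, 4.0]
        counts = [2, 0, 3, 3, 1, 5]
        metrics, meta = self.build(counts, cov)
        res = sw.duration_correlation(metrics, meta)
        assert res.statistic == pytest.approx(
            spearman_oracle(np.array(cov), np.array(counts, dtype=float)), abs=1e-12
        )


class TestSubjectPipeline:
    config = stats.PipelineConfig(bandpass=None, bandstop=None, rereference=False)

    def test_event_free_background_no_events(self, small_background):
        m = sw.run_subject_pipeline(small_background, self.config)
        assert m.per_area["n_events"].sum() == 0
        assert m.pct_time_subject == 0.0

    def test_planted_event_found_only_in_its_area(self, small_background, montage):
        labels = tuple(l for l in small_background.labels if montage.area_of(l) == 3)
        ev = sw.PlantedEvent(
            "T", labels, start_s=8.0, duration_s=10.0, dominant_freq=3.0, amplitude_ratio=5.0
        )
        rec = sw.plant_slow_event(small_background, ev)
        m = sw.run_subject_pipeline(rec, self.config)
        per_area = m.per_area.set_index("area_id")["n_events"]
        assert per_area.loc[3] >= 1
        assert per_area.drop(3).sum() == 0

    def test_deterministic(self, small_background):
        a = sw.run_subject_pipeline(small_background, self.config)
        b = sw.run_subject_pipeline(small_background, self.config)
        assert a.to_frame().equals(b.to_frame())

    def test_stage_errors_are_labelled(self):
        short = sw.generate_background(sw.SynthSpec(n_channels=9, duration_s=8.0, seed=1))
        cfg = stats.PipelineConfig()  # 8 s < 3x the default 825-tap filter
        with pytest.raises(ValidationError, match=r"\[preprocess\]"):
            sw.run_subject_pipeline(short, cfg)


class TestEndToEndParameterRecovery:
    def test_estimated_rho_tracks_true_count_rho(self):
        # one seed here; the 50-seed version runs in the acceptance suite
        cspec = sw.CohortSpec(
            n_subjects_per_group=31,
            groups=("PD",),
            base_event_rate=0.5,
            rate_covariate_slope=0.25,
            seed=12,
        )
        synth_spec = sw.SynthSpec(n_channels=9, duration_s=120.0, seed=0)
        recordings, table = sw.generate_cohort(cspec, synth_spec)
        detected = []
        for rec in recordings:
            region = sw.spatial_average(rec)
            n = sum(len(sw.detect_pswe(s)) for s in sw.mpf_timecourse(region))
            detected.append(n)
        true_rho, _ = sw.spearman_correlation(table["covariate"], table["n_true_events"])
        est_rho, _ = sw.spearman_correlation(table["covariate"], detected)
        assert est_rho == pytest.approx(true_rho, abs=0.25)
        assert est_rho > 0
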
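"""Window geometry, correlation profiles and anomaly calling."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phagesig.composition import tetra_signature
from phagesig.genome_io import SequenceRecord
from phagesig.simulate import make_chimera, markov_from_gc, simulate, toy_orfs
from phagesig.window_scan import (
    CorrelationProfile,
    WindowEntry,
    WindowSpec,
    call_anomalies,
    make_windows,
    robust_threshold,
    window_profile,
)


class TestMakeWindows:
    def test_phage_sized_genome_gives_41_windows(self):
        # 40,452 bp at 10 kb / 1 kb with truncated terminal windows
        wins = make_windows(40_452, WindowSpec())
        assert len(wins) == 41
        assert wins[0] == (0, 10_000)
        assert wins[-1] == (40_000, 40_452)

    def test_truncated_windows_included_by_default(self):
        wins = make_windows(10_000, WindowSpec(window=10_000, step=1_000))
        assert len(wins) == 10
        assert wins[0] == (0, 10_000)
        assert all(end == 10_000 for _, end in wins)

    def test_full_windows_only(self):
        spec = WindowSpec(window=10_000, step=1_000, include_truncated=False)
        assert make_windows(10_000, spec) == [(0, 10_000)]

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            WindowSpec(window=100, step=200)

    @given(
        L=st.integers(1, 5_000),
        window=st.integers(1, 500),
        step=st.integers(1, 500),
    )
    def test_coverage_invariant(self, L, window, step):
        if window < step:
            window, step = step, window
        spec = WindowSpec(window=window, step=step)
        wins = make_windows(L, spec)
        assert len(wins) == math.ceil(L / step)
        # union covers [0, L); every base in 1..ceil(window/step) windows
        cover = np.zeros(L, dtype=int)
        for s, e in wins:
            cover[s:e] += 1
        assert cover.min() >= 1
        assert cover.max() <= math.ceil(window / step)


def profile_from_r(r_values, window=10_000, step=1_000, L=None):
    entries = [
        WindowEntry(start=i * step, end=min(i * step + window, L or 10**9), r=r)
        for i, r in enumerate(r_values)
    ]
    return CorrelationProfile(entries=entries, genome_signature=None)


class TestWindowProfile:
    def test_window_equal_to_genome_gives_r_exactly_one(self):
        seq = simulate(markov_from_gc(0.5, order=0), 5_000, seed=0)
        rec = SequenceRecord(id="g", seq=seq)
        prof = window_profile(rec, WindowSpec(window=5_000, step=5_000))
        assert len(prof.entries) == 1
        assert prof.entries[0].r == 1.0

    def test_uniform_background_full_windows_correlate_highly(self):
        # full-length windows of a single-model genome track the genome
        # signature; truncated tail windows are noisier and excluded here
        for seed in range(5):
            rec, _, _ = make_chimera(L=40_000, insert_spans=[], seed=seed)
            prof = window_profile(rec)
            full = [e.r for e in prof.entries if e.end - e.start == 10_000]
            assert min(full) >= 0.8, f"seed {seed}: min full-window r {min(full):.3f}"

    def test_chimera_minimum_window_overlaps_insert(self, default_chimera):
        rec, truth, _ = default_chimera
        prof = window_profile(rec)
        e = prof.min_entry()
        s0, e0, _ = truth.inserts[0]
        assert e.start < e0 and s0 < e.end

    def test_zscore_mode_runs(self, default_chimera):
        rec, _, _ = default_chimera
        prof = window_profile(
            rec, WindowSpec(window=20_000, step=20_000), correlate="zscore"
        )
        assert all(-1 <= e.r <= 1 for e in prof.entries if not math.isnan(e.r))

    def test_unknown_mode_rejected(self, default_chimera):
        with pytest.raises(ValueError):
            window_profile(default_chimera[0], correlate="cosine")

    def test_profile_deterministic(self, default_chimera):
        rec, _, _ = default_chimera
        a = window_profile(rec)
        b = window_profile(rec)
        assert [(e.start, e.end, e.r) for e in a.entries] == [
            (e.start, e.end, e.r) for e in b.entries
        ]


class TestCallAnomalies:
    def test_constant_profile_flags_nothing(self):
        call = call_anomalies(profile_from_r([0.99] * 41, L=50_000))
        assert call.regions == [] and call.flagged_features == []

    def test_single_outlier_flagged_as_its_own_span(self):
        r = [0.97] * 40
        r.insert(20, 0.5)
        call = call_anomalies(profile_from_r(r, L=50_000))
        assert call.regions == [(20_000, 30_000, 0.5)]

    def test_adjacent_outliers_merge(self):
        r = [0.97] * 41
        r[10] = r[11] = 0.4
        call = call_anomalies(profile_from_r(r, L=51_000))
        assert call.regions == [(10_000, 21_000, 0.4)]

    def test_monotone_in_fixed_threshold(self):
        rng = np.random.default_rng(0)
        r = rng.uniform(0.3, 1.0, size=41)
        prof = profile_from_r(list(r), L=50_452)
        counts = []
        for cut in [0.9, 0.7, 0.5, 0.3]:
            call = call_anomalies(prof, threshold=cut)
            counts.append(sum(e - s for s, e, _ in call.regions))
        assert counts == sorted(counts, reverse=True)

    def test_missing_r_excluded_and_never_flagged(self):
        r = [0.97] * 10 + [float("nan")] + [0.97] * 10
        call = call_anomalies(profile_from_r(r, L=30_000), threshold=0.99)
        flagged_starts = {s for s, _, _ in call.regions}
        assert 10_000 not in flagged_starts  # the NaN window

    def test_all_missing_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            call_anomalies(profile_from_r([float("nan")] * 5, L=14_000))

    def test_robust_threshold_formula(self):
        r = np.array([0.9, 0.91, 0.92, 0.93, 0.94])
        med = np.median(r)
        mad = np.median(np.abs(r - med))
        assert robust_threshold(r) == pytest.approx(med - 3 * 1.4826 * mad)

    def test_chimera_features_localized_to_insert(self, default_chimera):
        # every ORF inside the insert is flagged; every flagged ORF lies
        # within one window length of it (scan resolution = window size)
        rec, truth, feats = default_chimera
        prof = window_profile(rec)
        call = call_anomalies(prof, feats)
        s0, e0, _ = truth.inserts[0]
        inside = {f.feature_id for f in feats if f.start >= s0 and f.end <= e0}
        flagged = {fid for fid, _ in call.flagged_features}
        assert inside <= flagged
        window = 10_000
        for f in feats:
            if f.feature_id in flagged:
                assert f.end > s0 - window and f.start < e0 + window

    def test_feature_score_is_min_over_overlapping_windows(self):
        r = [0.9] * 10
        r[3] = 0.4
        prof = profile_from_r(r, window=1_000, step=1_000, L=10_000)
        feats = toy_orfs(10_000, tile=1_000)
        call = call_anomalies(prof, feats, threshold=0.5)
        assert call.feature_scores["ORF_4"] == 0.4
        assert call.flagged_features == [("ORF_4", 0.4)]
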
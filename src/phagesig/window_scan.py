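"""Sliding-window tetranucleotide correlation profile and anomaly calling.

Each window's signature is correlated (Pearson, on Z-vectors) against the
whole-genome signature; runs of unusually low correlation mark regions whose
composition departs from the genome-wide signature — the classic footprint
of horizontally acquired modules and prophage cargo. Flagged windows are
merged into maximal regions and mapped onto ORFs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .composition import (
    TetraSignature,
    frequency_correlation,
    signature_correlation,
    tetra_signature,
)
from .genome_io import FeatureInterval, SequenceRecord


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry. Defaults: 10 kb windows, 1 kb step.

    With ``include_truncated`` (the default) window starts run 0, step,
    2*step, ... for every start < L, and terminal windows are truncated at
    the sequence end, giving ceil(L/step) windows; a 40,452 bp genome at
    10 kb / 1 kb therefore yields 41 windows.
    """

    window: int = 10_000
    step: int = 1_000
    include_truncated: bool = True

    def __post_init__(self) -> None:
        if not (self.window >= self.step >= 1):
            raise ValueError(
                f"require window >= step >= 1, got window={self.window} step={self.step}"
            )


@dataclass(frozen=True)
class WindowEntry:
    start: int      # 0-based inclusive
    end: int        # 0-based exclusive
    r: float        # NaN when undefined


@dataclass(frozen=True)
class CorrelationProfile:
    entries: list[WindowEntry]
    genome_signature: TetraSignature

    def r_values(self) -> np.ndarray:
        return np.array([e.r for e in self.entries], dtype=float)

    def min_entry(self) -> WindowEntry:
        """Entry with the lowest defined correlation."""
        defined = [e for e in self.entries if not math.isnan(e.r)]
        if not defined:
            raise ValueError("profile has no defined correlations")
        return min(defined, key=lambda e: e.r)


@dataclass(frozen=True)
class AnomalyCall:
    regions: list[tuple[int, int, float]]            # (start, end, min_r), merged
    flagged_features: list[tuple[str, float]]        # (feature_id, feature_min_r)
    threshold: float
    feature_scores: dict[str, float] = field(default_factory=dict)


def make_windows(L: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """Window intervals (0-based half-open) covering [0, L)."""
    if L < 1:
        raise ValueError(f"sequence length must be >= 1, got {L}")
    out = []
    for start in range(0, L, spec.step):
        end = min(start + spec.window, L)
        if not spec.include_truncated and end - start < spec.window:
            continue
        out.append((start, end))
    return out


def window_profile(
    rec: SequenceRecord,
    spec: WindowSpec | None = None,
    correlate: str = "frequency",
) -> CorrelationProfile:
    """Correlation of every window's tetranucleotide signature vs the genome's.

    The genome signature is computed once on the rc-extended full sequence;
    each window signature on the rc-extended window subsequence. Windows
    whose signature is degenerate carry NaN.

    ``correlate`` selects the vectors the Pearson r is taken over:
    ``"frequency"`` (default) correlates the observed 4-mer frequency
    vectors, which keep the base-composition signal and stay informative on
    any genome; ``"zscore"`` correlates the Markov-corrected Z-score
    vectors, which carry signal only where the genome has tetranucleotide
    structure beyond the order-2 model (true of real genomes, not of
    low-order simulations).
    """
    try:
        corr = {"frequency": frequency_correlation, "zscore": signature_correlation}[correlate]
    except KeyError:
        raise ValueError(f"correlate must be 'frequency' or 'zscore', got {correlate!r}")
    spec = spec or WindowSpec()
    genome_sig = tetra_signature(rec.seq)
    entries = []
    for start, end in make_windows(rec.length, spec):
        win_sig = tetra_signature(rec.seq[start:end])
        r = corr(win_sig, genome_sig)
        entries.append(WindowEntry(start=start, end=end, r=r))
    return CorrelationProfile(entries=entries, genome_signature=genome_sig)


def robust_threshold(r: np.ndarray) -> float:
    """Default anomaly cutoff: median(r) - 3 * 1.4826 * MAD(r).

    With constant r the MAD is 0 and the cutoff equals the median, so no
    window is strictly below it and nothing is flagged.
    """
    med = float(np.median(r))
    mad = float(np.median(np.abs(r - med)))
    return med - 3.0 * 1.4826 * mad


def call_anomalies(
    profile: CorrelationProfile,
    features: list[FeatureInterval] | None = None,
    threshold: float | None = None,
) -> AnomalyCall:
    """Flag low-correlation windows, merge them into regions, map to features.

    Windows with r strictly below the threshold are flagged; the default
    threshold is the robust median - 3*MAD rule, overridable with a fixed
    value. Flagged windows are merged when overlapping or within one step of
    each other. A feature's score is the minimum r over windows overlapping
    it (a feature is as anomalous as its worst window); features scoring
    below the threshold are flagged. Windows with missing r are excluded
    from the threshold statistics and never flagged.
    """
    defined = [e for e in profile.entries if not math.isnan(e.r)]
    if not defined:
        raise ValueError("degenerate profile: all window correlations are missing")
    r = np.array([e.r for e in defined])
    cut = robust_threshold(r) if threshold is None else float(threshold)

    flagged = [e for e in defined if e.r < cut]

    step = _infer_step(profile)
    regions: list[tuple[int, int, float]] = []
    for e in flagged:
        if regions and e.start <= regions[-1][1] + step:
            start, end, min_r = regions[-1]
            regions[-1] = (start, max(end, e.end), min(min_r, e.r))
        else:
            regions.append((e.start, e.end, e.r))

    feature_scores: dict[str, float] = {}
    flagged_features: list[tuple[str, float]] = []
    for f in features or []:
        over = [e.r for e in defined if f.overlaps(e.start, e.end)]
        if not over:
            continue
        score = min(over)
        feature_scores[f.feature_id] = score
        if score < cut:
            flagged_features.append((f.feature_id, score))
    return AnomalyCall(
        regions=regions,
        flagged_features=flagged_features,
        threshold=cut,
        feature_scores=feature_scores,
    )


def _infer_step(profile: CorrelationProfile) -> int:
    starts = [e.start for e in profile.entries]
    if len(starts) < 2:
        return 0
    return min(b - a for a, b in zip(starts, starts[1:]))
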
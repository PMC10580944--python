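"""Windowed and cumulative GC skew, with origin/terminus calling.

GC skew, (G-C)/(G+C), flips sign between leading and lagging strands in
most prokaryotic and many phage genomes because of strand-asymmetric
mutation and repair pressure. The cumulative curve — the running sum of the
raw per-window (G - C) counts — therefore has its global minimum near the
replication origin and its global maximum near the terminus, which is how
both are called here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genome_io import SequenceRecord
from .window_scan import WindowSpec, make_windows

logger = logging.getLogger(__name__)

#: Defaults suited to genomes well under 100 kb.
SKEW_DEFAULTS = WindowSpec(window=500, step=100)


@dataclass(frozen=True)
class SkewProfile:
    """Per-window and cumulative GC skew with called replication extremes.

    ``positions`` are the reporting positions of the windows: the 1-based
    window center snapped to the nearest multiple of step (ties to the lower
    multiple, so round positions like the step grid are produced).
    ``window_skew`` is (G-C)/(G+C) of the full (possibly overlapping)
    window, NaN where a window has no G or C. ``cumulative`` accumulates the
    raw (G-C) count of each window's leading step-sized chunk — the
    non-overlapping partition of the genome — so that its last value always
    equals the sequence's total #G - #C regardless of the window/step
    choice; when window == step the chunks are the windows themselves.
    Origin is the position of the global cumulative minimum, terminus of the
    global maximum; ties resolve to the smallest position.
    """

    spec: WindowSpec
    positions: np.ndarray
    window_skew: np.ndarray
    cumulative: np.ndarray
    origin_pos: int
    terminus_pos: int


def _grid_position(start: int, end: int, step: int) -> int:
    """1-based window center snapped to the step grid, ties downward."""
    center = start + (end - start + 1) // 2  # 1-based center, ties toward start
    q, rem = divmod(center, step)
    return (q + 1) * step if 2 * rem > step else q * step


def skew_profile(rec: SequenceRecord, spec: WindowSpec | None = None) -> SkewProfile:
    """Compute windowed and cumulative GC skew and call origin/terminus."""
    spec = spec or SKEW_DEFAULTS
    if rec.length < spec.window:
        logger.warning(
            "sequence length %d < window %d: degenerate single-window profile",
            rec.length,
            spec.window,
        )
    windows = make_windows(rec.length, spec)
    is_g = np.frombuffer(rec.seq.encode("ascii"), dtype=np.uint8) == ord("G")
    is_c = np.frombuffer(rec.seq.encode("ascii"), dtype=np.uint8) == ord("C")
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_c = np.concatenate([[0], np.cumsum(is_c)])

    positions = np.empty(len(windows), dtype=np.int64)
    diff = np.empty(len(windows), dtype=np.int64)
    skew = np.empty(len(windows), dtype=float)
    for i, (start, end) in enumerate(windows):
        g = int(cum_g[end] - cum_g[start])
        c = int(cum_c[end] - cum_c[start])
        positions[i] = _grid_position(start, end, spec.step)
        skew[i] = (g - c) / (g + c) if g + c > 0 else np.nan
        # non-overlapping chunk for the cumulative track (== window when step==window)
        chunk_end = min(start + spec.step, rec.length)
        diff[i] = int((cum_g[chunk_end] - cum_g[start]) - (cum_c[chunk_end] - cum_c[start]))

    cumulative = np.cumsum(diff)
    origin_pos = int(positions[int(np.argmin(cumulative))])
    terminus_pos = int(positions[int(np.argmax(cumulative))])
    return SkewProfile(
        spec=spec,
        positions=positions,
        window_skew=skew,
        cumulative=cumulative,
        origin_pos=origin_pos,
        terminus_pos=terminus_pos,
    )
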
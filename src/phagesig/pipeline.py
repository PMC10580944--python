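"""End-to-end orchestration: stats -> tetra-scan -> gc-skew -> summary files.

Everything here is deterministic: re-running with an identical config
reproduces bit-identical output files. All defaults are materialized into
the emitted summary so a run is self-describing.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

from . import __version__
from .gc_skew import SKEW_DEFAULTS, skew_profile
from .genome_io import (
    FeatureInterval,
    SequenceRecord,
    read_fasta,
    read_features,
    write_interval_table,
)
from .window_scan import WindowSpec, call_anomalies, window_profile

logger = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (so 0.005 -> 0.01), matching reported precision."""
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -ndigits, rounding=ROUND_HALF_UP))


def genome_stats(rec: SequenceRecord) -> tuple[int, float | None]:
    """Length (all characters, N included) and GC percent (N excluded).

    GC percent is 100*(G+C)/(A+C+G+T); an all-N sequence has undefined GC,
    returned as None. Full precision is returned; round for display with
    :func:`round_half_up`.
    """
    L = rec.length
    counts = {b: rec.seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        return L, None
    return L, 100.0 * (counts["G"] + counts["C"]) / denom


@dataclass
class RunConfig:
    genome_path: str
    features_path: str | None = None
    features_format: str = "tsv"
    window: int = 10_000
    step: int = 1_000
    skew_window: int = SKEW_DEFAULTS.window
    skew_step: int = SKEW_DEFAULTS.step
    threshold: float | None = None  # None -> robust median-3*MAD rule
    correlate: str = "frequency"
    out_prefix: str = "phagesig"


@dataclass
class RunSummary:
    genome_id: str
    length_bp: int
    gc_percent: float | None
    n_windows: int
    min_r: float | None
    min_r_window: tuple[int, int] | None  # 1-based inclusive
    threshold: float
    flagged_regions: list[tuple[int, int, float]]  # 1-based inclusive spans
    flagged_features: list[tuple[str, float]]
    origin_pos: int
    terminus_pos: int
    version: str = ""
    config: dict = field(default_factory=dict)


def run_all(config: RunConfig) -> RunSummary:
    """Run the whole analysis and write all output tables.

    Writes ``{out_prefix}.windows.tsv`` (per-window r), ``.flagged.bed``
    (merged anomalous regions, min_r as score), ``.features.tsv`` (per-ORF
    min r and flag; only when an annotation was given), ``.skew.tsv`` and
    ``.summary.json``.
    """
    rec = read_fasta(config.genome_path)
    features: list[FeatureInterval] = []
    if config.features_path:
        features = read_features(config.features_path, config.features_format, record=rec)
        logger.info("loaded %d features from %s", len(features), config.features_path)
    else:
        logger.info("no features file given; window-to-feature mapping disabled")

    L, gc = genome_stats(rec)
    logger.info("genome %s: %d bp, GC %s%%", rec.id, L,
                "undefined" if gc is None else f"{round_half_up(gc):.2f}")

    spec = WindowSpec(window=config.window, step=config.step)
    logger.info("tetra scan: window=%d step=%d correlate=%s",
                spec.window, spec.step, config.correlate)
    profile = window_profile(rec, spec, correlate=config.correlate)
    call = call_anomalies(profile, features, threshold=config.threshold)
    logger.info("anomaly threshold r < %.4f: %d region(s), %d feature(s) flagged",
                call.threshold, len(call.regions), len(call.flagged_features))

    skew_spec = WindowSpec(window=config.skew_window, step=config.skew_step)
    logger.info("gc skew: window=%d step=%d", skew_spec.window, skew_spec.step)
    skew = skew_profile(rec, skew_spec)
    logger.info("origin=%d terminus=%d", skew.origin_pos, skew.terminus_pos)

    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    with open(f"{prefix}.windows.tsv", "w") as fh:
        fh.write("start_1based\tend_1based\tr\n")
        for e in profile.entries:
            r_txt = "NA" if math.isnan(e.r) else f"{e.r:.6f}"
            fh.write(f"{e.start + 1}\t{e.end}\t{r_txt}\n")

    write_interval_table(
        [(s, e, f"region_{i + 1}", round(r, 6)) for i, (s, e, r) in enumerate(call.regions)],
        f"{prefix}.flagged.bed",
        fmt="bed",
        chrom=rec.id,
    )

    if features:
        flagged_ids = {fid for fid, _ in call.flagged_features}
        with open(f"{prefix}.features.tsv", "w") as fh:
            fh.write("feature_id\tfeature_min_r\tflagged\n")
            for f in features:
                score = call.feature_scores.get(f.feature_id)
                s_txt = "NA" if score is None else f"{score:.6f}"
                fh.write(f"{f.feature_id}\t{s_txt}\t{int(f.feature_id in flagged_ids)}\n")

    with open(f"{prefix}.skew.tsv", "w") as fh:
        fh.write("position\twindow_skew\tcumulative\n")
        for pos, s, c in zip(skew.positions, skew.window_skew, skew.cumulative):
            s_txt = "NA" if math.isnan(s) else f"{s:.6f}"
            fh.write(f"{pos}\t{s_txt}\t{c}\n")

    defined = [e for e in profile.entries if not math.isnan(e.r)]
    min_entry = min(defined, key=lambda e: e.r) if defined else None
    summary = RunSummary(
        genome_id=rec.id,
        length_bp=L,
        gc_percent=None if gc is None else round_half_up(gc),
        n_windows=len(profile.entries),
        min_r=None if min_entry is None else round_half_up(min_entry.r),
        min_r_window=None if min_entry is None else (min_entry.start + 1, min_entry.end),
        threshold=call.threshold,
        flagged_regions=[(s + 1, e, round_half_up(r)) for s, e, r in call.regions],
        flagged_features=[(fid, round_half_up(r)) for fid, r in call.flagged_features],
        origin_pos=skew.origin_pos,
        terminus_pos=skew.terminus_pos,
        version=__version__,
        config=asdict(config),
    )
    with open(f"{prefix}.summary.json", "w") as fh:
        json.dump(asdict(summary), fh, indent=2)
        fh.write("\n")
    return summary
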
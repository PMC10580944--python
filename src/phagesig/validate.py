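"""Optional validation against the deposited Halomonas phage genome.

The reference genome (GenBank accession OQ832096, phage vB_HmeY_H4907) is
not bundled and is never fetched over the network; the user downloads the
FASTA themselves and points this module at it. Published values for that
record: length 40,452 bp; GC 57.64%; cumulative GC-skew minimum (origin)
near 40,400 nt and maximum (terminus) near 200 nt; minimum window-vs-genome
tetranucleotide correlation 0.79. The skew extrema and the 0.79 depend on
windowing parameters the original analysis did not publish, so they are
validation targets rather than hard guarantees.
"""

from __future__ import annotations

from pathlib import Path

from .gc_skew import skew_profile
from .genome_io import read_fasta
from .pipeline import genome_stats, round_half_up
from .window_scan import WindowSpec, window_profile

#: Published values for accession OQ832096.
REFERENCE = {
    "length_bp": 40_452,
    "gc_percent": 57.64,
    "origin_pos": 40_400,
    "terminus_pos": 200,
    "min_r": 0.79,
}

#: Conventional location users may drop the genome at, relative to repo root.
DEFAULT_REFERENCE_PATH = Path("data") / "OQ832096.fasta"


def validate_reference_genome(path: str | Path) -> dict:
    """Recompute the published quantities for the deposited genome.

    Returns a dict with the computed values, the published references and a
    boolean ``matches`` per quantity (skew extrema compared to the nearest
    100 nt, min_r to 2 decimals).
    """
    rec = read_fasta(path)
    L, gc = genome_stats(rec)
    skew = skew_profile(rec)
    profile = window_profile(rec, WindowSpec(window=10_000, step=1_000))
    min_r = round_half_up(profile.min_entry().r)
    computed = {
        "length_bp": L,
        "gc_percent": None if gc is None else round_half_up(gc),
        "origin_pos": skew.origin_pos,
        "terminus_pos": skew.terminus_pos,
        "min_r": min_r,
        "n_windows": len(profile.entries),
    }
    matches = {
        "length_bp": computed["length_bp"] == REFERENCE["length_bp"],
        "gc_percent": computed["gc_percent"] == REFERENCE["gc_percent"],
        "origin_pos": abs(computed["origin_pos"] - REFERENCE["origin_pos"]) <= 100,
        "terminus_pos": abs(computed["terminus_pos"] - REFERENCE["terminus_pos"]) <= 100,
        "min_r": computed["min_r"] == REFERENCE["min_r"],
    }
    return {"computed": computed, "reference": dict(REFERENCE), "matches": matches}
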
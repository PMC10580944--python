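"""The whole pipeline on files, as the CLI runs it.

Writes a simulated chimera to FASTA/TSV, runs stats -> tetra-scan ->
gc-skew through run_all, and prints the machine-readable summary. The same
thing from a shell:

    phagesig simulate --seed 7 --out-prefix sim
    phagesig run-all --genome sim.fasta --features sim.features.tsv --out-prefix run
"""

import json
import tempfile
from dataclasses import asdict
from pathlib import Path

from phagesig import RunConfig, make_chimera, run_all
from phagesig.genome_io import write_features_tsv

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    rec, truth, orfs = make_chimera(seed=7)
    with open(tmp / "sim.fasta", "w") as fh:
        fh.write(f">{rec.id}\n{rec.seq}\n")
    write_features_tsv(orfs, tmp / "sim.features.tsv")

    summary = run_all(RunConfig(
        genome_path=str(tmp / "sim.fasta"),
        features_path=str(tmp / "sim.features.tsv"),
        out_prefix=str(tmp / "run"),
    ))
    print(json.dumps({k: v for k, v in asdict(summary).items() if k != "config"}, indent=2))
    print("outputs written:", sorted(p.name for p in tmp.glob("run.*")))
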
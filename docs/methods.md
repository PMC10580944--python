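# Methods

## Model and procedure

The package detects compositionally anomalous regions in a single genome by
comparing local tetranucleotide usage against the genome-wide signature,
and calls the replication origin/terminus from cumulative GC skew. Both
analyses are alignment-free and assume one linear, single-contig dsDNA
sequence over {A,C,G,T,N}.

### Tetranucleotide signature

Every counted sequence is first extended by reverse complementation
(`seq + N + revcomp(seq)`), which makes all k-mer statistics exactly
strand-symmetric; the single-`N` separator keeps k-mers from spanning the
junction (k-mer windows containing `N` are skipped and tallied). From the
2-, 3- and 4-mer counts of the extended sequence, the maximal-order Markov
model — the highest-order model whose parameters the 4-mer table itself
determines, i.e. the trinucleotide-conditional chain — gives for each
4-mer `w = n1n2n3n4`:

- `E(w) = N(n1n2n3)·N(n2n3n4)/N(n2n3)`
- `Var(w) = E(w)·(N(n2n3)−N(n1n2n3))·(N(n2n3)−N(n2n3n4))/N(n2n3)²`
- `Z(w) = (N(w)−E(w))/√Var(w)`, with `Z(w) = 0` whenever `Var(w) = 0`.

The zero-variance convention makes the statistic total: no input reaches a
division by zero, and homopolymeric or sub-4-mer sequences yield a defined
(all-zero or near-zero) signature. Counts rather than frequencies feed the
formulas; Z is invariant to that choice up to the variance approximation.
4-mers are indexed lexicographically with A<C<G<T throughout.

### Window scan and the choice of correlation vectors

The genome signature is computed once; each window (default 10 kb, stepped
1 kb, truncated terminal windows included so a genome of length L yields
⌈L/1000⌉ windows) is scored by the Pearson correlation between its
tetranucleotide vector and the genome's.

Two vector choices are implemented and the distinction matters:

- **`frequency` (default).** Observed 4-mer frequency vectors. These are
  dominated by base composition and short-range structure, so a window of
  typical composition correlates near 1 with its genome and a
  compositionally foreign segment drops sharply.
- **`zscore`.** The Markov-corrected Z-vectors (the classic
  tetranucleotide-signature correlation). These measure only structure
  *beyond* what the order-2 model explains. On real genomes that residual
  structure is strong and shared along the chromosome, so both choices
  rank windows similarly. On sequences that genuinely follow a low-order
  Markov model — including everything this package's simulator produces —
  the residual is pure sampling noise: window–genome Z-correlation then
  hovers near √(window/genome) for any window and carries no anomaly
  signal at all, and a foreign insert can even *raise* it by inducing
  apparent structure in the genome signature. The default is therefore
  `frequency`, which is informative on both real and simulated inputs;
  `zscore` is retained for comparison on real genomes.

Windows whose vectors are degenerate (no countable 4-mers) carry a missing
r, are excluded from threshold statistics and are never flagged.

**Anomaly threshold.** Default cutoff `median(r) − 3·1.4826·MAD(r)`, a
robust rule that flags nothing when the profile is flat (MAD = 0 puts the
cutoff at the median, and flagging is strict `<`). A fixed cutoff can be
supplied instead. Flagged windows merge into maximal regions when
overlapping or within one step. Each ORF is scored by the minimum r over
the windows overlapping it — a feature is as anomalous as its worst window.
Because windows are long, this reduction deliberately smears: any feature
within one window length of a foreign segment overlaps a contaminated
window, so flagged-feature lists localize the insert to window resolution,
not to the base pair.

### Cumulative GC skew

Per window (default 500 bp, stepped 100 bp) the skew `(G−C)/(G+C)` is
reported (missing when the window has no G or C). The cumulative track
accumulates the raw (G−C) count of each window's leading step-sized chunk —
the non-overlapping partition of the genome — so its final value equals the
sequence's total `#G − #C` for every window/step choice; when window equals
step the chunks are exactly the windows. The origin is called at the global
cumulative minimum and the terminus at the global maximum (ties resolve to
the smallest position). Reported positions are the 1-based window center
snapped to the nearest multiple of the step, with ties resolved to the
lower grid point (so a 500 bp window starting at 0 reports 200 on a 100 bp
grid). The defaults suit genomes well under 100 kb; the extremes are robust
to the exact window/step, the reported position only to the step grid.

## Synthetic data: what it emulates, what it does not

`markov_from_gc(gc, order, skew)` builds a context-independent chain with
`P(G) = gc/2·(1+skew)`, `P(C) = gc/2·(1−skew)`, `P(A) = P(T) = (1−gc)/2`;
`fit_markov` estimates an order-m chain from a sequence by maximum
likelihood with add-one smoothing (requiring L ≥ 10·4^(m+1));
`simulate` draws sequences reproducibly from an integer seed. The standard
chimera is a 40,452 bp background at GC 0.5764 — the size and composition
of a small temperate marine phage — with one 6 kb insert at GC 0.35
starting at position 28,000, a composition gap chosen to depress the
window–genome correlation to the level observed over horizontally acquired
modules in real phage genomes (minimum r ≈ −0.5 against a ≈ 0.95
background at these defaults; real anomalies are often subtler). Toy ORFs
are uniform 600 bp tiles so feature-level calls can be scored against the
truth table.

The simulator reproduces composition and insert geometry only. It does not
emulate codon structure, gene order, repeats, or the genuine
beyond-order-2 tetranucleotide structure of real genomes — which is
precisely why the Z-vector correlation has no power on simulated input
(see above). Passing recovery tests therefore demonstrates that the scan
localizes composition shifts of the simulated magnitude; they say nothing
about sensitivity to inserts whose composition matches the host's.

## Numerical and design choices

- Coordinates are 0-based half-open internally; all human-facing tables
  are 1-based inclusive (BED output keeps BED's native convention).
- Ambiguity codes degrade to `N` (with a logged count) rather than
  erroring; multi-record FASTA uses the first record with a warning.
- Identical signature vectors short-circuit to r = 1.0 exactly, so the
  window-equals-genome case is exact rather than within float error.
- Reported percentages and correlations round half away from zero to two
  decimals; full precision is kept internally.
- Seeding: `make_chimera` spawns independent child streams (numpy
  `SeedSequence`) for the background and each insert, so truth intervals,
  not draw order, determine the sequence around them.
- Determinism: all analysis stages are seed-free and bit-reproducible;
  only the simulator consumes randomness, always from an explicit seed.
- Problem sizes in the shipped checks (40 kb genomes, 100 kb null
  sequences, 100 recovery seeds, 20 calibration seeds) were chosen as the
  smallest at which the stochastic properties measured are stable.

## Known limitations

- Single-contig analyses only; no wrap-around windows (the terminal
  windows are truncated instead, matching the linear-genome reading).
- Truncated tail windows (down to a few hundred bp) are sampling-noise
  dominated and can show r well below the background level on their own;
  the anomaly caller tolerates this through the robust threshold, but
  per-window r values near the 3' end should be read with their window
  length in mind.
- The per-ORF reduction localizes anomalies to window resolution (see
  above); it cannot say which gene inside a flagged region is foreign.
- GC-skew extreme positions are only meaningful to the step grid, and skew
  calling assumes a bidirectional-replication-like strand bias; genomes
  replicated by other mechanisms may show extremes with no ori/ter
  interpretation.
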
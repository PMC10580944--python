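"""Tetranucleotide signature computation.

The genomic signature used here is the 256-vector of Z-scores measuring
over- or under-representation of each 4-mer relative to the expectation of
the maximal-order Markov model, i.e. the order-2 (trinucleotide-conditional)
model built from the sequence's own 3-mer and 2-mer counts:

    E(n1n2n3n4)   = N(n1n2n3) * N(n2n3n4) / N(n2n3)
    Var(n1n2n3n4) = E * (N(n2n3) - N(n1n2n3)) * (N(n2n3) - N(n2n3n4)) / N(n2n3)^2
    Z(n1n2n3n4)   = (N(n1n2n3n4) - E) / sqrt(Var)

with the convention Z = 0 wherever Var = 0, which keeps the signature
defined on homopolymeric or tiny inputs and makes division by zero
unreachable. Counts are taken on the reverse-complement-extended sequence
(seq + N + revcomp(seq)), so the signature is exactly strand-symmetric; the
single-N separator prevents any k-mer from spanning the junction.

K-mers are indexed lexicographically with A<C<G<T, so index 0 is AAAA and
index 255 is TTTT; signatures are comparable across runs and tools that use
the same ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte -> base code (A=0, C=1, G=2, T=3, anything else -1)
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

BASES = "ACGT"


def kmer_index(kmer: str) -> int:
    """Lexicographic index of a k-mer (A<C<G<T)."""
    idx = 0
    for ch in kmer:
        code = BASES.find(ch)
        if code < 0:
            raise ValueError(f"non-ACGT character in k-mer {kmer!r}")
        idx = idx * 4 + code
    return idx


def index_kmer(idx: int, k: int) -> str:
    """Inverse of :func:`kmer_index`."""
    out = []
    for _ in range(k):
        out.append(BASES[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; N is self-complementary."""
    return seq.translate(_COMPLEMENT)[::-1]


def rc_extend(seq: str) -> str:
    """Concatenate seq, a single N separator, and its reverse complement.

    Counting k-mers on the result makes any k-mer statistic strand-symmetric;
    the N separator keeps k-mers from spanning the forward/reverse junction.
    Output length is 2L+1.
    """
    return seq + "N" + reverse_complement(seq)


@dataclass(frozen=True)
class KmerCountTable:
    """Counts of all 4^k k-mers of a sequence, lexicographic A<C<G<T order.

    Windows containing N are not counted; their number is kept in
    ``n_skipped`` so that counts + skipped always account for every window:
    sum(counts) + n_skipped == max(L - k + 1, 0).
    """

    k: int
    counts: np.ndarray
    n_skipped: int

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def source_length(self) -> int:
        """Length of the sequence the table was counted on."""
        return self.total + self.n_skipped + self.k - 1


def count_kmers(seq: str, k: int) -> KmerCountTable:
    """Sliding count of every k-length window made solely of A/C/G/T.

    Windows containing N (or any non-ACGT character left by normalization)
    are tallied in ``n_skipped`` rather than counted.
    """
    if k not in {2, 3, 4}:
        raise ValueError(f"k must be in {{2,3,4}}, got {k}")
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n_win = len(codes) - k + 1
    if n_win <= 0:
        return KmerCountTable(k=k, counts=np.zeros(4**k, dtype=np.int64), n_skipped=0)
    idx = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    for j in range(k):
        c = codes[j : j + n_win]
        valid &= c >= 0
        idx = idx * 4 + np.where(c >= 0, c, 0)
    counts = np.bincount(idx[valid], minlength=4**k)
    return KmerCountTable(k=k, counts=counts, n_skipped=int(n_win - valid.sum()))


@dataclass(frozen=True)
class TetraSignature:
    """Observed/expected 4-mer statistics and the 256-vector of Z-scores."""

    z: np.ndarray
    obs: np.ndarray
    exp: np.ndarray
    var: np.ndarray


# index arithmetic for tetramer w = n1 n2 n3 n4 (base-4 digits of w's index)
_I4 = np.arange(256)
_PREFIX3 = _I4 // 4          # n1 n2 n3
_SUFFIX3 = _I4 % 64          # n2 n3 n4
_MIDDLE2 = (_I4 // 4) % 16   # n2 n3


def tetra_zscores(
    c2: KmerCountTable, c3: KmerCountTable, c4: KmerCountTable
) -> TetraSignature:
    """Z-scores of 4-mer counts under the trinucleotide-conditional model.

    All three tables must come from the same (rc-extended) sequence; this is
    checked through the count-sum invariant, which recovers the source
    length from each table.
    """
    if (c2.k, c3.k, c4.k) != (2, 3, 4):
        raise ValueError("expected tables with k=2, 3, 4 in that order")
    lengths = {t.source_length() for t in (c2, c3, c4)}
    if len(lengths) != 1:
        raise ValueError(f"count tables disagree on source length: {sorted(lengths)}")

    obs = c4.counts.astype(float)
    n3a = c3.counts[_PREFIX3].astype(float)
    n3b = c3.counts[_SUFFIX3].astype(float)
    n2 = c2.counts[_MIDDLE2].astype(float)

    with np.errstate(divide="ignore", invalid="ignore"):
        exp = np.where(n2 > 0, n3a * n3b / np.where(n2 > 0, n2, 1), 0.0)
        var = np.where(
            n2 > 0,
            exp * (n2 - n3a) * (n2 - n3b) / np.where(n2 > 0, n2, 1) ** 2,
            0.0,
        )
        z = np.where(var > 0, (obs - exp) / np.sqrt(np.where(var > 0, var, 1)), 0.0)
    return TetraSignature(z=z, obs=c4.counts.copy(), exp=exp, var=var)


def tetra_signature(seq: str) -> TetraSignature:
    """Signature of a sequence: rc-extend, count k=2,3,4, take Z-scores."""
    ext = rc_extend(seq)
    return tetra_zscores(count_kmers(ext, 2), count_kmers(ext, 3), count_kmers(ext, 4))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.shape != (256,) or y.shape != (256,):
        raise ValueError("signatures must be length-256 vectors")
    if x.std() == 0.0 or y.std() == 0.0:
        return float("nan")
    if np.array_equal(x, y):
        return 1.0
    return float(np.corrcoef(x, y)[0, 1])


def signature_correlation(a: TetraSignature, b: TetraSignature) -> float:
    """Pearson correlation of two Z-score vectors.

    Returns NaN (reported downstream as missing) when either vector is
    constant, e.g. for the all-zero signature of a homopolymer. Identical
    vectors return exactly 1.0.
    """
    return _pearson(np.asarray(a.z, dtype=float), np.asarray(b.z, dtype=float))


def frequency_correlation(a: TetraSignature, b: TetraSignature) -> float:
    """Pearson correlation of the observed tetranucleotide frequency vectors.

    Raw 4-mer frequencies keep the base-composition signal that the
    maximal-order Markov correction removes, so this measure stays
    informative even on sequences with no compositional structure beyond
    order 2 (where the Z-scores are pure sampling noise). NaN when either
    sequence contributed no countable 4-mers.
    """
    ta, tb = a.obs.sum(), b.obs.sum()
    if ta == 0 or tb == 0:
        return float("nan")
    return _pearson(a.obs / ta, b.obs / tb)
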
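"""k-tuple sequence signatures.

The signature of a sample is the vector of occurrence counts of all 4^k
nucleotide words of length k over the sample's reads. Because shotgun reads
carry no strand information, every read is counted together with its reverse
complement, which makes the count vector exactly invariant under the
reverse-complement permutation of word indices.

Words are indexed lexicographically with A<C<G<T and the leftmost base most
significant, i.e. index(w) = sum_j code(w_j) * 4^(k-1-j) with
code(A,C,G,T) = 0,1,2,3. Windows containing N (or any symbol mapped to N at
ingestion) are skipped entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np

from .errors import DegenerateSampleError, FormatError, ParameterError
from .sequence_io import ReadSet

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte -> 2-bit code; anything outside ACGT (incl. N) -> -1
_ENC_TABLE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _ENC_TABLE[ord(_b)] = _i

#: default cap on tuple size; 4^12 ~ 17M entries
MAX_K_DEFAULT = 12


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to int8 codes (A,C,G,T -> 0..3; else -1)."""
    return _ENC_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_word(index: int, k: int) -> str:
    """Inverse of the lexicographic word index."""
    chars = []
    for _ in range(k):
        chars.append(_BASES[index & 3])
        index >>= 2
    return "".join(reversed(chars))


def word_index(word: str) -> int:
    idx = 0
    for c in word:
        code = _BASES.find(c)
        if code < 0:
            raise ParameterError(f"word {word!r} contains non-ACGT symbol")
        idx = (idx << 2) | code
    return idx


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N is a fixed point; involution."""
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ParameterError(f"sequence contains non-ACGTN symbols: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=None)
def revcomp_permutation(k: int) -> np.ndarray:
    """Index permutation sending each word to its reverse complement."""
    idx = np.arange(4**k, dtype=np.int64)
    out = np.zeros_like(idx)
    for j in range(k):
        digit = (idx >> (2 * (k - 1 - j))) & 3  # j-th base from the left
        out |= (3 - digit) << (2 * j)
    out.setflags(write=False)
    return out


@dataclass
class KTupleSignature:
    """The 4^k-long count vector of one sample at tuple size k."""

    sample_id: str
    k: int
    counts: np.ndarray  # int64, length 4^k, lexicographic ACGT order
    n: int  # total count, sum of the vector
    complement_included: bool = True

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4**self.k,):
            raise FormatError(
                f"count vector length {self.counts.shape} inconsistent with k={self.k}"
            )

    def frequencies(self) -> np.ndarray:
        """Relative frequencies counts/n (sum to 1)."""
        if self.n <= 0:
            raise DegenerateSampleError(
                f"signature of {self.sample_id!r} has zero total count"
            )
        return self.counts / self.n


def count_ktuples(rs: ReadSet, k: int, max_k: int = MAX_K_DEFAULT) -> KTupleSignature:
    """Count every length-k window of every read and of its reverse complement.

    Windows containing N are skipped on both strands. Raises
    :class:`DegenerateSampleError` if no read yields a single valid window.
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if k > max_k:
        raise ParameterError(
            f"k={k} exceeds the cap of {max_k} (4^{k} = {4**k} vector entries); "
            "pass max_k explicitly to override"
        )
    # Concatenate reads with a -1 separator so windows never span reads.
    parts = []
    sep = np.array([-1], dtype=np.int8)
    for read in rs.reads:
        parts.append(encode(read))
        parts.append(sep)
    if not parts:
        raise DegenerateSampleError(f"read set {rs.sample_id!r} is empty")
    big = np.concatenate(parts)

    n_win = len(big) - k + 1
    if n_win <= 0:
        raise DegenerateSampleError(f"no read of length >= {k} in {rs.sample_id!r}")
    code = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    for j in range(k):
        seg = big[j : j + n_win]
        valid &= seg >= 0
        code = (code << 2) | np.where(seg >= 0, seg, 0)
    fwd = np.bincount(code[valid], minlength=4**k)
    # Counting the reverse-complement strand of every read is equivalent to
    # adding the forward counts under the reverse-complement permutation.
    counts = fwd + fwd[revcomp_permutation(k)]
    n = int(counts.sum())
    if n == 0:
        raise DegenerateSampleError(
            f"no valid {k}-tuple window in {rs.sample_id!r} (reads too short or all N)"
        )
    return KTupleSignature(sample_id=rs.sample_id, k=k, counts=counts, n=n)


def to_frequencies(sig: KTupleSignature) -> np.ndarray:
    """Relative k-tuple frequency vector (sums to 1)."""
    return sig.frequencies()


def write_signature(sig: KTupleSignature, path: str | Path) -> Path:
    """Write a signature as a headered TSV of nonzero words.

    Header records sample id, k, total count, strand convention and word
    order so dialect mismatches are detectable on read.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#sample={sig.sample_id}\n")
        fh.write(f"#k={sig.k}\n")
        fh.write(f"#n={sig.n}\n")
        comp = "both_strands" if sig.complement_included else "single_strand"
        fh.write(f"#complement={comp}\n")
        fh.write("#order=lexicographic_ACGT\n")
        nz = np.nonzero(sig.counts)[0]
        for idx in nz:
            fh.write(f"{decode_word(int(idx), sig.k)}\t{int(sig.counts[idx])}\n")
    return path


def read_signature(path: str | Path) -> KTupleSignature:
    """Read a signature file written by :func:`write_signature`."""
    path = Path(path)
    header: dict[str, str] = {}
    rows: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                header[key] = value
                continue
            try:
                word, count = line.split("\t")
                rows.append((word, int(count)))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad row {line!r}") from exc
    for req in ("sample", "k", "n"):
        if req not in header:
            raise FormatError(f"{path}: missing #{req}= header")
    k = int(header["k"])
    counts = np.zeros(4**k, dtype=np.int64)
    for word, count in rows:
        if len(word) != k:
            raise FormatError(
                f"{path}: word {word!r} has length {len(word)}, header says k={k}"
            )
        counts[word_index(word)] = count
    n = int(header["n"])
    if n != int(counts.sum()):
        raise FormatError(f"{path}: header n={n} != sum of counts {counts.sum()}")
    return KTupleSignature(
        sample_id=header["sample"],
        k=k,
        counts=counts,
        n=n,
        complement_included=header.get("complement", "both_strands") == "both_strands",
    )
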
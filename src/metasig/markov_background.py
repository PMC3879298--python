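"""Per-sample Markov background models.

Each sample's k-tuple expectations are computed under a Markov chain of order
r in {0,1,2,3} fitted to that sample's own reads (strand-augmented counts, so
expectations share the signature's reverse-complement symmetry). The chain
gives every k-word w = w1..wk the probability

    p_w = p(w1..wr) * prod_{i=1..k-r} p(w_{i+r} | w_i..w_{i+r-1})

with the initial distribution estimated from r-tuple frequencies and each
transition row from (r+1)-tuple counts divided by their r-tuple context
counts. The factorisation needs k >= r+1; smaller k is reported as NA.

The module also provides the CVTree-style expectation used by the Hao
measure, where the expected frequency of a k-word under the (k-2)-order
chain is written directly in terms of observed (k-1)- and (k-2)-tuple
frequencies of the same sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DegenerateSampleError, FormatError, NotApplicableError, ParameterError
from .kmer_signature import (
    KTupleSignature,
    count_ktuples,
    decode_word,
    word_index,
)
from .sequence_io import ReadSet

logger = logging.getLogger(__name__)

MAX_ORDER = 3


@dataclass
class MarkovModel:
    """Order-r background chain of one sample.

    ``initial`` is the probability vector over the 4^r r-tuples (for r=0 the
    single-entry vector [1.0]); ``transitions`` is the (4^r, 4) conditional
    table p(base | context); ``context_observed`` marks rows with at least
    one observed (r+1)-tuple (unobserved rows are all-zero and resolved by
    the floor rule downstream). ``n_bases`` is the strand-augmented single
    base total used for flooring.
    """

    sample_id: str
    order: int
    initial: np.ndarray
    transitions: np.ndarray
    context_observed: np.ndarray
    n_bases: int

    @property
    def floor(self) -> float:
        """Probability floor 1/(10*n) applied to zero p_w with observed counts."""
        return 1.0 / (10.0 * max(self.n_bases, 1))


def fit_markov(rs: ReadSet, r: int) -> MarkovModel:
    """Fit an order-r background model from strand-augmented tuple counts."""
    if not 0 <= r <= MAX_ORDER:
        raise ParameterError(f"Markov order must be in 0..{MAX_ORDER}, got {r}")
    sig1 = count_ktuples(rs, 1)  # also validates non-degeneracy
    try:
        sig_r1 = count_ktuples(rs, r + 1)
    except DegenerateSampleError as exc:
        raise DegenerateSampleError(
            f"no ({r + 1})-tuple observable in {rs.sample_id!r}; cannot fit order {r}"
        ) from exc
    if r == 0:
        base_freq = sig1.counts / sig1.n
        return MarkovModel(
            sample_id=rs.sample_id,
            order=0,
            initial=np.array([1.0]),
            transitions=base_freq[None, :],
            context_observed=np.array([True]),
            n_bases=sig1.n,
        )
    sig_r = count_ktuples(rs, r)
    initial = sig_r.counts / sig_r.n
    ext = sig_r1.counts.reshape(4**r, 4).astype(float)
    row_tot = ext.sum(axis=1)
    observed = row_tot > 0
    transitions = np.zeros_like(ext)
    transitions[observed] = ext[observed] / row_tot[observed, None]
    return MarkovModel(
        sample_id=rs.sample_id,
        order=r,
        initial=initial,
        transitions=transitions,
        context_observed=observed,
        n_bases=sig1.n,
    )


def word_probabilities(m: MarkovModel, k: int) -> np.ndarray:
    """Vector of p_w for all 4^k words under the chain, lexicographic order.

    Sums to 1 (within numerical tolerance) when every context is observed.
    Raises :class:`NotApplicableError` for k < r+1.
    """
    r = m.order
    if k < r + 1:
        raise NotApplicableError(
            f"order-{r} chain factorisation undefined for k={k} < {r + 1}"
        )
    vec = m.initial.astype(float).copy()
    mask = 4**r - 1 if r > 0 else 0
    for _ in range(k - r):
        ctx = np.arange(len(vec), dtype=np.int64) & mask  # last r bases
        vec = (vec[:, None] * m.transitions[ctx]).ravel()
    return vec


def word_probability(m: MarkovModel, word: str) -> float:
    """Probability of a single k-word under the chain."""
    k = len(word)
    r = m.order
    if k < r + 1:
        raise NotApplicableError(
            f"order-{r} chain factorisation undefined for k={k} < {r + 1}"
        )
    p = m.initial[word_index(word[:r])] if r > 0 else 1.0
    for i in range(k - r):
        ctx = word_index(word[i : i + r]) if r > 0 else 0
        p *= m.transitions[ctx, word_index(word[i + r])]
    return float(p)


def expected_counts(m: MarkovModel, k: int, n: int) -> np.ndarray:
    """Expected count vector n * p_w over all 4^k words."""
    if n <= 0:
        raise DegenerateSampleError(f"total tuple count must be positive, got {n}")
    return n * word_probabilities(m, k)


def floored_probabilities(
    p: np.ndarray, counts: np.ndarray, m: MarkovModel
) -> np.ndarray:
    """Apply the zero-probability floor where an observed word has p_w = 0.

    Words with positive observed count but zero model probability (an
    unobserved context on the other strand-collapsed path) get the floor
    1/(10*n); words with zero count keep p_w = 0 and contribute nothing
    downstream.
    """
    needs_floor = (counts > 0) & (p <= 0)
    if needs_floor.any():
        logger.warning(
            "%s: floored %d zero word probabilities at %.3g",
            m.sample_id,
            int(needs_floor.sum()),
            m.floor,
        )
        p = p.copy()
        p[needs_floor] = m.floor
    return p


def cvtree_expected_frequencies(
    sig_k: KTupleSignature,
    sig_km1: KTupleSignature,
    sig_km2: KTupleSignature,
) -> np.ndarray:
    """Expected frequency f0(w) of every k-word under the (k-2)-order chain.

    f0(w1..wk) = f(w1..w_{k-1}) * f(w2..wk) / f(w2..w_{k-1}), all frequencies
    observed in the same sample; 0 where the middle (k-2)-word frequency is 0.
    """
    k = sig_k.k
    if k < 3:
        raise NotApplicableError(f"(k-2)-order expectation undefined for k={k} < 3")
    if sig_km1.k != k - 1 or sig_km2.k != k - 2:
        raise ParameterError("signatures must have tuple sizes k, k-1, k-2")
    f_km1 = sig_km1.frequencies()
    f_km2 = sig_km2.frequencies()
    idx = np.arange(4**k, dtype=np.int64)
    prefix = idx >> 2  # w1..w_{k-1}
    suffix = idx & (4 ** (k - 1) - 1)  # w2..wk
    middle = suffix >> 2  # w2..w_{k-1}
    denom = f_km2[middle]
    num = f_km1[prefix] * f_km1[suffix]
    return np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)


def cvtree_expected_frequency(
    sig_k: KTupleSignature,
    sig_km1: KTupleSignature,
    sig_km2: KTupleSignature,
    word: str,
) -> float:
    """Scalar f0 for a single word (see :func:`cvtree_expected_frequencies`)."""
    k = sig_k.k
    if k < 3:
        raise NotApplicableError(f"(k-2)-order expectation undefined for k={k} < 3")
    if len(word) != k:
        raise ParameterError(f"word length {len(word)} != k={k}")
    f_km1 = sig_km1.frequencies()
    f_km2 = sig_km2.frequencies()
    mid = f_km2[word_index(word[1:-1])]
    if mid == 0:
        return 0.0
    return float(f_km1[word_index(word[:-1])] * f_km1[word_index(word[1:])] / mid)


def write_probabilities(
    m: MarkovModel, k: int, path: str | Path, nonzero_only: bool = True
) -> Path:
    """Write the word-probability vector as a reusable headered TSV."""
    p = word_probabilities(m, k)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#sample={m.sample_id}\n")
        fh.write(f"#k={k}\n")
        fh.write(f"#markov_order={m.order}\n")
        idx = np.nonzero(p)[0] if nonzero_only else np.arange(len(p))
        for i in idx:
            fh.write(f"{decode_word(int(i), k)}\t{p[i]:.17g}\n")
    return path


def read_probabilities(path: str | Path) -> tuple[str, int, int, np.ndarray]:
    """Read a probability file; returns (sample_id, k, order, probabilities)."""
    path = Path(path)
    header: dict[str, str] = {}
    rows: list[tuple[str, float]] = []
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
                word, prob = line.split("\t")
                rows.append((word, float(prob)))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad row {line!r}") from exc
    for req in ("sample", "k", "markov_order"):
        if req not in header:
            raise FormatError(f"{path}: missing #{req}= header")
    k = int(header["k"])
    p = np.zeros(4**k)
    for word, prob in rows:
        if len(word) != k:
            raise FormatError(
                f"{path}: word {word!r} has length {len(word)}, header says k={k}"
            )
        p[word_index(word)] = prob
    return header["sample"], k, int(header["markov_order"]), p
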
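"""Independent naive reference implementations used as oracles.

Everything here is deliberately written with plain-Python dictionaries,
explicit loops and textbook formulas, sharing no code path with the
package's vectorised implementations.
"""

from __future__ import annotations

import itertools
import math

BASES = "ACGT"
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(COMP[c] for c in reversed(seq))


def naive_count(reads: list[str], k: int) -> dict[str, int]:
    """Dictionary k-mer counter over each read and its reverse complement."""
    counts: dict[str, int] = {}
    for read in reads:
        for strand in (read, naive_revcomp(read)):
            for i in range(len(strand) - k + 1):
                w = strand[i : i + k]
                if "N" in w:
                    continue
                counts[w] = counts.get(w, 0) + 1
    return counts


def all_words(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product(BASES, repeat=k)]


def naive_count_vector(reads: list[str], k: int) -> list[int]:
    c = naive_count(reads, k)
    return [c.get(w, 0) for w in all_words(k)]


def naive_markov_probs(reads: list[str], r: int, k: int) -> dict[str, float]:
    """Word probabilities under an order-r chain fitted on both strands."""
    init_counts = naive_count(reads, r) if r > 0 else {}
    init_total = sum(init_counts.values())
    ext_counts = naive_count(reads, r + 1)
    probs: dict[str, float] = {}
    if r == 0:
        base_tot = sum(ext_counts.values())
        base_p = {b: ext_counts.get(b, 0) / base_tot for b in BASES}
        for w in all_words(k):
            p = 1.0
            for c in w:
                p *= base_p[c]
            probs[w] = p
        return probs
    ctx_totals: dict[str, int] = {}
    for w, c in ext_counts.items():
        ctx_totals[w[:r]] = ctx_totals.get(w[:r], 0) + c
    for w in all_words(k):
        p = init_counts.get(w[:r], 0) / init_total
        for i in range(k - r):
            ctx = w[i : i + r]
            tot = ctx_totals.get(ctx, 0)
            p *= ext_counts.get(ctx + w[i + r], 0) / tot if tot else 0.0
        probs[w] = p
    return probs


def _centered(reads: list[str], r: int, k: int) -> tuple[dict[str, float], dict[str, float], int]:
    counts = naive_count(reads, k)
    n = sum(counts.values())
    probs = naive_markov_probs(reads, r, k)
    floor = 1.0 / (10.0 * sum(naive_count(reads, 1).values()))
    expect = {}
    for w in all_words(k):
        p = probs[w]
        if counts.get(w, 0) > 0 and p <= 0:
            p = floor
        expect[w] = n * p
    cent = {w: counts.get(w, 0) - expect[w] for w in all_words(k)}
    return cent, expect, n


def naive_d2(readsX: list[str], readsY: list[str], k: int) -> float:
    cx = naive_count(readsX, k)
    cy = naive_count(readsY, k)
    dot = sum(cx.get(w, 0) * cy.get(w, 0) for w in all_words(k))
    nx = math.sqrt(sum(v * v for v in cx.values()))
    ny = math.sqrt(sum(v * v for v in cy.values()))
    return (1.0 - dot / (nx * ny)) / 2.0


def naive_d2s(readsX: list[str], readsY: list[str], k: int, r: int) -> float:
    cx, _, _ = _centered(readsX, r, k)
    cy, _, _ = _centered(readsY, r, k)
    D = A = B = 0.0
    for w in all_words(k):
        x, y = cx[w], cy[w]
        denom = math.sqrt(x * x + y * y)
        if denom == 0:
            continue
        D += x * y / denom
        A += x * x / denom
        B += y * y / denom
    return (1.0 - D / math.sqrt(A * B)) / 2.0


def naive_d2star(readsX: list[str], readsY: list[str], k: int, r: int) -> float:
    cx, ex, _ = _centered(readsX, r, k)
    cy, ey, _ = _centered(readsY, r, k)
    D = A = B = 0.0
    for w in all_words(k):
        x, y = cx[w], cy[w]
        if ex[w] > 0 and ey[w] > 0:
            D += x * y / math.sqrt(ex[w] * ey[w])
        if ex[w] > 0:
            A += x * x / ex[w]
        if ey[w] > 0:
            B += y * y / ey[w]
    return (1.0 - D / math.sqrt(A * B)) / 2.0


def naive_lp(readsX: list[str], readsY: list[str], k: int, variant: str) -> float:
    cx = naive_count(readsX, k)
    cy = naive_count(readsY, k)
    nx, ny = sum(cx.values()), sum(cy.values())
    diffs = [abs(cx.get(w, 0) / nx - cy.get(w, 0) / ny) for w in all_words(k)]
    if variant == "ma":
        return sum(diffs)
    if variant == "eu":
        return math.sqrt(sum(d * d for d in diffs))
    return max(diffs)


def naive_composition_vector(reads: list[str], k: int) -> dict[str, float]:
    fk = naive_count(reads, k)
    f1 = naive_count(reads, k - 1)
    f2 = naive_count(reads, k - 2)
    nk, n1, n2 = sum(fk.values()), sum(f1.values()), sum(f2.values())
    a = {}
    for w in all_words(k):
        mid = f2.get(w[1:-1], 0) / n2
        if mid == 0:
            a[w] = 0.0
            continue
        f0 = (f1.get(w[:-1], 0) / n1) * (f1.get(w[1:], 0) / n1) / mid
        f = fk.get(w, 0) / nk
        a[w] = (f - f0) / f0 if f0 != 0 else 0.0
    return a


def naive_hao(readsX: list[str], readsY: list[str], k: int) -> float:
    ax = naive_composition_vector(readsX, k)
    ay = naive_composition_vector(readsY, k)
    dot = sum(ax[w] * ay[w] for w in all_words(k))
    nx = math.sqrt(sum(v * v for v in ax.values()))
    ny = math.sqrt(sum(v * v for v in ay.values()))
    return (1.0 - dot / (nx * ny)) / 2.0


def naive_s2(readsX: list[str], readsY: list[str], k: int, r: int) -> float:
    """Cross form: each sample's frequencies against the partner's model."""
    total = 0.0
    for reads, partner in ((readsX, readsY), (readsY, readsX)):
        counts = naive_count(reads, k)
        n = sum(counts.values())
        probs = naive_markov_probs(partner, r, k)
        floor = 1.0 / (10.0 * sum(naive_count(partner, 1).values()))
        for w, c in counts.items():
            f = c / n
            p = probs[w]
            if p <= 0:
                p = floor
            total += f * math.log(f / p)
    return total
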
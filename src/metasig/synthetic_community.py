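"""Synthetic metatranscriptomic communities with planted structure.

Every stage of the comparison pipeline is testable without external data:
source pools emulate communities whose expressed gene pools differ both in
sequence composition (perturbed Markov transition tables) and in expression
abundance (Dirichlet expression weights); read sets are drawn from the pools
with configurable read-length distributions; mixture gradients emulate an
environmental gradient such as collection depth; and a homogeneous
indel/substitution injector emulates pyrosequencing-style errors.

All generators are deterministic end to end for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .community_analysis import Dendrogram, from_newick
from .errors import DegenerateSampleError, ParameterError
from .kmer_signature import encode
from .sequence_io import ReadSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: shortest read the generator will emit; generous for tuple sizes up to 12
MIN_READ_LEN = 20


@dataclass
class SourcePool:
    """A pool of expressed transcripts with abundance weights."""

    pool_id: str
    transcripts: list[str]
    expression_weights: np.ndarray
    generator_seed: int
    divergence: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.transcripts or any(len(t) == 0 for t in self.transcripts):
            raise ParameterError("transcripts must be nonempty")
        w = np.asarray(self.expression_weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-12:
            raise ParameterError("expression weights must sum to 1")
        self.expression_weights = w


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _sample_chain(
    rng: np.random.Generator,
    transitions: np.ndarray,
    order: int,
    n_seqs: int,
    length: int,
) -> list[str]:
    """Draw n_seqs sequences of the given length from an order-r chain."""
    if length < max(order, 1):
        raise ParameterError(f"sequence length {length} too short for order {order}")
    out = np.empty((n_seqs, length), dtype=np.int64)
    if order == 0:
        cum = np.cumsum(transitions[0])
        u = rng.random((n_seqs, length))
        out[:] = np.searchsorted(cum, u.ravel(), side="right").reshape(n_seqs, length)
        out = np.clip(out, 0, 3)
    else:
        state = rng.integers(0, 4, size=(n_seqs, order))
        out[:, :order] = state
        code = np.zeros(n_seqs, dtype=np.int64)
        for j in range(order):
            code = (code << 2) | state[:, j]
        mask = 4**order - 1
        cum = np.cumsum(transitions, axis=1)
        for pos in range(order, length):
            u = rng.random(n_seqs)
            base = (u[:, None] > cum[code]).sum(axis=1)
            base = np.clip(base, 0, 3)
            out[:, pos] = base
            code = ((code << 2) | base) & mask
    return [_decode(row) for row in out]


def _random_transition_table(rng: np.random.Generator, order: int) -> np.ndarray:
    """Dirichlet(1) rows over the 4 successor bases for every context."""
    return rng.dirichlet(np.ones(4), size=4 ** max(order, 0) if order > 0 else 1)


def iid_readset(
    n_reads: int,
    read_len: int,
    base_probs,
    seed: int,
    sample_id: str = "iid",
) -> ReadSet:
    """Read set of iid bases (an order-0 source with fixed composition)."""
    p = np.asarray(base_probs, dtype=float)
    if p.shape != (4,) or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ParameterError("base_probs must be a length-4 probability vector")
    rng = np.random.default_rng(seed)
    codes = rng.choice(4, size=(n_reads, read_len), p=p / p.sum())
    reads = [_decode(row) for row in codes]
    return ReadSet(
        sample_id=sample_id,
        reads=reads,
        provenance={"source": "iid", "base_probs": p.tolist(), "seed": seed},
    )


def make_source_pools(
    G: int,
    n_genes: int = 40,
    gene_len: int = 900,
    order: int = 1,
    divergence: float = 0.3,
    seed: int = 0,
    expression_alpha: float = 1.0,
) -> list[SourcePool]:
    """Generate G divergent source pools sharing a perturbed base chain.

    A base transition table is drawn once; each pool mixes it with an
    independent random table at weight ``divergence`` and regenerates its own
    transcripts and Dirichlet expression weights from the perturbed chain.
    """
    if G < 2:
        raise ParameterError(f"need at least 2 pools, got G={G}")
    if not 0 < divergence <= 0.5:
        raise ParameterError(f"divergence must be in (0, 0.5], got {divergence}")
    rng = np.random.default_rng(seed)
    base = _random_transition_table(rng, order)
    pools = []
    for g in range(G):
        perturb = _random_transition_table(rng, order)
        table = (1.0 - divergence) * base + divergence * perturb
        transcripts = _sample_chain(rng, table, order, n_genes, gene_len)
        weights = rng.dirichlet(np.full(n_genes, expression_alpha))
        pools.append(
            SourcePool(
                pool_id=f"pool{g + 1}",
                transcripts=transcripts,
                expression_weights=weights,
                generator_seed=seed,
                divergence=divergence,
                meta={"order": order, "gene_len": gene_len},
            )
        )
    return pools


def sample_reads(
    pool: SourcePool,
    n_reads: int,
    len_mean: float,
    len_sd: float,
    seed: int,
    sample_id: str | None = None,
) -> ReadSet:
    """Draw reads from a pool: transcript by expression weight, uniform start,
    length ~ Normal(len_mean, len_sd) truncated to [MIN_READ_LEN, transcript
    length] (len_sd = 0 gives fixed-length reads)."""
    if n_reads < 1:
        raise ParameterError(f"n_reads must be >= 1, got {n_reads}")
    rng = np.random.default_rng(seed)
    usable = [i for i, t in enumerate(pool.transcripts) if len(t) >= MIN_READ_LEN]
    if not usable:
        raise DegenerateSampleError(
            f"all transcripts of {pool.pool_id!r} shorter than {MIN_READ_LEN}"
        )
    w = pool.expression_weights[usable]
    w = w / w.sum()
    t_idx = rng.choice(len(usable), size=n_reads, p=w)
    if len_sd > 0:
        lens = np.rint(rng.normal(len_mean, len_sd, size=n_reads)).astype(int)
    else:
        lens = np.full(n_reads, int(round(len_mean)))
    reads = []
    for ti, ln in zip(t_idx, lens):
        tr = pool.transcripts[usable[ti]]
        ln = int(np.clip(ln, MIN_READ_LEN, len(tr)))
        start = int(rng.integers(0, len(tr) - ln + 1))
        reads.append(tr[start : start + ln])
    return ReadSet(
        sample_id=sample_id or f"{pool.pool_id}_s",
        reads=reads,
        provenance={"pool": pool.pool_id, "seed": seed, "n_reads": n_reads},
    )


def make_gradient_panel(
    poolA: SourcePool,
    poolB: SourcePool,
    levels: list[float],
    reps: int,
    n_reads: int,
    seed: int,
    len_mean: float = 150.0,
    len_sd: float = 0.0,
) -> tuple[list[ReadSet], np.ndarray]:
    """Mixture-gradient panel: at level t each read comes from poolB with
    probability t, else from poolA. Returns reps samples per level plus the
    per-sample covariate vector (the mixing level)."""
    if len(levels) < 3:
        raise ParameterError("need at least 3 gradient levels")
    if any(not 0 <= t <= 1 for t in levels):
        raise ParameterError(f"levels must lie in [0, 1]: {levels}")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(levels) * reps)
    samples: list[ReadSet] = []
    covariate: list[float] = []
    ci = 0
    for li, t in enumerate(levels):
        for rep in range(reps):
            rng = np.random.default_rng(children[ci])
            from_b = rng.random(n_reads) < t
            n_b = int(from_b.sum())
            reads: list[str] = []
            sub_seeds = rng.integers(0, 2**31 - 1, size=2)
            if n_reads - n_b > 0:
                reads += sample_reads(
                    poolA, n_reads - n_b, len_mean, len_sd, int(sub_seeds[0])
                ).reads
            if n_b > 0:
                reads += sample_reads(
                    poolB, n_b, len_mean, len_sd, int(sub_seeds[1])
                ).reads
            samples.append(
                ReadSet(
                    sample_id=f"L{li + 1}_rep{rep + 1}",
                    reads=reads,
                    provenance={"level": t, "rep": rep + 1, "seed": seed},
                )
            )
            covariate.append(t)
            ci += 1
    return samples, np.asarray(covariate)


def inject_errors(
    rs: ReadSet, indel_rate: float, sub_rate: float, seed: int
) -> ReadSet:
    """Inject homogeneous per-base sequencing errors.

    Per base independently: with probability ``sub_rate`` replace by a
    uniformly chosen different base; with probability ``indel_rate/2`` insert
    a uniform base after it; with probability ``indel_rate/2`` delete it.
    Insertions and deletions balance, so expected read length is preserved.
    """
    for name, rate in (("indel_rate", indel_rate), ("sub_rate", sub_rate)):
        if not 0 <= rate <= 0.1:
            raise ParameterError(f"{name} must be in [0, 0.1], got {rate}")
    rng = np.random.default_rng(seed)
    enc_parts = [encode(r) for r in rs.reads]
    read_id = np.repeat(np.arange(len(rs.reads)), [len(r) for r in rs.reads])
    arr = np.concatenate(enc_parts).astype(np.int8)
    L = len(arr)

    # substitutions (never applied to N positions)
    sub_mask = (rng.random(L) < sub_rate) & (arr >= 0)
    if sub_mask.any():
        shift = rng.integers(1, 4, size=int(sub_mask.sum()))
        arr = arr.copy()
        arr[sub_mask] = (arr[sub_mask] + shift) % 4

    u = rng.random(L)
    del_mask = u < indel_rate / 2.0
    ins_mask = (u >= indel_rate / 2.0) & (u < indel_rate)
    repeats = np.ones(L, dtype=np.int64)
    repeats[del_mask] = 0
    repeats[ins_mask] = 2
    out = np.repeat(arr, repeats)
    out_ids = np.repeat(read_id, repeats)
    if ins_mask.any():
        # the inserted copy sits at the end of each repeated run
        ends = np.cumsum(repeats) - 1
        ins_pos = ends[ins_mask]
        out[ins_pos] = rng.integers(0, 4, size=len(ins_pos)).astype(np.int8)

    reads: list[str] = []
    dropped = 0
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    boundaries = np.searchsorted(out_ids, np.arange(len(rs.reads) + 1))
    for i in range(len(rs.reads)):
        seg = out[boundaries[i] : boundaries[i + 1]]
        if len(seg) == 0:
            dropped += 1
            continue
        chars = np.where(seg >= 0, alphabet[np.clip(seg, 0, 3)], ord("N")).astype(
            np.uint8
        )
        reads.append(chars.tobytes().decode("ascii"))
    if not reads:
        raise DegenerateSampleError("all reads deleted by error injection")
    prov = dict(rs.provenance)
    prov.update(
        {
            "indel_rate": indel_rate,
            "sub_rate": sub_rate,
            "error_seed": seed,
            "reads_dropped": dropped,
        }
    )
    return ReadSet(sample_id=rs.sample_id, reads=reads, provenance=prov)


def make_group_panel(
    G: int = 4,
    samples_per_group: int = 5,
    n_reads: int = 2000,
    len_mean: float = 150.0,
    len_sd: float = 0.0,
    n_genes: int = 40,
    gene_len: int = 900,
    order: int = 1,
    divergence: float = 0.3,
    seed: int = 0,
) -> tuple[list[ReadSet], Dendrogram]:
    """Panel of replicate samples from G planted pools plus the planted tree.

    The reference tree is a star of groups, each group a polytomy of its
    samples (G nontrivial clusters; no branch lengths). Defaults are the
    panel layout the robustness protocols use: 4 pools x 5 samples x
    2000 reads x 150 bp at divergence 0.3.
    """
    if G * samples_per_group < 4:
        raise ParameterError("need at least 4 samples in total")
    ss = np.random.SeedSequence(seed)
    pool_seed, *sample_seeds = ss.spawn(1 + G * samples_per_group)
    pools = make_source_pools(
        G,
        n_genes=n_genes,
        gene_len=gene_len,
        order=order,
        divergence=divergence,
        seed=pool_seed,
    )
    samples: list[ReadSet] = []
    group_clauses: list[str] = []
    si = 0
    for g, pool in enumerate(pools):
        names = []
        for rep in range(samples_per_group):
            name = f"g{g + 1}_s{rep + 1}"
            rs = sample_reads(
                pool, n_reads, len_mean, len_sd, sample_seeds[si], sample_id=name
            )
            rs.provenance["group"] = g + 1
            samples.append(rs)
            names.append(name)
            si += 1
        group_clauses.append("(" + ",".join(names) + ")")
    planted = from_newick("(" + ",".join(group_clauses) + ");")
    return samples, planted
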
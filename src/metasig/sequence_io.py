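"""Reading, writing and subsampling of read sets (FASTA/FASTQ).

A :class:`ReadSet` is the basic unit of comparison: all reads sequenced from
one community sample. Sequences are canonicalised to uppercase {A,C,G,T,N};
any other IUPAC/ambiguity symbol is mapped to N at ingestion so every
downstream stage sees a single alphabet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DegenerateSampleError, EmptyInputError, FormatError, ParameterError

logger = logging.getLogger(__name__)

_FASTA_SUFFIXES = {".fa", ".fasta", ".fna"}
_FASTQ_SUFFIXES = {".fq", ".fastq"}

# uppercase, then map anything outside ACGTN to N
_CANONICAL = {c: c for c in "ACGTN"}
_CLEAN_TABLE = str.maketrans(
    {chr(i): _CANONICAL.get(chr(i).upper(), "N") for i in range(256)}
)


@dataclass
class ReadSet:
    """A named, ordered collection of nucleotide reads from one sample."""

    sample_id: str
    reads: list[str]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reads)

    @property
    def total_bases(self) -> int:
        return sum(len(r) for r in self.reads)


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in _FASTA_SUFFIXES:
        return "fasta"
    if suffix in _FASTQ_SUFFIXES:
        return "fastq"
    raise FormatError(
        f"cannot infer sequence format from suffix {suffix!r} of {path}"
    )


def clean_sequence(seq: str) -> tuple[str, int]:
    """Uppercase *seq* and map non-ACGTN symbols to N.

    Returns the cleaned sequence and the number of substituted characters.
    """
    up = seq.upper()
    cleaned = up.translate(_CLEAN_TABLE)
    n_mapped = sum(1 for a, b in zip(up, cleaned) if a != b)
    return cleaned, n_mapped


def read_sequences(path: str | Path, format: str = "auto") -> ReadSet:
    """Load a FASTA/FASTQ file into a :class:`ReadSet`.

    ``format="auto"`` infers the format from the file suffix
    (.fa/.fasta/.fna -> FASTA; .fq/.fastq -> FASTQ). Records are kept in file
    order; sequences are uppercased and non-ACGTN symbols mapped to N with a
    logged warning count.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = _infer_format(path) if format == "auto" else format
    if fmt not in ("fasta", "fastq"):
        raise ParameterError(f"unsupported format {fmt!r}")

    reads: list[str] = []
    mapped = 0
    try:
        for rec in SeqIO.parse(str(path), fmt):
            seq, n_mapped = clean_sequence(str(rec.seq))
            if not seq:
                raise FormatError(f"empty sequence for record {rec.id!r} in {path}")
            mapped += n_mapped
            reads.append(seq)
    except ValueError as exc:  # Biopython parse failure
        raise FormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if not reads:
        raise EmptyInputError(f"no sequence records in {path}")
    if mapped:
        logger.warning(
            "%s: mapped %d non-ACGTN characters to N", path.name, mapped
        )
    return ReadSet(
        sample_id=path.stem.split(".")[0],
        reads=reads,
        provenance={"source": str(path), "format": fmt, "n_mapped_to_N": mapped},
    )


def write_sequences(rs: ReadSet, path: str | Path, format: str = "auto") -> Path:
    """Write *rs* to FASTA or FASTQ (Sanger offset-33, placeholder quality I).

    Round-trips: reading the written file reproduces reads and order.
    """
    if not rs.reads:
        raise EmptyInputError(f"refusing to write empty read set {rs.sample_id!r}")
    path = Path(path)
    fmt = _infer_format(path) if format == "auto" else format
    records = []
    for i, seq in enumerate(rs.reads):
        rec = SeqRecord(Seq(seq), id=f"{rs.sample_id}_r{i + 1}", description="")
        if fmt == "fastq":
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    try:
        SeqIO.write(records, str(path), fmt)
    except OSError as exc:
        raise FormatError(f"cannot write {path}: {exc}") from exc
    return path


def subsample_reads(rs: ReadSet, rate: float, seed: int) -> ReadSet:
    """Draw ``round(rate * N)`` reads uniformly without replacement.

    Emulates a reduction in sequencing depth. Deterministic for a fixed seed;
    original read order is preserved in the output.
    """
    if not 0 < rate <= 1:
        raise ParameterError(f"sampling rate must be in (0, 1], got {rate}")
    if not rs.reads:
        raise EmptyInputError(f"read set {rs.sample_id!r} is empty")
    n = int(round(rate * len(rs.reads)))
    if n == 0:
        raise DegenerateSampleError(
            f"rate {rate} of {len(rs.reads)} reads rounds to 0; raise the rate"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(rs.reads), size=n, replace=False))
    prov = dict(rs.provenance)
    prov.update({"subsample_rate": rate, "subsample_seed": seed})
    return ReadSet(sample_id=rs.sample_id, reads=[rs.reads[i] for i in idx], provenance=prov)
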
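"""Reading ligand libraries, core extraction, deduplication and shuffling.

A ligand is a fixed-architecture synthetic DNA molecule: a randomized core
flanked by constant adaptors (default 30-bp core inside a 76-bp ligand).
All enrichment statistics downstream operate on the extracted cores.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO

from ._alphabet import encode_matrix

# Placeholder adaptor flanks of the documented lengths (23 + 23 = 46 bp,
# so the default full ligand is 76 bp). Real experiments supply their own.
DEFAULT_FLANK5 = "ACACTCTTTCCCTACACGACGCT"
DEFAULT_FLANK3 = "AGATCGGAAGAGCACACGTCTGA"


@dataclass(frozen=True)
class AdaptorSpec:
    """Fixed-flank architecture of a ligand."""

    flank5: str = DEFAULT_FLANK5
    flank3: str = DEFAULT_FLANK3
    core_length: int = 30

    def __post_init__(self) -> None:
        for name in ("flank5", "flank3"):
            flank = getattr(self, name)
            if set(flank) - set("ACGT"):
                raise ValueError(f"{name} must contain only ACGT, got {flank!r}")
        if self.core_length < 1:
            raise ValueError("core_length must be >= 1")

    @property
    def total_length(self) -> int:
        return len(self.flank5) + self.core_length + len(self.flank3)


@dataclass
class LigandRead:
    id: str
    sequence: str
    quality: str | None = None


@dataclass
class LigandLibrary:
    """An ordered collection of ligand reads from one sample/round.

    Round 0 denotes the unselected input library.
    """

    reads: list[LigandRead] = field(default_factory=list)
    sample_name: str = ""
    round: int = 0
    is_control: bool = False

    def __len__(self) -> int:
        return len(self.reads)

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.reads]

    def read_length(self) -> int:
        """Uniform read length; raises if the library is ragged or empty."""
        lengths = {len(r.sequence) for r in self.reads}
        if len(lengths) != 1:
            raise ValueError(f"library is not uniform-length: lengths {sorted(lengths)}")
        return lengths.pop()

    def to_matrix(self) -> np.ndarray:
        """Encoded (n, L) int8 matrix of all reads."""
        return encode_matrix(self.sequences())


def _open_maybe_gzip(path, mode="rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_sequences(path, format: str = "fasta", sample_name: str = "", round: int = 0) -> LigandLibrary:
    """Read a FASTA/FASTQ(.gz) file into a LigandLibrary, order preserved."""
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}; use 'fasta' or 'fastq'")
    reads: list[LigandRead] = []
    with _open_maybe_gzip(path) as handle:
        try:
            for rec in SeqIO.parse(handle, format):
                qual = None
                if format == "fastq":
                    qual = "".join(
                        chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                    )
                reads.append(LigandRead(rec.id, str(rec.seq).upper(), qual))
        except ValueError as exc:
            raise ValueError(
                f"malformed {format} record near record {len(reads) + 1} in {path}: {exc}"
            ) from exc
    if not reads:
        warnings.warn(f"no records parsed from {path}; returning empty library")
    return LigandLibrary(reads=reads, sample_name=sample_name, round=round)


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def extract_cores(
    lib: LigandLibrary, spec: AdaptorSpec | None = None, max_flank_mismatch: int = 0
) -> tuple[LigandLibrary, dict]:
    """Extract the randomized core from every read.

    Reads already exactly ``core_length`` long are accepted as pre-trimmed.
    Longer reads must match both flanks at their fixed positions with at
    most ``max_flank_mismatch`` mismatches in total. Cores containing N and
    reads of unusable length are dropped and counted.

    Returns the core library plus a dict of drop counts.
    """
    spec = spec or AdaptorSpec()
    n5, nc = len(spec.flank5), spec.core_length
    kept: list[LigandRead] = []
    stats = {"n_input": len(lib), "flank_mismatch": 0, "with_n": 0, "bad_length": 0}
    for read in lib.reads:
        seq = read.sequence
        if len(seq) == nc:
            core = seq
        elif len(seq) >= spec.total_length:
            mm = _mismatches(seq[:n5], spec.flank5)
            mm += _mismatches(seq[n5 + nc : n5 + nc + len(spec.flank3)], spec.flank3)
            if mm > max_flank_mismatch:
                stats["flank_mismatch"] += 1
                continue
            core = seq[n5 : n5 + nc]
        else:
            stats["bad_length"] += 1
            continue
        if "N" in core:
            stats["with_n"] += 1
            continue
        kept.append(LigandRead(read.id, core))
    stats["n_output"] = len(kept)
    if lib.reads and not kept:
        warnings.warn(
            "no read matched the adaptor spec; returning empty library "
            f"(drop counts: {stats})"
        )
    return (
        LigandLibrary(kept, sample_name=lib.sample_name, round=lib.round, is_control=lib.is_control),
        stats,
    )


def dedup_exact(lib: LigandLibrary) -> tuple[LigandLibrary, int]:
    """Keep the first occurrence of each exact sequence; order preserved."""
    seen: set[str] = set()
    kept = []
    for read in lib.reads:
        if read.sequence not in seen:
            seen.add(read.sequence)
            kept.append(read)
    out = replace(lib, reads=kept)
    return out, len(lib) - len(kept)


def shuffle_control(lib: LigandLibrary, rng_seed: int, mode: str = "mononucleotide") -> LigandLibrary:
    """Per-read mononucleotide shuffle: an exact-composition control library.

    Each read is independently permuted, so per-read base counts are
    preserved exactly. One numpy Generator is created from ``rng_seed`` and
    consumed row by row in read order.
    """
    if mode != "mononucleotide":
        raise ValueError(f"unsupported shuffle mode {mode!r}")
    if not lib.reads:
        return replace(lib, reads=[], is_control=True)
    lib.read_length()  # uniformity check
    rng = np.random.default_rng(rng_seed)
    mat = lib.to_matrix()
    perm = rng.random(mat.shape).argsort(axis=1)
    shuffled = np.take_along_axis(mat, perm, axis=1)
    base_arr = np.frombuffer("ACGTN".encode(), dtype=np.uint8)
    out_bytes = base_arr[np.where(shuffled >= 0, shuffled, 4)].tobytes().decode()
    L = mat.shape[1]
    reads = [
        LigandRead(f"{read.id}_shuf", out_bytes[i * L : (i + 1) * L])
        for i, read in enumerate(lib.reads)
    ]
    return LigandLibrary(
        reads, sample_name=f"{lib.sample_name}_shuffled", round=lib.round, is_control=True
    )


def write_fasta(lib: LigandLibrary, path) -> None:
    with _open_maybe_gzip(path, "wt") as fh:
        for read in lib.reads:
            fh.write(f">{read.id}\n{read.sequence}\n")


def write_fastq(lib: LigandLibrary, path) -> None:
    with _open_maybe_gzip(path, "wt") as fh:
        for read in lib.reads:
            qual = read.quality or "I" * len(read.sequence)
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")
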
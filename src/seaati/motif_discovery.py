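"""Seed discovery by locally maximal enriched k-mers and multinomial PFMs.

A seed is a k-mer (k = 8-10 by default) whose pooled forward+revcomp count
strictly exceeds every count in its neighborhood — all Hamming-1
substitutions plus single-base left/right shifts — and reaches the
local-max count cutoff (default 40). From each seed a position frequency
matrix is built by multinomial-1 counting: column j is tallied from read
windows that match the seed at every position except j. Seeds at Hamming
distance >= 2 therefore yield separate models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._alphabet import (
    BASES,
    code_to_kmer,
    encode,
    kmer_to_code,
    revcomp,
    revcomp_code_table,
    revcomp_matrix,
    window_codes,
)

_LOG2_4 = 2.0


@dataclass(frozen=True)
class SeedCandidate:
    kmer: str  # canonical (lexicographically smaller of kmer/revcomp)
    count: int  # pooled forward + revcomp occurrences
    is_local_max: bool = True


@dataclass(frozen=True)
class DiscoveryConfig:
    multinomial: int = 1
    seed_lengths: tuple[int, ...] = (8, 9, 10)
    local_max_cutoff: int = 40
    flank_extension: int = 2
    ppm_pseudocount: float = 1.0
    flank_ic_trim: float = 0.1  # trim terminal extension columns below this IC

    def __post_init__(self):
        if self.multinomial not in (0, 1, 2):
            raise ValueError("multinomial must be 0, 1 or 2")
        if self.local_max_cutoff < 1:
            raise ValueError("local_max_cutoff must be >= 1")


def information_content(column) -> float:
    """IC of one probability column: sum p * log2(p / 0.25), in [0, 2] bits."""
    col = np.asarray(column, dtype=float)
    if (col < 0).any():
        raise ValueError("negative probability in column")
    if not np.isclose(col.sum(), 1.0, atol=1e-6):
        raise ValueError(f"column sums to {col.sum()}, not 1")
    nz = col > 0
    return float((col[nz] * (np.log2(col[nz]) + _LOG2_4)).sum())


def motif_summary(pfm: np.ndarray, ppm: np.ndarray):
    """Consensus plus column/total/per-base IC of a probability matrix.

    Consensus ties resolve to the first base in A,C,G,T order.
    """
    ppm = np.asarray(ppm, dtype=float)
    consensus = "".join(BASES[j] for j in ppm.argmax(axis=0))
    ic_cols = np.array([information_content(ppm[:, j]) for j in range(ppm.shape[1])])
    total = float(ic_cols.sum())
    return consensus, ic_cols, total, total / ppm.shape[1]


@dataclass
class MotifModel:
    """A discovered (or reference) motif: counts, probabilities and IC."""

    id: str
    pfm: np.ndarray  # (4, L) counts, rows A,C,G,T
    ppm: np.ndarray  # (4, L) probabilities (pseudocounted)
    name: str = ""
    seed: SeedCandidate | None = None
    consensus: str = ""
    ic_per_column: np.ndarray = field(default_factory=lambda: np.empty(0))
    total_ic: float = 0.0
    per_base_ic: float = 0.0
    provenance: str = ""

    def __post_init__(self):
        if not self.consensus:
            self.consensus, self.ic_per_column, self.total_ic, self.per_base_ic = motif_summary(
                self.pfm, self.ppm
            )
        if not self.name:
            self.name = self.id

    @property
    def length(self) -> int:
        return self.ppm.shape[1]

    @classmethod
    def from_counts(cls, id: str, pfm, pseudocount: float = 1.0, **kw) -> "MotifModel":
        pfm = np.asarray(pfm, dtype=float)
        if pfm.shape[0] != 4:
            raise ValueError("PFM must have 4 rows (A, C, G, T)")
        ppm = (pfm + pseudocount) / (pfm + pseudocount).sum(axis=0, keepdims=True)
        return cls(id=id, pfm=pfm, ppm=ppm, **kw)

    def consensus_ic(self) -> float:
        """Mean per-column IC contribution of the consensus base.

        High values flag homonucleotide-run-like, near-deterministic
        consensi; used by the curation filters.
        """
        p = self.ppm.max(axis=0)
        return float(np.mean(p * (np.log2(p) + _LOG2_4)))

    def revcomp(self) -> "MotifModel":
        return MotifModel.from_counts(
            self.id, self.pfm[::-1, ::-1], name=self.name, provenance=self.provenance
        )


def canonical_kmer_counts(lib, k: int) -> np.ndarray:
    """Dense count array over canonical k-mer codes (k-mer pooled with revcomp).

    The canonical representative is the numerically (= lexicographically)
    smaller of code and revcomp code; the array has 4**k slots with counts
    stored only at canonical slots.
    """
    from .kmer_stats import _matrix_of

    mat = _matrix_of(lib)
    rc = revcomp_code_table(k)
    counts = np.zeros(4**k, dtype=np.int64)
    if mat.size == 0:
        return counts
    codes = window_codes(mat, k).ravel()
    codes = codes[codes >= 0]
    codes = np.minimum(codes, rc[codes])
    np.add.at(counts, codes, 1)
    return counts


def _neighbor_codes(code: int, k: int) -> list[int]:
    """Hamming-1 substitutions plus one-base left/right shifts."""
    out = []
    for j in range(k):
        place = 4 ** (k - 1 - j)
        cur = (code // place) % 4
        for b in range(4):
            if b != cur:
                out.append(code + (b - cur) * place)
    head = code // 4  # drop rightmost
    tail = code % (4 ** (k - 1))  # drop leftmost
    for b in range(4):
        out.append(tail * 4 + b)  # left shift, append right
        out.append(b * (4 ** (k - 1)) + head)  # right shift, prepend left
    return out


def find_local_max_seeds(lib, config: DiscoveryConfig | None = None) -> list[SeedCandidate]:
    """Enriched local-max k-mers over both strands, sorted by count.

    A k-mer is a seed iff its canonical count reaches the cutoff and
    strictly exceeds the canonical count of every neighborhood k-mer
    (neighbors that canonicalize onto the k-mer itself are ignored).
    """
    config = config or DiscoveryConfig()
    seeds: list[SeedCandidate] = []
    for k in config.seed_lengths:
        counts = canonical_kmer_counts(lib, k)
        rc = revcomp_code_table(k)
        candidates = np.nonzero(counts >= config.local_max_cutoff)[0]
        for code in candidates:
            code = int(code)
            c = counts[code]
            is_max = True
            for nb in _neighbor_codes(code, k):
                nb_canon = min(nb, int(rc[nb]))
                if nb_canon == code:
                    continue
                if counts[nb_canon] >= c:
                    is_max = False
                    break
            if is_max:
                seeds.append(SeedCandidate(code_to_kmer(code, k), int(c)))
    return sorted(seeds, key=lambda s: (-s.count, s.kmer))


def build_pfm_multinomial(lib, seed, config: DiscoveryConfig | None = None) -> MotifModel:
    """Build a PFM around a seed by multinomial counting over both strands.

    multinomial-1 (default): column j of the seed region is tallied from
    windows matching the seed at every position except j — exact-match
    windows contribute to all columns, single-mismatch windows only to
    their mismatched column. multinomial-0 uses exact matches only. Flank
    extension columns are tallied from exact-match windows and trimmed
    back while terminal IC stays below ``flank_ic_trim``.
    """
    config = config or DiscoveryConfig()
    seed_str = seed.kmer if isinstance(seed, SeedCandidate) else str(seed)
    k = len(seed_str)
    seed_codes = encode(seed_str)
    ext = config.flank_extension
    from .kmer_stats import _matrix_of

    mat = _matrix_of(lib)
    if mat.size == 0:
        raise ValueError(f"no reads to match seed {seed_str}")
    L = mat.shape[1]
    if k > L:
        raise ValueError(f"seed {seed_str} longer than reads")
    width = k + 2 * ext
    pfm = np.zeros((4, width), dtype=np.int64)
    n_windows = 0

    if config.multinomial > 1:
        raise NotImplementedError("only multinomial 0 and 1 counting is implemented")
    for strand_mat in (mat, revcomp_matrix(mat)):
        for off in range(L - k + 1):
            win = strand_mat[:, off : off + k]
            diff = win != seed_codes
            mm = diff.sum(axis=1)
            exact = np.nonzero(mm == 0)[0]
            if exact.size:
                n_windows += exact.size
                # exact matches feed every seed column with the seed base
                for j in range(k):
                    pfm[seed_codes[j], ext + j] += exact.size
                for j in range(-ext, 0):
                    pos = off + j
                    if 0 <= pos:
                        col = strand_mat[exact, pos]
                        valid = col[col >= 0]
                        np.add.at(pfm[:, ext + j], valid, 1)
                for j in range(k, k + ext):
                    pos = off + j
                    if pos < L:
                        col = strand_mat[exact, pos]
                        valid = col[col >= 0]
                        np.add.at(pfm[:, ext + j], valid, 1)
            if config.multinomial >= 1:
                one = np.nonzero(mm == 1)[0]
                if one.size:
                    n_windows += one.size
                    jstar = diff[one].argmax(axis=1)
                    bases = win[one, jstar]
                    ok = bases >= 0
                    np.add.at(pfm, (bases[ok], ext + jstar[ok]), 1)

    if n_windows == 0:
        raise ValueError(f"no read window matches seed {seed_str}")

    # trim low-information extension columns from the ends
    lo, hi = 0, width
    with np.errstate(divide="ignore", invalid="ignore"):
        colsum = pfm.sum(axis=0)
        probs = np.divide(pfm + config.ppm_pseudocount, colsum + 4 * config.ppm_pseudocount)
        ic = np.array([information_content(probs[:, j]) for j in range(width)])
    while lo < ext and ic[lo] < config.flank_ic_trim:
        lo += 1
    while hi > width - ext and ic[hi - 1] < config.flank_ic_trim:
        hi -= 1
    pfm = pfm[:, lo:hi]

    seed_obj = seed if isinstance(seed, SeedCandidate) else SeedCandidate(seed_str, 0, False)
    return MotifModel.from_counts(
        id=seed_str, pfm=pfm, pseudocount=config.ppm_pseudocount, seed=seed_obj
    )


def discover_motifs(
    lib, config: DiscoveryConfig | None = None, max_seeds: int | None = None
) -> list[MotifModel]:
    """Full discovery: local-max seeds, then a multinomial PFM per seed."""
    config = config or DiscoveryConfig()
    seeds = find_local_max_seeds(lib, config)
    if max_seeds is not None:
        seeds = seeds[:max_seeds]
    models = []
    for i, seed in enumerate(seeds):
        model = build_pfm_multinomial(lib, seed, config)
        model.id = f"{seed.kmer}_{i}"
        model.name = seed.kmer
        models.append(model)
    return models
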
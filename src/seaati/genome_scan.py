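"""PWM scanning with exact p-value thresholds and genomic context statistics.

Log-odds matrices are integer-scaled (default 1000 units per bit, floor
rounding) so the null score distribution under the background model can be
computed exactly by dynamic-programming convolution, column by column. The
match threshold at p-value alpha is the smallest score t with
P(score >= t) <= alpha under the background. Coordinates are 0-based
half-open throughout (BED convention); GFF3 input is converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._alphabet import encode


@dataclass
class PWMModel:
    log_odds: np.ndarray  # (4, L) bits
    background: np.ndarray  # (4,)
    int_matrix: np.ndarray  # (4, L) integer-scaled log-odds
    score_scale: int
    motif_id: str = ""

    @property
    def length(self) -> int:
        return self.log_odds.shape[1]


def pwm_from_ppm(ppm, background=None, score_scale: int = 1000, motif_id: str = "") -> PWMModel:
    ppm = np.asarray(ppm, dtype=float)
    background = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if (background <= 0).any():
        raise ValueError("background probabilities must all be positive")
    if (ppm <= 0).any():
        raise ValueError("ppm must be strictly positive (apply a pseudocount first)")
    log_odds = np.log2(ppm / background[:, None])
    int_matrix = np.floor(log_odds * score_scale).astype(np.int64)
    return PWMModel(log_odds, background, int_matrix, score_scale, motif_id)


def exact_score_distribution(pwm: PWMModel) -> tuple[np.ndarray, int]:
    """Exact integer-score pmf under the background model.

    Returns (pmf, min_score): pmf[i] = P(score == min_score + i) for a
    random background sequence of the motif's length.
    """
    im = pwm.int_matrix
    mins = im.min(axis=0)
    maxs = im.max(axis=0)
    size = int((maxs - mins).sum()) + 1
    dist = np.zeros(size)
    dist[0] = 1.0
    width = 1
    for j in range(pwm.length):
        new = np.zeros(size)
        for b in range(4):
            shift = int(im[b, j] - mins[j])
            new[shift : shift + width] += pwm.background[b] * dist[:width]
        dist = new
        width += int(maxs[j] - mins[j])
    return dist, int(mins.sum())


def pwm_threshold(
    ppm, background=None, pvalue: float = 1e-4, score_scale: int = 1000, motif_id: str = ""
) -> tuple[PWMModel, int]:
    """Integer score threshold with exact type-I rate <= pvalue.

    Returns (PWMModel, threshold). The threshold is the smallest integer
    score t such that P(score >= t) <= pvalue under the background; if even
    the maximal score is more probable than pvalue, max+1 is returned (no
    window can match).
    """
    if not (0 < pvalue <= 1):
        raise ValueError("pvalue must be in (0, 1]")
    pwm = pwm_from_ppm(ppm, background, score_scale, motif_id)
    pmf, min_score = exact_score_distribution(pwm)
    sf = np.cumsum(pmf[::-1])[::-1]  # sf[i] = P(score >= min_score + i)
    # the threshold is reported on the achievable-score grid (pmf > 0)
    ok = np.nonzero((pmf > 0) & (sf <= pvalue + 1e-15))[0]
    threshold = min_score + (int(ok[0]) if ok.size else len(pmf))
    return pwm, threshold


@dataclass(frozen=True)
class GenomicHit:
    seq_id: str
    start: int  # 0-based
    end: int  # exclusive
    strand: str  # '+' or '-'
    score: int  # integer-scaled log-odds


def _iter_sequences(sequences):
    if hasattr(sequences, "items"):
        yield from sequences.items()
    elif hasattr(sequences, "keys"):  # pyfaidx.Fasta
        for name in sequences.keys():
            yield name, str(sequences[name])
    else:
        raise TypeError("sequences must be a mapping or a pyfaidx.Fasta")


def _window_scores(seq_codes: np.ndarray, int_matrix: np.ndarray) -> np.ndarray:
    """Integer score of every window; invalid windows get a -inf-like score."""
    L = int_matrix.shape[1]
    n_win = seq_codes.size - L + 1
    if n_win <= 0:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(seq_codes, L)
    safe = np.where(win >= 0, win, 0)
    scores = np.take_along_axis(int_matrix.T[None, :, :], safe[:, :, None], axis=2)[:, :, 0].sum(axis=1)
    scores[(win < 0).any(axis=1)] = np.iinfo(np.int64).min
    return scores


def scan_sequences(sequences, pwm: PWMModel, threshold: int) -> list[GenomicHit]:
    """All windows scoring >= threshold on either strand, in (seq, start, strand) order."""
    L = pwm.length
    im_fwd = pwm.int_matrix
    im_rev = im_fwd[::-1, ::-1]  # scores the minus strand on forward coordinates
    hits: list[GenomicHit] = []
    for name, seq in _iter_sequences(sequences):
        codes = encode(seq.upper())
        for strand, im in (("+", im_fwd), ("-", im_rev)):
            scores = _window_scores(codes, im)
            for i in np.nonzero(scores >= threshold)[0]:
                hits.append(GenomicHit(name, int(i), int(i) + L, strand, int(scores[i])))
    hits.sort(key=lambda h: (h.seq_id, h.start, h.strand))
    return hits


def count_matches(lib, pwm: PWMModel, threshold: int) -> int:
    """Total matching windows (both strands) across a ligand library."""
    seqs = lib.sequences() if hasattr(lib, "sequences") else list(lib)
    total = 0
    for seq in seqs:
        codes = encode(seq.upper())
        total += int((_window_scores(codes, pwm.int_matrix) >= threshold).sum())
        total += int((_window_scores(codes, pwm.int_matrix[::-1, ::-1]) >= threshold).sum())
    return total


def write_bed(hits: list[GenomicHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.seq_id}\t{h.start}\t{h.end}\tmotif\t{h.score}\t{h.strand}\n")


# ---------------------------------------------------------------------------
# Intervals and gene models


@dataclass
class PeakSet:
    """Merged genomic intervals (0-based half-open)."""

    intervals: list[tuple[str, int, int]]
    label: str = ""

    def __post_init__(self):
        merged: list[tuple[str, int, int]] = []
        for seq_id, start, end in sorted(self.intervals):
            if start < 0 or end <= start:
                raise ValueError(f"invalid interval {(seq_id, start, end)}")
            if merged and merged[-1][0] == seq_id and start <= merged[-1][2]:
                merged[-1] = (seq_id, merged[-1][1], max(end, merged[-1][2]))
            else:
                merged.append((seq_id, start, end))
        self.intervals = merged

    def total_bp(self) -> int:
        return sum(end - start for _, start, end in self.intervals)

    def contains(self, seq_id: str, pos: int) -> bool:
        return any(s == seq_id and start <= pos < end for s, start, end in self.intervals)


def read_bed(path, label: str = "") -> PeakSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
                     names=["chrom", "start", "end"])
    return PeakSet([(r.chrom, int(r.start), int(r.end)) for r in df.itertuples()], label=label)


@dataclass(frozen=True)
class GeneModel:
    id: str
    seq_id: str
    strand: str
    start: int  # 0-based genomic start (leftmost)
    end: int  # exclusive genomic end

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


def read_gff3_genes(path, feature: str = "gene") -> list[GeneModel]:
    """Parse gene records from a GFF3 file (1-based inclusive -> 0-based half-open)."""
    cols = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=cols)
    genes = []
    for row in df.itertuples():
        if row.type != feature:
            continue
        attrs = dict(
            kv.split("=", 1) for kv in str(row.attributes).split(";") if "=" in kv
        )
        gid = attrs.get("ID", f"{row.seqid}:{row.start}-{row.end}")
        genes.append(GeneModel(gid, row.seqid, row.strand, int(row.start) - 1, int(row.end)))
    return genes


# ---------------------------------------------------------------------------
# Context statistics


def ths_enrichment(hits: list[GenomicHit], peaks: PeakSet, genome_length: int) -> float:
    """Density ratio of motif hits inside vs outside accessible intervals.

    ratio = ((hits_in + 1) / bp_in) / ((hits_out + 1) / bp_out).
    """
    bp_in = peaks.total_bp()
    bp_out = genome_length - bp_in
    if bp_in <= 0:
        raise ValueError("peak set is empty")
    if bp_out <= 0:
        raise ValueError("peaks cover the whole genome; no outside region")
    hits_in = sum(peaks.contains(h.seq_id, (h.start + h.end) // 2) for h in hits)
    hits_out = len(hits) - hits_in
    return ((hits_in + 1) / bp_in) / ((hits_out + 1) / bp_out)


def metagene_profile(
    hits: list[GenomicHit],
    genes: list[GeneModel],
    body_length: int = 2000,
    flank: int = 1000,
    bin_size: int = 50,
) -> pd.DataFrame:
    """Hit density over gene bodies rescaled to a common length.

    Every hit midpoint falling within [TSS - flank, TTS + flank] of a gene
    is mapped onto the metagene axis: upstream flank at real scale, gene
    body linearly rescaled to ``body_length``, downstream flank at real
    scale. Minus-strand genes are flipped. Returns a DataFrame with bin
    start coordinates (TSS at 0), raw counts and per-gene density.
    """
    n_bins = (2 * flank + body_length) // bin_size
    counts = np.zeros(n_bins)
    for gene in genes:
        glen = gene.length
        if glen < 1:
            continue
        lo, hi = gene.start - flank, gene.end + flank
        for h in hits:
            if h.seq_id != gene.seq_id:
                continue
            mid = (h.start + h.end) // 2
            if not (lo <= mid < hi):
                continue
            if gene.strand == "+":
                rel = mid - gene.start
            else:
                rel = (gene.end - 1) - mid
            if rel < 0:
                x = rel  # upstream, real scale
            elif rel >= glen:
                x = body_length + (rel - glen)
            else:
                x = rel * body_length / glen
            b = int((x + flank) // bin_size)
            if 0 <= b < n_bins:
                counts[b] += 1
    starts = np.arange(n_bins) * bin_size - flank
    density = counts / max(len(genes), 1)
    return pd.DataFrame({"bin_start": starts, "count": counts, "density": density})


def tss_window_enrichment(
    hits: list[GenomicHit],
    genes: list[GeneModel],
    expression: dict,
    window: int = 300,
    quantile: float = 0.15,
) -> float:
    """Hit enrichment near TSSs of high- vs low-expressed genes.

    Genes are ranked by expression (ties broken by gene id); hits within
    +/- window of the TSS are counted for the top and bottom ``quantile``
    sets and the size-normalized, pseudocounted ratio is returned.
    """
    ranked = sorted(genes, key=lambda g: (expression.get(g.id, 0.0), g.id))
    n_q = max(1, int(quantile * len(ranked)))
    if len(ranked) < 2 * n_q:
        raise ValueError("not enough genes for the requested quantile split")
    bottom, top = ranked[:n_q], ranked[-n_q:]

    def window_hits(gene_set):
        total = 0
        for gene in gene_set:
            for h in hits:
                if h.seq_id == gene.seq_id and abs((h.start + h.end) // 2 - gene.tss) <= window:
                    total += 1
        return total

    return ((window_hits(top) + 1) / len(top)) / ((window_hits(bottom) + 1) / len(bottom))


def read_fasta(path) -> dict:
    """Load a FASTA file into a dict of name -> sequence (uppercase)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return {name: str(fa[name]).upper() for name in fa.keys()}
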
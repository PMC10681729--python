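"""Footprint depth, accessibility classification, bound/unbound splitting,
TPM and CRE dose-response.

The module consumes bias-corrected per-base cut-count tracks (bedGraph) —
correcting Tn5 sequence bias is an upstream concern. Footprint depth for a
set of aggregated CRE sites is the difference of mean cut frequencies
between the flanking regions and the footprint core, further subtracted
with the same quantity computed on a protein-free control track (residual
footprints survive bias correction in the control, so the subtraction
matters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Expression


def tpm(read_counts, gene_lengths, gene_ids=None) -> pd.DataFrame:
    """Transcripts-per-million table; TPM sums to 1e6 by construction.

    TPM_g = 1e6 * (c_g / l_g) / sum_genes(c / l).
    """
    counts = np.asarray(read_counts, dtype=float)
    lengths = np.asarray(gene_lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ValueError("counts and lengths differ in shape")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (counts < 0).any():
        raise ValueError("read counts must be non-negative")
    rates = counts / lengths
    denom = rates.sum()
    if denom == 0:
        raise ValueError("all read counts are zero; TPM undefined")
    if gene_ids is None:
        gene_ids = [f"gene{i}" for i in range(len(counts))]
    return pd.DataFrame(
        {"gene_id": list(gene_ids), "read_count": counts, "gene_length": lengths,
         "tpm": 1e6 * rates / denom}
    )


# ---------------------------------------------------------------------------
# Cut tracks and footprints


def read_bedgraph(path, lengths: dict | None = None) -> dict:
    """Expand a bedGraph into per-base numpy arrays keyed by sequence id.

    ``lengths`` fixes array sizes; otherwise each array extends to the
    rightmost covered coordinate.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    tracks: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        size = lengths[chrom] if lengths else int(sub["end"].max())
        arr = np.zeros(size)
        for row in sub.itertuples():
            arr[int(row.start) : int(row.end)] = row.value
        tracks[str(chrom)] = arr
    return tracks


@dataclass
class CutProfile:
    """Per-site cut-count rows over a fixed window centered on each CRE."""

    matrix: np.ndarray  # (n_sites, window)
    window: int
    site_ids: list
    n_dropped: int = 0

    def __post_init__(self):
        if self.window % 2 == 0:
            raise ValueError("window width must be odd")

    def mean_profile(self) -> np.ndarray:
        return self.matrix.mean(axis=0)


def aggregate_profile(cut_track: dict, hits, window: int = 121) -> CutProfile:
    """Stack per-base cut counts around each hit midpoint, motif-oriented.

    Minus-strand hits are flipped so that all rows share the motif
    orientation. Hits whose window leaves the track are dropped and
    counted.
    """
    if window % 2 == 0:
        raise ValueError("window width must be odd")
    half = window // 2
    rows, ids = [], []
    dropped = 0
    for h in hits:
        track = cut_track.get(h.seq_id)
        if track is None:
            dropped += 1
            continue
        center = (h.start + h.end) // 2
        lo, hi = center - half, center + half + 1
        if lo < 0 or hi > len(track):
            dropped += 1
            continue
        row = track[lo:hi]
        if getattr(h, "strand", "+") == "-":
            row = row[::-1]
        rows.append(row)
        ids.append(f"{h.seq_id}:{h.start}-{h.end}({getattr(h, 'strand', '+')})")
    if not rows:
        raise ValueError("no hit window fits inside the cut track")
    return CutProfile(np.array(rows), window, ids, dropped)


def _depths(matrix: np.ndarray, core_width: int, flank_width: int) -> np.ndarray:
    """Per-site flank-mean minus core-mean, core centered in the window."""
    window = matrix.shape[1]
    if core_width + 2 * flank_width > window:
        raise ValueError("core + flanks exceed the profile window")
    center = window // 2
    c_lo = center - core_width // 2
    c_hi = c_lo + core_width
    flank = np.concatenate(
        [matrix[:, c_lo - flank_width : c_lo], matrix[:, c_hi : c_hi + flank_width]], axis=1
    )
    return flank.mean(axis=1) - matrix[:, c_lo:c_hi].mean(axis=1)


@dataclass
class FootprintResult:
    motif_id: str
    sample_id: str
    depth: float  # control-subtracted aggregate depth (cuts/bp)
    per_site_depths: np.ndarray
    control_depth: float


def footprint_depth(
    profile: CutProfile,
    core_width: int,
    flank_width: int = 25,
    control_profile: CutProfile | None = None,
    motif_id: str = "",
    sample_id: str = "",
) -> FootprintResult:
    """Aggregate footprint depth with optional control subtraction.

    depth = mean(flank cells) - mean(core cells), computed on the
    aggregated profile, minus the same quantity on the control profile.
    Per-site depths are control-subtracted by the aggregate control depth.
    """
    per_site = _depths(profile.matrix, core_width, flank_width)
    depth = float(per_site.mean())
    control = 0.0
    if control_profile is not None:
        if control_profile.window != profile.window:
            raise ValueError("control profile window differs from sample window")
        control = float(_depths(control_profile.matrix, core_width, flank_width).mean())
    return FootprintResult(motif_id, sample_id, depth - control, per_site - control, control)


# ---------------------------------------------------------------------------
# Accessibility classification and bound/unbound splitting


def accessibility_classify(
    depths: pd.DataFrame, ths_ratios: pd.DataFrame, pos: float = 0.5, neg: float = -0.5
) -> pd.DataFrame:
    """Correlate footprint depth with accessibility enrichment per motif.

    Both inputs are motif x sample tables over identical indices. A motif
    is a 'positive' model when its across-sample Pearson r exceeds ``pos``
    and 'negative' below ``neg``; otherwise unclassified. Zero-variance
    rows are unclassified with a warning.
    """
    if not depths.index.equals(ths_ratios.index) or not depths.columns.equals(ths_ratios.columns):
        raise ValueError("depth and accessibility tables must share index and columns")
    if depths.shape[1] < 3:
        raise ValueError("need at least 3 samples per motif")
    rows = []
    for motif in depths.index:
        x = depths.loc[motif].to_numpy(dtype=float)
        y = ths_ratios.loc[motif].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            warnings.warn(f"zero variance for motif {motif}; unclassified")
            rows.append((motif, np.nan, "unclassified"))
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        category = "positive" if r > pos else "negative" if r < neg else "unclassified"
        rows.append((motif, r, category))
    return pd.DataFrame(rows, columns=["motif_id", "pearson_r", "category"]).set_index("motif_id")


def split_bound_unbound(per_site_depths, control_depths, k: float = 1.0) -> pd.DataFrame:
    """Label sites bound when depth exceeds control mean + k * control SD."""
    control = np.asarray(control_depths, dtype=float)
    if control.size < 10:
        raise ValueError(f"need >= 10 control sites, got {control.size}")
    site = np.asarray(per_site_depths, dtype=float)
    threshold = control.mean() + k * control.std(ddof=1)
    bound = site > threshold
    return pd.DataFrame({"depth": site, "bound": bound})


# ---------------------------------------------------------------------------
# Dose-response


def cre_dose_response(
    bound_hits,
    genes,
    expression: dict,
    promoter_window: int = 1000,
    max_class: int = 3,
) -> pd.DataFrame:
    """Median expression grouped by the number of bound CREs in the promoter.

    The promoter is ``promoter_window`` bp immediately upstream of the TSS
    (strand-aware). Classes are 0, 1, ..., max_class-1 and >= max_class.
    """
    counts = {g.id: 0 for g in genes}
    for gene in genes:
        if gene.strand == "+":
            lo, hi = gene.tss - promoter_window, gene.tss
        else:
            lo, hi = gene.tss + 1, gene.tss + 1 + promoter_window
        for h in bound_hits:
            if h.seq_id != gene.seq_id:
                continue
            mid = (h.start + h.end) // 2
            if lo <= mid < hi:
                counts[gene.id] += 1
    rows = []
    for cls in range(max_class + 1):
        if cls < max_class:
            members = [g.id for g in genes if counts[g.id] == cls]
            label = str(cls)
        else:
            members = [g.id for g in genes if counts[g.id] >= max_class]
            label = f">={max_class}"
        tpms = [expression.get(gid, np.nan) for gid in members]
        tpms = [v for v in tpms if np.isfinite(v)]
        rows.append((label, len(members), float(np.median(tpms)) if tpms else np.nan))
    return pd.DataFrame(rows, columns=["cre_class", "n_genes", "median_tpm"])


def permutation_r_distribution(
    depths: pd.DataFrame, ths_ratios: pd.DataFrame, n_perm: int = 100, rng_seed: int = 0
) -> np.ndarray:
    """Pearson r per motif after permuting sample labels independently.

    The null counterpart of accessibility_classify: a unimodal distribution
    centered near 0 is expected when associations are broken.
    """
    rng = np.random.default_rng(rng_seed)
    out = []
    n = depths.shape[1]
    for _ in range(n_perm):
        for motif in depths.index:
            x = depths.loc[motif].to_numpy(dtype=float)
            y = ths_ratios.loc[motif].to_numpy(dtype=float)[rng.permutation(n)]
            if x.std() == 0 or y.std() == 0:
                continue
            out.append(float(np.corrcoef(x, y)[0, 1]))
    return np.array(out)
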
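"""Curation of discovered motifs: IC filters, dedup, classification, activity.

Filters drop homonucleotide-run artefacts (consensus IC), degenerate and
over-long models (total IC bounds) and diffuse models (per-base IC). Motifs
whose best ungapped alignment exceeds Pearson r = 0.90 are considered the
same model; the highest-total-IC representative of each such group is
kept. Against a reference library, motifs are classified as reported /
similar / distinct by configurable correlation thresholds (the original
classification was manual; the defaults here are documented choices).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .motif_discovery import MotifModel


@dataclass(frozen=True)
class CurationFilters:
    consensus_ic_max: float = 1.8
    total_ic_min: float = 2.0
    total_ic_max: float = 30.0
    per_base_ic_min: float = 0.2
    homopolymer_fraction: float = 0.9  # flag if one base dominates the consensus

    def __post_init__(self):
        if self.total_ic_min >= self.total_ic_max:
            raise ValueError("total_ic_min must be < total_ic_max")


def is_homopolymer_like(motif: MotifModel, fraction: float = 0.9) -> bool:
    cons = motif.consensus
    return max(cons.count(b) for b in "ACGT") >= fraction * len(cons)


def curate_motifs(
    motifs: list[MotifModel], filters: CurationFilters | None = None
) -> tuple[list[MotifModel], list[tuple[MotifModel, str]]]:
    """Apply the IC filters; returns (retained, rejected-with-reason)."""
    filters = filters or CurationFilters()
    retained, rejected = [], []
    for m in motifs:
        if m.consensus_ic() >= filters.consensus_ic_max:
            rejected.append((m, f"consensus_ic {m.consensus_ic():.3f} >= {filters.consensus_ic_max}"))
        elif m.total_ic <= filters.total_ic_min:
            rejected.append((m, f"total_ic {m.total_ic:.3f} <= {filters.total_ic_min}"))
        elif m.total_ic >= filters.total_ic_max:
            rejected.append((m, f"total_ic {m.total_ic:.3f} >= {filters.total_ic_max}"))
        elif m.per_base_ic <= filters.per_base_ic_min:
            rejected.append((m, f"per_base_ic {m.per_base_ic:.3f} <= {filters.per_base_ic_min}"))
        else:
            retained.append(m)
    return retained, rejected


@dataclass(frozen=True)
class MotifAlignment:
    offset: int  # start of m2 relative to start of m1
    strand: str  # 'fwd' or 'revcomp' (orientation of m2)
    pearson_r: float
    n_overlap_columns: int


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def align_motifs(m1: MotifModel, m2: MotifModel, min_overlap: int = 4) -> MotifAlignment:
    """Best Pearson correlation over all ungapped offsets and both strands.

    r is computed on the flattened overlapping probability cells. Ties
    resolve to the smaller |offset|, then to the forward strand.
    """
    L1, L2 = m1.length, m2.length
    if min(L1, L2) < min_overlap:
        raise ValueError(f"motifs shorter than min_overlap={min_overlap}")
    best: MotifAlignment | None = None
    for strand, ppm2 in (("fwd", m2.ppm), ("revcomp", m2.ppm[::-1, ::-1])):
        for offset in range(-(L2 - min_overlap), L1 - min_overlap + 1):
            lo1, hi1 = max(0, offset), min(L1, offset + L2)
            if hi1 - lo1 < min_overlap:
                continue
            seg1 = m1.ppm[:, lo1:hi1].ravel()
            seg2 = ppm2[:, lo1 - offset : hi1 - offset].ravel()
            r = _pearson(seg1, seg2)
            cand = MotifAlignment(offset, strand, r, hi1 - lo1)
            if (
                best is None
                or r > best.pearson_r + 1e-12
                or (
                    abs(r - best.pearson_r) <= 1e-12
                    and (abs(offset), strand != "fwd") < (abs(best.offset), best.strand != "fwd")
                )
            ):
                best = cand
    if best is None:
        raise ValueError("no offset achieves the minimum overlap")
    return best


def dedup_motifs(
    motifs: list[MotifModel], r_threshold: float = 0.90, min_overlap: int = 4
) -> list[MotifModel]:
    """Collapse near-identical motifs (best aligned r strictly > threshold).

    Edges with r > r_threshold define connected components; within each
    component the motif with the highest total IC survives (ties broken by
    id). Input order of the survivors is preserved.
    """
    n = len(motifs)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if align_motifs(motifs[i], motifs[j], min_overlap).pearson_r > r_threshold:
                parent[find(i)] = find(j)
    best_in: dict[int, int] = {}
    for i, m in enumerate(motifs):
        root = find(i)
        if root not in best_in:
            best_in[root] = i
        else:
            cur = motifs[best_in[root]]
            if (m.total_ic, cur.id) > (cur.total_ic, m.id):
                best_in[root] = i
    keep = sorted(best_in.values())
    return [motifs[i] for i in keep]


def classify_motifs(
    motifs: list[MotifModel],
    reference_library: list[MotifModel],
    r_reported: float = 0.85,
    r_similar: float = 0.70,
    min_overlap: int = 4,
) -> pd.DataFrame:
    """Label each motif distinct / similar / reported vs a reference library.

    Returns a DataFrame with columns motif_id, category, best_match,
    best_r, assigned_name. Distinct motifs get sequential ``seaATId-N``
    names; others inherit the best-matching reference name.
    """
    if not reference_library:
        warnings.warn("empty reference library; all motifs classified distinct")
    rows = []
    n_distinct = 0
    for m in motifs:
        best_r, best_name = -np.inf, ""
        for ref in reference_library:
            r = align_motifs(m, ref, min_overlap).pearson_r
            if r > best_r:
                best_r, best_name = r, ref.name or ref.id
        if best_r >= r_reported:
            cat, name = "reported", best_name
        elif best_r >= r_similar:
            cat, name = "similar", best_name
        else:
            n_distinct += 1
            cat, name = "distinct", f"seaATId-{n_distinct}"
        rows.append((m.id, cat, best_name if np.isfinite(best_r) else "",
                     best_r if np.isfinite(best_r) else np.nan, name))
    return pd.DataFrame(
        rows, columns=["motif_id", "category", "best_match", "best_r", "assigned_name"]
    )


def motif_activity(lib, motif: MotifModel, ctrl, match_pvalue: float = 1e-4) -> float:
    """log2 enrichment of PWM matches in a library over its control.

    Matches are counted at an exact-p-value score threshold on both
    strands and normalized per read, so libraries of different depth are
    comparable. Identical library and control give 0.
    """
    from .genome_scan import count_matches, pwm_threshold

    pwm, threshold = pwm_threshold(motif.ppm, pvalue=match_pvalue)
    n_lib = len(lib.reads) if hasattr(lib, "reads") else len(list(lib))
    n_ctrl = len(ctrl.reads) if hasattr(ctrl, "reads") else len(list(ctrl))
    if n_lib == 0 or n_ctrl == 0:
        raise ValueError("empty library or control")
    m_lib = count_matches(lib, pwm, threshold)
    m_ctrl = count_matches(ctrl, pwm, threshold)
    return float(np.log2(((m_lib + 1) / n_lib) / ((m_ctrl + 1) / n_ctrl)))


def activity_matrix(
    libs: dict, motifs: list[MotifModel], controls: dict, match_pvalue: float = 1e-4
) -> pd.DataFrame:
    """Motifs x libraries activity table (Fig-2A-style)."""
    data = {
        name: [motif_activity(lib, m, controls[name], match_pvalue) for m in motifs]
        for name, lib in libs.items()
    }
    return pd.DataFrame(data, index=[m.id for m in motifs])


def specificity_contrast(activity: pd.DataFrame, categories: dict) -> tuple[float, float, pd.Series]:
    """Welch t of per-motif activity SDs, distinct vs all other motifs.

    ``categories`` maps motif id -> category string. Returns (t, p, sds).
    """
    if activity.shape[1] < 2:
        raise ValueError("need at least two tissues/libraries")
    sds = activity.std(axis=1, ddof=1)
    distinct = sds[[categories.get(i) == "distinct" for i in activity.index]]
    others = sds[[categories.get(i) != "distinct" for i in activity.index]]
    if len(distinct) == 0 or len(others) == 0:
        raise ValueError("both the distinct and the non-distinct groups must be non-empty")
    t, p = stats.ttest_ind(distinct, others, equal_var=False)
    if not np.isfinite(t):
        raise ValueError("t statistic undefined (zero variance in both groups)")
    return float(t), float(p), sds


# ---------------------------------------------------------------------------
# JASPAR-style PFM text I/O (via Bio.motifs)

def read_jaspar(path_or_handle, pseudocount: float = 1.0) -> list[MotifModel]:
    """Read a JASPAR-format PFM library into MotifModels."""
    from Bio import motifs as bio_motifs

    if hasattr(path_or_handle, "read"):
        records = bio_motifs.parse(path_or_handle, "jaspar")
    else:
        with open(path_or_handle) as fh:
            records = bio_motifs.parse(fh, "jaspar")
    out = []
    for rec in records:
        pfm = np.array([rec.counts[b] for b in "ACGT"], dtype=float)
        out.append(
            MotifModel.from_counts(
                id=rec.matrix_id or rec.name, pfm=pfm, pseudocount=pseudocount, name=rec.name or rec.matrix_id
            )
        )
    return out


def write_jaspar(motifs_list: list[MotifModel], path) -> None:
    with open(path, "w") as fh:
        for m in motifs_list:
            fh.write(f">{m.id} {m.name}\n")
            for b, row in zip("ACGT", m.pfm):
                cells = " ".join(f"{v:.2f}".rstrip("0").rstrip(".") for v in row)
                fh.write(f"{b} [ {cells} ]\n")


def read_jaspar_string(text: str, pseudocount: float = 1.0) -> list[MotifModel]:
    return read_jaspar(io.StringIO(text), pseudocount)
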
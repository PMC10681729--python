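"""Orientation x spacing landscapes of dimeric core-sequence pairs.

For a core C (default TTGAC, the W-box) and its reverse complement R, a
pair of matches on the scanned strand is classified as

    DR  (direct repeat)      C....C   — and R....R, which is the same
                                        physical arrangement read from the
                                        other strand, is canonicalized to DR
    IR  (inverted repeat,     C....R   — head-to-head; strand-symmetric
         head-to-head)
    ER  (everted repeat,      R....C   — tail-to-tail; strand-symmetric
         tail-to-tail)

Spacing is the number of bases strictly between the two core matches
(adjacent cores have spacing 0); overlapping pairs are excluded. Because
IR and ER are strand-symmetric and minus-strand DRs are folded into DR,
scanning the given strand once counts every physical dimer exactly once.
A run of three cores contributes all three pairwise arrangements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._alphabet import revcomp

ORIENTATIONS = ("DR", "IR", "ER")


@dataclass(frozen=True)
class DimerSpec:
    core: str = "TTGAC"
    orientations: tuple[str, ...] = ORIENTATIONS
    max_spacing: int = 20

    def __post_init__(self):
        if set(self.core) - set("ACGT"):
            raise ValueError(f"core must contain only ACGT, got {self.core!r}")
        if any(o not in ORIENTATIONS for o in self.orientations):
            raise ValueError(f"orientations must be among {ORIENTATIONS}")

    @property
    def spacings(self) -> range:
        return range(0, self.max_spacing + 1)


@dataclass
class DimerLandscape:
    """Counts (or log2 enrichments) per orientation x spacing cell."""

    matrix: np.ndarray  # (len(orientations), max_spacing+1)
    n_sequences: int
    spec: DimerSpec
    is_enrichment: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=list(self.spec.orientations), columns=list(self.spec.spacings)
        )

    def argmax_cell(self) -> tuple[str, int]:
        i, j = np.unravel_index(np.argmax(self.matrix), self.matrix.shape)
        return self.spec.orientations[i], int(self.spec.spacings[j])

    def total(self) -> int:
        return int(self.matrix.sum())


def _core_matches(seq: str, core: str, rc: str):
    """(position, is_forward) for every match of core or revcomp on one strand."""
    k = len(core)
    hits = []
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if window == core:
            hits.append((i, True))
        elif window == rc:
            hits.append((i, False))
    return hits


_CLASS = {(True, True): "DR", (True, False): "IR", (False, True): "ER", (False, False): "DR"}


def count_dimers(seqs, spec: DimerSpec | None = None) -> DimerLandscape:
    """Count core pairs per orientation and spacing over a sequence set.

    ``seqs`` is a LigandLibrary or iterable of strings. A palindromic core
    cannot be oriented; all its pairs are then classified DR.
    """
    spec = spec or DimerSpec()
    if hasattr(seqs, "sequences"):
        seqs = seqs.sequences()
    else:
        seqs = list(seqs)
    core, rc = spec.core, revcomp(spec.core)
    k = len(core)
    orient_idx = {o: i for i, o in enumerate(spec.orientations)}
    matrix = np.zeros((len(spec.orientations), spec.max_spacing + 1), dtype=np.int64)
    for seq in seqs:
        hits = _core_matches(seq, core, rc)
        for a in range(len(hits)):
            for b in range(a + 1, len(hits)):
                spacing = hits[b][0] - hits[a][0] - k
                if spacing < 0 or spacing > spec.max_spacing:
                    continue
                cls = _CLASS[(hits[a][1], hits[b][1])]
                if cls in orient_idx:
                    matrix[orient_idx[cls], spacing] += 1
    return DimerLandscape(matrix, len(seqs), spec)


def dimer_enrichment(
    obs: DimerLandscape, ctrl: DimerLandscape, pseudocount: float = 1.0
) -> DimerLandscape:
    """Per-cell log2 enrichment of observed over control counts.

    Counts are normalized by the number of sequences in each landscape
    before the ratio, so differently sized libraries compare fairly.
    """
    if obs.spec != ctrl.spec:
        raise ValueError("landscapes built with different specs")
    if obs.is_enrichment or ctrl.is_enrichment:
        raise ValueError("inputs must be count landscapes")
    fo = (obs.matrix + pseudocount) / max(obs.n_sequences, 1)
    fc = (ctrl.matrix + pseudocount) / max(ctrl.n_sequences, 1)
    return DimerLandscape(np.log2(fo / fc), obs.n_sequences, obs.spec, is_enrichment=True)


def sum_landscapes(landscapes: list[DimerLandscape]) -> DimerLandscape:
    """Aggregate signal across libraries (the 'top row sums up' view)."""
    if not landscapes:
        raise ValueError("no landscapes to sum")
    spec = landscapes[0].spec
    if any(ls.spec != spec for ls in landscapes):
        raise ValueError("landscapes built with different specs")
    matrix = np.sum([ls.matrix for ls in landscapes], axis=0)
    return DimerLandscape(
        matrix,
        sum(ls.n_sequences for ls in landscapes),
        spec,
        is_enrichment=landscapes[0].is_enrichment,
    )


def dimeric_tenmer_scatter(lib, ctrl, w: int = 5, gaps=range(0, 9), pseudocount: float = 1.0) -> pd.DataFrame:
    """Gapped dimeric 10-mer frequencies, library vs control.

    Rows are restricted to (left, right, gap) keys whose right half equals
    the left half or its reverse complement — the signature of a dimeric
    element built from two copies of one pentamer.
    """
    from .kmer_stats import GapSpec, count_kmers

    rows = []
    n_keys = 4 ** (2 * w)
    for g in gaps:
        spec = GapSpec(w, g)
        t_obs = count_kmers(lib, gap_spec=spec)
        t_ctrl = count_kmers(ctrl, gap_spec=spec)
        for key in sorted(set(t_obs.counts) | set(t_ctrl.counts)):
            left, right, gap = key
            if right != left and right != revcomp(left):
                continue
            lf_obs = np.log2(t_obs.frequency(key, pseudocount, n_keys))
            lf_ctrl = np.log2(t_ctrl.frequency(key, pseudocount, n_keys))
            rows.append((left, right, gap, lf_obs, lf_ctrl, lf_obs - lf_ctrl))
    df = pd.DataFrame(
        rows, columns=["left", "right", "gap", "log_freq_obs", "log_freq_ctrl", "log_ratio"]
    )
    return df.sort_values(["log_ratio", "left", "right", "gap"], ascending=[False, True, True, True],
                          ignore_index=True)
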
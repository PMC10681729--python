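"""Mutual-information statistics between 3-mer distributions at position pairs.

The signal model: a TF footprint covers two non-overlapping 3-bp windows of
the ligand, so selection induces dependence between the 3-mer distributions
at those windows. Three statistics are computed from the 64x64 joint table:

* ``full_mi``  - the plug-in mutual information over all 4096 pairs,
* ``emi``      - the sum of the top-N (default 10) pointwise contributions,
* ``dmi``      - the sum over the 128 identical / reverse-complement pairs,
                 which is specifically sensitive to dimeric elements.

No pseudocounts are used inside the MI sums (they would bias the null
upward); zero-probability pairs contribute 0 by the 0*log0 := 0 convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from ._alphabet import revcomp_code_table, window_codes

_RC3 = revcomp_code_table(3)
_IDENTICAL_MASK = np.eye(64, dtype=bool)
_REVCOMP_MASK = np.zeros((64, 64), dtype=bool)
_REVCOMP_MASK[np.arange(64), _RC3] = True


@dataclass
class TrimerJoint:
    """Joint 3-mer counts at two non-overlapping 3-bp windows."""

    pos1: int
    pos2: int
    joint_counts: np.ndarray  # (64, 64) ints
    n: int

    @property
    def p_joint(self) -> np.ndarray:
        return self.joint_counts / self.n

    @property
    def p_pos1(self) -> np.ndarray:
        return self.joint_counts.sum(axis=1) / self.n

    @property
    def p_pos2(self) -> np.ndarray:
        return self.joint_counts.sum(axis=0) / self.n


def trimer_joint(lib, pos1: int, pos2: int) -> TrimerJoint:
    """Tally the joint 3-mer table at (pos1, pos2) over a library.

    Windows are 3 bp and must not overlap (pos2 >= pos1 + 3). Reads with N
    inside either window are skipped; each remaining read contributes one
    count. ``lib`` is a LigandLibrary or iterable of equal-length strings.
    """
    if pos2 < pos1 + 3:
        raise ValueError(f"windows overlap: pos1={pos1}, pos2={pos2}")
    from .kmer_stats import _matrix_of

    mat = _matrix_of(lib)
    if mat.size == 0:
        raise ValueError("empty library")
    L = mat.shape[1]
    if pos2 + 3 > L:
        raise ValueError(f"pos2+3={pos2 + 3} exceeds read length {L}")
    codes = window_codes(mat, 3)
    c1, c2 = codes[:, pos1], codes[:, pos2]
    ok = (c1 >= 0) & (c2 >= 0)
    joint = np.zeros((64, 64), dtype=np.int64)
    np.add.at(joint, (c1[ok], c2[ok]), 1)
    return TrimerJoint(pos1, pos2, joint, int(ok.sum()))


def pointwise_contributions(joint: TrimerJoint) -> np.ndarray:
    """The 64x64 matrix of P * log2(P / (P1*P2)) terms (0 where P = 0)."""
    if joint.n <= 0:
        raise ValueError("joint table has no counts")
    P = joint.p_joint
    expected = np.outer(joint.p_pos1, joint.p_pos2)
    out = np.zeros_like(P)
    nz = P > 0
    out[nz] = P[nz] * np.log2(P[nz] / expected[nz])
    return out


def full_mi(joint: TrimerJoint) -> float:
    """Plug-in mutual information over all 4096 3-mer pairs, in bits."""
    return float(pointwise_contributions(joint).sum())


def emi(joint: TrimerJoint, top_n: int = 10, ranking: str = "contribution") -> float:
    """Sum of the ``top_n`` largest pointwise-MI contributions.

    ``ranking='contribution'`` (default) orders pairs by the pointwise term
    itself; ``ranking='ratio'`` orders by P/(P1*P2) but still sums the
    contributions of the selected pairs.
    """
    contrib = pointwise_contributions(joint)
    if ranking == "contribution":
        keys = contrib.ravel()
    elif ranking == "ratio":
        P = joint.p_joint
        expected = np.outer(joint.p_pos1, joint.p_pos2)
        with np.errstate(divide="ignore", invalid="ignore"):
            keys = np.where(P > 0, P / expected, 0.0).ravel()
    else:
        raise ValueError(f"unknown ranking {ranking!r}")
    idx = np.argsort(keys)[::-1][:top_n]
    return float(contrib.ravel()[idx].sum())


class DMIResult(NamedTuple):
    total: float
    identical: float
    revcomp: float


def dmi_components(joint: TrimerJoint) -> DMIResult:
    """D-MI with its identical-pair and reverse-complement-pair partial sums."""
    contrib = pointwise_contributions(joint)
    ident = float(contrib[_IDENTICAL_MASK].sum())
    rc = float(contrib[_REVCOMP_MASK].sum())
    return DMIResult(ident + rc, ident, rc)


def dmi(joint: TrimerJoint) -> float:
    """Sum of contributions over the 128 identical or revcomp 3-mer pairs."""
    return dmi_components(joint).total


@dataclass
class MITriangle:
    """A statistic evaluated at every valid non-overlapping position pair."""

    statistic: str
    values: dict  # (pos1, pos2) -> bits
    core_length: int

    def max_pair(self) -> tuple[int, int]:
        return max(self.values, key=lambda p: (self.values[p], -p[0], -p[1]))

    def to_frame(self):
        import pandas as pd

        rows = [(p1, p2, v) for (p1, p2), v in sorted(self.values.items())]
        return pd.DataFrame(rows, columns=["pos1", "pos2", "bits"])


_STATS = {"emi": "E-MI", "dmi": "D-MI", "full": "full-MI"}


def mi_triangle(lib, statistic: str = "emi", top_n: int = 10) -> MITriangle:
    """Evaluate E-MI / D-MI / full MI at every valid (pos1, pos2) pair."""
    if statistic not in _STATS:
        raise ValueError(f"statistic must be one of {sorted(_STATS)}")
    from .kmer_stats import _matrix_of

    mat = _matrix_of(lib)
    if mat.size == 0:
        raise ValueError("empty library")
    L = mat.shape[1]
    if L < 6:
        raise ValueError(f"core length {L} too short for two 3-bp windows")
    codes = window_codes(mat, 3)
    values: dict = {}
    for pos1 in range(L - 5):
        for pos2 in range(pos1 + 3, L - 2):
            c1, c2 = codes[:, pos1], codes[:, pos2]
            ok = (c1 >= 0) & (c2 >= 0)
            joint_counts = np.zeros((64, 64), dtype=np.int64)
            np.add.at(joint_counts, (c1[ok], c2[ok]), 1)
            joint = TrimerJoint(pos1, pos2, joint_counts, int(ok.sum()))
            if statistic == "emi":
                values[(pos1, pos2)] = emi(joint, top_n=top_n)
            elif statistic == "dmi":
                values[(pos1, pos2)] = dmi(joint)
            else:
                values[(pos1, pos2)] = full_mi(joint)
    return MITriangle(_STATS[statistic], values, L)
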
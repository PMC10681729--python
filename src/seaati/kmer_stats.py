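"""Continuous and gapped k-mer counting and enrichment statistics.

Counting is code-based: every length-k window of every read is converted
to an integer base-4 code and tallied with numpy, so even the gapped
10-mer feature space (two 5-mer halves, gaps 0-8) is cheap. Enrichment is
always measured against a matched mononucleotide-shuffled control of the
same library.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._alphabet import code_to_kmer, window_codes
from .ligand_io import LigandLibrary, shuffle_control


@dataclass(frozen=True)
class GapSpec:
    """Two ``half_width``-mers separated by exactly ``gap`` free bases."""

    half_width: int
    gap: int

    def __post_init__(self):
        if self.half_width < 1 or self.gap < 0:
            raise ValueError("half_width >= 1 and gap >= 0 required")

    @property
    def span(self) -> int:
        return 2 * self.half_width + self.gap


@dataclass
class KmerTable:
    """Counts of continuous k-mers or gapped k-mer pairs.

    Keys are strings for continuous k-mers and ``(left, right, gap)``
    tuples for gapped ones.
    """

    k: int
    counts: dict
    total: int
    gap_spec: GapSpec | None = None
    strands: str = "given"

    def frequency(self, key, pseudocount: float = 1.0, n_keys: int | None = None) -> float:
        if n_keys is None:
            n_keys = 4**self.k if self.gap_spec is None else 4 ** (2 * self.gap_spec.half_width)
        return (self.counts.get(key, 0) + pseudocount) / (self.total + pseudocount * n_keys)


def _matrix_of(lib) -> np.ndarray:
    if isinstance(lib, LigandLibrary):
        return lib.to_matrix()
    from ._alphabet import encode_matrix

    return encode_matrix(lib)


def count_kmers(
    lib, k: int | None = None, gap_spec: GapSpec | None = None, strands: str = "given"
) -> KmerTable:
    """Count every window of every read, once per strand requested.

    ``lib`` is a LigandLibrary or an iterable of equal-length strings.
    Windows containing N are skipped. For gapped counting pass ``gap_spec``
    (``k`` is then ignored and set to ``2 * half_width``).
    """
    if strands not in ("given", "both"):
        raise ValueError("strands must be 'given' or 'both'")
    mat = _matrix_of(lib)
    if mat.size == 0:
        kk = k if gap_spec is None else 2 * gap_spec.half_width
        return KmerTable(k=kk or 0, counts={}, total=0, gap_spec=gap_spec, strands=strands)
    L = mat.shape[1]
    mats = [mat]
    if strands == "both":
        from ._alphabet import revcomp_matrix

        mats.append(revcomp_matrix(mat))

    if gap_spec is None:
        if k is None:
            raise ValueError("k is required for continuous counting")
        if k > L:
            raise ValueError(f"k={k} exceeds read length {L}")
        agg = np.zeros(4**k, dtype=np.int64)
        for m in mats:
            codes = window_codes(m, k).ravel()
            codes = codes[codes >= 0]
            np.add.at(agg, codes, 1)
        nz = np.nonzero(agg)[0]
        counts = {code_to_kmer(int(c), k): int(agg[c]) for c in nz}
        return KmerTable(k=k, counts=counts, total=int(agg.sum()), strands=strands)

    w, g = gap_spec.half_width, gap_spec.gap
    if gap_spec.span > L:
        raise ValueError(f"gapped span {gap_spec.span} exceeds read length {L}")
    agg = np.zeros(4 ** (2 * w), dtype=np.int64)
    for m in mats:
        half = window_codes(m, w)  # (n, L-w+1)
        left = half[:, : L - gap_spec.span + 1]
        right = half[:, w + g : w + g + left.shape[1]]
        pair = np.where((left >= 0) & (right >= 0), left * (4**w) + right, -1).ravel()
        pair = pair[pair >= 0]
        np.add.at(agg, pair, 1)
    nz = np.nonzero(agg)[0]
    counts = {
        (code_to_kmer(int(c) // 4**w, w), code_to_kmer(int(c) % 4**w, w), g): int(agg[c])
        for c in nz
    }
    return KmerTable(k=2 * w, counts=counts, total=int(agg.sum()), gap_spec=gap_spec, strands=strands)


def enrichment_scatter(obs: KmerTable, ctrl: KmerTable, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-key log2 frequencies in observed vs control, shared pseudocount.

    One row per key present in either table; ``log_ratio`` sorts the most
    enriched keys first.
    """
    if obs.k != ctrl.k or obs.gap_spec != ctrl.gap_spec:
        raise ValueError("observed and control tables have mismatched k/gap specs")
    keys = sorted(set(obs.counts) | set(ctrl.counts))
    n_keys = 4**obs.k
    lf_obs = np.array([np.log2(obs.frequency(key, pseudocount, n_keys)) for key in keys])
    lf_ctrl = np.array([np.log2(ctrl.frequency(key, pseudocount, n_keys)) for key in keys])
    df = pd.DataFrame(
        {"kmer": keys, "log_freq_obs": lf_obs, "log_freq_ctrl": lf_ctrl, "log_ratio": lf_obs - lf_ctrl}
    )
    return df.sort_values(["log_ratio", "kmer"], ascending=[False, True], ignore_index=True)


def _enrichment_ranks(lib: LigandLibrary, ctrl: LigandLibrary, w: int, gaps, pseudocount=1.0):
    """Enrichment ratio of every gapped pair key (lib vs its control)."""
    ratios: dict = {}
    for g in gaps:
        spec = GapSpec(w, g)
        t_obs = count_kmers(lib, gap_spec=spec)
        t_ctrl = count_kmers(ctrl, gap_spec=spec)
        n_keys = 4 ** (2 * w)
        for key in set(t_obs.counts) | set(t_ctrl.counts):
            ratios[key] = t_obs.frequency(key, pseudocount, n_keys) / t_ctrl.frequency(
                key, pseudocount, n_keys
            )
    return ratios


def rank_feature_matrix(
    libs: list[LigandLibrary],
    controls: list[LigandLibrary] | None = None,
    w: int = 5,
    gaps=range(0, 9),
    top_n: int = 10000,
    rng_seed: int = 0,
    n_components: int = 2,
):
    """Gapped 10-mer rank matrix across libraries plus PCA coordinates.

    Per library, gapped (w,w)-mers at the given gaps are ranked by
    enrichment ratio against that library's shuffled control (generated
    here when ``controls`` is None). Features are the union of each
    library's ``top_n`` keys; matrix entries are within-library ranks over
    that union (1 = most enriched; ties broken lexicographically).

    Returns ``(features, rank_matrix, pca_coords)`` where rank_matrix is a
    pandas DataFrame (libraries x features).
    """
    if len(libs) < 2:
        raise ValueError("need at least two libraries to compare")
    if controls is None:
        controls = [shuffle_control(lib, rng_seed + i) for i, lib in enumerate(libs)]
    per_lib = [_enrichment_ranks(lib, ctrl, w, gaps) for lib, ctrl in zip(libs, controls)]

    feature_set: set = set()
    for ratios in per_lib:
        keys = sorted(ratios, key=lambda key: (-ratios[key], key))
        if len(keys) < top_n:
            warnings.warn(
                f"only {len(keys)} distinct gapped k-mers available (< top_n={top_n}); using all"
            )
        feature_set.update(keys[:top_n])
    features = sorted(feature_set)

    worst = len(features)
    rows = []
    for ratios in per_lib:
        order = sorted(features, key=lambda key: (-ratios.get(key, -np.inf), key))
        rank_of = {key: i + 1 for i, key in enumerate(order)}
        rows.append([rank_of[key] if key in ratios else worst for key in features])
    names = [lib.sample_name or f"lib{i}" for i, lib in enumerate(libs)]
    matrix = pd.DataFrame(rows, index=names, columns=[str(f) for f in features])

    from sklearn.decomposition import PCA

    n_comp = min(n_components, len(libs), len(features))
    coords = PCA(n_components=n_comp, random_state=0).fit_transform(matrix.to_numpy(dtype=float))
    return features, matrix, coords
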
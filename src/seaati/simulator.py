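"""Synthetic selection experiments and genome-context fixtures.

Two generators with full ground truth:

* ligand-library selection — i.i.d. random cores inside fixed adaptor
  flanks, enriched over 3-5 rounds by PWM-defined monomeric TFs (logistic
  occupancy in the score) and/or dimeric TFs (orientation/spacing affinity
  for a core pair), followed by PCR duplication;
* a toy genome with planted CREs, accessibility peaks, per-base cut tracks
  (sample + protein-free control) and CRE-coupled expression counts.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; sub-steps draw from one generator in a
documented order, so outputs are bit-reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ._alphabet import encode, revcomp, window_codes
from .ligand_io import AdaptorSpec, LigandLibrary, LigandRead
from .motif_discovery import MotifModel


@dataclass
class SimTF:
    """A selecting TF: monomeric PWM binding and/or dimeric core-pair affinity."""

    motif: MotifModel | None = None
    beta: float = 1.0  # per-bit steepness of the occupancy logistic
    dimer_core: str | None = None
    dimer_affinity: dict | None = None  # (orientation, spacing) -> occupancy in [0, 1]

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.dimer_affinity and any(a < 0 for a in self.dimer_affinity.values()):
            raise ValueError("dimer affinities must be non-negative")
        if self.motif is None and not self.dimer_core:
            raise ValueError("a SimTF needs a motif and/or a dimer spec")


@dataclass
class SimConfig:
    n_ligands: int = 10000
    adaptor: AdaptorSpec = field(default_factory=AdaptorSpec)
    n_rounds: int = 4
    selection_fraction: float = 0.3
    pcr_duplication_rate: float = 0.3  # expected copies per template = 1/(1-rate)
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        for name in ("selection_fraction", "pcr_duplication_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0 < self.selection_fraction):
            raise ValueError("selection_fraction must be positive")


def simulate_initial_library(config: SimConfig, sample_name: str = "sim") -> LigandLibrary:
    """Round-0 library: uniform random cores inside the fixed flanks."""
    rng = np.random.default_rng(config.rng_seed)
    spec = config.adaptor
    cores = rng.integers(0, 4, size=(config.n_ligands, spec.core_length))
    base_arr = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    blob = base_arr[cores].tobytes().decode()
    L = spec.core_length
    reads = [
        LigandRead(f"lig{i}", spec.flank5 + blob[i * L : (i + 1) * L] + spec.flank3)
        for i in range(config.n_ligands)
    ]
    return LigandLibrary(reads, sample_name=sample_name, round=0)


def _core_matrix(lib: LigandLibrary, spec: AdaptorSpec) -> np.ndarray:
    """Encoded core region of every read (handles pre-trimmed libraries)."""
    length = lib.read_length()
    mat = lib.to_matrix()
    if length == spec.core_length:
        return mat
    if length == spec.total_length:
        n5 = len(spec.flank5)
        return mat[:, n5 : n5 + spec.core_length]
    raise ValueError(f"read length {length} matches neither core nor full ligand")


def _monomer_weights(core_mat: np.ndarray, tf: SimTF) -> np.ndarray:
    """1 - prod(1 - occupancy) over all windows of both strands."""
    ppm = tf.motif.ppm
    lo = np.log2(ppm / 0.25)  # bits, uniform background
    L = lo.shape[1]
    smax = lo.max(axis=0).sum()
    mats = [core_mat, np.where(core_mat >= 0, 3 - core_mat, -1)[:, ::-1]]
    log_unbound = np.zeros(core_mat.shape[0])
    for mat in mats:
        if mat.shape[1] < L:
            continue
        win = np.lib.stride_tricks.sliding_window_view(mat, L, axis=1)
        safe = np.where(win >= 0, win, 0)
        scores = np.take_along_axis(lo.T[None, None, :, :], safe[:, :, :, None], axis=3)[
            :, :, :, 0
        ].sum(axis=2)
        occ = 1.0 / (1.0 + np.exp(-tf.beta * (scores - smax)))
        log_unbound += np.log1p(-np.clip(occ, 0, 1 - 1e-12)).sum(axis=1)
    return 1.0 - np.exp(log_unbound)


def _dimer_weights(core_mat: np.ndarray, tf: SimTF) -> np.ndarray:
    """Occupancy from orientation/spacing-specific dimeric sites."""
    core = tf.dimer_core
    k = len(core)
    c_code = int(np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[b] for b in core])
                 @ (4 ** np.arange(k - 1, -1, -1)))
    r_code = int(np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[b] for b in revcomp(core)])
                 @ (4 ** np.arange(k - 1, -1, -1)))
    codes = window_codes(core_mat, k)
    isC = codes == c_code
    isR = codes == r_code
    n, W = isC.shape
    log_unbound = np.zeros(n)
    for (orient, spacing), aff in (tf.dimer_affinity or {}).items():
        step = k + spacing
        if step >= W:
            continue
        first, second = isC[:, : W - step], isC[:, step:]
        firstR, secondR = isR[:, : W - step], isR[:, step:]
        if orient == "DR":
            pairs = (first & second) | (firstR & secondR)
        elif orient == "IR":
            pairs = first & secondR
        elif orient == "ER":
            pairs = firstR & second
        else:
            raise ValueError(f"unknown orientation {orient!r}")
        n_pairs = pairs.sum(axis=1)
        log_unbound += n_pairs * np.log1p(-min(aff, 1 - 1e-12))
    return 1.0 - np.exp(log_unbound)


def selection_weights(lib: LigandLibrary, tfs: list[SimTF], config: SimConfig) -> np.ndarray:
    """Per-read selection weight: 1 - prod over TFs of (1 - TF occupancy)."""
    core_mat = _core_matrix(lib, config.adaptor)
    log_unbound = np.zeros(len(lib))
    for tf in tfs:
        w = np.zeros(len(lib))
        if tf.motif is not None:
            w = _monomer_weights(core_mat, tf)
        if tf.dimer_core is not None:
            wd = _dimer_weights(core_mat, tf)
            w = 1 - (1 - w) * (1 - wd)
        log_unbound += np.log1p(-np.clip(w, 0, 1 - 1e-12))
    return 1.0 - np.exp(log_unbound)


def selection_round(
    lib: LigandLibrary, tfs: list[SimTF], config: SimConfig, rng_seed: int | None = None
) -> LigandLibrary:
    """One cycle: affinity-proportional resampling, then PCR duplication.

    Draws in order: (1) round(selection_fraction * n) template draws with
    probability proportional to the selection weight (with replacement —
    abundant high-affinity molecules are captured repeatedly); (2) one
    geometric copy number per draw with mean 1/(1 - pcr_duplication_rate).
    The output lists templates in index order, duplicates adjacent, with
    fresh read ids.
    """
    if not lib.reads:
        raise ValueError("cannot select from an empty library")
    rng = np.random.default_rng(config.rng_seed if rng_seed is None else rng_seed)
    weights = selection_weights(lib, tfs, config)
    n = len(lib)
    m = max(1, round(config.selection_fraction * n))
    total = weights.sum()
    if total <= 0:
        warnings.warn("all selection weights are zero; sampling uniformly")
        probs = np.full(n, 1.0 / n)
    else:
        probs = weights / total
    chosen = np.sort(rng.choice(n, size=m, replace=True, p=probs))
    copies = (
        rng.geometric(1 - config.pcr_duplication_rate, size=m)
        if config.pcr_duplication_rate > 0
        else np.ones(m, dtype=int)
    )
    reads = []
    for draw, (idx, c) in enumerate(zip(chosen, copies)):
        seq = lib.reads[idx].sequence
        for dup in range(int(c)):
            reads.append(LigandRead(f"r{lib.round + 1}_t{idx}_d{draw}_c{dup}", seq))
    return LigandLibrary(reads, sample_name=lib.sample_name, round=lib.round + 1)


def run_experiment(
    config: SimConfig, tfs: list[SimTF], sample_name: str = "sim"
) -> list[LigandLibrary]:
    """Simulate all rounds; returns [round0, round1, ..., roundN].

    Round r uses a child seed spawned deterministically from the config
    seed (SeedSequence(seed).spawn), so rounds have independent streams.
    """
    seeds = np.random.SeedSequence(config.rng_seed).spawn(config.n_rounds + 1)
    lib = simulate_initial_library(
        replace(config, rng_seed=int(seeds[0].generate_state(1)[0])), sample_name
    )
    out = [lib]
    for r in range(config.n_rounds):
        lib = selection_round(lib, tfs, config, rng_seed=int(seeds[r + 1].generate_state(1)[0]))
        out.append(lib)
    return out


# ---------------------------------------------------------------------------
# Genome-context fixture


@dataclass
class GenomeSimConfig:
    genome_length: int = 120_000
    chrom: str = "chr1"
    n_genes: int = 60
    gene_length: int = 800
    promoter_window: int = 1000
    occupancy: float = 0.9  # probability a planted CRE is bound
    max_cres_per_promoter: int = 3
    peak_halfwidth: int = 700
    background_cut_rate: float = 2.0
    peak_cut_multiplier: float = 4.0
    dip_fraction: float = 0.8  # cut-rate reduction at bound CRE cores
    control_dip_fraction: float = 0.15  # residual dip in the protein-free control
    expression_base: float = 50.0
    cre_expression_effect: float = 0.8  # multiplicative boost per bound CRE
    rng_seed: int = 0


@dataclass
class PlantedCRE:
    seq_id: str
    start: int
    end: int
    gene_id: str
    bound: bool


@dataclass
class GenomeSim:
    genome: dict  # seq_id -> sequence
    genes: list  # GeneModel
    cres: list[PlantedCRE]
    peaks: list[tuple[str, int, int]]
    cut_track: dict  # seq_id -> per-base counts (sample)
    control_track: dict  # seq_id -> per-base counts (protein-free)
    expression: "object"  # pandas DataFrame (gene_id, read_count, gene_length, tpm)
    manifest: dict

    def write_all(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "genome.fa"), "w") as fh:
            for name, seq in self.genome.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        with open(os.path.join(outdir, "cres.bed"), "w") as fh:
            for cre in self.cres:
                fh.write(
                    f"{cre.seq_id}\t{cre.start}\t{cre.end}\t{cre.gene_id}\t"
                    f"{int(cre.bound)}\t+\n"
                )
        with open(os.path.join(outdir, "peaks.bed"), "w") as fh:
            for chrom, start, end in self.peaks:
                fh.write(f"{chrom}\t{start}\t{end}\n")
        for label, track in (("sample", self.cut_track), ("control", self.control_track)):
            with open(os.path.join(outdir, f"cuts_{label}.bedgraph"), "w") as fh:
                for chrom, arr in track.items():
                    for i, v in enumerate(arr):
                        if v:
                            fh.write(f"{chrom}\t{i}\t{i + 1}\t{v:g}\n")
        with open(os.path.join(outdir, "genes.gff3"), "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes:
                fh.write(
                    f"{g.seq_id}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.id}\n"
                )
        self.expression.to_csv(os.path.join(outdir, "expression.tsv"), sep="\t", index=False)
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=1)


def simulate_genome_tracks(
    config: GenomeSimConfig, motif: MotifModel, occupancy_plan: list[bool] | None = None
) -> GenomeSim:
    """Toy genome with planted CREs, peaks, cut tracks and expression.

    Per gene: the promoter (upstream window) receives 0..max_cres planted
    copies of the motif consensus; each is bound per ``occupancy_plan`` (or
    Bernoulli(config.occupancy)). A peak covers each promoter. Cut counts
    are Poisson with peak elevation and occupancy-dependent dips at bound
    CRE cores; the control track is flat background with a residual dip.
    Expression counts are Poisson with a multiplicative boost per bound
    promoter CRE. Draw order: genome bases, CRE placement, occupancy,
    sample track, control track, expression.
    """
    from .cistrome_context import tpm as tpm_table
    from .genome_scan import GeneModel

    rng = np.random.default_rng(config.rng_seed)
    cons = motif.consensus
    Lm = len(cons)
    slot = config.promoter_window + config.gene_length + 600  # per-gene stride
    if config.n_genes * slot > config.genome_length:
        raise ValueError("genome too short for the requested gene grid")

    genome = rng.integers(0, 4, size=config.genome_length)
    genes: list[GeneModel] = []
    cres: list[PlantedCRE] = []
    peaks: list[tuple[str, int, int]] = []
    cons_codes = encode(cons)

    plan_iter = iter(occupancy_plan) if occupancy_plan is not None else None
    for gi in range(config.n_genes):
        g_start = gi * slot + config.promoter_window + 300
        gene = GeneModel(f"g{gi}", config.chrom, "+", g_start, g_start + config.gene_length)
        genes.append(gene)
        n_cre = int(rng.integers(0, config.max_cres_per_promoter + 1))
        # non-overlapping CRE slots within the promoter
        positions = []
        attempts = 0
        while len(positions) < n_cre and attempts < 50:
            attempts += 1
            p = int(rng.integers(g_start - config.promoter_window, g_start - Lm))
            if all(abs(p - q) >= Lm + 10 for q in positions):
                positions.append(p)
        for p in sorted(positions):
            genome[p : p + Lm] = cons_codes
            if plan_iter is not None:
                bound = bool(next(plan_iter))
            else:
                bound = bool(rng.random() < config.occupancy)
            cres.append(PlantedCRE(config.chrom, p, p + Lm, gene.id, bound))
        peaks.append(
            (config.chrom, max(0, g_start - config.promoter_window - 50), g_start + config.peak_halfwidth)
        )

    base_arr = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    genome_str = base_arr[genome].tobytes().decode()

    lam = np.full(config.genome_length, config.background_cut_rate)
    for chrom, start, end in peaks:
        lam[start:end] *= config.peak_cut_multiplier
    for cre in cres:
        if cre.bound:
            lam[cre.start : cre.end] *= 1 - config.dip_fraction
    cut = rng.poisson(lam).astype(float)

    lam_ctrl = np.full(config.genome_length, config.background_cut_rate)
    for cre in cres:
        lam_ctrl[cre.start : cre.end] *= 1 - config.control_dip_fraction
    control = rng.poisson(lam_ctrl).astype(float)

    bound_per_gene = {g.id: 0 for g in genes}
    for cre in cres:
        if cre.bound:
            bound_per_gene[cre.gene_id] += 1
    mu = np.array(
        [config.expression_base * (1 + config.cre_expression_effect) ** bound_per_gene[g.id]
         for g in genes]
    )
    counts = rng.poisson(mu)
    expression = tpm_table(counts, [g.length for g in genes], [g.id for g in genes])

    manifest = {
        "rng_seed": config.rng_seed,
        "n_genes": config.n_genes,
        "n_cres": len(cres),
        "n_bound": sum(c.bound for c in cres),
        "motif_consensus": cons,
        "bound_per_gene": bound_per_gene,
    }
    return GenomeSim(
        genome={config.chrom: genome_str},
        genes=genes,
        cres=cres,
        peaks=peaks,
        cut_track={config.chrom: cut},
        control_track={config.chrom: control},
        expression=expression,
        manifest=manifest,
    )


def consensus_motif(consensus: str, p: float = 0.85, motif_id: str = "sim_tf") -> MotifModel:
    """A sharply peaked MotifModel around a consensus (off-bases share 1-p)."""
    codes = encode(consensus)
    if (codes < 0).any():
        raise ValueError("consensus must be ACGT only")
    L = len(consensus)
    pfm = np.full((4, L), (1 - p) / 3 * 1000.0)
    pfm[codes, np.arange(L)] = p * 1000.0
    return MotifModel.from_counts(motif_id, pfm, pseudocount=1.0, name=motif_id)
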
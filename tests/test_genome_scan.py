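import itertools

import numpy as np
import pytest

from seaati._alphabet import revcomp
from seaati.genome_scan import (
    GeneModel,
    PeakSet,
    metagene_profile,
    pwm_from_ppm,
    pwm_threshold,
    read_bed,
    read_gff3_genes,
    scan_sequences,
    ths_enrichment,
    tss_window_enrichment,
    write_bed,
)


def random_ppm(L, seed, concentration=0.5):
    rng = np.random.default_rng(seed)
    ppm = rng.dirichlet(np.ones(4) * concentration, size=L).T
    return np.clip(ppm, 1e-6, None) / np.clip(ppm, 1e-6, None).sum(axis=0, keepdims=True)


def exhaustive_threshold(ppm, background, pvalue, score_scale=1000):
    """Independent oracle: enumerate all 4^L sequences."""
    L = ppm.shape[1]
    int_matrix = np.floor(np.log2(ppm / background[:, None]) * score_scale).astype(int)
    scores, probs = [], []
    for seq in itertools.product(range(4), repeat=L):
        scores.append(sum(int_matrix[b, j] for j, b in enumerate(seq)))
        p = 1.0
        for b in seq:
            p *= background[b]
        probs.append(p)
    scores = np.array(scores)
    probs = np.array(probs)
    candidates = np.unique(scores)
    for t in candidates:
        if probs[scores >= t].sum() <= pvalue + 1e-15:
            return int(t)
    return int(scores.max()) + 1


def soft_ppm(consensus, p=0.9):
    from seaati._alphabet import encode

    codes = encode(consensus)
    ppm = np.full((4, len(consensus)), (1 - p) / 3)
    ppm[codes, np.arange(len(consensus))] = p
    return ppm


class TestPwmThreshold:
    def test_uniform_bg_minimal_pvalue_gives_consensus_score(self):
        ppm = soft_ppm("TTGAC", 0.9)
        pwm, thr = pwm_threshold(ppm, pvalue=0.25**5)
        assert thr == pwm.int_matrix.max(axis=0).sum()

    def test_pvalue_one_gives_min_score(self):
        ppm = soft_ppm("TTGAC", 0.9)
        pwm, thr = pwm_threshold(ppm, pvalue=1.0)
        assert thr == pwm.int_matrix.min(axis=0).sum()

    def test_matches_exhaustive_enumeration_uniform_bg(self):
        bg = np.full(4, 0.25)
        for seed in range(10):
            L = 3 + seed % 4
            ppm = random_ppm(L, seed)
            _, thr = pwm_threshold(ppm, pvalue=1e-3)
            assert thr == exhaustive_threshold(ppm, bg, 1e-3)

    def test_matches_exhaustive_enumeration_skewed_bg(self):
        bg = np.array([0.4, 0.1, 0.1, 0.4])
        ppm = random_ppm(6, 99)
        _, thr = pwm_threshold(ppm, background=bg, pvalue=1e-3)
        assert thr == exhaustive_threshold(ppm, bg, 1e-3)

    def test_invalid_pvalue(self):
        with pytest.raises(ValueError):
            pwm_threshold(soft_ppm("ACGT"), pvalue=0)

    def test_degenerate_background_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            pwm_from_ppm(soft_ppm("ACGT"), background=[0.5, 0.5, 0.0, 0.0])


class TestScanSequences:
    def test_embedded_consensus_found(self):
        ppm = soft_ppm("TTGACCA", 0.95)
        pwm, thr = pwm_threshold(ppm, pvalue=1e-4)
        seq = "A" * 10 + "TTGACCA" + "G" * 10
        hits = scan_sequences({"chr1": seq}, pwm, thr)
        fwd = [h for h in hits if h.strand == "+"]
        assert len(fwd) == 1 and fwd[0].start == 10

    def test_strand_mirror_invariance(self):
        ppm = soft_ppm("TTGACCA", 0.95)
        pwm, thr = pwm_threshold(ppm, pvalue=1e-4)
        rng = np.random.default_rng(3)
        base = np.frombuffer(b"ACGT", dtype=np.uint8)
        seq = base[rng.integers(0, 4, 500)].tobytes().decode()
        seq = seq[:100] + "TTGACCA" + seq[107:]
        hits_f = scan_sequences({"s": seq}, pwm, thr)
        hits_r = scan_sequences({"s": revcomp(seq)}, pwm, thr)
        L = len(seq)
        mirrored = {(L - h.end, L - h.start, "-" if h.strand == "+" else "+", h.score)
                    for h in hits_f}
        got = {(h.start, h.end, h.strand, h.score) for h in hits_r}
        assert got == mirrored

    def test_planted_sites_full_recall(self):
        rng = np.random.default_rng(4)
        base = np.frombuffer(b"ACGT", dtype=np.uint8)
        genome = list(base[rng.integers(0, 4, 100_000)].tobytes().decode())
        starts = sorted(rng.choice(np.arange(0, 99_000, 1000), size=50, replace=False))
        consensus = "TTGACGTCAT"
        for s in starts:
            genome[s : s + 10] = consensus
        seq = "".join(genome)
        ppm = soft_ppm(consensus, 0.95)
        pwm, thr = pwm_threshold(ppm, pvalue=1e-4)
        hits = scan_sequences({"chr1": seq}, pwm, thr)
        found = {h.start for h in hits if h.strand == "+"}
        assert set(starts) <= found

    def test_bed_roundtrip(self, tmp_path):
        ppm = soft_ppm("TTGACCA", 0.95)
        pwm, thr = pwm_threshold(ppm, pvalue=1e-4)
        hits = scan_sequences({"c": "A" * 5 + "TTGACCA" + "C" * 5}, pwm, thr)
        p = tmp_path / "hits.bed"
        write_bed(hits, p)
        peaks = read_bed(p)
        assert peaks.intervals[0][1] == hits[0].start


class TestPeakSet:
    def test_overlaps_merged(self):
        ps = PeakSet([("c", 0, 100), ("c", 50, 150), ("c", 200, 300)])
        assert ps.intervals == [("c", 0, 150), ("c", 200, 300)]
        assert ps.total_bp() == 250

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            PeakSet([("c", 10, 10)])


class TestThsEnrichment:
    def _hits(self, positions, L=10):
        from seaati.genome_scan import GenomicHit

        return [GenomicHit("c", p, p + L, "+", 0) for p in positions]

    def test_uniform_density_ratio_one(self):
        # 10 hits in 1 kb peaks, 90 in 9 kb outside: equal densities
        peaks = PeakSet([("c", 0, 1000)])
        hits = self._hits(list(range(50, 1000, 100)) + list(range(1050, 9950, 99)))
        in_n = sum(peaks.contains("c", (h.start + h.end) // 2) for h in hits)
        ratio = ths_enrichment(hits, peaks, 10_000)
        expected = ((in_n + 1) / 1000) / ((len(hits) - in_n + 1) / 9000)
        assert ratio == pytest.approx(expected)

    def test_all_hits_inside(self):
        peaks = PeakSet([("c", 0, 1000)])
        ratio = ths_enrichment(self._hits(range(10, 900, 30)), peaks, 100_000)
        assert ratio > 50

    def test_peaks_cover_genome_error(self):
        with pytest.raises(ValueError, match="whole genome"):
            ths_enrichment([], PeakSet([("c", 0, 100)]), 100)

    def test_planted_odds_recovered(self):
        rng = np.random.default_rng(5)
        peaks = PeakSet([("c", i * 10_000, i * 10_000 + 1000) for i in range(10)])
        genome_length = 100_000
        inside = [int(rng.integers(i * 10_000, i * 10_000 + 990)) for i in range(10) for _ in range(20)]
        ratio = ths_enrichment(self._hits(inside), peaks, genome_length)
        # all 200 hits inside 10 kb of peaks vs pseudocount outside
        expected = ((200 + 1) / 10_000) / (1 / 90_000)
        assert ratio == pytest.approx(expected, rel=1e-9)


class TestMetagene:
    def _genes(self):
        return [
            GeneModel("g1", "c", "+", 5000, 6000),
            GeneModel("g2", "c", "-", 20_000, 22_000),
        ]

    def _hit(self, pos):
        from seaati.genome_scan import GenomicHit

        return GenomicHit("c", pos, pos + 10, "+", 0)

    def test_tss_spike(self):
        genes = self._genes()
        hits = [self._hit(4995), self._hit(21_990)]  # midpoints at both TSSs
        prof = metagene_profile(hits, genes, flank=1000, bin_size=50)
        spike = prof[prof["count"] > 0]
        assert len(spike) == 1
        assert spike.iloc[0]["bin_start"] == 0
        assert spike.iloc[0]["count"] == 2

    def test_upstream_spike_strand_aware(self):
        genes = self._genes()
        # 50 bp upstream of each TSS (strand-aware)
        hits = [self._hit(5000 - 50 - 5), self._hit(22_000 + 50 - 1 - 5)]
        prof = metagene_profile(hits, genes, flank=1000, bin_size=50)
        spike = prof[prof["count"] > 0]
        assert len(spike) == 1
        assert spike.iloc[0]["bin_start"] == -50
        assert spike.iloc[0]["count"] == 2

    def test_mass_conservation(self):
        rng = np.random.default_rng(6)
        genes = self._genes()
        hits = [self._hit(int(p)) for p in rng.integers(3000, 24_000, 300)]
        prof = metagene_profile(hits, genes, flank=1000, bin_size=50)
        mapped = 0
        for g in genes:
            lo, hi = g.start - 1000, g.end + 1000
            mapped += sum(lo <= (h.start + h.end) // 2 < hi for h in hits)
        assert prof["count"].sum() == mapped

    def test_uniform_hits_flat_profile(self):
        genes = [GeneModel("g", "c", "+", 10_000, 12_000)]  # body length == rescale target
        hits = [self._hit(p) for p in range(9000, 13_000, 10)]
        prof = metagene_profile(hits, genes, body_length=2000, flank=1000, bin_size=100)
        counts = prof["count"].to_numpy()
        assert counts.std() / counts.mean() < 0.35


class TestTssWindowEnrichment:
    def _setup(self, per_gene_hits):
        genes = [GeneModel(f"g{i}", "c", "+", 10_000 * (i + 1), 10_000 * (i + 1) + 2000)
                 for i in range(20)]
        from seaati.genome_scan import GenomicHit

        hits = []
        for i, g in enumerate(genes):
            for _ in range(per_gene_hits[i]):
                hits.append(GenomicHit("c", g.tss - 100, g.tss - 90, "+", 0))
        expr = {g.id: float(i) for i, g in enumerate(genes)}
        return hits, genes, expr

    def test_identical_counts_ratio_one(self):
        hits, genes, expr = self._setup([2] * 20)
        assert tss_window_enrichment(hits, genes, expr) == pytest.approx(1.0)

    def test_hits_only_at_top_genes(self):
        counts = [0] * 17 + [5, 5, 5]
        hits, genes, expr = self._setup(counts)
        assert tss_window_enrichment(hits, genes, expr) > 1

    def test_planted_threefold_recovered(self):
        rng = np.random.default_rng(7)
        n = 200
        genes = [GeneModel(f"g{i}", "c", "+", 5000 * (i + 1), 5000 * (i + 1) + 1000)
                 for i in range(n)]
        expr = {g.id: float(i) for i, g in enumerate(genes)}
        from seaati.genome_scan import GenomicHit

        hits = []
        for i, g in enumerate(genes):
            lam = 3.0 if i >= n - n * 15 // 100 else 1.0
            for _ in range(rng.poisson(lam)):
                hits.append(GenomicHit("c", g.tss - 200, g.tss - 190, "+", 0))
        ratio = tss_window_enrichment(hits, genes, expr)
        assert 2.0 < ratio < 4.5

    def test_too_few_genes(self):
        hits, genes, expr = self._setup([1] * 20)
        with pytest.raises(ValueError):
            tss_window_enrichment(hits, genes[:1], expr)


class TestGff3:
    def test_read_genes(self, tmp_path):
        p = tmp_path / "genes.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tID=gA\n"
            "chr1\tsrc\texon\t1001\t1200\t.\t+\t.\tParent=gA\n"
            "chr1\tsrc\tgene\t5001\t6000\t.\t-\t.\tID=gB\n"
        )
        genes = read_gff3_genes(p)
        assert [g.id for g in genes] == ["gA", "gB"]
        assert genes[0].start == 1000 and genes[0].end == 2000
        assert genes[0].tss == 1000
        assert genes[1].tss == 5999  # minus strand
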
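import numpy as np
import pytest

from seaati.motif_curation import (
    CurationFilters,
    align_motifs,
    classify_motifs,
    curate_motifs,
    dedup_motifs,
    motif_activity,
    read_jaspar_string,
    specificity_contrast,
    write_jaspar,
    read_jaspar,
)
from seaati.motif_discovery import MotifModel


def motif_from_ppm(ppm, motif_id="m", scale=1000.0, **kw):
    ppm = np.asarray(ppm, dtype=float)
    return MotifModel.from_counts(motif_id, ppm * scale, pseudocount=0.01, **kw)


def soft_consensus_ppm(consensus, p=0.9):
    from seaati._alphabet import encode

    codes = encode(consensus)
    ppm = np.full((4, len(consensus)), (1 - p) / 3)
    ppm[codes, np.arange(len(consensus))] = p
    return ppm


def noisy_ppm(base_ppm, alpha, seed=0):
    rng = np.random.default_rng(seed)
    noise = rng.dirichlet(np.ones(4), size=base_ppm.shape[1]).T
    mix = (1 - alpha) * base_ppm + alpha * noise
    return mix / mix.sum(axis=0, keepdims=True)


class TestCurateMotifs:
    def test_homopolymer_rejected_by_consensus_ic(self):
        ppm = soft_consensus_ppm("A" * 10, p=0.99)
        m = motif_from_ppm(ppm, "polyA")
        retained, rejected = curate_motifs([m])
        assert retained == []
        assert "consensus_ic" in rejected[0][1]

    def test_low_total_ic_rejected(self):
        # near-uniform columns: total IC ~ 0.3 < 2
        ppm = soft_consensus_ppm("ACGTACGT", p=0.30)
        m = motif_from_ppm(ppm, "weak")
        retained, rejected = curate_motifs([m])
        assert retained == [] and "total_ic" in rejected[0][1]

    def test_good_motif_retained(self):
        ppm = soft_consensus_ppm("ACGTACGTACGT", p=0.75)
        m = motif_from_ppm(ppm, "good")
        retained, rejected = curate_motifs([m])
        assert retained == [m]

    def test_filters_are_pure_predicates(self):
        ppm = soft_consensus_ppm("ACGTACGTACGT", p=0.75)
        retained, _ = curate_motifs([motif_from_ppm(ppm, "good")])
        again, _ = curate_motifs(retained)
        assert again == retained

    def test_invalid_filter_bounds(self):
        with pytest.raises(ValueError):
            CurationFilters(total_ic_min=30, total_ic_max=2)


class TestAlignMotifs:
    def test_self_alignment(self):
        m = motif_from_ppm(soft_consensus_ppm("TTGACCAT"))
        al = align_motifs(m, m)
        assert al.pearson_r == pytest.approx(1.0)
        assert al.offset == 0 and al.strand == "fwd"

    def test_revcomp_alignment(self):
        m = motif_from_ppm(soft_consensus_ppm("TTGACCAT"))
        al = align_motifs(m, m.revcomp())
        assert al.pearson_r == pytest.approx(1.0)
        assert al.strand == "revcomp"

    def test_shifted_motif_found_at_offset(self):
        ppm = soft_consensus_ppm("TTGACCATGG")
        m1 = motif_from_ppm(ppm)
        m2 = motif_from_ppm(ppm[:, 2:])  # m2 = columns 2.. of m1
        al = align_motifs(m1, m2)
        assert al.offset == 2 and al.pearson_r == pytest.approx(1.0)

    def test_exhaustive_oracle(self):
        # brute-force maximization over offsets/strands on shuffled columns
        rng = np.random.default_rng(1)
        ppm1 = soft_consensus_ppm("TTGACCAT", 0.8)
        ppm2 = ppm1[:, rng.permutation(8)]
        m1, m2 = motif_from_ppm(ppm1, "a"), motif_from_ppm(ppm2, "b")
        al = align_motifs(m1, m2, min_overlap=4)

        best = -np.inf
        for ppm2v in (m2.ppm, m2.ppm[::-1, ::-1]):
            for off in range(-4, 5):
                lo, hi = max(0, off), min(8, off + 8)
                if hi - lo < 4:
                    continue
                a = m1.ppm[:, lo:hi].ravel()
                b = ppm2v[:, lo - off : hi - off].ravel()
                if a.std() > 0 and b.std() > 0:
                    best = max(best, np.corrcoef(a, b)[0, 1])
        assert al.pearson_r == pytest.approx(best, abs=1e-12)

    def test_min_overlap_violation(self):
        m = motif_from_ppm(soft_consensus_ppm("ACG"))
        with pytest.raises(ValueError):
            align_motifs(m, m, min_overlap=4)


class TestDedupMotifs:
    def _pair_with_r(self, target_r, seed=0):
        """Mix base with Dirichlet noise until the aligned r brackets target."""
        base = soft_consensus_ppm("TTGACCATGG", 0.85)
        m1 = motif_from_ppm(base, "base")
        lo, hi = 0.0, 1.0
        for _ in range(50):
            alpha = (lo + hi) / 2
            m2 = motif_from_ppm(noisy_ppm(base, alpha, seed), "noisy")
            r = align_motifs(m1, m2).pearson_r
            if r > target_r:
                lo = alpha
            else:
                hi = alpha
        return m1, motif_from_ppm(noisy_ppm(base, (lo + hi) / 2, seed), "noisy")

    def test_pair_above_threshold_merges_keeping_higher_ic(self):
        m1, m2 = self._pair_with_r(0.95)
        out = dedup_motifs([m1, m2])
        assert len(out) == 1
        assert out[0].id == max((m1, m2), key=lambda m: m.total_ic).id

    def test_pair_below_threshold_retained(self):
        m1, m2 = self._pair_with_r(0.89)
        r = align_motifs(m1, m2).pearson_r
        assert r < 0.90
        assert len(dedup_motifs([m1, m2])) == 2

    def test_chain_components_collapse(self):
        base = soft_consensus_ppm("TTGACCATGG", 0.85)
        a = motif_from_ppm(base, "A")
        b = motif_from_ppm(noisy_ppm(base, 0.12, seed=3), "B")
        c = motif_from_ppm(noisy_ppm(base, 0.24, seed=3), "C")
        rab = align_motifs(a, b).pearson_r
        rbc = align_motifs(b, c).pearson_r
        if rab > 0.9 and rbc > 0.9:
            out = dedup_motifs([a, b, c])
            assert len(out) == 1

    def test_idempotent_and_order_invariant(self):
        m1, m2 = self._pair_with_r(0.95, seed=4)
        m3 = motif_from_ppm(soft_consensus_ppm("GGGGCCCCAA", 0.8), "other")
        out1 = dedup_motifs([m1, m2, m3])
        out2 = dedup_motifs([m3, m2, m1])
        assert {m.id for m in out1} == {m.id for m in out2}
        assert [m.id for m in dedup_motifs(out1)] == [m.id for m in out1]


class TestClassifyMotifs:
    def _reference(self):
        return [
            motif_from_ppm(soft_consensus_ppm("TTGACTTT", 0.85), "REF1", name="WRKY_ref"),
            motif_from_ppm(soft_consensus_ppm("CACGTGCA", 0.85), "REF2", name="bHLH_ref"),
        ]

    def test_identical_is_reported(self):
        ref = self._reference()
        df = classify_motifs([motif_from_ppm(ref[0].ppm, "q")], ref)
        assert df.iloc[0]["category"] == "reported"
        assert df.iloc[0]["assigned_name"] == "WRKY_ref"

    def test_distinct_gets_seaatid_name(self):
        ref = self._reference()
        q = motif_from_ppm(soft_consensus_ppm("AGAGAGAGAG", 0.95), "q")
        df = classify_motifs([q], ref)
        assert df.iloc[0]["category"] == "distinct"
        assert df.iloc[0]["assigned_name"].startswith("seaATId-")

    def test_similar_band(self):
        ref = self._reference()
        base = ref[0].ppm
        for alpha in np.linspace(0.1, 0.9, 17):
            q = motif_from_ppm(noisy_ppm(base, alpha, seed=5), "q")
            r = align_motifs(q, ref[0]).pearson_r
            if 0.70 <= r < 0.85:
                df = classify_motifs([q], ref)
                assert df.iloc[0]["category"] == "similar"
                break
        else:
            pytest.skip("no alpha landed in the similar band")

    def test_revcomp_reference_invariance(self):
        ref = self._reference()
        ref_rc = [ref[0].revcomp(), ref[1]]
        q = motif_from_ppm(ref[0].ppm, "q")
        cat1 = classify_motifs([q], ref).iloc[0]["category"]
        cat2 = classify_motifs([q], ref_rc).iloc[0]["category"]
        assert cat1 == cat2 == "reported"

    def test_empty_reference_warns_all_distinct(self):
        q = motif_from_ppm(soft_consensus_ppm("TTGACCAT"), "q")
        with pytest.warns(UserWarning, match="empty reference"):
            df = classify_motifs([q], [])
        assert df.iloc[0]["category"] == "distinct"


class TestMotifActivity:
    def test_lib_equals_ctrl_zero(self, uniform_lib):
        lib = uniform_lib(300, seed=1)
        m = motif_from_ppm(soft_consensus_ppm("TTGACCAT", 0.9))
        assert motif_activity(lib, m, lib) == pytest.approx(0.0)

    def test_absent_from_both_zero(self, make_lib):
        lib = make_lib(["A" * 30] * 20)
        m = motif_from_ppm(soft_consensus_ppm("CCCGGGCC", 0.97))
        assert motif_activity(lib, m, lib) == pytest.approx(0.0)

    def test_planted_motif_beats_nonplanted_reference(self, uniform_lib, make_lib):
        rng = np.random.default_rng(6)
        base = np.frombuffer(b"ACGT", dtype=np.uint8)
        seqs = []
        for i in range(2000):
            s = base[rng.integers(0, 4, 30)].tobytes().decode()
            if i % 4 == 0:
                s = s[:6] + "TTGACCAT" + s[14:]
            seqs.append(s)
        lib = make_lib(seqs)
        from seaati.ligand_io import shuffle_control

        ctrl = shuffle_control(lib, 0)
        planted = motif_from_ppm(soft_consensus_ppm("TTGACCAT", 0.9), "planted")
        other = motif_from_ppm(soft_consensus_ppm("CACGTGCA", 0.9), "other")
        assert motif_activity(lib, planted, ctrl) > motif_activity(lib, other, ctrl)


class TestSpecificityContrast:
    def test_identical_rows_error(self):
        import pandas as pd

        act = pd.DataFrame(np.ones((4, 3)), index=list("abcd"))
        cats = {"a": "distinct", "b": "reported", "c": "reported", "d": "similar"}
        with pytest.raises(ValueError):
            specificity_contrast(act, cats)

    def test_constructed_contrast_positive_t(self):
        import pandas as pd

        rng = np.random.default_rng(7)
        rows = [rng.normal(0, 2.0, 6) for _ in range(6)] + [
            rng.normal(0, 1.0, 6) for _ in range(6)
        ]
        act = pd.DataFrame(rows, index=[f"m{i}" for i in range(12)])
        cats = {f"m{i}": ("distinct" if i < 6 else "reported") for i in range(12)}
        t, p, sds = specificity_contrast(act, cats)
        assert t > 0 and p < 0.05

    def test_permuted_labels_small_t(self):
        import pandas as pd

        rng = np.random.default_rng(8)
        act = pd.DataFrame(rng.normal(0, 1, (20, 5)), index=[f"m{i}" for i in range(20)])
        ts = []
        for _ in range(20):
            labels = rng.permutation(["distinct"] * 10 + ["reported"] * 10)
            cats = dict(zip(act.index, labels))
            t, _, _ = specificity_contrast(act, cats)
            ts.append(t)
        assert abs(np.mean(ts)) < 1.0


class TestJasparIO:
    JASPAR_TEXT = """>MA0001.1 TEST1
A [ 10 0 0 5 ]
C [ 0 10 0 5 ]
G [ 0 0 10 0 ]
T [ 0 0 0 0 ]
"""

    def test_read(self):
        motifs = read_jaspar_string(self.JASPAR_TEXT)
        assert len(motifs) == 1
        m = motifs[0]
        assert m.length == 4
        assert m.pfm[0, 0] == 10
        assert m.consensus[:3] == "ACG"

    def test_roundtrip(self, tmp_path):
        motifs = read_jaspar_string(self.JASPAR_TEXT)
        p = tmp_path / "out.jaspar"
        write_jaspar(motifs, p)
        back = read_jaspar(p)
        assert np.allclose(back[0].pfm, motifs[0].pfm)
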
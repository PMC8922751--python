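"""MEME I/O, PWM similarity, motif calling, scanning, profiles."""

import itertools

import numpy as np
import pytest

from tssmotif import motifs
from tssmotif.core import NUCLEOTIDES, Pwm, SequenceRecord

from .conftest import consensus_pwm, soft_pwm


def random_library(n_motifs: int, seed: int) -> motifs.MotifLibrary:
    rng = np.random.default_rng(seed)
    pwms = []
    for i in range(n_motifs):
        w = int(rng.integers(4, 15))
        mat = rng.dirichlet(np.ones(4), size=w).T
        pwms.append(Pwm(mat, name=f"m{i}", nsites=int(rng.integers(5, 50))))
    bg = rng.dirichlet(np.ones(4))
    background = dict(zip("ACGT", bg))
    return motifs.MotifLibrary(pwms, background=background)


class TestMemeIO:
    def test_round_trip_three_motifs(self, tmp_path):
        lib = random_library(3, seed=0)
        path = tmp_path / "lib.meme"
        motifs.write_meme(lib, path)
        back = motifs.read_meme(path)
        assert back.names() == lib.names()
        for a, b in zip(lib, back):
            assert np.allclose(a.matrix, b.matrix, atol=1e-6)
            assert a.nsites == b.nsites
        for c in "ACGT":
            assert back.background[c] == pytest.approx(lib.background[c], abs=1e-6)

    def test_uniform_motif_serialization(self, tmp_path):
        lib = motifs.MotifLibrary([Pwm(np.full((4, 4), 0.25), name="u")])
        path = tmp_path / "u.meme"
        motifs.write_meme(lib, path)
        lines = path.read_text().splitlines()
        assert lines.count("0.250000 0.250000 0.250000 0.250000") == 4

    def test_round_trip_100_random_libraries(self, tmp_path):
        for seed in range(100):
            lib = random_library(3, seed=seed)
            path = tmp_path / f"lib{seed}.meme"
            motifs.write_meme(lib, path)
            back = motifs.read_meme(path)
            for a, b in zip(lib, back):
                assert np.allclose(a.matrix, b.matrix, atol=1e-6)

    def test_biopython_parses_our_output(self, tmp_path):
        """Files we write conform to the minimal MEME motif format as
        read by an independent parser."""
        from Bio import motifs as bio_motifs

        lib = random_library(4, seed=7)
        for m in lib:  # Biopython rebuilds counts as prob * nsites
            m.nsites = 100_000
        path = tmp_path / "conform.meme"
        motifs.write_meme(lib, path)
        with open(path) as fh:
            parsed = bio_motifs.parse(fh, "minimal")
        assert [m.name for m in parsed] == lib.names()
        for ours, theirs in zip(lib, parsed):
            for j, letter in enumerate("ACGT"):
                ours_row = ours.matrix[NUCLEOTIDES.index(letter)]
                theirs_row = np.array(theirs.pwm[letter])
                assert np.allclose(ours_row, theirs_row, atol=1e-4)

    @pytest.mark.parametrize(
        "text, fragment",
        [
            ("MEME version 4\n\nMOTIF\n", "name"),
            (
                "MEME version 4\n\nMOTIF x\nletter-probability matrix: "
                "alength= 4 w= 3\n0.1 0.2 0.3 0.4\n0.1 0.2 0.3\n",
                "expected 4",
            ),
            ("no header at all\n", "version"),
        ],
    )
    def test_malformed_files_raise_with_line_number(self, tmp_path, text, fragment):
        path = tmp_path / "bad.meme"
        path.write_text(text)
        with pytest.raises(motifs.MemeParseError) as exc:
            motifs.read_meme(path)
        assert fragment in str(exc.value)


class TestSimilarity:
    def test_self_similarity_is_one(self):
        x = soft_pwm(width=8)
        score, offset, degenerate = motifs.pwm_similarity(x, x)
        assert score == pytest.approx(1.0)
        assert offset == 0
        assert not degenerate

    def test_constant_matrices_are_degenerate(self):
        u = Pwm(np.full((4, 6), 0.25), name="u")
        score, _, degenerate = motifs.pwm_similarity(u, u)
        assert degenerate and score == 0.0

    def test_symmetry(self):
        a, b = soft_pwm(width=6, seed=1), soft_pwm(width=9, seed=2)
        sa = motifs.pwm_similarity(a, b)
        sb = motifs.pwm_similarity(b, a)
        assert sa[0] == pytest.approx(sb[0])

    def test_padded_copy_found_by_offset_search(self):
        x = soft_pwm(width=6, seed=4)
        padded = Pwm(
            np.hstack([np.full((4, 3), 0.25), x.matrix]), name="padded"
        )
        score, offset, _ = motifs.pwm_similarity(padded, x)
        # brute-force: correlation is maximal when x aligns at column 3
        assert score == pytest.approx(1.0)
        assert offset == 3

    def test_brute_force_offset_enumeration(self):
        rng = np.random.default_rng(5)
        a = Pwm(rng.dirichlet(np.ones(4), size=7).T, name="a")
        b = Pwm(rng.dirichlet(np.ones(4), size=5).T, name="b")
        score, offset, _ = motifs.pwm_similarity(a, b)
        best = -np.inf
        best_off = None
        for off in range(-(b.width - 4), a.width - 4 + 1):
            lo, hi = max(0, off), min(a.width, off + b.width)
            if hi - lo < 4:
                continue
            sa = a.matrix[:, lo:hi].ravel()
            sb = b.matrix[:, lo - off : hi - off].ravel()
            r = np.corrcoef(sa, sb)[0, 1]
            if r > best:
                best, best_off = r, off
        assert score == pytest.approx(best)
        assert offset == best_off

    def test_too_narrow_errors(self):
        a = soft_pwm(width=8)
        with pytest.raises(ValueError):
            motifs.pwm_similarity(a, Pwm(np.full((4, 3), 0.25), name="w3"))


class TestCommonCalling:
    def test_two_fold_presence_is_common(self):
        folds = [{"m"}, set(), set(), {"m"}, set()]
        common, specific = motifs.call_common(folds)
        assert common == {"m"} and specific == set()

    def test_single_fold_presence_is_specific(self):
        folds = [set(), set(), {"m"}, set(), set()]
        common, specific = motifs.call_common(folds)
        assert common == set() and specific == {"m"}

    def test_set_arithmetic_example(self):
        folds = [{"m1"}, {"m1"}, {"m1"}, {"m1"}, {"m1", "m2"}]
        common, specific = motifs.call_common(folds)
        assert common == {"m1"} and specific == {"m2"}

    def test_monotone_in_fold_growth(self):
        rng = np.random.default_rng(6)
        names = [f"m{i}" for i in range(20)]
        folds = [
            {n for n in names if rng.random() < 0.3} for _ in range(5)
        ]
        common, _ = motifs.call_common(folds)
        bigger = [set(f) for f in folds]
        bigger[2] |= {"m0", "m19"}
        common2, _ = motifs.call_common(bigger)
        assert common <= common2


class TestDedup:
    def test_identical_list_collapses_to_singleton(self):
        x = soft_pwm(width=8)
        out = motifs.dedup_novel([x] * 5)
        assert out == [x]

    def test_dissimilar_list_unchanged(self):
        pwms = [consensus_pwm(seed=s, name=f"c{s}") for s in (1, 4, 9)]
        sims = [
            motifs.pwm_similarity(a, b)[0]
            for a, b in itertools.combinations(pwms, 2)
        ]
        assert all(s < 0.8 for s in sims)  # precondition of the scenario
        assert motifs.dedup_novel(pwms) == pwms

    def test_greedy_chain_keeps_first_and_last(self):
        # a ~ b, b ~ c, a !~ c: greedy order keeps {a, c}
        rng = np.random.default_rng(8)
        base = rng.dirichlet(np.ones(4), size=8).T
        drift = rng.dirichlet(np.ones(4), size=8).T

        def mix(t):
            m = (1 - t) * base + t * drift
            return Pwm(m / m.sum(axis=0), name=f"t{t}")

        a, b, c = mix(0.0), mix(0.35), mix(0.7)
        sim = lambda x, y: motifs.pwm_similarity(x, y)[0]
        assert sim(a, b) >= 0.8 and sim(b, c) >= 0.8 and sim(a, c) < 0.8
        out = motifs.dedup_novel([a, b, c])
        assert out == [a, c]


class TestScan:
    BG = np.full(4, 0.25)

    def brute_force_pvalues(self, motif):
        """All 4^w background-weighted sequences, same discretization."""
        sm = motifs._discretize_motif(motif, self.BG)
        w = motif.width
        totals = {}
        for combo in itertools.product(range(4), repeat=w):
            s = int(sum(sm.int_scores[c, j] for j, c in enumerate(combo)))
            totals[combo] = s
        return sm, totals

    @pytest.mark.parametrize("width", [4, 6])
    def test_pvalues_match_brute_force(self, width):
        motif = soft_pwm(width=width, dominant=0.6, seed=width)
        sm, totals = self.brute_force_pvalues(motif)
        observed = sorted(set(totals.values()))
        for obs in observed[:: max(1, len(observed) // 20)]:
            bf = sum(
                0.25**motif.width for s in totals.values() if s >= obs
            )
            dp = motifs.exact_scan_pvalue(motif, obs, self.BG)
            assert dp == pytest.approx(bf, rel=1e-9)

    def test_uniform_motif_scores_zero_bits(self):
        u = Pwm(np.full((4, 5), 0.25), name="u")
        lib = motifs.MotifLibrary([u])
        rec = SequenceRecord("g", "ACGTACGTACGT", "expressed")
        hits = motifs.scan(lib, [rec], q_threshold=1.0)
        assert all(h.score == pytest.approx(0.0, abs=1e-9) for h in hits)

    def _consensus_and_window(self):
        motif = consensus_pwm(seed=13, name="fwd")
        consensus = "".join(
            NUCLEOTIDES[i] for i in motif.matrix.argmax(axis=0)
        )
        rng = np.random.default_rng(13)
        bg = "".join(rng.choice(list("ACGT"), size=90))
        return motif, consensus, bg

    def test_forward_instance_found(self):
        motif, consensus, bg = self._consensus_and_window()
        rec = SequenceRecord("g", bg[:40] + consensus + bg[40:], "expressed")
        hits = motifs.scan(motifs.MotifLibrary([motif]), [rec])
        assert any(h.offset == 40 for h in hits)

    def test_reverse_complement_instance_not_found(self):
        from tssmotif.core import reverse_complement

        motif, consensus, bg = self._consensus_and_window()
        rc = reverse_complement(consensus)
        assert rc != consensus
        rec = SequenceRecord("g", bg[:40] + rc + bg[40:], "expressed")
        hits = motifs.scan(motifs.MotifLibrary([motif]), [rec])
        assert hits == []

    def test_n_scores_zero_bits(self):
        motif = soft_pwm(width=6, seed=2, name="m")
        lib = motifs.MotifLibrary([motif])
        rec = SequenceRecord("g", "N" * 20, "expressed")
        hits = motifs.scan(lib, [rec], q_threshold=1.0)
        assert all(h.score == pytest.approx(0.0, abs=1e-9) for h in hits)

    def test_q_values_are_bh_consistent(self):
        motif = soft_pwm(width=6, seed=3)
        rng = np.random.default_rng(3)
        recs = [
            SequenceRecord(f"g{i}", "".join(rng.choice(list("ACGT"), 60)), "expressed")
            for i in range(5)
        ]
        hits = motifs.scan(motifs.MotifLibrary([motif]), recs, q_threshold=1.0)
        ps = np.array([h.p_value for h in hits])
        qs = np.array([h.q_value for h in hits])
        expected = motifs.benjamini_hochberg(ps)
        assert np.allclose(qs, expected)
        assert np.all(qs >= ps - 1e-12)

    def test_motif_wider_than_window_skipped(self, caplog):
        motif = soft_pwm(width=12, seed=4)
        rec = SequenceRecord("g", "ACGTACGT", "expressed")
        hits = motifs.scan(motifs.MotifLibrary([motif]), [rec])
        assert hits == []


class TestOccurrenceProfile:
    def test_zero_hits_gives_zero_profiles(self):
        prof = motifs.occurrence_profile([], {"g1": "expressed", "g2": "low"})
        assert set(prof) == {"expressed", "low"}
        assert not prof["expressed"].any() and not prof["low"].any()

    def test_planted_offset_peaks_in_expressed_only(self):
        labels = {f"e{i}": "expressed" for i in range(10)}
        labels.update({f"l{i}": "low" for i in range(10)})
        hits = [
            motifs.MotifHit(f"e{i}", "m", 700, 8, 5.0, 1e-4, 0.01)
            for i in range(10)
        ]
        prof = motifs.occurrence_profile(hits, labels)
        assert prof["expressed"][700] == 1.0
        assert prof["expressed"].sum() == 1.0
        assert not prof["low"].any()

    def test_profiles_bounded(self):
        labels = {"g": "expressed"}
        hits = [
            motifs.MotifHit("g", "m", off, 8, 1.0, 0.05, 0.05)
            for off in (3, 3, 7)  # duplicate offset counts once
        ]
        prof = motifs.occurrence_profile(hits, labels)
        assert prof["expressed"].max() <= 1.0
        assert prof["expressed"][3] == 1.0 and prof["expressed"][7] == 1.0
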
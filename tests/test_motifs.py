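"""Motif scanning against brute-force oracles; overlap/positional/tAI features."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfnoise.motifs import (
    OCCUPANCY_WINDOWS,
    Motif,
    MotifSite,
    count_overlaps,
    occupancy_windows,
    overlap_degeneracy,
    positional_site_counts,
    scan_motif,
    tai,
)
from tfnoise.synthetic import reverse_complement


def brute_force_scan(seq: str, motif: Motif, max_mismatch: int, both_strands: bool) -> dict:
    """Enumerate every window and every variant; minimal Hamming distance."""
    length = len(motif)
    variants = motif.variants()
    out: dict[tuple[int, int], int] = {}
    pools = [variants] + ([[reverse_complement(v) for v in variants]] if both_strands else [])
    for pool in pools:
        for s in range(len(seq) - length + 1):
            window = seq[s : s + length]
            d = min(sum(a != b for a, b in zip(window, v)) for v in pool)
            if d <= max_mismatch:
                key = (s, s + length)
                out[key] = min(d, out.get(key, length + 1))
    return out


class TestScanner:
    def test_exact_substring_found(self, tata):
        sites = scan_motif("GCGTATAAAGC", tata, max_mismatch=0)
        forward = [s for s in sites if s.strand == "+"]
        assert [(s.start, s.end) for s in forward] == [(3, 9)]

    def test_default_mismatch_tolerance_is_two(self, tata):
        import inspect

        assert inspect.signature(scan_motif).parameters["max_mismatch"].default == 2

    def test_iupac_consensus_expansion(self):
        motif = Motif.from_consensus("X", "TAWA")  # W = A or T
        assert sorted(motif.variants()) == ["TAAA", "TATA"]
        sites = scan_motif("CCTATACC", motif, max_mismatch=0, both_strands=False)
        assert [(s.start, s.n_mismatches) for s in sites] == [(2, 0)]

    def test_pwm_expansion_and_cap(self):
        pwm = np.array([[0.9, 0.1, 0.0, 0.0], [0.0, 0.0, 0.0, 1.0]])
        motif = Motif.from_pwm("X", pwm)
        assert sorted(motif.variants()) == ["AT", "CT"]
        big = np.ones((11, 4))  # 4^11 > 10^6 variants
        with pytest.raises(ValueError, match="variants"):
            Motif.from_pwm("huge", big)

    def test_non_acgt_positions_mismatch_everything(self, tata):
        with pytest.warns(UserWarning, match="non-ACGT"):
            sites = scan_motif("GCGTATANAGC", tata, max_mismatch=1)
        hit = [s for s in sites if (s.start, s.end) == (3, 9)]
        assert hit and hit[0].n_mismatches == 1

    def test_sites_sorted_by_start(self, tata, rng):
        seq = "".join(rng.choice(list("ACGT"), size=500))
        sites = scan_motif(seq, tata, max_mismatch=2)
        starts = [s.start for s in sites]
        assert starts == sorted(starts)

    @pytest.mark.parametrize("max_mismatch", [0, 1, 2])
    def test_matches_bruteforce_oracle(self, max_mismatch, rng):
        for _ in range(25):
            seq = "".join(rng.choice(list("ACGT"), size=150))
            motif = Motif.from_consensus(
                "m", "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 9))))
            )
            got = {(s.start, s.end): s.n_mismatches for s in scan_motif(seq, motif, max_mismatch)}
            assert got == brute_force_scan(seq, motif, max_mismatch, True)


class TestOverlaps:
    def test_three_bp_overlap(self):
        a = MotifSite("p", "A", 0, 6, "+", 0)
        b = MotifSite("p", "B", 3, 9, "+", 0)
        stats = count_overlaps([a, b])
        assert stats.n_overlapping_pairs == 1
        assert stats.mean_overlap_length == 3

    def test_k_identical_sites_give_k_choose_2_pairs(self):
        sites = [MotifSite("p", f"t{i}", 10, 16, "+", 0) for i in range(5)]
        assert count_overlaps(sites).n_overlapping_pairs == 10

    def test_empty_site_list_all_zero(self):
        stats = count_overlaps([])
        assert stats.n_sites == 0 and stats.n_overlapping_pairs == 0

    def test_matches_quadratic_oracle_and_reorder_invariance(self, rng):
        sites = [
            MotifSite("p", f"t{i}", s, s + 6, "+", 0)
            for i, s in enumerate(rng.integers(0, 300, size=50))
        ]
        expected = sum(
            1
            for i in range(50)
            for j in range(i + 1, 50)
            if max(sites[i].start, sites[j].start) < min(sites[i].end, sites[j].end)
        )
        assert count_overlaps(sites).n_overlapping_pairs == expected
        shuffled = [sites[i] for i in rng.permutation(50)]
        assert count_overlaps(shuffled).n_overlapping_pairs == expected

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_adding_a_site_never_decreases_pairs(self, seed):
        r = np.random.default_rng(seed)
        sites = [
            MotifSite("p", "t", int(s), int(s) + 6, "+", 0) for s in r.integers(0, 100, size=8)
        ]
        before = count_overlaps(sites).n_overlapping_pairs
        extra = MotifSite("p", "x", int(r.integers(0, 100)), int(r.integers(0, 100)) + 6, "+", 0)
        assert count_overlaps(sites + [extra]).n_overlapping_pairs >= before

    def test_role_category_fractions(self):
        sites = [
            MotifSite("p", "act1", 0, 6, "+", 0),
            MotifSite("p", "act2", 3, 9, "+", 0),
            MotifSite("p", "rep1", 5, 11, "+", 0),
        ]
        roles = {"act1": "activator", "act2": "activator", "rep1": "repressor"}
        stats = count_overlaps(sites, role_map=roles)
        assert stats.pair_category_fractions["activator-activator"] == pytest.approx(1 / 3)
        assert stats.pair_category_fractions["activator-repressor"] == pytest.approx(2 / 3)

    def test_same_tf_pairs_can_be_excluded(self):
        sites = [MotifSite("p", "t", 0, 6, "+", 0), MotifSite("p", "t", 3, 9, "+", 0)]
        assert count_overlaps(sites).n_overlapping_pairs == 1
        assert count_overlaps(sites, exclude_same_tf=True).n_overlapping_pairs == 0


class TestPositionalCounts:
    def test_site_150bp_upstream_in_second_window(self):
        # start-codon at local 1000; local start 850 is 150 bp upstream
        sites = [MotifSite("p", "t", 850, 856, "+", 0)]
        counts = positional_site_counts(sites)
        assert counts["100-200bp upstream"] == 1
        assert counts.sum() == 1

    def test_counts_partition_the_sites(self, rng):
        starts = rng.integers(0, 1005, size=200)
        sites = [MotifSite("p", "t", int(s), int(s) + 5, "+", 0) for s in starts]
        counts = positional_site_counts(sites)
        assert counts.sum() == 200
        # brute-force histogram by upstream distance
        upstream = 1000 - starts
        brute_down = int((upstream <= 0).sum())
        assert counts["downstream"] == brute_down
        for i in range(10):
            expected = int(((upstream > i * 100) & (upstream <= (i + 1) * 100)).sum())
            assert counts[f"{i * 100}-{(i + 1) * 100}bp upstream"] == expected


class TestOccupancyWindows:
    def test_window_list_matches_methodology(self):
        assert len(OCCUPANCY_WINDOWS) == 12
        assert OCCUPANCY_WINDOWS[0] == (-1000, -900)
        assert OCCUPANCY_WINDOWS[8] == (-200, -150)
        assert OCCUPANCY_WINDOWS[-1] == (-50, 10)

    def test_constant_track(self):
        pos = np.arange(-1000, 11)
        vals = np.full(len(pos), 2.5)
        out = occupancy_windows(pos, vals)
        assert np.allclose(out, 2.5)

    def test_step_track_fractional_in_spanning_window(self):
        pos = np.arange(-1000, 11)
        vals = (pos >= -450).astype(float)  # step inside the -500:-400 window
        out = occupancy_windows(pos, vals)
        assert out["-1000:-900"] == 0.0
        assert out["-400:-300"] == 1.0
        assert out["-500:-400"] == pytest.approx(0.5, abs=0.01)

    def test_missing_positions_excluded_with_warning(self):
        pos = np.arange(-1000, -500)
        vals = np.ones(len(pos))
        with pytest.warns(UserWarning, match="covers"):
            out = occupancy_windows(pos, vals)
        assert np.isnan(out["-100:-50"])
        assert out["-1000:-900"] == 1.0

    def test_occupied_threshold(self):
        pos = np.arange(-1000, 11)
        vals = np.where(pos % 2 == 0, 4.0, 0.5)
        out = occupancy_windows(pos, vals, occupied_threshold=1.0)
        assert np.allclose(out, 4.0)  # only above-threshold positions average


class TestTAI:
    def test_all_weights_one(self):
        weights = {"AAA": 1.0, "CCC": 1.0}
        out = tai("AAACCC" * 30, weights)
        assert np.allclose(out["tai"], 1.0)

    def test_geometric_mean_two_codons(self):
        out = tai("TTTGGC", {"TTT": 0.25, "GGC": 1.0})
        assert out.loc["full", "tai"] == pytest.approx(0.5)

    def test_matches_bruteforce_product(self, rng):
        codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
        sense = [c for c in codons if c not in ("TAA", "TAG", "TGA")]
        weights = {c: float(w) for c, w in zip(codons, rng.uniform(0.05, 1.0, size=64))}
        gene = "".join(rng.choice(sense, size=80))
        out = tai(gene, weights)
        for prefix in (5, 10, 40):
            sub = [gene[i : i + 3] for i in range(0, prefix * 3, 3)]
            brute = np.prod([weights[c] for c in sub]) ** (1 / prefix)
            assert out.loc[f"first_{prefix}", "tai"] == pytest.approx(brute)

    def test_prefix_longer_than_gene_flagged(self):
        out = tai("TTTGGC", {"TTT": 0.5, "GGC": 0.5})
        assert out.loc["first_50", "truncated"]
        assert out.loc["first_50", "tai"] == out.loc["full", "tai"]

    def test_internal_stop_codon_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="stop codon"):
            out = tai("TTTTAAGGC", {"TTT": 0.25, "GGC": 1.0})
        assert out.loc["full", "tai"] == pytest.approx(0.5)
        assert out.loc["full", "n_codons"] == 2

    def test_increasing_any_weight_increases_tai(self):
        base = {"TTT": 0.3, "GGC": 0.6}
        low = tai("TTTGGC", base).loc["full", "tai"]
        high = tai("TTTGGC", {"TTT": 0.5, "GGC": 0.6}).loc["full", "tai"]
        assert high > low

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError):
            tai("TTTG", {"TTT": 1.0})


class TestOverlapDegeneracy:
    def test_exact_sites_give_zero_means(self):
        sites = [MotifSite("p", "a", 0, 6, "+", 0), MotifSite("p", "b", 3, 9, "+", 0)]
        out = overlap_degeneracy(sites)
        assert out["mean_mismatches_overlapping"] == 0

    def test_planted_difference_recovered(self):
        sites = [
            MotifSite("p", "a", 0, 6, "+", 2),
            MotifSite("p", "b", 3, 9, "+", 2),
            MotifSite("p", "c", 100, 106, "+", 0),
        ]
        out = overlap_degeneracy(sites)
        assert out["difference"] == pytest.approx(2.0)

    def test_no_overlaps_leaves_category_undefined(self):
        sites = [MotifSite("p", "a", 0, 6, "+", 1)]
        out = overlap_degeneracy(sites)
        assert not out["overlapping_defined"]
        assert np.isnan(out["mean_mismatches_overlapping"])
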
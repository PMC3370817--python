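"""Landmark domain scanner, candidate filtering, residue profiling, and
named-motif pattern matching."""

import re

import numpy as np
import pytest

from mybkit.domain import (
    AMINO_ACIDS,
    BHLH_INTERACTION,
    MIXTA,
    DomainModel,
    filter_candidates,
    parse_motif_pattern,
    profile_alignment,
    scan_named_motif,
    scan_protein,
)


def brute_force_scan(sequence: str, model: DomainModel, min_score: int):
    """Independent oracle: check every ungapped window against the landmarks."""
    hits = []
    for s in range(len(sequence) - model.length + 1):
        window = sequence[s:s + model.length]
        score = sum(window[p - 1] in allowed
                    for p, allowed in model.scored_landmarks())
        if score >= min_score:
            hits.append((s + 1, score))
    return hits


class TestScanProtein:
    def test_consensus_scores_all_seven_landmarks(self, consensus, model):
        for pos, allowed in model.scored_landmarks():
            assert consensus[pos - 1] in allowed  # fixture is landmark-perfect
        hits = scan_protein(consensus, model, min_score=7)
        assert len(hits) == 1
        hit = hits[0]
        assert (hit.start, hit.end, hit.landmark_score) == (1, 108, 7)
        assert hit.missed == ()
        assert hit.position62_residue == "W"
        assert hit.insertion_residue == "L"

    def test_poly_alanine_has_no_hits(self, model):
        assert scan_protein("A" * 200, model, min_score=1) == []

    def test_short_sequence_returns_empty(self, model):
        assert scan_protein("MKTW", model) == []

    def test_position62_tolerates_hydrophobic_substitution(self, consensus, model):
        mutated = consensus[:61] + "F" + consensus[62:]
        hits = scan_protein(mutated, model, min_score=7)
        assert len(hits) == 1
        assert hits[0].landmark_score == 7
        assert hits[0].position62_residue == "F"

    def test_non_amino_acid_characters_error(self, model):
        with pytest.raises(ValueError):
            scan_protein("MKT1" + "A" * 120, model)

    def test_embedded_domain_start_is_recovered(self, consensus, model):
        rng = np.random.default_rng(5)
        flank = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=40))
        seq = flank + consensus + flank
        hits = scan_protein(seq, model, min_score=7)
        assert [h.start for h in hits] == [41]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_short_sequences(self, seed, model):
        rng = np.random.default_rng(seed)
        seq = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=250))
        # plant a consensus fragment to make hits likely
        seq = seq[:60] + model.consensus + seq[60 + model.length:]
        expected = brute_force_scan(seq, model, min_score=5)
        got = [(h.start, h.landmark_score) for h in scan_protein(seq, model, 5)
               if h.width == model.length]
        # every oracle window must be found (possibly merged by overlap rules)
        top = max(s for _, s in expected)
        assert any(s == top for _, s in got)
        for start, score in got:
            assert (start, score) in expected

    def test_raising_min_score_never_adds_hits(self, consensus, model):
        rng = np.random.default_rng(7)
        noisy = list(consensus)
        for i in rng.integers(0, 108, size=12):
            noisy[i] = "A"
        seq = "".join(noisy) * 2
        previous = None
        for ms in range(1, 8):
            n = len(scan_protein(seq, model, min_score=ms))
            if previous is not None:
                assert n <= previous
            previous = n

    def test_single_deletion_tolerated(self, consensus, model):
        # drop one non-landmark residue between W29 and C41
        deleted = consensus[:34] + consensus[35:]
        hits = scan_protein(deleted, model, min_score=6)
        assert hits and hits[0].landmark_score == 7
        assert hits[0].width == model.length - 1


class TestFilterCandidates:
    LOCI = {
        "ok": ("chr1", 1000, 2000),
        "no_met": ("chr1", 5000, 6000),
        "iso_a": ("chr2", 100, 900),
        "iso_b": ("chr2", 150, 950),
    }

    def _hits(self, model, consensus, pid, n=1):
        return [h for h in scan_protein("M" + consensus, model)][:n] * n

    def test_protein_without_leading_met_excluded(self, consensus, model):
        prots = {"ok": "M" + consensus, "no_met": consensus}
        hits = {p: scan_protein(prots[p], model) for p in prots}
        result = filter_candidates(hits, prots, self.LOCI)
        assert result.accepted == ("ok",)
        assert result.rejected["no_met"] == "incomplete_orf"

    def test_redundant_locus_keeps_one_representative(self, consensus, model):
        prots = {"iso_a": "M" + consensus, "iso_b": "M" + consensus + "AAA"}
        hits = {p: scan_protein(prots[p], model) for p in prots}
        result = filter_candidates(hits, prots, self.LOCI)
        assert len(result.accepted) == 1
        assert len(result.rejected) == 1
        assert next(iter(result.rejected.values())).startswith("redundant_locus")

    def test_clean_single_domain_protein_accepted(self, consensus, model):
        prots = {"ok": "M" + consensus}
        result = filter_candidates({"ok": scan_protein(prots["ok"], model)},
                                   prots, self.LOCI)
        assert result.accepted == ("ok",)

    def test_two_domain_protein_flagged_atypical(self, consensus, model):
        prots = {"ok": "M" + consensus + "GSGS" + consensus}
        hits = {"ok": scan_protein(prots["ok"], model)}
        assert len(hits["ok"]) == 2
        result = filter_candidates(hits, prots, self.LOCI)
        assert result.accepted == ()
        assert result.atypical == ("ok",)

    def test_missing_locus_errors(self, consensus, model):
        with pytest.raises(KeyError):
            filter_candidates({}, {"ghost": "M" + consensus}, {})


class TestProfileAlignment:
    def test_identical_copies_fully_conserved_at_landmarks(self, consensus, model):
        domains = {f"d{i}": consensus for i in range(10)}
        profile, stats = profile_alignment(domains, model)
        for pos, _ in model.scored_landmarks():
            assert profile.conservation[pos - 1] == 1.0
        assert stats["cys45_conserved_fraction"] == 1.0
        assert stats["linker_match_fraction"] == 1.0
        assert np.allclose(profile.frequencies.sum(axis=1), 1.0, atol=1e-9)

    def test_w62_substitution_fraction_counted_directly(self, consensus, model):
        domains = {f"c{i}": consensus for i in range(8)}
        w62f = consensus[:61] + "F" + consensus[62:]
        domains.update({"f1": w62f, "f2": w62f})
        _, stats = profile_alignment(domains, model)
        assert stats["position62_substitution_fraction"] == pytest.approx(0.2)
        assert stats["position62_counts"] == {"W": 8, "F": 2}

    def test_unmappable_length_reported_not_fatal(self, consensus, model):
        domains = {"a": consensus, "b": consensus, "short": consensus[:90]}
        profile, stats = profile_alignment(domains, model)
        assert profile.excluded == ("short",)
        assert stats["n_sequences"] == 2

    def test_landmarks_outconserve_nonlandmarks_in_synthetic_family(
            self, family, family_domains, model):
        domains = {g: family.proteins[g][h.start - 1:h.end]
                   for g, h in family_domains.items() if h.width == model.length}
        profile, _ = profile_alignment(domains, model)
        landmark_pos = [p - 1 for p, _ in model.scored_landmarks()]
        other = [i for i in range(model.length) if i not in landmark_pos]
        assert (profile.conservation[landmark_pos].min()
                >= profile.conservation[other].mean())


class TestNamedMotifPatterns:
    @pytest.mark.parametrize("text,length,specified", [
        ("[DE]Lx2[RK]x3Lx6Lx3R", 20, 6),
        ("AQWESARxxAExRLxRES", 18, 14),
        ("WxW", 3, 2),
    ])
    def test_expansion_and_specified_counts(self, text, length, specified):
        pattern = parse_motif_pattern(text)
        assert pattern.length == length
        assert pattern.n_specified == specified

    @pytest.mark.parametrize("bad", ["", "x5", "[DE", "D]x", "[de]L", "D-E"])
    def test_malformed_patterns_raise(self, bad):
        with pytest.raises(ValueError):
            parse_motif_pattern(bad)

    @pytest.mark.parametrize("seq,pattern,expected", [
        ("ELGGRAAALAAAAAALAAAR", BHLH_INTERACTION, [(1, 20)]),
        ("AQWESARGGAEGRLGRES", MIXTA, [(1, 18)]),
        ("AAAAAAAAAAAAAAAAAAAAAA", BHLH_INTERACTION, []),
    ])
    def test_known_occurrences(self, seq, pattern, expected):
        assert scan_named_motif(seq, pattern) == expected

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_regex_engine_oracle(self, seed):
        rng = np.random.default_rng(seed)
        alphabet = "DELRKAGW"
        seq = "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=400))
        pattern = parse_motif_pattern("[DE]Lx2[RK]")
        oracle = [(m.start() + 1, m.start() + 5)
                  for m in re.finditer(r"(?=([DE]L..[RK]))", seq)]
        assert scan_named_motif(seq, pattern) == oracle

    def test_overlapping_occurrences_all_reported(self):
        pattern = parse_motif_pattern("WxW")
        assert scan_named_motif("WAWAW", pattern) == [(1, 3), (3, 5)]
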
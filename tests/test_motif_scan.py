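import re

import numpy as np
import pytest

from betrewire import motif_scan
from betrewire.errors import ContractError, ValidationError
from betrewire.motif_scan import et_patterns
from betrewire.tables_io import PtmSite, STANDARD_AA


# ---------------------------------------------------------------------------
# Independent regular-expression oracle (overlap via lookahead)

def regex_k_linker_k(seq, linker_min, linker_max):
    hits = set()
    for n in range(linker_min, linker_max + 1):
        pattern = re.compile(rf"(?=(K[{STANDARD_AA}]{{{n}}}K))")
        for m in pattern.finditer(seq):
            hits.add((m.start() + 1, m.start() + n + 2))
    return hits


def regex_pattern(seq, pattern):
    classes = "".join(f"[{''.join(sorted(s))}]" for s in pattern.positions)
    return {m.start() + 1 for m in re.compile(rf"(?=({classes}))").finditer(seq)}


def random_sequences(n, rng, min_len=50, max_len=500):
    for _ in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        yield "".join(rng.choice(list(STANDARD_AA), size=length))


# ---------------------------------------------------------------------------

class TestKLinkerK:
    def test_h4_tail_linker_2(self, h4_tail):
        hits = motif_scan.scan_k_linker_k(h4_tail, 2, 2)
        assert [(h.anchor1, h.linker, h.anchor2) for h in hits] == [(5, "GG", 8)]

    def test_h4_tail_linker_3(self, h4_tail):
        hits = motif_scan.scan_k_linker_k(h4_tail, 3, 3)
        assert [(h.anchor1, h.linker, h.anchor2) for h in hits] == [
            (8, "GLG", 12), (12, "GGA", 16), (16, "RHR", 20)
        ]

    def test_adjacent_lysines_no_two_residue_linker(self):
        assert motif_scan.scan_k_linker_k("KK", 2, 2) == []

    def test_shared_anchor_overlaps_reported(self):
        # middle K is anchor2 of the first hit and anchor1 of the second
        hits = motif_scan.scan_k_linker_k("KAAKAAK", 2, 2)
        assert [(h.anchor1, h.anchor2) for h in hits] == [(1, 4), (4, 7)]

    def test_nonstandard_letter_strict_vs_permissive(self):
        with pytest.raises(ValidationError):
            motif_scan.scan_k_linker_k("KXAK", 2, 2)
        with pytest.warns(UserWarning):
            assert motif_scan.scan_k_linker_k("KXAK", 2, 2, strict=False) == []

    def test_invalid_linker_range(self):
        with pytest.raises(ContractError):
            motif_scan.scan_k_linker_k("KAAK", 3, 2)

    def test_widening_range_never_removes_hits(self):
        rng = np.random.default_rng(19)
        for seq in random_sequences(30, rng, 50, 150):
            previous = set()
            for linker_max in range(2, 7):
                hits = {(h.anchor1, h.anchor2)
                        for h in motif_scan.scan_k_linker_k(seq, 2, linker_max)}
                assert previous <= hits
                previous = hits


class TestHistoneLike:
    @pytest.mark.parametrize("linker,expected", [("GG", True), ("DS", False), ("WW", False),
                                                 ("TP", True), ("SA", True)])
    def test_membership(self, linker, expected):
        assert motif_scan.is_histone_like(linker) is expected

    def test_wrong_length_is_contract_error(self):
        with pytest.raises(ContractError):
            motif_scan.is_histone_like("GGG")

    def test_exactly_13_members(self):
        assert len(motif_scan.HISTONE_LIKE_LINKERS) == 13


class TestLinkerSpace:
    @pytest.mark.parametrize("alphabet,expected", [(STANDARD_AA, 400), ("A", 1), ("ACGT", 16)])
    def test_counts(self, alphabet, expected):
        assert motif_scan.enumerate_linker_space(alphabet) == expected

    def test_empty_alphabet(self):
        with pytest.raises(ContractError):
            motif_scan.enumerate_linker_space("")


class TestKyAndKyxk:
    def test_baz1b_window(self):
        # window around the BAZ1B K221ac site
        hits = motif_scan.scan_ky("FLPHKYDVKL")
        assert [(h.anchor1,) for h in hits] == [(5,)]

    @pytest.mark.parametrize("seq,n", [("KY", 1), ("YK", 0)])
    def test_ky_edges(self, seq, n):
        assert len(motif_scan.scan_ky(seq)) == n

    def test_srpk1_kysk(self):
        hits = motif_scan.scan_kyxk("VAGKYSKEFF")
        assert [(h.anchor1, h.linker, h.anchor2) for h in hits] == [(4, "YS", 7)]

    @pytest.mark.parametrize("seq,n", [("KYAK", 1), ("KYA", 0)])
    def test_kyxk_edges(self, seq, n):
        assert len(motif_scan.scan_kyxk(seq)) == n


class TestEtSlims:
    def test_brd9_slim_minimal_pattern(self):
        hits = motif_scan.scan_et_slim("LKLVLKV", et_patterns()["ET_minimal"])
        assert len(hits) == 1 and hits[0].anchor1 == 2

    def test_brd9_slim_brd9like_pattern(self):
        hits = motif_scan.scan_et_slim("LKLVLKV", et_patterns()["ET_BRD9like"])
        assert len(hits) == 1 and hits[0].anchor1 == 3

    def test_whsc1_slim(self):
        hits = motif_scan.scan_et_slim("IKLKI", et_patterns()["ET_WHSC1like"])
        assert len(hits) == 1 and hits[0].anchor1 == 1

    def test_include_phe_extends_phi(self):
        # the RPS26-style KFVIK motif needs F in the hydrophobic class
        assert motif_scan.scan_et_slim("KFVIK", et_patterns()["ET_minimal"]) == []
        hits = motif_scan.scan_et_slim("KFVIK", et_patterns(include_phe=True)["ET_minimal"])
        assert [h.anchor1 for h in hits] == [1]

    def test_cm2_flagged_uncertain(self):
        pattern = et_patterns()["CM2"]
        assert "uncertain" in pattern.notes
        assert [h.anchor1 for h in motif_scan.scan_et_slim("AKHA", pattern)] == [2]


class TestOracleEquivalence:
    def test_k_linker_k_matches_regex_oracle(self):
        rng = np.random.default_rng(23)
        for seq in random_sequences(100, rng):
            mine = {(h.anchor1, h.anchor2) for h in motif_scan.scan_k_linker_k(seq, 2, 4)}
            assert mine == regex_k_linker_k(seq, 2, 4)

    def test_slim_scans_match_regex_oracle(self):
        rng = np.random.default_rng(29)
        patterns = list(et_patterns().values())
        for seq in random_sequences(60, rng):
            for pattern in patterns:
                mine = {h.anchor1 for h in motif_scan.scan_et_slim(seq, pattern)}
                assert mine == regex_pattern(seq, pattern)

    def test_ky_and_kyxk_match_regex_oracle(self):
        rng = np.random.default_rng(31)
        for seq in random_sequences(60, rng):
            assert {h.anchor1 for h in motif_scan.scan_ky(seq)} == {
                m.start() + 1 for m in re.finditer(r"(?=KY)", seq)
            }
            assert {h.anchor1 for h in motif_scan.scan_kyxk(seq)} == {
                m.start() + 1 for m in re.finditer(rf"(?=KY[{STANDARD_AA}]K)", seq)
            }


class TestWindows:
    def test_window_reslices_to_source(self, h4_tail):
        for h in motif_scan.scan_k_linker_k(h4_tail, 2, 4):
            stripped = h.window.strip(motif_scan.GAP)
            assert stripped in h4_tail
            start = h4_tail.index(stripped) + 1
            offset1 = h.anchor1 - start
            assert stripped[offset1] == "K"
            assert stripped[h.anchor2 - start] == "K"

    def test_terminal_truncation_padded_and_flagged(self):
        (hit,) = motif_scan.scan_k_linker_k("KGGKAAAAA", 2, 2)
        assert hit.truncated
        assert hit.flank_n == "-----"
        assert hit.window.startswith("-----KGGK")


class TestOverlayKac:
    def test_states(self):
        hits = motif_scan.scan_k_linker_k("AAKGGKAA", 2, 2, accession="P1")
        both = motif_scan.overlay_kac(hits, [PtmSite("P1", 3, "K", "acetyl-K"),
                                             PtmSite("P1", 6, "K", "acetyl-K")])
        assert both[0].acetyl_state == motif_scan.DI_AC
        first = motif_scan.overlay_kac(hits, [PtmSite("P1", 3, "K", "acetyl-K")])
        assert first[0].acetyl_state == motif_scan.FIRST_K_AC
        second = motif_scan.overlay_kac(hits, [PtmSite("P1", 6, "K", "acetyl-K")])
        assert second[0].acetyl_state == motif_scan.SECOND_K_AC
        none = motif_scan.overlay_kac(hits, [PtmSite("P1", 3, "K", "phospho-S")])
        assert none[0].acetyl_state == motif_scan.UNMODIFIED

    def test_ky_hits_get_single_anchor_states(self):
        hits = motif_scan.scan_ky("AAKYAA", accession="P1")
        (annotated,) = motif_scan.overlay_kac(hits, [PtmSite("P1", 3, "K", "acetyl-K")])
        assert annotated.acetyl_state == motif_scan.K_AC


class TestUniqueWindows:
    def test_splice_variant_duplicates_collapse(self):
        seq = "AAAAAKGGKAAAAA"
        hits = (motif_scan.scan_k_linker_k(seq, 2, 2, accession="ISO1")
                + motif_scan.scan_k_linker_k(seq, 2, 2, accession="ISO2"))
        unique = motif_scan.unique_windows(hits)
        assert len(unique) == 1 and unique[0].multiplicity == 2

    def test_distinct_windows_stay_distinct(self):
        hits = (motif_scan.scan_k_linker_k("AAAAAKGGKAAAAA", 2, 2)
                + motif_scan.scan_k_linker_k("CCCCCKGSKCCCCC", 2, 2))
        assert len(motif_scan.unique_windows(hits)) == 2

    def test_even_width_rejected(self):
        with pytest.raises(ContractError):
            motif_scan.unique_windows([], width=14)
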
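"""Short-peptide homology matching: acceptance rules, search, consensus."""

import random

import pytest
from Bio.Align import substitution_matrices

from zipperscan.seqio import Peptide
from zipperscan.ss_homology import (
    StructureWindow,
    blosum62,
    blosum62_score,
    consensus_ss,
    match_window,
    read_structure_db,
    search,
    write_structure_db,
)

AA = sorted("ACDEFGHIKLMNPQRSTVWY")
_RAW62 = substitution_matrices.load("BLOSUM62")


# --- independent oracle -----------------------------------------------------

def oracle_accept(qwin: str, dwin: str, max_subs: int = 2) -> bool:
    """The acceptance clauses, restated from scratch on the raw matrix."""
    if len(qwin) != len(dwin) or len(qwin) < 5:
        return False
    subs = [int(_RAW62[a, b]) for a, b in zip(qwin, dwin) if a != b]
    if len(qwin) == 5 and subs:
        return False
    if len(subs) > max_subs:
        return False
    if any(s < 0 for s in subs):
        return False
    if len(subs) == 2 and not all(s > 0 for s in subs):
        return False
    return True


def oracle_search(query: str, db, min_len: int = 5):
    """Brute-force double loop over (query substring, db offset)."""
    accepted = set()
    for length in range(min_len, len(query) + 1):
        for qs in range(len(query) - length + 1):
            qwin = query[qs : qs + length]
            for w in db:
                for ds in range(len(w.sequence) - length + 1):
                    if oracle_accept(qwin, w.sequence[ds : ds + length]):
                        accepted.add((qs + 1, w.source_id, ds + 1, length))
    return accepted


class TestBlosumLookup:
    @pytest.mark.parametrize(
        "x,y,score", [("S", "L", -2), ("S", "A", 1), ("L", "L", 4), ("E", "E", 5)]
    )
    def test_published_entries(self, x, y, score):
        assert blosum62_score(x, y) == score

    def test_symmetric_over_all_pairs(self):
        m = blosum62()
        for x in AA:
            for y in AA:
                assert m.score(x, y) == m.score(y, x) == int(_RAW62[x, y])

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            blosum62_score("S", "X")


class TestMatchWindow:
    """The acceptance-rule clause table."""

    @pytest.mark.parametrize(
        "q,d,accepted,reason",
        [
            ("SLYQFV", "SLYQFV", True, None),            # len 6 identical
            ("SSYQF", "SSYQF", True, None),              # len 5 identical
            ("SSYQF", "SAYQF", False, "five_not_identical"),
            ("SSYQFV", "SAYQFV", True, None),            # 1 sub, score(S,A)=1 >= 0
            ("SSYQFV", "SLYQFV", False, "nonpositive_sub"),  # score(S,L)=-2
            ("SSYQFV", "TAYQFV", True, None),            # 2 subs, scores {1,1}
            ("SSYQFV", "ASYQFA", False, "zero_sub_pair"),  # 2 subs, scores {1,0}
            ("SSYQFV", "TAYQFW", False, "too_many_subs"),
            ("SSYQ", "SSYQ", False, "too_short"),
        ],
    )
    def test_clause_table(self, q, d, accepted, reason):
        m = match_window(q, d)
        assert m.accepted is accepted
        assert m.reject_reason == reason

    def test_two_substitution_scores_checked_individually(self):
        # S->A scores 1 (positive) while V->A scores 0: pair must be rejected
        m = match_window("SSYQFV", "ASYQFA", max_substitutions=2)
        assert sorted(m.substitution_scores) == [0, 1]
        assert not m.accepted and m.reject_reason == "zero_sub_pair"

    def test_substitution_count_and_scores_recorded(self):
        m = match_window("SSYQFV", "SAYQFV")
        assert m.n_substitutions == 1
        assert m.substitution_scores == (1,)

    def test_unequal_lengths_are_an_error(self):
        with pytest.raises(ValueError):
            match_window("SSYQF", "SSYQFV")

    def test_identity_conversion_is_monotone(self):
        """Turning any substitution into an identity never loses acceptance."""
        rng = random.Random(11)
        for _ in range(300):
            n = rng.randint(5, 10)
            qwin = "".join(rng.choice(AA) for _ in range(n))
            dwin = "".join(rng.choice(AA) for _ in range(n))
            if match_window(qwin, dwin).accepted:
                for i, (a, b) in enumerate(zip(qwin, dwin)):
                    if a != b:
                        fixed = dwin[:i] + a + dwin[i + 1 :]
                        assert match_window(qwin, fixed).accepted


class TestSearch:
    def test_planted_identical_window_found(self, scr14):
        win = StructureWindow("w1", "famA", "SLYQFVNSL", "H" * 9)
        matches = search(scr14, [win])
        top = matches[0]
        assert top.accepted
        assert (top.query_start, top.query_end) == (4, 12)
        assert top.db_seq == "SLYQFVNSL"

    def test_duplicate_sequence_same_family_collapses(self, scr14):
        w1 = StructureWindow("w1", "famA", "SLYQFVNSL", "H" * 9)
        w2 = StructureWindow("w2", "famA", "SLYQFVNSL", "H" * 9)
        matches = search(scr14, [w1, w2], keep_rejected=True)
        full = [m for m in matches if m.length == 9 and m.n_substitutions == 0]
        assert sum(m.accepted for m in full) == 1
        demoted = [m for m in full if not m.accepted]
        assert demoted and all(
            m.reject_reason == "duplicate_sequence" for m in demoted
        )

    def test_duplicate_sequence_different_family_kept(self, scr14):
        w1 = StructureWindow("w1", "famA", "SLYQFVNSL", "H" * 9)
        w2 = StructureWindow("w2", "famB", "SLYQFVNSL", "H" * 9)
        matches = search(scr14, [w1, w2])
        full_accepted = [m for m in matches if m.length == 9 and m.accepted]
        assert {m.source_id for m in full_accepted} == {"w1", "w2"}

    def test_dedup_keeps_one_per_family_pair(self, scr14):
        windows = [
            StructureWindow(f"w{i}", fam, "SLYQFVNSL", "H" * 9)
            for i, fam in enumerate(["famA", "famA", "famB"])
        ]
        matches = search(scr14, windows)
        full_accepted = [m for m in matches if m.length == 9 and m.accepted]
        assert len(full_accepted) == 2
        assert {m.family_id for m in full_accepted} == {"famA", "famB"}

    def test_query_shorter_than_min_len_is_an_error(self):
        with pytest.raises(ValueError):
            search(Peptide("q", "FAMS"), [StructureWindow("w", "f", "FAMSS", "HHHHH")])

    def test_agrees_with_bruteforce_on_random_instances(self):
        rng = random.Random(20240921)
        for _ in range(60):
            qlen = rng.randint(7, 16)
            query = Peptide("q", "".join(rng.choice(AA) for _ in range(qlen)))
            db = []
            for i in range(rng.randint(2, 5)):
                seq = "".join(rng.choice(AA) for _ in range(rng.randint(6, 14)))
                db.append(StructureWindow(f"w{i}", f"fam{i}", seq, "H" * len(seq)))
            got = {
                (m.query_start, m.source_id, m.db_start, m.length)
                for m in search(query, db, keep_rejected=True)
                if m.accepted or m.reject_reason == "duplicate_sequence"
            }
            assert got == oracle_search(query.sequence, db)

    def test_sort_order_accepted_first_longest_first(self, scr14):
        win = StructureWindow("w1", "famA", "SLYQFVNSL", "H" * 9)
        matches = search(scr14, [win], keep_rejected=True)
        flags = [m.accepted for m in matches]
        # accepted block strictly precedes the rejected block
        assert flags == sorted(flags, reverse=True)
        lengths = [m.length for m in matches if m.accepted]
        assert lengths == sorted(lengths, reverse=True)


class TestConsensusSS:
    def test_single_match_votes_its_labels(self, scr14):
        win = StructureWindow("w1", "famA", "SLYQFV", "HHHHHH")
        matches = [m for m in search(scr14, [win]) if m.length == 6]
        pred = consensus_ss(scr14, matches[:1], [win])
        assert pred.labels[3:9] == ("H",) * 6
        assert pred.labels[0] == "unsupported"
        assert pred.labels[-1] == "unsupported"

    def test_tied_votes_are_ambiguous(self, scr14):
        w_h = StructureWindow("wh", "famA", "SLYQFV", "HHHHHH")
        w_e = StructureWindow("we", "famB", "SLYQFV", "EEEEEE")
        matches = [m for m in search(scr14, [w_h, w_e]) if m.length == 6 and m.accepted]
        pred = consensus_ss(scr14, matches, [w_h, w_e])
        assert pred.labels[3] == "ambiguous"

    def test_vote_histogram_conserves_votes(self, scr14):
        win = StructureWindow("w1", "famA", "SLYQFVNSL", "HHHEEEHHH")
        matches = search(scr14, [win])
        pred = consensus_ss(scr14, matches, [win])
        total_votes = sum(sum(h.values()) for h in pred.support)
        assert total_votes == sum(m.length for m in matches if m.accepted)

    def test_variant_helix_run_longer_than_wild_type(self, scr_wt, scr14):
        """One all-helix window spanning both heptads of the variant supports a
        longer predicted helix for the variant than for the wild type, whose
        Ser at the first heptad's d breaks the full-length match."""
        win = StructureWindow("helix", "famH", scr14.sequence[1:15], "H" * 14)
        runs = {}
        for pep in (scr_wt, scr14):
            matches = search(pep, [win])
            pred = consensus_ss(pep, matches, [win])
            h_runs = pred.runs("H")
            assert len(h_runs) == 1
            runs[pep.id] = h_runs[0]
        wt_len = runs[scr_wt.id][1] - runs[scr_wt.id][0] + 1
        mut_len = runs[scr14.id][1] - runs[scr14.id][0] + 1
        assert mut_len > wt_len
        assert runs[scr14.id] == (2, 15)


class TestStructureDbIO:
    def test_round_trip(self, tmp_path):
        windows = [
            StructureWindow("w1", "famA", "SLYQFV", "HHHHHH"),
            StructureWindow("w2", "famB", "ACDEFG", "CCTTEE"),
        ]
        path = tmp_path / "db.tsv"
        write_structure_db(windows, path)
        assert read_structure_db(path) == windows

    def test_ss_alphabet_enforced(self):
        with pytest.raises(ValueError):
            StructureWindow("w", "f", "ACDEF", "HHXHH")

    def test_ss_length_must_match(self):
        with pytest.raises(ValueError):
            StructureWindow("w", "f", "ACDEF", "HHH")
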
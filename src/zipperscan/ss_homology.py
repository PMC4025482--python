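"""Rule-based secondary-structure inference by short-peptide homology.

A query peptide is compared, gaplessly, against a database of sequence
windows whose per-residue secondary structure is known (pre-extracted from
solved 3D structures).  A candidate alignment is accepted when:

* it is at least 6 residues long, or exactly 5 residues with perfect
  identity;
* it contains at most ``max_substitutions`` (default 2) mismatches;
* every mismatch has a BLOSUM62 substitution score >= 0; and
* when exactly two mismatches are present, both scores are strictly
  positive.

Accepted matches with the same matched database peptide are kept once per
protein family.  Per-residue majority vote over the secondary-structure
labels of accepted matches yields the consensus prediction.
"""

from __future__ import annotations

import dataclasses
import functools
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio.Align import substitution_matrices

from .seqio import CANONICAL_AA, Peptide

#: Secondary-structure labels: helix, strand, coil, turn.
SS_ALPHABET = frozenset("HECT")

#: Labels a consensus prediction may carry beyond the four structural ones.
AMBIGUOUS = "ambiguous"
UNSUPPORTED = "unsupported"

REJECT_TOO_SHORT = "too_short"
REJECT_FIVE_NOT_IDENTICAL = "five_not_identical"
REJECT_TOO_MANY_SUBS = "too_many_subs"
REJECT_NONPOSITIVE_SUB = "nonpositive_sub"
REJECT_ZERO_SUB_PAIR = "zero_sub_pair"
REJECT_DUPLICATE = "duplicate_sequence"


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric integer substitution scores over ordered residue pairs."""

    name: str
    scores: Mapping[tuple[str, str], int]

    def __post_init__(self) -> None:
        pairs = set(self.scores)
        expected = {(x, y) for x in CANONICAL_AA for y in CANONICAL_AA}
        if pairs != expected:
            raise ValueError(
                f"matrix {self.name!r} must score all 400 ordered residue pairs"
            )
        for (x, y), s in self.scores.items():
            if self.scores[(y, x)] != s:
                raise ValueError(f"matrix {self.name!r} asymmetric at ({x},{y})")
        object.__setattr__(self, "scores", dict(self.scores))

    def score(self, x: str, y: str) -> int:
        key = (x.upper(), y.upper())
        if key not in self.scores:
            raise ValueError(f"non-canonical residue pair ({x!r},{y!r})")
        return self.scores[key]


@functools.lru_cache(maxsize=None)
def blosum62() -> SubstitutionMatrix:
    """The BLOSUM62 matrix restricted to the 20 canonical residues."""
    raw = substitution_matrices.load("BLOSUM62")
    scores = {
        (x, y): int(raw[x, y]) for x in CANONICAL_AA for y in CANONICAL_AA
    }
    return SubstitutionMatrix("BLOSUM62", scores)


def blosum62_score(x: str, y: str, matrix: SubstitutionMatrix | None = None) -> int:
    """Substitution score for a residue pair (symmetric lookup)."""
    matrix = matrix if matrix is not None else blosum62()
    return matrix.score(x, y)


@dataclass(frozen=True)
class StructureWindow:
    """A sequence window with known per-residue secondary structure."""

    source_id: str
    family_id: str
    sequence: str
    ss: str

    def __post_init__(self) -> None:
        if not self.source_id or not self.family_id:
            raise ValueError("source_id and family_id must be non-empty")
        seq = self.sequence.upper()
        bad = sorted(set(seq) - CANONICAL_AA)
        if bad:
            raise ValueError(
                f"window {self.source_id!r}: non-canonical residue(s) {''.join(bad)}"
            )
        ss = self.ss.upper()
        bad_ss = sorted(set(ss) - SS_ALPHABET)
        if bad_ss:
            raise ValueError(
                f"window {self.source_id!r}: secondary-structure labels must be "
                f"H/E/C/T, got {''.join(bad_ss)}"
            )
        if len(ss) != len(seq):
            raise ValueError(
                f"window {self.source_id!r}: ss length {len(ss)} != sequence "
                f"length {len(seq)}"
            )
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "ss", ss)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MatchResult:
    """One gapless alignment of a query substring against a database window.

    Coordinates are 1-based inclusive on the query; ``db_start`` is the
    1-based offset of the alignment within the database window.
    """

    query_id: str
    query_start: int
    query_end: int
    source_id: str
    family_id: str
    db_start: int
    length: int
    query_seq: str
    db_seq: str
    n_substitutions: int
    substitution_scores: tuple[int, ...]
    accepted: bool
    reject_reason: str | None

    def __post_init__(self) -> None:
        if self.accepted and self.reject_reason is not None:
            raise ValueError("accepted match cannot carry a reject reason")


def match_window(
    query_window: str,
    db_window: str,
    matrix: SubstitutionMatrix | None = None,
    *,
    max_substitutions: int = 2,
    query_id: str = "query",
    query_start: int = 1,
    source_id: str = "db",
    family_id: str = "db",
    db_start: int = 1,
) -> MatchResult:
    """Assess one gapless, equal-length alignment under the acceptance rules.

    Raises ``ValueError`` on unequal lengths (gapped comparisons are out of
    contract).  Alignments shorter than 5 residues are rejected as
    ``too_short``; 5-mers must be perfectly identical.
    """
    matrix = matrix if matrix is not None else blosum62()
    qwin = query_window.upper()
    dwin = db_window.upper()
    if len(qwin) != len(dwin):
        raise ValueError(
            f"gapless alignment requires equal lengths ({len(qwin)} vs {len(dwin)})"
        )
    length = len(qwin)
    sub_scores = tuple(
        matrix.score(a, b) for a, b in zip(qwin, dwin) if a != b
    )
    n_subs = len(sub_scores)

    reason: str | None = None
    if length < 5:
        reason = REJECT_TOO_SHORT
    elif length == 5 and n_subs > 0:
        reason = REJECT_FIVE_NOT_IDENTICAL
    elif n_subs > max_substitutions:
        reason = REJECT_TOO_MANY_SUBS
    elif any(s < 0 for s in sub_scores):
        reason = REJECT_NONPOSITIVE_SUB
    elif n_subs == 2 and any(s == 0 for s in sub_scores):
        reason = REJECT_ZERO_SUB_PAIR

    return MatchResult(
        query_id=query_id,
        query_start=query_start,
        query_end=query_start + length - 1,
        source_id=source_id,
        family_id=family_id,
        db_start=db_start,
        length=length,
        query_seq=qwin,
        db_seq=dwin,
        n_substitutions=n_subs,
        substitution_scores=sub_scores,
        accepted=reason is None,
        reject_reason=reason,
    )


def _sort_key(m: MatchResult):
    return (
        not m.accepted,
        -m.length,
        m.n_substitutions,
        m.query_start,
        m.source_id,
        m.db_start,
    )


def search(
    query: Peptide,
    db: Sequence[StructureWindow],
    matrix: SubstitutionMatrix | None = None,
    min_len: int = 5,
    max_substitutions: int = 2,
    keep_rejected: bool = False,
) -> list[MatchResult]:
    """Score every gapless alignment of the query against the database.

    Every query substring of length >= ``min_len`` is compared at every
    compatible offset of every window.  Results are sorted by
    (accepted desc, length desc, substitutions asc, query start asc,
    source_id asc, db offset asc).  Among accepted matches with the same
    matched database peptide, one representative is kept per family; later
    copies are demoted with reason ``duplicate_sequence``.

    By default only accepted matches (plus demoted duplicates) are returned;
    pass ``keep_rejected=True`` to retain every assessed alignment.
    """
    if not db:
        raise ValueError("structure database is empty")
    if len(query) < min_len:
        raise ValueError(
            f"query {query.id!r} shorter than minimum match length {min_len}"
        )
    matrix = matrix if matrix is not None else blosum62()
    qseq = query.sequence
    results: list[MatchResult] = []
    for length in range(min_len, len(qseq) + 1):
        for qstart in range(1, len(qseq) - length + 2):
            qwin = qseq[qstart - 1 : qstart - 1 + length]
            for window in db:
                wseq = window.sequence
                for dstart in range(1, len(wseq) - length + 2):
                    m = match_window(
                        qwin,
                        wseq[dstart - 1 : dstart - 1 + length],
                        matrix,
                        max_substitutions=max_substitutions,
                        query_id=query.id,
                        query_start=qstart,
                        source_id=window.source_id,
                        family_id=window.family_id,
                        db_start=dstart,
                    )
                    if m.accepted or keep_rejected:
                        results.append(m)

    results.sort(key=_sort_key)
    # One accepted representative per (matched db peptide, family).
    seen: set[tuple[str, str]] = set()
    deduped: list[MatchResult] = []
    for m in results:
        if m.accepted:
            key = (m.db_seq, m.family_id)
            if key in seen:
                m = dataclasses.replace(
                    m, accepted=False, reject_reason=REJECT_DUPLICATE
                )
                if not keep_rejected:
                    continue
            else:
                seen.add(key)
        deduped.append(m)
    deduped.sort(key=_sort_key)
    return deduped


@dataclass(frozen=True)
class SSPrediction:
    """Per-residue consensus secondary structure for a query peptide.

    ``labels[i]`` is the strict-majority label at query position ``i+1``
    (``ambiguous`` on ties, ``unsupported`` with zero coverage);
    ``support[i]`` is the vote histogram over H/E/C/T at that position.
    """

    query_id: str
    labels: tuple[str, ...]
    support: tuple[Mapping[str, int], ...]
    n_accepted_matches: int

    def runs(self, label: str) -> list[tuple[int, int]]:
        """Maximal 1-based inclusive runs of a given label."""
        out: list[tuple[int, int]] = []
        start = None
        for i, lab in enumerate(self.labels, start=1):
            if lab == label and start is None:
                start = i
            elif lab != label and start is not None:
                out.append((start, i - 1))
                start = None
        if start is not None:
            out.append((start, len(self.labels)))
        return out


def consensus_ss(
    query: Peptide,
    matches: Sequence[MatchResult],
    db: Sequence[StructureWindow] | None = None,
    *,
    ss_lookup: Mapping[tuple[str, int], str] | None = None,
) -> SSPrediction:
    """Per-residue majority vote over accepted matches.

    Parameters
    ----------
    query:
        The query peptide the matches refer to.
    matches:
        Output of :func:`search`; rejected entries are ignored.
    db:
        The structure windows the matches were found in (used to read the
        secondary-structure labels).  May be omitted when ``ss_lookup`` maps
        ``(source_id, db_position)`` to a label directly.
    """
    if ss_lookup is None:
        if db is None:
            raise ValueError("consensus_ss needs the structure db (or ss_lookup)")
        windows = {w.source_id: w for w in db}
    counts: list[dict[str, int]] = [dict() for _ in range(len(query))]
    n_accepted = 0
    for m in matches:
        if not m.accepted:
            continue
        if m.query_id != query.id:
            raise ValueError(
                f"match for query {m.query_id!r} mixed into {query.id!r}"
            )
        n_accepted += 1
        for k in range(m.length):
            qpos = m.query_start + k
            dpos = m.db_start + k
            if ss_lookup is not None:
                label = ss_lookup[(m.source_id, dpos)]
            else:
                label = windows[m.source_id].ss[dpos - 1]
            hist = counts[qpos - 1]
            hist[label] = hist.get(label, 0) + 1

    labels: list[str] = []
    for hist in counts:
        if not hist:
            labels.append(UNSUPPORTED)
            continue
        best = max(hist.values())
        winners = sorted(lab for lab, c in hist.items() if c == best)
        labels.append(winners[0] if len(winners) == 1 else AMBIGUOUS)
    return SSPrediction(
        query_id=query.id,
        labels=tuple(labels),
        support=tuple(dict(sorted(h.items())) for h in counts),
        n_accepted_matches=n_accepted,
    )


# ---------------------------------------------------------------------------
# Structure-window database I/O (TSV: source_id, family_id, sequence, ss)
# ---------------------------------------------------------------------------


def read_structure_db(path: str | Path) -> list[StructureWindow]:
    """Read a TSV of structure windows (columns source_id, family_id, sequence, ss)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["source_id", "family_id", "sequence", "ss"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return [
        StructureWindow(row.source_id, row.family_id, row.sequence, row.ss)
        for row in df.itertuples(index=False)
    ]


def write_structure_db(windows: Sequence[StructureWindow], path: str | Path) -> None:
    pd.DataFrame(
        {
            "source_id": [w.source_id for w in windows],
            "family_id": [w.family_id for w in windows],
            "sequence": [w.sequence for w in windows],
            "ss": [w.ss for w in windows],
        }
    ).to_csv(path, sep="\t", index=False)
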
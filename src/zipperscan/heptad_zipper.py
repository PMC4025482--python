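"""Heptad-repeat enumeration and putative leucine-zipper calling.

A coiled-coil heptad is a seven-residue period written (a b c d e f g), with
the hydrophobic core at positions *a* and *d*.  This module slides a 7-residue
window along a peptide, flags windows whose *a* and *d* residues are
hydrophobic (optionally requiring leucine at *d*), and groups passing windows
that abut at exactly 7-residue spacing into putative zipper calls.  Two
consecutive in-register heptads are the minimal motif treated as a zipper,
reflecting evidence that two-heptad zippers can act as oligomerization
domains.

Internally heptads are phased a-first (a b c d e f g).  The g-first rendering
(g a b c d e f), which makes the inter-helix g–e′ pairing contiguous, is a
display convention only; :data:`CONSENSUS_GFIRST` stores the Drosophila bZIP
consensus in that phase and :data:`CONSENSUS_AFIRST` re-phases it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from .seqio import (
    ACIDIC,
    BASIC,
    DEFAULT_CLASSES,
    HYDROPHOBIC,
    Peptide,
    ResidueClassTable,
    classify_residue,
)
from .ss_homology import SubstitutionMatrix, blosum62_score

HEPTAD_LETTERS = "abcdefg"

#: Drosophila bZIP heptad consensus in g-first phase: E_g L_a E_b A_c L_d R_e Q_f.
CONSENSUS_GFIRST = "ELEALRQ"
#: The same consensus re-phased a-first: L_a E_b A_c L_d R_e Q_f E_g.
CONSENSUS_AFIRST = "LEALRQE"

RULE_HYDROPHOBIC_AD = "hydrophobic_ad"
RULE_LEUCINE_D = "leucine_d"
_RULES = (RULE_HYDROPHOBIC_AD, RULE_LEUCINE_D)


@dataclass(frozen=True)
class HeptadHit:
    """One 7-residue window assessed as a candidate heptad.

    ``start`` is the 1-based index of position *a*; ``register`` is
    ``start mod 7`` so that hits 7 apart share a register.  ``charged_eg``
    lists which of the e/g positions carry charged (basic or acidic)
    residues — reported for g–e′ pairing annotation, never required.
    """

    register: int
    start: int
    window: str
    position_map: tuple[tuple[str, str], ...]
    a_class: str
    d_class: str
    passes: bool
    charged_eg: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.window) != 7:
            raise ValueError("heptad window must be 7 residues")
        rebuilt = "".join(res for _, res in self.position_map)
        if rebuilt != self.window:
            raise ValueError("position_map does not reconstruct the window")

    @property
    def d_position(self) -> int:
        """1-based sequence index of position *d* (= a + 3)."""
        return self.start + 3

    def residue_at(self, letter: str) -> str:
        return dict(self.position_map)[letter]


@dataclass(frozen=True)
class ZipperCall:
    """A maximal run of passing heptads abutting at 7-residue spacing."""

    register: int
    heptads: tuple[HeptadHit, ...]
    n_heptads: int
    is_zipper: bool

    def __post_init__(self) -> None:
        if self.n_heptads != len(self.heptads) or self.n_heptads < 1:
            raise ValueError("n_heptads must equal the number of heptads (>= 1)")
        for prev, nxt in zip(self.heptads, self.heptads[1:]):
            if nxt.start - prev.start != 7:
                raise ValueError("heptads in a run must abut at spacing 7")

    @property
    def start(self) -> int:
        return self.heptads[0].start

    @property
    def end(self) -> int:
        """1-based inclusive end of the run."""
        return self.heptads[-1].start + 6


def enumerate_heptads(
    peptide: Peptide,
    table: ResidueClassTable | None = None,
    rule: str = RULE_HYDROPHOBIC_AD,
    exclude_proline: bool = True,
) -> list[HeptadHit]:
    """Assess every 7-residue window of a peptide as a candidate heptad.

    A window passes under ``hydrophobic_ad`` when its *a* and *d* residues
    are both hydrophobic and (by default) no proline occupies any of the
    seven positions; ``leucine_d`` additionally requires leucine at *d*.
    Proline is excluded despite being grouped hydrophobic in the default
    class table because it breaks helices; set ``exclude_proline=False`` to
    lift that.

    All windows are returned, passing or not, with ``passes`` set; peptides
    shorter than 7 yield an empty list with a warning.
    """
    if rule not in _RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {_RULES}")
    table = table if table is not None else DEFAULT_CLASSES
    seq = peptide.sequence
    if len(seq) < 7:
        warnings.warn(
            f"peptide {peptide.id!r} shorter than one heptad ({len(seq)} < 7)",
            stacklevel=2,
        )
        return []

    hits: list[HeptadHit] = []
    for start in range(1, len(seq) - 5):
        window = seq[start - 1 : start + 6]
        a_class = classify_residue(window[0], table)
        d_class = classify_residue(window[3], table)
        passes = a_class == HYDROPHOBIC and d_class == HYDROPHOBIC
        if exclude_proline and "P" in window:
            passes = False
        if rule == RULE_LEUCINE_D and window[3] != "L":
            passes = False
        charged_eg = tuple(
            letter
            for letter, res in (("e", window[4]), ("g", window[6]))
            if classify_residue(res, table) in (BASIC, ACIDIC)
        )
        hits.append(
            HeptadHit(
                register=start % 7,
                start=start,
                window=window,
                position_map=tuple(zip(HEPTAD_LETTERS, window)),
                a_class=a_class,
                d_class=d_class,
                passes=passes,
                charged_eg=charged_eg,
            )
        )
    return hits


def call_zippers(
    hits: Sequence[HeptadHit], min_heptads: int = 2
) -> list[ZipperCall]:
    """Group passing heptads into maximal in-register runs.

    Passing hits are grouped by register; within a register, maximal runs of
    starts spaced exactly 7 apart become :class:`ZipperCall` objects with
    ``is_zipper`` true when the run reaches ``min_heptads``.  Calls are
    sorted by (run length desc, start asc).
    """
    passing = sorted((h for h in hits if h.passes), key=lambda h: h.start)
    by_register: dict[int, list[HeptadHit]] = {}
    for h in passing:
        by_register.setdefault(h.register, []).append(h)

    calls: list[ZipperCall] = []
    for register, group in by_register.items():
        run: list[HeptadHit] = []
        for h in group:
            if run and h.start - run[-1].start != 7:
                calls.append(_make_call(register, run, min_heptads))
                run = []
            run.append(h)
        if run:
            calls.append(_make_call(register, run, min_heptads))
    calls.sort(key=lambda c: (-c.n_heptads, c.start))
    return calls


def _make_call(register: int, run: list[HeptadHit], min_heptads: int) -> ZipperCall:
    return ZipperCall(
        register=register,
        heptads=tuple(run),
        n_heptads=len(run),
        is_zipper=len(run) >= min_heptads,
    )


@dataclass(frozen=True)
class ConsensusScore:
    """Position-wise substitution scores of a heptad against a consensus."""

    window: str
    consensus: str
    phase: str
    per_position: tuple[int, ...]
    total: int

    def __post_init__(self) -> None:
        if sum(self.per_position) != self.total:
            raise ValueError("total must equal the sum of per-position scores")


def score_vs_consensus(
    heptad: str,
    consensus: str = CONSENSUS_AFIRST,
    matrix: SubstitutionMatrix | None = None,
    phase: str = "a_first",
) -> ConsensusScore:
    """Score a 7-residue window against a heptad consensus, position by position.

    Both strings must be in the same phase (default a-first); the score at
    each position is the BLOSUM62 substitution score of the window residue
    against the consensus residue, and ``total`` is their sum.
    """
    if len(heptad) != 7 or len(consensus) != 7:
        raise ValueError("heptad and consensus must both be 7 residues")
    per_position = tuple(
        blosum62_score(a, b, matrix) for a, b in zip(heptad.upper(), consensus.upper())
    )
    return ConsensusScore(
        window=heptad.upper(),
        consensus=consensus.upper(),
        phase=phase,
        per_position=per_position,
        total=sum(per_position),
    )


def mutate_d_positions(peptide: Peptide, run: ZipperCall, spec: str) -> Peptide:
    """Substitute the *d* residues of a zipper run.

    ``spec`` assigns one residue per heptad in order (e.g. ``"SL"`` sets the
    first heptad's *d* to serine and the second's to leucine); only those
    positions change.  The returned peptide is renamed with the concatenated
    *d* residues as a suffix (``<id>_SL``).
    """
    spec = spec.upper()
    if len(spec) != run.n_heptads:
        raise ValueError(
            f"spec {spec!r} assigns {len(spec)} residues but the run has "
            f"{run.n_heptads} heptads"
        )
    seq = list(peptide.sequence)
    for heptad, res in zip(run.heptads, spec):
        seq[heptad.d_position - 1] = res
    return Peptide(
        id=f"{peptide.id}_{spec}",
        sequence="".join(seq),
        description=(
            f"{peptide.description} d->{spec}".strip()
        ),
    )
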
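"""ZOC and ZF-NC consensus-motif location and identity/similarity scoring.

Two short N-terminal motifs help diagnose zic proteins:

* ZOC (Zic1-3 odd-paired conserved): published consensus ``(S/T)RDFLxxxR``,
  revised here-supported form ``RDFL-(1-2AA)-RR``;
* ZF-NC: ``GAF(F/L)RYMRQP-(0-7AA)-IKQE``, located immediately N-terminal to
  the first zinc finger.

A consensus is a sequence of scored positions (a fixed residue or an
alternative set such as F/L) interrupted by at most one bounded-length
spacer. Matching is gapless within each segment; only scored positions
enter the identity and similarity percentages — the spacer contributes
nothing. *Identity* requires the query residue to be (one of) the consensus
residue(s); *similarity* additionally accepts residues from the same
physicochemical class. ``X`` is never identical or similar.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .zf_scanner import ZFArchitecture


class MotifError(ValueError):
    """Raised on malformed patterns or mismatched query lengths."""


@dataclass(frozen=True)
class Spacer:
    """A bounded run of unscored arbitrary residues inside a consensus."""

    min_len: int
    max_len: int

    def __post_init__(self) -> None:
        if not (0 <= self.min_len <= self.max_len):
            raise MotifError("spacer requires 0 <= min <= max")


@dataclass(frozen=True)
class ConsensusPattern:
    """An ordered consensus: scored positions and bounded spacers.

    ``elements`` holds frozensets of allowed residues (scored positions)
    and :class:`Spacer` objects, in consensus order.
    """

    name: str
    elements: tuple  # of frozenset[str] | Spacer

    @property
    def scored_positions(self) -> tuple[frozenset, ...]:
        return tuple(e for e in self.elements if isinstance(e, frozenset))

    @property
    def n_scored(self) -> int:
        return len(self.scored_positions)

    def spacer_ranges(self) -> list[tuple[int, int]]:
        return [(e.min_len, e.max_len) for e in self.elements if isinstance(e, Spacer)]

    @classmethod
    def from_string(cls, name: str, notation: str) -> "ConsensusPattern":
        """Build a pattern from compact notation.

        Single letters are fixed residues, ``(F/L)`` is an alternative set,
        ``{m,n}`` is a spacer of m..n arbitrary residues.
        """
        elements: list = []
        i = 0
        while i < len(notation):
            ch = notation[i]
            if ch == "(":
                j = notation.index(")", i)
                elements.append(frozenset(notation[i + 1 : j].split("/")))
                i = j + 1
            elif ch == "{":
                j = notation.index("}", i)
                lo, hi = notation[i + 1 : j].split(",")
                elements.append(Spacer(int(lo), int(hi)))
                i = j + 1
            else:
                elements.append(frozenset(ch))
                i += 1
        return cls(name=name, elements=tuple(elements))


# The three consensus definitions used throughout the pipeline. The
# published ZOC form writes three arbitrary residues as "xxx": a fixed
# spacer of exactly 3.
ZFNC = ConsensusPattern.from_string("ZFNC", "GAF(F/L)RYMRQP{0,7}IKQE")
ZOC_REVISED = ConsensusPattern.from_string("ZOC_revised", "RDFL{1,2}RR")
ZOC_PUBLISHED = ConsensusPattern.from_string("ZOC_published", "(S/T)RDFL{3,3}R")

PATTERNS = {p.name: p for p in (ZFNC, ZOC_REVISED, ZOC_PUBLISHED)}


@dataclass(frozen=True)
class SimilarityGrouping:
    """Partition of the 20 amino acids into physicochemical classes.

    The default is the standard partition: aliphatic, aromatic, basic,
    acidic, amide, hydroxyl, and the singletons G, P, C. Two residues are
    *similar* iff they share a class; X belongs to no class.
    """

    classes: tuple[frozenset, ...] = (
        frozenset("AVLIM"),   # aliphatic
        frozenset("FYW"),     # aromatic
        frozenset("KRH"),     # basic
        frozenset("DE"),      # acidic
        frozenset("NQ"),      # amide
        frozenset("ST"),      # hydroxyl
        frozenset("G"),
        frozenset("P"),
        frozenset("C"),
    )

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cls_ in self.classes:
            if cls_ & seen:
                raise MotifError("similarity classes must be disjoint")
            seen |= cls_
        if seen != set("ACDEFGHIKLMNPQRSTVWY"):
            raise MotifError("similarity classes must cover exactly the 20 amino acids")

    def similar(self, a: str, b: str) -> bool:
        if a == b and a != "X":
            return True
        for cls_ in self.classes:
            if a in cls_ and b in cls_:
                return True
        return False


DEFAULT_GROUPING = SimilarityGrouping()


def _check_length(query: str, positions: Sequence[frozenset]) -> None:
    if len(query) != len(positions):
        raise MotifError(
            f"query length {len(query)} != {len(positions)} scored consensus positions"
        )


def percent_identity(query: str, consensus: ConsensusPattern | Sequence[frozenset]) -> float:
    """Percent of scored positions where the query residue is (in) the consensus.

    Alternative-set positions (e.g. F/L) count as identical for any member.
    """
    positions = consensus.scored_positions if isinstance(consensus, ConsensusPattern) else tuple(consensus)
    _check_length(query, positions)
    n_id = sum(1 for q, allowed in zip(query, positions) if q != "X" and q in allowed)
    return 100.0 * n_id / len(positions)


def percent_similarity(
    query: str,
    consensus: ConsensusPattern | Sequence[frozenset],
    grouping: SimilarityGrouping = DEFAULT_GROUPING,
) -> float:
    """Percent of scored positions identical or physicochemically similar.

    For alternative sets the query is similar if similar to any member, so
    identity always implies similarity.
    """
    positions = consensus.scored_positions if isinstance(consensus, ConsensusPattern) else tuple(consensus)
    _check_length(query, positions)
    n_sim = 0
    for q, allowed in zip(query, positions):
        if q == "X":
            continue
        if q in allowed or any(grouping.similar(q, c) for c in allowed):
            n_sim += 1
    return 100.0 * n_sim / len(positions)


@dataclass(frozen=True)
class MotifMatch:
    """A located consensus candidate with its scores.

    ``start``/``end`` delimit the match in the scanned region (0-based,
    half-open); ``spacer_lengths`` are the realized spacer lengths;
    ``aligned`` pairs each scored consensus position with the query residue.
    """

    pattern: str
    start: int
    end: int
    spacer_lengths: tuple[int, ...]
    aligned: tuple[tuple[str, frozenset], ...]
    percent_identity: float
    percent_similarity: float

    @property
    def query(self) -> str:
        return "".join(q for q, _ in self.aligned)


def _spacer_combinations(pattern: ConsensusPattern) -> Iterable[tuple[int, ...]]:
    import itertools

    ranges = [range(lo, hi + 1) for lo, hi in pattern.spacer_ranges()]
    return itertools.product(*ranges)


def scan_motif(
    region: str,
    pattern: ConsensusPattern,
    min_similarity: float = 70.0,
    grouping: SimilarityGrouping = DEFAULT_GROUPING,
    keep_all: bool = False,
) -> list[MotifMatch]:
    """Score the consensus at every offset and admissible spacer length.

    Returns matches with similarity >= ``min_similarity`` (or every scored
    placement when ``keep_all``), best-first: similarity, then identity,
    then leftmost, then shortest.
    """
    matches = []
    for spacers in _spacer_combinations(pattern):
        # realized layout: per-element (is_scored, length)
        layout: list[tuple[bool, int]] = []
        it = iter(spacers)
        for el in pattern.elements:
            if isinstance(el, Spacer):
                layout.append((False, next(it)))
            else:
                layout.append((True, 1))
        total = sum(length for _, length in layout)
        for start in range(0, len(region) - total + 1):
            pos = start
            aligned = []
            for (scored, length), el in zip(layout, pattern.elements):
                if scored:
                    aligned.append((region[pos], el))
                pos += length
            query = "".join(q for q, _ in aligned)
            pid = percent_identity(query, pattern)
            psim = percent_similarity(query, pattern, grouping)
            matches.append(
                MotifMatch(
                    pattern=pattern.name,
                    start=start,
                    end=start + total,
                    spacer_lengths=spacers,
                    aligned=tuple(aligned),
                    percent_identity=pid,
                    percent_similarity=psim,
                )
            )
    if not keep_all:
        matches = [m for m in matches if m.percent_similarity >= min_similarity]
    matches.sort(
        key=lambda m: (-m.percent_similarity, -m.percent_identity, m.start, m.end)
    )
    return matches


def best_match(
    region: str,
    pattern: ConsensusPattern,
    grouping: SimilarityGrouping = DEFAULT_GROUPING,
) -> MotifMatch | None:
    """Best-scoring placement regardless of threshold ('ZOC-like' logging)."""
    all_matches = scan_motif(region, pattern, min_similarity=0.0, grouping=grouping, keep_all=True)
    return all_matches[0] if all_matches else None


def zfnc_location_check(match: MotifMatch, arch: ZFArchitecture, max_gap: int = 30) -> bool:
    """True iff the match ends at most ``max_gap`` residues before ZF1's Cys1.

    The ZF-NC domain sits immediately N-terminal to ZF1; a candidate
    downstream of Cys1 (or too far upstream) fails the check. ``match.end``
    is half-open, so a match abutting Cys1 has ``end == cys1`` (gap 0).
    """
    cys1 = arch.hits[0].cys1
    gap = cys1 - match.end
    return 0 <= gap <= max_gap


def motif_report_rows(
    record_id: str,
    matches: Iterable[MotifMatch],
    location_flags: dict[int, bool] | None = None,
) -> list[dict]:
    """TSV-ready rows; percentages reported to one decimal."""
    rows = []
    for i, m in enumerate(matches):
        rows.append(
            {
                "id": record_id,
                "pattern": m.pattern,
                "start": m.start,
                "end": m.end,
                "spacer": ";".join(map(str, m.spacer_lengths)),
                "pct_identity": round(m.percent_identity, 1),
                "pct_similarity": round(m.percent_similarity, 1),
                "location_ok": (location_flags or {}).get(i, ""),
            }
        )
    return rows
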
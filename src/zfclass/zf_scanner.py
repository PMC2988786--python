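"""C2H2 zinc-finger detection, tandem-architecture assembly and trimming.

The gli/glis/nkl/zic superfamily is defined by five tandem C2H2 zinc fingers.
A C2H2 finger is matched here as the literal pattern

    C - x(a..b) - C - x(c..d) - H - x(e..f) - H

where x(m..n) is a bounded run of arbitrary residues and the gap counts are
the residues *strictly between* the flanking coordinating positions. The
zic sub-family is diagnosed by an expanded Cys-Cys spacer in the first
finger (ZF1): canonical C2H2 fingers carry 2-4 residues between the
cysteines, zic ZF1 carries substantially more.

Two trimming rules feed downstream analyses:

* the *ZF region* (ZF1 first cysteine through ZF5 last histidine,
  inclusive) — the region used for distance/tree building;
* the *N-terminal region* (sequence start through the second residue after
  ZF1's first cysteine) — the region scanned for ZOC and ZF-NC motifs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import itertools
import logging

from .seqio import ProteinRecord

logger = logging.getLogger("zfclass")


@dataclass(frozen=True)
class ScanParams:
    """Pattern bounds and architecture thresholds; all configurable.

    Gap bounds count residues strictly between the two flanking positions.
    The wide Cys-Cys upper bound accommodates the expanded zic ZF1 spacer.
    """

    cc_min: int = 2      # Cys1..Cys2 spacer
    cc_max: int = 25
    ch_min: int = 9      # Cys2..His1 gap
    ch_max: int = 16
    hh_min: int = 3      # His1..His2 spacer
    hh_max: int = 6
    max_linker: int = 15          # max residues between consecutive fingers
    zf1_spacing_threshold: int = 8  # >= threshold -> zic-like ZF1
    allow_partial: bool = False   # accept best 4-finger chain, flagged partial


@dataclass(frozen=True)
class ZFDomainHit:
    """One candidate C2H2 finger: 0-based positions of C, C, H, H."""

    cys1: int
    cys2: int
    his1: int
    his2: int
    index: int = 0  # 1..5 once placed in an architecture; 0 = unplaced

    def __post_init__(self) -> None:
        if not (self.cys1 < self.cys2 < self.his1 < self.his2):
            raise ValueError("C2H2 positions must satisfy Cys1 < Cys2 < His1 < His2")

    @property
    def spacer_cc(self) -> int:
        """Residues strictly between the two cysteines."""
        return self.cys2 - self.cys1 - 1

    @property
    def spacer_hh(self) -> int:
        """Residues strictly between the two histidines."""
        return self.his2 - self.his1 - 1

    @property
    def start(self) -> int:
        return self.cys1

    @property
    def end(self) -> int:
        """Exclusive end (half-open interval)."""
        return self.his2 + 1

    def overlaps(self, other: "ZFDomainHit") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class ZFArchitecture:
    """An ordered tandem chain of C2H2 fingers (5, or 4 in partial mode)."""

    hits: tuple[ZFDomainHit, ...]
    partial: bool = False

    def __post_init__(self) -> None:
        n = len(self.hits)
        if n not in (4, 5):
            raise ValueError(f"architecture must have 4 or 5 fingers, got {n}")
        if n == 5 and self.partial:
            raise ValueError("a 5-finger architecture is not partial")
        for a, b in itertools.pairwise(self.hits):
            if a.end > b.start:
                raise ValueError("architecture fingers must be ordered and non-overlapping")

    @property
    def linkers(self) -> tuple[int, ...]:
        """Residue counts between consecutive fingers (His2 .. next Cys1)."""
        return tuple(b.start - a.end for a, b in itertools.pairwise(self.hits))

    @property
    def zf1_spacing(self) -> int:
        """Cys-Cys spacer of the first detected finger.

        In partial mode the first finger may be ZF2, mirroring proteins where
        ZF1 could not be recovered; the spacing then refers to that finger
        and the partial flag marks the call as provisional.
        """
        return self.hits[0].spacer_cc

    @property
    def span(self) -> int:
        """Residues from first Cys through last His, inclusive."""
        return self.hits[-1].his2 - self.hits[0].cys1 + 1


def find_c2h2_hits(record: ProteinRecord, params: ScanParams = ScanParams()) -> list[ZFDomainHit]:
    """Enumerate every C2H2 position quadruple satisfying the pattern bounds.

    All candidates are reported, including mutually overlapping ones;
    resolution into a tandem chain happens in :func:`assemble_architecture`.
    Hits are ordered left-to-right by (cys1, cys2, his1, his2).
    """
    seq = record.sequence
    c_pos = [i for i, ch in enumerate(seq) if ch == "C"]
    h_pos = [i for i, ch in enumerate(seq) if ch == "H"]

    def in_window(positions: list[int], lo: int, hi: int) -> list[int]:
        return [p for p in positions if lo <= p <= hi]

    hits: list[ZFDomainHit] = []
    for c1 in c_pos:
        for c2 in in_window(c_pos, c1 + params.cc_min + 1, c1 + params.cc_max + 1):
            for h1 in in_window(h_pos, c2 + params.ch_min + 1, c2 + params.ch_max + 1):
                for h2 in in_window(h_pos, h1 + params.hh_min + 1, h1 + params.hh_max + 1):
                    hits.append(ZFDomainHit(c1, c2, h1, h2))
    hits.sort(key=lambda h: (h.cys1, h.cys2, h.his1, h.his2))
    return hits


def assemble_architecture(
    hits: list[ZFDomainHit], params: ScanParams = ScanParams()
) -> ZFArchitecture | None:
    """Pick the best tandem chain of exactly 5 non-overlapping fingers.

    A chain is valid when consecutive fingers do not overlap and every
    linker is at most ``params.max_linker``. Among valid chains the one
    with the smallest total span wins; ties break to the leftmost start.
    Returns ``None`` when no 5-chain exists, unless ``params.allow_partial``
    is set, in which case the best 4-chain is returned flagged ``partial``.
    """
    chain = _best_chain(hits, 5, params.max_linker)
    if chain is not None:
        return ZFArchitecture(hits=_reindex(chain), partial=False)
    if params.allow_partial:
        chain = _best_chain(hits, 4, params.max_linker)
        if chain is not None:
            return ZFArchitecture(hits=_reindex(chain), partial=True)
    return None


def _reindex(chain: tuple[ZFDomainHit, ...]) -> tuple[ZFDomainHit, ...]:
    return tuple(
        ZFDomainHit(h.cys1, h.cys2, h.his1, h.his2, index=i + 1)
        for i, h in enumerate(chain)
    )


def _best_chain(
    hits: list[ZFDomainHit], k: int, max_linker: int
) -> tuple[ZFDomainHit, ...] | None:
    """Depth-first search over ordered hit chains of length *k*.

    Candidate hit lists are small in practice (a handful per finger), so
    exhaustive search with sort-order pruning is both simple and exact.
    Optimality key: (span, chain start, chain position tuple).
    """
    ordered = sorted(hits, key=lambda h: (h.start, h.end))
    n = len(ordered)
    best: tuple[tuple[int, int, tuple[int, ...]], tuple[ZFDomainHit, ...]] | None = None

    def extend(chain: list[ZFDomainHit], next_idx: int) -> None:
        nonlocal best
        if len(chain) == k:
            cand = tuple(chain)
            key = (
                cand[-1].his2 - cand[0].cys1 + 1,
                cand[0].cys1,
                tuple(p for h in cand for p in (h.cys1, h.cys2, h.his1, h.his2)),
            )
            if best is None or key < best[0]:
                best = (key, cand)
            return
        if n - next_idx < k - len(chain):
            return
        for i in range(next_idx, n):
            h = ordered[i]
            if chain:
                gap = h.start - chain[-1].end
                if gap < 0 or gap > max_linker:
                    continue
            chain.append(h)
            extend(chain, i + 1)
            chain.pop()

    extend([], 0)
    return best[1] if best is not None else None


def zf1_spacing_diagnostic(arch: ZFArchitecture, threshold: int = 8) -> bool:
    """True iff the first finger's Cys-Cys spacer is zic-like (>= threshold)."""
    return arch.zf1_spacing >= threshold


def trim_zf_region(record: ProteinRecord, arch: ZFArchitecture) -> str:
    """Subsequence from ZF1's first Cys through ZF5's last His, inclusive.

    This is the region used for pairwise distances and tree building.
    """
    return record.sequence[arch.hits[0].cys1 : arch.hits[-1].his2 + 1]


def trim_nterm_region(record: ProteinRecord, arch: ZFArchitecture) -> str:
    """Prefix ending two residues after ZF1's first Cys (inclusive).

    In 0-based coordinates the prefix length is ``cys1 + 3``; this is the
    region scanned for ZOC and ZF-NC motifs. A Cys within the first three
    residues yields the available prefix with a logged warning.
    """
    cys1 = arch.hits[0].cys1
    end = cys1 + 3
    if end > len(record.sequence):
        logger.warning(
            "record %r: N-terminal trim point beyond sequence end; returning full sequence",
            record.id,
        )
        end = len(record.sequence)
    return record.sequence[:end]


def architecture_report_row(record: ProteinRecord, arch: ZFArchitecture | None,
                            params: ScanParams = ScanParams()) -> dict:
    """One TSV-ready report row per record; thresholds surfaced for audit."""
    if arch is None:
        return {
            "id": record.id,
            "n_zf": 0,
            "zf_positions": "",
            "spacer_cc": "",
            "zf1_spacing": "",
            "zic_like_zf1": "",
            "partial": "",
            "zf1_threshold": params.zf1_spacing_threshold,
        }
    return {
        "id": record.id,
        "n_zf": len(arch.hits),
        "zf_positions": ";".join(
            f"{h.cys1},{h.cys2},{h.his1},{h.his2}" for h in arch.hits
        ),
        "spacer_cc": ";".join(str(h.spacer_cc) for h in arch.hits),
        "zf1_spacing": arch.zf1_spacing,
        "zic_like_zf1": zf1_spacing_diagnostic(arch, params.zf1_spacing_threshold),
        "partial": arch.partial,
        "zf1_threshold": params.zf1_spacing_threshold,
    }
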
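"""Subfamily calling from architecture + motif evidence, with NJ placement.

The decision logic mirrors how the superfamily is diagnosed in practice:

1. no five-tandem-ZF architecture (nor a flagged partial one) -> non-family;
2. architecture present but no zic character -> gli/glis/nkl-like;
3. an expanded ZF1 inter-cysteine spacer OR a ZOC / location-checked ZF-NC
   motif above the similarity threshold -> zic.

Placement against a labelled reference panel is advisory: it refines
gli/glis/nkl-like calls into gli vs glis vs nkl (those subfamilies carry no
distinguishing sequence character, only tree affinity), and it never
overturns the rule-based zic / non-zic decision. Distances are p-distances
over the trimmed ZF regions — the same region a full phylogenetic analysis
would align — under a gapless sliding-offset best alignment. Tree building
uses standard neighbor joining.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import skbio

from .seqio import ProteinRecord, SeqIOError, SpeciesTree, parse_newick
from .zf_scanner import (
    ScanParams,
    ZFArchitecture,
    assemble_architecture,
    find_c2h2_hits,
    trim_nterm_region,
    trim_zf_region,
    zf1_spacing_diagnostic,
)
from .motif_scoring import (
    DEFAULT_GROUPING,
    MotifMatch,
    PATTERNS,
    SimilarityGrouping,
    ZFNC,
    ZOC_REVISED,
    best_match,
    scan_motif,
    zfnc_location_check,
)

#: The full call vocabulary.
LABELS = ("zic", "gli", "glis", "nkl", "gli/glis/nkl-like", "non-family")


@dataclass(frozen=True)
class ClassifyParams:
    """Thresholds feeding the rule-based call; all configurable."""

    scan: ScanParams = ScanParams()
    min_similarity: float = 70.0   # motif "present" threshold (%)
    zfnc_max_gap: int = 30         # max residues between ZF-NC end and ZF1 Cys1
    grouping: SimilarityGrouping = DEFAULT_GROUPING


@dataclass(frozen=True)
class SubfamilyCall:
    """A label with its full evidence trail and optional placement."""

    record_id: str
    label: str
    evidence: tuple[tuple[str, object, bool], ...]
    partial: bool = False
    placement: tuple[str, float] | None = None
    placement_tie: bool = False

    def passed(self) -> list[str]:
        return [c for c, _, ok in self.evidence if ok]


def rule_classify(
    record: ProteinRecord,
    arch: ZFArchitecture | None,
    motif_matches: dict[str, MotifMatch | None],
    params: ClassifyParams = ClassifyParams(),
) -> SubfamilyCall:
    """Combine architecture, spacing and motif evidence into a call.

    ``motif_matches`` maps pattern name to the best located match (or None)
    in the record's N-terminal region; location checking for ZF-NC happens
    here so the evidence trail records it.
    """
    evidence: list[tuple[str, object, bool]] = []
    if arch is None:
        evidence.append(("five_tandem_zf", 0, False))
        return SubfamilyCall(record.id, "non-family", tuple(evidence))

    evidence.append(("five_tandem_zf", len(arch.hits), True))
    spacing_ok = zf1_spacing_diagnostic(arch, params.scan.zf1_spacing_threshold)
    evidence.append(
        (
            f"zf1_spacing>={params.scan.zf1_spacing_threshold}",
            arch.zf1_spacing,
            spacing_ok and not arch.partial,  # partial: first finger may be ZF2
        )
    )

    zoc = motif_matches.get(ZOC_REVISED.name) or motif_matches.get("ZOC_published")
    zoc_ok = zoc is not None and zoc.percent_similarity >= params.min_similarity
    evidence.append(
        ("zoc_motif", None if zoc is None else round(zoc.percent_similarity, 1), zoc_ok)
    )

    zfnc = motif_matches.get(ZFNC.name)
    zfnc_ok = (
        zfnc is not None
        and zfnc.percent_similarity >= params.min_similarity
        and zfnc_location_check(zfnc, arch, params.zfnc_max_gap)
    )
    evidence.append(
        ("zfnc_motif", None if zfnc is None else round(zfnc.percent_similarity, 1), zfnc_ok)
    )

    if (spacing_ok and not arch.partial) or zoc_ok or zfnc_ok:
        label = "zic"
    else:
        label = "gli/glis/nkl-like"
    return SubfamilyCall(record.id, label, tuple(evidence), partial=arch.partial)


def classify_record(
    record: ProteinRecord, params: ClassifyParams = ClassifyParams()
) -> tuple[SubfamilyCall, ZFArchitecture | None]:
    """Run the per-record pipeline: scan, assemble, motif-scan, classify."""
    hits = find_c2h2_hits(record, params.scan)
    arch = assemble_architecture(hits, params.scan)
    matches: dict[str, MotifMatch | None] = {}
    if arch is not None:
        region = trim_nterm_region(record, arch)
        for name, pattern in PATTERNS.items():
            found = scan_motif(region, pattern, params.min_similarity, params.grouping)
            matches[name] = found[0] if found else best_match(region, pattern, params.grouping)
            if matches[name] is not None and matches[name].percent_similarity < params.min_similarity:
                # below-threshold best match is retained for reporting only
                pass
    return rule_classify(record, arch, matches, params), arch


# ---------------------------------------------------------------------------
# Distances, NJ and placement
# ---------------------------------------------------------------------------

def pairwise_distance(a: str, b: str) -> float:
    """p-distance under the best gapless sliding offset.

    The shorter sequence is slid along the longer; at each full-containment
    offset the identical fraction over the shorter's length is computed and
    the best (largest) is kept. Returns 1 - best_fraction, in [0, 1].
    X matches nothing, including itself.
    """
    if not a or not b:
        raise ValueError("pairwise_distance requires non-empty sequences")
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    n = len(short)
    best = 0
    for off in range(len(long_) - n + 1):
        ident = sum(
            1 for x, y in zip(short, long_[off : off + n]) if x == y and x != "X"
        )
        best = max(best, ident)
    return 1.0 - best / n


def distance_matrix(named_seqs: list[tuple[str, str]]) -> skbio.DistanceMatrix:
    """Symmetric p-distance matrix over (name, sequence) pairs."""
    ids = [name for name, _ in named_seqs]
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_distance(named_seqs[i][1], named_seqs[j][1])
            mat[i, j] = mat[j, i] = d
    return skbio.DistanceMatrix(mat, ids=ids)


def nj_tree(dm: skbio.DistanceMatrix) -> SpeciesTree:
    """Neighbor-joining tree from a distance matrix, rooted for display.

    Standard NJ agglomeration (scikit-bio); the unrooted result is returned
    rooted at its final join. Fewer than 3 taxa is an error.
    """
    if dm.shape[0] < 3:
        raise SeqIOError("neighbor joining requires at least 3 taxa")
    tree = skbio.tree.nj(dm)
    return parse_newick(str(tree))


@dataclass(frozen=True)
class ReferencePanel:
    """Labelled reference proteins with their trimmed ZF regions cached."""

    members: tuple[tuple[ProteinRecord, str, str], ...]  # (record, label, trimmed)

    @classmethod
    def build(
        cls,
        labelled_records: list[tuple[ProteinRecord, str]],
        params: ClassifyParams = ClassifyParams(),
    ) -> "ReferencePanel":
        members = []
        for rec, label in labelled_records:
            if label not in LABELS:
                raise SeqIOError(f"panel label {label!r} not in vocabulary")
            hits = find_c2h2_hits(rec, params.scan)
            arch = assemble_architecture(hits, params.scan)
            if arch is None:
                raise SeqIOError(f"panel record {rec.id!r} has no ZF architecture")
            members.append((rec, label, trim_zf_region(rec, arch)))
        counts: dict[str, int] = {}
        for _, label, _ in members:
            counts[label] = counts.get(label, 0) + 1
        thin = [l for l, c in counts.items() if c < 2]
        if thin:
            raise SeqIOError(
                f"placement needs >= 2 members per subfamily; too few for: {thin}"
            )
        return cls(members=tuple(members))

    def labels(self) -> list[str]:
        return sorted({label for _, label, _ in self.members})


def place_query(
    query_trimmed: str,
    panel: ReferencePanel,
    rule_label: str | None = None,
) -> tuple[str, float, bool]:
    """Nearest-subfamily placement by smallest mean p-distance.

    Returns (label, mean distance, tie flag). An exact tie breaks to the
    rule-based label when that label is among the tied set, else to the
    lexicographically first, and is flagged.
    """
    if not panel.members:
        raise SeqIOError("cannot place against an empty panel")
    sums: dict[str, list[float]] = {}
    for _, label, trimmed in panel.members:
        sums.setdefault(label, []).append(pairwise_distance(query_trimmed, trimmed))
    means = {label: float(np.mean(ds)) for label, ds in sums.items()}
    best = min(means.values())
    tied = sorted(l for l, m in means.items() if np.isclose(m, best, atol=1e-12))
    tie = len(tied) > 1
    if tie and rule_label in tied:
        return rule_label, best, True
    return tied[0], best, tie


def classify_and_place(
    record: ProteinRecord,
    panel: ReferencePanel | None = None,
    params: ClassifyParams = ClassifyParams(),
) -> SubfamilyCall:
    """Full per-record call: rules first, placement refining only the
    gli/glis/nkl-like bucket. Without a panel that bucket stays as-is."""
    call, arch = classify_record(record, params)
    if panel is None or arch is None:
        return call
    trimmed = trim_zf_region(record, arch)
    label, dist, tie = place_query(trimmed, panel, rule_label=call.label)
    placement = (label, dist)
    final = call.label
    if call.label == "gli/glis/nkl-like" and label in ("gli", "glis", "nkl"):
        final = label
    return SubfamilyCall(
        record_id=call.record_id,
        label=final,
        evidence=call.evidence,
        partial=call.partial,
        placement=placement,
        placement_tie=tie,
    )


def calls_report_rows(calls: list[SubfamilyCall]) -> list[dict]:
    rows = []
    for c in calls:
        rows.append(
            {
                "id": c.record_id,
                "label": c.label,
                "partial": c.partial,
                "evidence": ";".join(
                    f"{name}={val}:{'pass' if ok else 'fail'}"
                    for name, val, ok in c.evidence
                ),
                "placement": "" if c.placement is None else c.placement[0],
                "placement_distance": "" if c.placement is None else round(c.placement[1], 4),
                "placement_tie": c.placement_tie,
            }
        )
    return rows
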
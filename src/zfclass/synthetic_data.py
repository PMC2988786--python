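"""Labelled synthetic superfamily proteins with planted ground truth.

Each generated protein emulates the characters that define the
gli/glis/nkl/zic superfamily: five tandem C2H2 zinc fingers, a
subfamily-dependent ZF1 inter-cysteine spacer (expanded for zic, canonical
2-4 for the others), and — for zic — optional exact-consensus ZOC and ZF-NC
motifs planted in the N-terminal tail, the ZF-NC immediately upstream of
ZF1. Filler residues are drawn from a background alphabet that excludes C
and H so that the planted coordinating positions are the only pattern
anchors; point mutations are then applied residue-wise at rate mu,
sparing the four zinc-coordinating positions of every finger so recovery
tests measure the pipeline rather than generator damage.

Every protein carries a :class:`GroundTruth` with the planted coordinates.
Generation is fully reproducible from the seed. No claim of biological
realism is made for filler composition; the geometry and motifs are the
modelled characters.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .seqio import AMINO_ACIDS, ProteinRecord, write_fasta
from .zf_scanner import ZFDomainHit

#: Background alphabet for filler: the 18 residues that are not C or H.
BACKGROUND_ALPHABET = "".join(a for a in AMINO_ACIDS if a not in "CH")

#: Subfamily labels the generator can plant (non-family is not generated).
GENERATOR_LABELS = ("zic", "gli", "glis", "nkl")

# Fixed per-subfamily template seeds so that every dataset (panels and
# queries alike) shares one canonical ZF-region template per subfamily;
# placement distance then reflects subfamily membership, not draw identity.
_TEMPLATE_SEEDS = {"zic": 11, "gli": 23, "glis": 37, "nkl": 53}

# Fixed per-subfamily finger geometry. Canonical subfamilies keep distinct
# but canonical (2-4) ZF1 spacers; zic draws an expanded spacer per protein.
_CANONICAL_ZF1 = {"gli": 2, "glis": 3, "nkl": 4}
_CH_GAP = 12   # Cys2..His1 gap, within the 9..16 scan window
_HH_GAP = 4    # His1..His2 spacer, within 3..6
_BODY_SPACER = 3  # Cys-Cys spacer of fingers 2-5
_LINKER = 7    # inter-finger linker length


@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions for synthetic protein generation.

    ``mu`` is the per-residue point-mutation probability; zic motif
    presence probabilities default to 1 so a zic protein carries both
    diagnostic motifs unless configured otherwise.
    """

    zic_zf1_spacer_min: int = 10
    zic_zf1_spacer_max: int = 14
    zoc_probability: float = 1.0
    zfnc_probability: float = 1.0
    zoc_spacer_range: tuple[int, int] = (1, 2)
    zfnc_spacer_range: tuple[int, int] = (0, 7)
    ntail_range: tuple[int, int] = (25, 60)
    ctail_range: tuple[int, int] = (5, 30)
    mu: float = 0.0
    partial: bool = False  # drop ZF1 (plant fingers 2-5 only)

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu < 1.0):
            raise ValueError("mu must be in [0, 1)")
        for p in (self.zoc_probability, self.zfnc_probability):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Planted coordinates and states for one synthetic protein."""

    label: str
    zf_hits: tuple[ZFDomainHit, ...]
    zf1_spacing: int
    zoc_interval: tuple[int, int] | None  # half-open, None if not planted
    zfnc_interval: tuple[int, int] | None
    mutated_positions: tuple[int, ...]
    partial: bool = False


def _template_rng(label: str) -> np.random.Generator:
    return np.random.default_rng(_TEMPLATE_SEEDS[label])


def _filler(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return "".join(rng.choice(list(BACKGROUND_ALPHABET), size=n))


def _finger(rng: np.random.Generator, cc_spacer: int) -> str:
    """One C2H2 finger body with the given Cys-Cys spacer."""
    return (
        "C" + _filler(rng, cc_spacer) + "C" + _filler(rng, _CH_GAP)
        + "H" + _filler(rng, _HH_GAP) + "H"
    )


def _zf_region_template(label: str, zf1_spacer: int) -> str:
    """Deterministic subfamily ZF-region template with the given ZF1 spacer.

    Fingers 2-5 and the linkers come from the subfamily's fixed template
    RNG, so two proteins of the same subfamily share their entire ZF region
    up to mutations and the (zic-only) variable ZF1 spacer fill.
    """
    rng = _template_rng(label)
    parts = [_finger(rng, zf1_spacer if label != "zic" else 12)]
    for _ in range(4):
        parts.append(_filler(rng, _LINKER))
        parts.append(_finger(rng, _BODY_SPACER))
    region = "".join(parts)
    if label == "zic" and zf1_spacer != 12:
        # re-render ZF1 with the drawn spacer, reusing the template filler
        rng2 = _template_rng(label)
        base_fill = _filler(rng2, 12)
        fill = (base_fill * 3)[:zf1_spacer]
        zf1 = "C" + fill + "C" + region[14 : 14 + _CH_GAP + 1 + _HH_GAP + 1]
        region = zf1 + region[12 + 2 + _CH_GAP + 1 + _HH_GAP + 1 :]
    return region


def _motif_instance(rng: np.random.Generator, kind: str, params: GeneratorParams) -> str:
    if kind == "zoc":
        lo, hi = params.zoc_spacer_range
        spacer = int(rng.integers(lo, hi + 1))
        return "RDFL" + _filler(rng, spacer) + "RR"
    lo, hi = params.zfnc_spacer_range
    spacer = int(rng.integers(lo, hi + 1))
    alt = "F" if rng.random() < 0.5 else "L"
    return "GAF" + alt + "RYMRQP" + _filler(rng, spacer) + "IKQE"


def _has_chance_motif(region: str, threshold: float = 70.0) -> bool:
    from .motif_scoring import PATTERNS, scan_motif

    return any(
        scan_motif(region, pattern, min_similarity=threshold)
        for pattern in PATTERNS.values()
    )


def _plan_zf_hits(offset: int, zf1_spacer: int, n_fingers: int) -> tuple[ZFDomainHit, ...]:
    hits = []
    pos = offset
    for i in range(n_fingers):
        spacer = zf1_spacer if i == 0 else _BODY_SPACER
        c1 = pos
        c2 = c1 + spacer + 1
        h1 = c2 + _CH_GAP + 1
        h2 = h1 + _HH_GAP + 1
        hits.append(ZFDomainHit(c1, c2, h1, h2, index=i + 1))
        pos = h2 + 1 + _LINKER
    return tuple(hits)


def make_protein(
    label: str,
    params: GeneratorParams,
    rng: np.random.Generator,
    record_id: str = "syn",
) -> tuple[ProteinRecord, GroundTruth]:
    """Generate one labelled protein and its planted ground truth.

    Layout: N-tail [ZOC] mid-fill [ZF-NC] short-gap ZF-region C-tail.
    Mutations at rate ``mu`` replace a residue by a different background
    residue, never touching the planted C/C/H/H coordinating positions.
    """
    if label not in GENERATOR_LABELS:
        raise ValueError(f"label must be one of {GENERATOR_LABELS}, got {label!r}")

    if label == "zic":
        zf1_spacer = int(
            rng.integers(params.zic_zf1_spacer_min, params.zic_zf1_spacer_max + 1)
        )
    else:
        zf1_spacer = _CANONICAL_ZF1[label]

    zf_region = _zf_region_template(label, zf1_spacer)
    if params.partial:
        # drop ZF1 and its linker: architecture starts at ZF2
        drop = zf1_spacer + 2 + _CH_GAP + 1 + _HH_GAP + 1 + _LINKER
        zf_region = zf_region[drop:]
        zf1_spacer_planted = _BODY_SPACER
        n_fingers = 4
    else:
        zf1_spacer_planted = zf1_spacer
        n_fingers = 5

    zoc = zfnc = ""
    if label == "zic":
        if rng.random() < params.zoc_probability:
            zoc = _motif_instance(rng, "zoc", params)
        if rng.random() < params.zfnc_probability:
            zfnc = _motif_instance(rng, "zfnc", params)

    # Non-zic tails are rejection-sampled so the planted label is consistent
    # with the diagnostic characters: a background tail that happens to carry
    # an above-threshold ZOC/ZF-NC-like stretch would mislabel the protein
    # by construction.
    for _ in range(200):
        pre = _filler(rng, int(rng.integers(*_incl(params.ntail_range))))
        mid = _filler(rng, int(rng.integers(8, 20))) if (zoc and zfnc) else ""
        gap = _filler(rng, int(rng.integers(2, 9)))  # ZF-NC sits close to ZF1
        ctail = _filler(rng, int(rng.integers(*_incl(params.ctail_range))))

        zoc_iv = zfnc_iv = None
        pos = len(pre)
        if zoc:
            zoc_iv = (pos, pos + len(zoc))
            pos += len(zoc)
        pos += len(mid)
        if zfnc:
            zfnc_iv = (pos, pos + len(zfnc))
            pos += len(zfnc)
        pos += len(gap)
        zf_offset = pos
        sequence = pre + zoc + mid + zfnc + gap + zf_region + ctail
        if label == "zic" or not _has_chance_motif(sequence[: zf_offset + 3]):
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not draw a motif-free background tail")

    hits = _plan_zf_hits(zf_offset, zf1_spacer if not params.partial else _BODY_SPACER,
                         n_fingers)

    protected = {p for h in hits for p in (h.cys1, h.cys2, h.his1, h.his2)}
    seq = list(sequence)
    mutated = []
    if params.mu > 0:
        draws = rng.random(len(seq))
        for i, (ch, d) in enumerate(zip(seq, draws)):
            if d < params.mu and i not in protected:
                choices = [a for a in BACKGROUND_ALPHABET if a != ch]
                seq[i] = str(rng.choice(choices))
                mutated.append(i)
    record = ProteinRecord(id=record_id, sequence="".join(seq), species=f"synthetic_{label}")
    truth = GroundTruth(
        label=label,
        zf_hits=hits,
        zf1_spacing=zf1_spacer_planted,
        zoc_interval=zoc_iv,
        zfnc_interval=zfnc_iv,
        mutated_positions=tuple(mutated),
        partial=params.partial,
    )
    return record, truth


def _incl(rng_pair: tuple[int, int]) -> tuple[int, int]:
    lo, hi = rng_pair
    return lo, hi + 1


def make_dataset(
    n: int,
    label_mix: dict[str, float],
    params: GeneratorParams,
    seed: int,
) -> tuple[list[ProteinRecord], list[GroundTruth]]:
    """Generate *n* labelled proteins with labels drawn from ``label_mix``.

    ``label_mix`` maps subfamily labels to sampling weights (normalized
    internally). Fully reproducible for a given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    labels = list(label_mix)
    bad = [l for l in labels if l not in GENERATOR_LABELS]
    if bad:
        raise ValueError(f"unknown labels in mix: {bad}")
    weights = np.asarray([label_mix[l] for l in labels], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("label mix weights must sum to a positive value")
    weights = weights / weights.sum()

    rng = np.random.default_rng(seed)
    records, truths = [], []
    for i in range(n):
        label = str(rng.choice(labels, p=weights))
        rec, truth = make_protein(label, params, rng, record_id=f"syn{i:04d}_{label}")
        records.append(rec)
        truths.append(truth)
    return records, truths


def write_dataset(
    records: list[ProteinRecord],
    truths: list[GroundTruth],
    fasta_path: str | Path,
    truth_path: str | Path,
) -> None:
    """Write the FASTA and companion ground-truth TSV."""
    write_fasta(records, fasta_path)
    with open(truth_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["id", "label", "zf1_spacing", "zf_positions", "zoc", "zfnc",
             "n_mutations", "partial"]
        )
        for rec, t in zip(records, truths):
            writer.writerow(
                [
                    rec.id,
                    t.label,
                    t.zf1_spacing,
                    ";".join(f"{h.cys1},{h.cys2},{h.his1},{h.his2}" for h in t.zf_hits),
                    "" if t.zoc_interval is None else f"{t.zoc_interval[0]}-{t.zoc_interval[1]}",
                    "" if t.zfnc_interval is None else f"{t.zfnc_interval[0]}-{t.zfnc_interval[1]}",
                    len(t.mutated_positions),
                    t.partial,
                ]
            )


def make_reference_panel(
    per_label: int = 4,
    mu: float = 0.01,
    seed: int = 2024,
) -> list[tuple[ProteinRecord, str]]:
    """A labelled synthetic reference panel for distance-based placement."""
    panel = []
    rng = np.random.default_rng(seed)
    params = GeneratorParams(mu=mu)
    for label in GENERATOR_LABELS:
        for j in range(per_label):
            rec, _ = make_protein(label, params, rng, record_id=f"panel_{label}{j}")
            panel.append((rec, label))
    return panel
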
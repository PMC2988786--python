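"""Sequence, tree and presence-table I/O.

All downstream coordinates are defined here: sequence positions are 0-based
and intervals are half-open unless a function explicitly documents inclusive
endpoints. Amino-acid sequences are uppercase strings over the 20 standard
residues plus ``X`` (unknown, as produced by translated genome assemblies);
``X`` never matches a consensus position and never counts as identical or
similar anywhere in the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("zfclass")

#: The 20 standard amino acids.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residues accepted in a ProteinRecord sequence.
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")


class SeqIOError(ValueError):
    """Raised on malformed sequence, tree or table input."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an identifier and optional species tag."""

    id: str
    sequence: str
    species: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SeqIOError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.sequence):
            if ch not in VALID_RESIDUES:
                raise SeqIOError(
                    f"record {self.id!r}: illegal residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PresenceMap:
    """Taxon -> gene presence (True) / absence (False) for one gene family."""

    presence: Mapping[str, bool]

    def present_taxa(self) -> frozenset[str]:
        return frozenset(t for t, p in self.presence.items() if p)

    def validate_against(self, tree: "SpeciesTree") -> None:
        """Every taxon in the map must be a leaf label of *tree*."""
        leaves = set(tree.leaf_labels())
        unknown = sorted(set(self.presence) - leaves)
        if unknown:
            raise SeqIOError(f"taxa not in tree: {', '.join(unknown)}")


class SpeciesTree:
    """A rooted species tree with unique leaf labels.

    Thin wrapper over a :class:`dendropy.Tree`; internal nodes may carry
    labels naming candidate gene-family origin points.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise SeqIOError(f"duplicate leaf labels: {', '.join(sorted(dupes))}")

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    def find_node(self, label: str) -> dendropy.Node:
        """Locate a node by internal label or leaf (taxon) label."""
        for node in self._tree.preorder_node_iter():
            if node.taxon is not None and node.taxon.label == label:
                return node
            if node.label == label:
                return node
        raise SeqIOError(f"no node labelled {label!r} in tree")

    def node_label(self, node: dendropy.Node) -> str:
        if node.taxon is not None:
            return node.taxon.label
        return node.label or "<unlabelled>"

    def leaf_labels_under(self, node: dendropy.Node) -> frozenset[str]:
        return frozenset(
            lf.taxon.label for lf in node.leaf_iter()
        )

    def as_newick(self) -> str:
        return (
            self._tree.as_string(
                schema="newick", suppress_rooting=True, unquoted_underscores=True
            ).strip()
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _record_from_seqio(rec: SeqRecord) -> ProteinRecord:
    seq = str(rec.seq).upper()
    if seq.endswith("*") or "*" in seq:
        logger.warning("record %r: stripping '*' stop character(s)", rec.id)
        seq = seq.replace("*", "")
    # species tag = description after the first whitespace, when present
    desc = rec.description
    species = ""
    if desc and desc != rec.id:
        parts = desc.split(None, 1)
        if len(parts) == 2:
            species = parts[1].strip()
    return ProteinRecord(id=rec.id, sequence=seq, species=species)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into a list of :class:`ProteinRecord`.

    Order is preserved; the header text after the first whitespace is stored
    as the species tag. An empty file or an illegal residue raises
    :class:`SeqIOError` (the error names the record and 0-based position).
    """
    records = [_record_from_seqio(r) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise SeqIOError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA."""
    seqio_records = []
    for rec in records:
        desc = rec.species if rec.species else ""
        seqio_records.append(SeqRecord(Seq(rec.sequence), id=rec.id, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqio_records)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> SpeciesTree:
    """Read a rooted newick tree, keeping internal node labels.

    Child ordering is preserved as written. Unbalanced parentheses or
    duplicate leaf labels raise :class:`SeqIOError`.
    """
    text = Path(path).read_text()
    return parse_newick(text)


def parse_newick(text: str) -> SpeciesTree:
    """Parse a rooted newick string (see :func:`read_newick`)."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise SeqIOError(f"invalid newick: {exc}") from exc
    tree.is_rooted = True
    return SpeciesTree(tree)


def write_newick(tree: SpeciesTree, path: str | Path) -> None:
    Path(path).write_text(tree.as_newick() + "\n")


# ---------------------------------------------------------------------------
# Presence table
# ---------------------------------------------------------------------------

def read_presence_table(path: str | Path) -> PresenceMap:
    """Read a two-column delimited table of taxon and 0/1 presence.

    Columns may be separated by tabs or spaces; lines starting with ``#``
    are ignored. Values outside {0, 1} and duplicate taxa raise
    :class:`SeqIOError`.
    """
    presence: dict[str, bool] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise SeqIOError(f"{path}:{lineno}: expected 'taxon 0/1', got {raw!r}")
        taxon, value = parts
        if value not in ("0", "1"):
            raise SeqIOError(
                f"{path}:{lineno}: presence value must be 0 or 1, got {value!r}"
            )
        if taxon in presence:
            raise SeqIOError(f"{path}:{lineno}: duplicate taxon {taxon!r}")
        presence[taxon] = value == "1"
    if not presence:
        raise SeqIOError(f"{path}: empty presence table")
    return PresenceMap(presence=presence)


def write_presence_table(pmap: PresenceMap, path: str | Path) -> None:
    lines = [f"{taxon}\t{int(flag)}" for taxon, flag in pmap.presence.items()]
    Path(path).write_text("\n".join(lines) + "\n")
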
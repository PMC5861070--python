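"""Alignment, metadata and tree I/O.

Aligned FASTA (protein or nucleotide), a tab-separated metadata table
mapping sequence id to species/clade/group, and Newick trees with integer
bootstrap labels on internal nodes.  All user-facing coordinates are
1-based inclusive; internally columns are 0-based half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: controlled vocabulary for the clade column; anything else maps to "other"
VALID_CLADES = frozenset(
    {"mammal", "bird", "reptile", "bony_fish", "cartilaginous_fish", "other"}
)


class SeqioError(ValueError):
    """Malformed input: duplicate ids, ragged alignments, bad Newick ..."""


@dataclass
class SequenceRecord:
    """One aligned sequence, optionally paired with its in-frame CDS.

    ``residues`` is the aligned string (upper case, gap ``-``, missing
    ``X``/``N``).  ``cds`` when present is the *ungapped* coding sequence
    whose translation equals the ungapped residues (a trailing stop codon
    is tolerated).
    """

    id: str
    residues: str
    cds: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqioError("sequence record with empty id")
        if not self.residues:
            raise SeqioError(f"record {self.id!r} has an empty sequence")
        if self.cds is not None:
            self.validate_cds()

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")

    def validate_cds(self) -> None:
        cds = self.cds.replace("-", "")
        prot = self.ungapped
        n = len(prot)
        if len(cds) not in (3 * n, 3 * n + 3):
            raise SeqioError(
                f"record {self.id!r}: CDS length {len(cds)} does not match "
                f"{n} residues (expected {3 * n} or {3 * n + 3})"
            )
        translated = str(Seq(cds[: 3 * n]).translate())
        # 'X' in the protein masks ambiguity; accept any translation there
        for a, b in zip(translated, prot):
            if b != "X" and a != b:
                raise SeqioError(
                    f"record {self.id!r}: CDS translation {translated!r} "
                    f"does not match residues {prot!r}"
                )


@dataclass
class Alignment:
    """An ordered multiple sequence alignment (all rows equal length)."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise SeqioError("alignment with no records")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            raise SeqioError(f"ragged alignment: row lengths {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SeqioError(f"duplicate sequence ids: {dupes}")
        self._index = {r.id: r for r in self.records}

    @property
    def length(self) -> int:
        return len(self.records[0].residues)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def get(self, seq_id: str) -> SequenceRecord:
        try:
            return self._index[seq_id]
        except KeyError:
            raise SeqioError(f"unknown sequence id {seq_id!r}") from None

    def column(self, i: int) -> str:
        """Column ``i`` (0-based) as a string, one character per record."""
        return "".join(r.residues[i] for r in self.records)

    def subset(self, ids: Iterable[str]) -> "Alignment":
        return Alignment([self.get(i) for i in ids])

    def take_columns(self, cols: Iterable[int]) -> "Alignment":
        """New alignment keeping 0-based columns ``cols`` (order given)."""
        cols = list(cols)
        out = []
        for r in self.records:
            residues = "".join(r.residues[c] for c in cols)
            cds = r.cds
            if cds is not None:
                # dropping an aligned residue drops its codon from the CDS
                kept = set(cols)
                codons, k = [], 0
                clean = cds.replace("-", "")
                for c, ch in enumerate(r.residues):
                    if ch == "-":
                        continue
                    if c in kept:
                        codons.append(clean[3 * k : 3 * k + 3])
                    k += 1
                tail = clean[3 * k :]  # retained stop codon, if any
                cds = "".join(codons) + tail
            out.append(SequenceRecord(r.id, residues, cds))
        return Alignment(out)


def read_fasta(path: str | Path) -> Alignment:
    """Read an aligned FASTA file.

    ``.`` is normalised to ``-`` and residues are case-folded to upper.
    Raises on duplicate ids or ragged row lengths.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper().replace(".", "-")
        records.append(SequenceRecord(rec.id, residues))
    if not records:
        raise SeqioError(f"no FASTA records in {path}")
    return Alignment(records)


def write_fasta(aln: Alignment, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for r in aln.records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.residues), width):
                fh.write(r.residues[i : i + width] + "\n")


def attach_cds(aln: Alignment, path: str | Path) -> Alignment:
    """Pair each alignment record with its CDS from a nucleotide FASTA."""
    cds = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in cds:
            raise SeqioError(f"duplicate CDS id {rec.id!r}")
        cds[rec.id] = str(rec.seq).upper().replace(".", "-")
    out = []
    for r in aln.records:
        if r.id not in cds:
            raise SeqioError(f"no CDS provided for {r.id!r}")
        out.append(SequenceRecord(r.id, r.residues, cds[r.id]))
    return Alignment(out)


@dataclass(frozen=True)
class MetaEntry:
    species: str
    clade: str
    group: str


@dataclass
class Metadata:
    """Lookup table: sequence id -> (species, clade, group)."""

    entries: dict[str, MetaEntry] = field(default_factory=dict)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.entries

    def __getitem__(self, seq_id: str) -> MetaEntry:
        return self.entries[seq_id]

    def ids_in_group(self, group: str) -> list[str]:
        return [i for i, e in self.entries.items() if e.group == group]

    def resolve(self, aln: Alignment) -> None:
        """Every alignment id must be present; missing ids are an error."""
        missing = [i for i in aln.ids if i not in self.entries]
        if missing:
            raise SeqioError(f"alignment ids missing from metadata: {missing}")


def read_metadata(path: str | Path) -> Metadata:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = ["id", "species", "clade", "group"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SeqioError(f"metadata missing columns: {missing}")
    if df["id"].duplicated().any():
        dupes = sorted(df.loc[df["id"].duplicated(), "id"])
        raise SeqioError(f"duplicate metadata ids: {dupes}")
    entries = {}
    for row in df.itertuples(index=False):
        clade = row.clade
        if clade not in VALID_CLADES:
            logger.warning(
                "unknown clade %r for id %r; storing as 'other'", clade, row.id
            )
            clade = "other"
        entries[row.id] = MetaEntry(row.species, clade, row.group)
    return Metadata(entries)


def write_metadata(meta: Metadata, path: str | Path) -> None:
    rows = [
        {"id": i, "species": e.species, "clade": e.clade, "group": e.group}
        for i, e in meta.entries.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- Newick ------------------------------------------------------------------

_SUPPORT_RE = re.compile(r"^\d+$")


def read_newick(path: str | Path) -> dendropy.Tree:
    """Parse a Newick tree; integer internal labels are bootstrap supports."""
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise SeqioError(f"malformed Newick in {path}: {exc}") from exc
    return tree


def parse_newick(newick: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise SeqioError(f"malformed Newick string: {exc}") from exc


def _node_newick(node: dendropy.Node) -> str:
    if node.is_leaf():
        s = node.taxon.label if node.taxon else (node.label or "")
    else:
        inner = ",".join(_node_newick(c) for c in node.child_nodes())
        label = node.label if node.label is not None else ""
        s = f"({inner}){label}"
    if node.edge.length is not None:
        s += ":" + format(node.edge.length, "g")
    return s


def tree_to_newick(tree: dendropy.Tree) -> str:
    """Serialise with ``%g`` branch lengths and bare internal support labels."""
    return _node_newick(tree.seed_node) + ";"


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(tree_to_newick(tree) + "\n")


def node_support(node: dendropy.Node) -> Optional[int]:
    """Integer bootstrap support stored on an internal node label, if any."""
    if node.label is not None and _SUPPORT_RE.match(str(node.label)):
        return int(node.label)
    return None
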
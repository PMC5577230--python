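"""Readers and writers for the plain-text formats the pipeline touches.

FASTA goes through Biopython, tables through pandas, and Newick parsing
through scikit-bio; serialization of trees is done locally so branch lengths
are printed with a fixed precision and internal support labels survive.
All writers are deterministic and every reader/writer pair round-trips.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from io import StringIO
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from skbio import TreeNode

from .dna import IUPAC_DNA, PROTEIN_LETTERS
from .util import FormatError

_FASTA_WRAP = 70
_NEWICK_META = re.compile(r"[\s()\[\]{}:;,']")


@dataclass
class SequenceRecord:
    """One FASTA record: identifier, free-text description, residues."""

    id: str
    description: str
    residues: str

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.residues)


_ALPHABETS = {
    "dna": set(IUPAC_DNA) | {"-"},
    "protein": set(PROTEIN_LETTERS) | {"X", "*", "-"},
}


def read_fasta(path: str | Path, alphabet: str = "dna") -> list[SequenceRecord]:
    """Read a FASTA file, join wrapped lines, upper-case, validate alphabet.

    Raises :class:`FormatError` naming the record and offending position on
    an illegal character, and on an empty file.
    """
    try:
        allowed = _ALPHABETS[alphabet]
    except KeyError:
        raise FormatError(f"unknown alphabet {alphabet!r}") from None
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        for pos, ch in enumerate(residues):
            if ch not in allowed:
                raise FormatError(
                    f"record {rec.id!r}: illegal {alphabet} character {ch!r} "
                    f"at position {pos}"
                )
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(id=rec.id, description=desc, residues=residues))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    """Write records in order, wrapping residues at 70 columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), _FASTA_WRAP):
                fh.write(rec.residues[i:i + _FASTA_WRAP] + "\n")


# --- Newick ---------------------------------------------------------------

def _quote(name: str) -> str:
    if _NEWICK_META.search(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _newick_node(node: TreeNode) -> str:
    if node.is_tip():
        label = _quote(node.name or "")
    else:
        children = ",".join(_newick_node(c) for c in node.children)
        label = f"({children})"
        if node.name:
            label += _quote(str(node.name))
    if node.length is not None:
        label += f":{node.length:.6f}"
    return label


def write_newick(tree: TreeNode, path: str | Path | None = None) -> str:
    """Serialize a tree to Newick with branch lengths at 6 decimals.

    Internal node names (e.g. bootstrap supports) are written as internal
    labels. Duplicate leaf names are a serialization error.
    """
    tips = [t.name for t in tree.tips()] or [tree.name]
    if len(tips) != len(set(tips)):
        raise FormatError("duplicate leaf names in tree")
    text = _newick_node(tree) + ";"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def read_newick(source: str | Path) -> TreeNode:
    """Parse Newick text or a file path into a scikit-bio ``TreeNode``."""
    text = Path(source).read_text() if isinstance(source, Path) else str(source)
    if not text.lstrip().startswith("(") and Path(str(source)).exists():
        text = Path(str(source)).read_text()
    return TreeNode.read(StringIO(text), convert_underscores=False)


# --- Matrices -------------------------------------------------------------

def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Tab-separated table with a header row and row-name column."""
    if matrix.index.has_duplicates or matrix.columns.has_duplicates:
        raise FormatError("row and column names must be unique")
    matrix.to_csv(path, sep="\t", index_label="id")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Inverse of :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col="id")
    df.index.name = None
    return df
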
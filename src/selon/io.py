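"""Reading and writing UCE datasets and trees.

A dataset is a directory of per-UCE FASTA alignments over one shared taxon
set.  Sequences are encoded as integer states A,C,G,T -> 0..3; gaps and IUPAC
ambiguity codes become the MISSING state (4), which contributes no
information to the likelihood.  U is read as T and case is ignored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .core import MISSING, NUCLEOTIDES
from .tree import RootedTree

_AMBIGUOUS = set("RYSWKMBDHVNX?-.")
_CODE = {b: i for i, b in enumerate(NUCLEOTIDES)}
_CODE["U"] = _CODE["T"]


class AlignmentFormatError(ValueError):
    """Ragged alignments or unparseable sequence characters."""


class TaxonMismatchError(ValueError):
    """Alignments in one dataset disagree on the taxon set."""


def encode_sequence(seq: str, context: str = "") -> np.ndarray:
    """Encode one sequence string into integer states."""
    out = np.empty(len(seq), dtype=np.int8)
    for k, ch in enumerate(seq.upper()):
        if ch in _CODE:
            out[k] = _CODE[ch]
        elif ch in _AMBIGUOUS:
            out[k] = MISSING
        else:
            raise AlignmentFormatError(f"unrecognized character {ch!r}{context}")
    return out


def decode_codes(codes: np.ndarray) -> str:
    letters = np.array(list(NUCLEOTIDES) + ["N"])
    return "".join(letters[np.asarray(codes, dtype=int)])


@dataclass
class UCEAlignment:
    """One UCE alignment: taxa x sites integer state matrix."""

    uce_id: str
    taxa: tuple[str, ...]
    codes: np.ndarray  # (n_taxa, n_sites) int8, 4 = missing

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.taxa):
            raise AlignmentFormatError(f"alignment {self.uce_id}: matrix/taxa shape mismatch")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return int(self.codes.shape[1])

    def reordered(self, taxa: tuple[str, ...]) -> "UCEAlignment":
        idx = [self.taxa.index(t) for t in taxa]
        return UCEAlignment(self.uce_id, tuple(taxa), self.codes[idx])


@dataclass
class UCEDataset:
    """Collection of per-UCE alignments tied to one ordered taxon set."""

    alignments: list[UCEAlignment]
    taxa: tuple[str, ...]

    def __post_init__(self):
        if not self.alignments:
            raise ValueError("a dataset needs at least one UCE")
        ids = [a.uce_id for a in self.alignments]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate UCE ids in dataset")
        for a in self.alignments:
            if set(a.taxa) != set(self.taxa):
                raise TaxonMismatchError(
                    f"alignment {a.uce_id} taxa differ from dataset: "
                    f"{sorted(set(a.taxa) ^ set(self.taxa))}"
                )
        self.alignments = [
            a if a.taxa == self.taxa else a.reordered(self.taxa) for a in self.alignments
        ]

    @property
    def n_uces(self) -> int:
        return len(self.alignments)

    @property
    def uce_ids(self) -> list[str]:
        return [a.uce_id for a in self.alignments]

    @property
    def total_sites(self) -> int:
        return sum(a.n_sites for a in self.alignments)

    @property
    def site_counts(self) -> np.ndarray:
        return np.array([a.n_sites for a in self.alignments])

    def concatenated_codes(self) -> np.ndarray:
        """(n_taxa, total_sites) matrix with UCEs side by side."""
        return np.concatenate([a.codes for a in self.alignments], axis=1)


def read_fasta_alignment(path, uce_id: str | None = None) -> UCEAlignment:
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentFormatError(f"{path}: no sequences found")
    taxa = tuple(r.id for r in records)
    if len(taxa) < 3:
        raise AlignmentFormatError(f"{path}: at least 3 taxa required")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise AlignmentFormatError(
            f"{path}: ragged alignment (sequence lengths {sorted(lengths)})"
        )
    rows = [
        encode_sequence(str(r.seq), context=f" in {path.name}:{r.id}") for r in records
    ]
    return UCEAlignment(uce_id or path.stem, taxa, np.vstack(rows))


def read_uce_directory(path) -> UCEDataset:
    """Load every FASTA file in a directory as one UCE dataset."""
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"{path} is not a directory")
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in {".fa", ".fas", ".fasta", ".fna"}
    )
    if not files:
        raise AlignmentFormatError(f"no FASTA files found in {path}")
    alignments = [read_fasta_alignment(p) for p in files]
    taxa = alignments[0].taxa
    return UCEDataset(alignments=alignments, taxa=taxa)


def write_fasta_alignment(alignment: UCEAlignment, path) -> None:
    with open(path, "w") as fh:
        for t, row in zip(alignment.taxa, alignment.codes):
            fh.write(f">{t}\n{decode_codes(row)}\n")


def write_uce_directory(dataset: UCEDataset, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for a in dataset.alignments:
        write_fasta_alignment(a, path / f"{a.uce_id}.fasta")


def read_tree(path) -> RootedTree:
    """Read a rooted binary Newick tree (see :class:`RootedTree`)."""
    return RootedTree.from_file(path)


def write_json(payload: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonify)
        fh.write("\n")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
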
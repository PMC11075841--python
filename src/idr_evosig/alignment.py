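"""Aligned sequences with optional per-residue disorder scores.

The container mirrors the shape of the study inputs: a protein multiple
sequence alignment (gap symbol ``-``), a parallel matrix of per-species
per-column disorder scores in [0, 1] (NaN wherever the residue is a gap or
unscored), and an optional boolean missing-data mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = [
    "STANDARD_AA",
    "ScoredAlignment",
    "read_msa_fasta",
    "read_score_tsv",
    "write_msa_fasta",
    "write_score_tsv",
]

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"


@dataclass
class ScoredAlignment:
    """An MSA plus optional aligned disorder scores and missingness mask.

    ``scores`` and ``missing_mask`` are ``(n_species, n_columns)`` arrays;
    scores are NaN at gaps and at unscored positions, the mask marks columns
    to be ignored per species (True = missing).
    """

    alignment_id: str
    species: list[str]
    rows: list[str]
    scores: np.ndarray | None = None
    missing_mask: np.ndarray | None = None
    flagged: set = field(default_factory=set)  # species with non-standard residues

    def __post_init__(self):
        if not self.rows:
            raise ValueError(f"{self.alignment_id}: empty alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"{self.alignment_id}: ragged alignment, row lengths {sorted(lengths)}")
        if len(set(self.species)) != len(self.species):
            dup = sorted({s for s in self.species if self.species.count(s) > 1})
            raise ValueError(f"{self.alignment_id}: duplicate header(s) {dup}")
        for sp, row in zip(self.species, self.rows):
            extra = set(row.upper()) - set(STANDARD_AA) - {GAP}
            if extra:
                self.flagged.add(sp)
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float)
            if self.scores.shape != (self.n_species, self.n_columns):
                raise ValueError("scores shape must be (n_species, n_columns)")
        if self.missing_mask is not None:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != (self.n_species, self.n_columns):
                raise ValueError("missing_mask shape must be (n_species, n_columns)")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def gap_matrix(self) -> np.ndarray:
        """Boolean (n_species, n_columns): True where the residue is a gap."""
        arr = np.frombuffer("".join(self.rows).encode(), dtype="S1")
        return (arr == GAP.encode()).reshape(self.n_species, self.n_columns)

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def segment(self, species: str, start: int, stop: int) -> str:
        """Ungapped residues of one species within columns [start, stop)."""
        row = self.rows[self.species.index(species)]
        return row[start:stop].replace(GAP, "")


def read_msa_fasta(path, alignment_id: str | None = None) -> ScoredAlignment:
    """Read an aligned FASTA (scores absent).

    Ragged rows, duplicate headers, and empty files are hard errors;
    non-standard residues only flag the record (filtering happens later).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty or non-FASTA file: {path}")
    if alignment_id is None:
        alignment_id = str(path).rsplit("/", 1)[-1].rsplit(".", 1)[0]
    species = [r.id for r in records]
    rows = [str(r.seq).upper() for r in records]
    return ScoredAlignment(alignment_id, species, rows)


def write_msa_fasta(aln: ScoredAlignment, path) -> None:
    with open(path, "w") as fh:
        for sp, row in zip(aln.species, aln.rows):
            fh.write(f">{sp}\n{row}\n")


def read_score_tsv(path, aln: ScoredAlignment) -> np.ndarray:
    """Read a species/column/score TSV into an aligned score matrix."""
    scores = np.full((aln.n_species, aln.n_columns), np.nan)
    index = {sp: i for i, sp in enumerate(aln.species)}
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header[:3] != ["species", "column", "score"]:
            raise ValueError(f"{path}: expected header species/column/score")
        for line in fh:
            sp, col, val = line.rstrip("\n").split("\t")
            if sp not in index:
                raise KeyError(f"{path}: unknown species {sp!r}")
            scores[index[sp], int(col)] = float(val)
    finite = scores[np.isfinite(scores)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError(f"{path}: scores must lie in [0, 1]")
    return scores


def write_score_tsv(aln: ScoredAlignment, path) -> None:
    if aln.scores is None:
        raise ValueError("alignment carries no scores")
    with open(path, "w") as fh:
        fh.write("species\tcolumn\tscore\n")
        for i, sp in enumerate(aln.species):
            for j in range(aln.n_columns):
                v = aln.scores[i, j]
                if np.isfinite(v):
                    fh.write(f"{sp}\t{j}\t{v:.6f}\n")
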
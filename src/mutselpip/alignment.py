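"""In-frame codon alignments.

Alignments are stored codon-indexed: an integer matrix over taxa x
sites, each entry either a sense-codon index (0..60) or MISSING (-1).
Gap codons and any triplet containing a non-ACGT character are treated
as fully missing data at the codon level; in-frame stop codons are
rejected with the offending taxon and site named.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .codons import NUCLEOTIDES, UNIVERSAL_CODE, GeneticCode

MISSING = -1


class AlignmentError(ValueError):
    """Frame violation, duplicate taxa, or in-frame stop codon."""


@dataclass
class CodonAlignment:
    """Codon-indexed alignment: ordered taxa and an (n_taxa, n_sites) code matrix."""

    taxa: list[str]
    codes: np.ndarray
    code_table: GeneticCode = UNIVERSAL_CODE

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.taxa):
            raise AlignmentError("code matrix shape does not match taxa")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon names")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    @classmethod
    def from_sequences(
        cls, records: list[tuple[str, str]], code: GeneticCode = UNIVERSAL_CODE
    ) -> "CodonAlignment":
        """Build from (name, nucleotide string) pairs; U is mapped to T."""
        if not records:
            raise AlignmentError("empty alignment")
        taxa = [name for name, _ in records]
        lengths = {len(seq) for _, seq in records}
        if len(lengths) != 1:
            raise AlignmentError("sequences have unequal lengths")
        (length,) = lengths
        if length % 3 != 0:
            raise AlignmentError(f"sequence length {length} is not divisible by 3")
        n_sites = length // 3
        codes = np.full((len(taxa), n_sites), MISSING, dtype=np.int64)
        for r, (name, seq) in enumerate(records):
            s = seq.upper().replace("U", "T")
            for n in range(n_sites):
                triplet = s[3 * n: 3 * n + 3]
                if any(b not in NUCLEOTIDES for b in triplet):
                    continue  # gap or ambiguity -> missing
                if code.is_stop(triplet):
                    raise AlignmentError(
                        f"in-frame stop codon {triplet} in taxon {name!r} at site {n + 1}"
                    )
                codes[r, n] = code.codon_index(triplet)
        return cls(taxa=taxa, codes=codes, code_table=code)

    def to_sequences(self) -> list[tuple[str, str]]:
        out = []
        for r, name in enumerate(self.taxa):
            seq = "".join(
                self.code_table.sense_codons[c] if c != MISSING else "---"
                for c in self.codes[r]
            )
            out.append((name, seq))
        return out

    def subset(self, taxa: list[str]) -> "CodonAlignment":
        """Restrict to the given taxa (order as given); site indexing preserved."""
        missing = set(taxa) - set(self.taxa)
        if missing:
            raise AlignmentError(f"taxa not in alignment: {sorted(missing)}")
        rows = [self.taxa.index(t) for t in taxa]
        return CodonAlignment(list(taxa), self.codes[rows], self.code_table)

    def column(self, n: int) -> np.ndarray:
        return self.codes[:, n]


def read_alignment(
    path: str | Path, format: str = "fasta", code: GeneticCode = UNIVERSAL_CODE
) -> CodonAlignment:
    """Read an in-frame coding alignment (``fasta`` or ``phylip``)."""
    fmt = {"fasta": "fasta", "phylip": "phylip-relaxed"}.get(format)
    if fmt is None:
        raise ValueError(f"unsupported alignment format {format!r}")
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), fmt)]
    return CodonAlignment.from_sequences(records, code=code)


def write_fasta(aln: CodonAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in aln.to_sequences():
            fh.write(f">{name}\n{seq}\n")


def write_phylip(aln: CodonAlignment, path: str | Path) -> None:
    """Sequential relaxed PHYLIP."""
    seqs = aln.to_sequences()
    with open(path, "w") as fh:
        fh.write(f" {aln.n_taxa} {aln.n_sites * 3}\n")
        for name, seq in seqs:
            fh.write(f"{name}  {seq}\n")
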
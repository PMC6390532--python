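"""Universal genetic code tables and codon indexing.

The model state space is the 61 sense codons of the universal genetic
code (stops TAA/TAG/TGA excluded). Codons are ordered lexicographically
over the alphabet A < C < G < T so that matrix indices are reproducible
across runs; amino acids are indexed alphabetically by one-letter code
(A, C, D, ..., Y). All indices are 0-based in Python; user-facing site
numbers in reports are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class StopCodonError(ValueError):
    """Raised when a stop codon appears where a sense codon is required."""


def _standard_table() -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[1]


@dataclass(frozen=True)
class GeneticCode:
    """The universal genetic code restricted to its 61 sense codons.

    Attributes
    ----------
    sense_codons : tuple of str
        The 61 sense codons in fixed lexicographic (A<C<G<T) order.
    aa_index : ndarray-like tuple of int
        ``aa_index[i]`` is the amino-acid index (0..19, alphabetical by
        one-letter code) encoded by sense codon ``i`` — the map *f* of
        the mutation-selection model.
    """

    sense_codons: tuple[str, ...]
    stop_codons: tuple[str, ...]
    aa_index: tuple[int, ...]
    _codon_to_index: dict[str, int] = field(repr=False, default_factory=dict)

    @classmethod
    def universal(cls) -> "GeneticCode":
        table = _standard_table()
        stops = tuple(sorted(table.stop_codons))
        sense = tuple(
            "".join(c) for c in product(NUCLEOTIDES, repeat=3) if "".join(c) not in stops
        )
        aa = tuple(AMINO_ACIDS.index(table.forward_table[c]) for c in sense)
        code = cls(sense_codons=sense, stop_codons=stops, aa_index=aa)
        code._codon_to_index.update({c: i for i, c in enumerate(sense)})
        return code

    @property
    def n_codons(self) -> int:
        return len(self.sense_codons)

    def codon_index(self, codon: str) -> int:
        """Index of ``codon`` in the fixed sense-codon ordering.

        RNA input (U) is silently mapped to DNA (T). Stop codons raise
        :class:`StopCodonError`; other invalid strings raise ValueError.
        """
        c = codon.upper().replace("U", "T")
        if len(c) != 3 or any(b not in NUCLEOTIDES for b in c):
            raise ValueError(f"invalid codon {codon!r}")
        if c in self.stop_codons:
            raise StopCodonError(f"stop codon {codon!r}")
        return self._codon_to_index[c]

    def is_stop(self, codon: str) -> bool:
        return codon.upper().replace("U", "T") in self.stop_codons

    def translate(self, i: int) -> str:
        """One-letter amino acid encoded by sense codon ``i``."""
        return AMINO_ACIDS[self.aa_index[i]]

    def nucleotide_at(self, i: int, c: int) -> int:
        """Nucleotide index (0..3 over A,C,G,T) at position ``c`` (0..2) of codon ``i``."""
        return NUCLEOTIDES.index(self.sense_codons[i][c])

    def single_nt_neighbors(self, i: int) -> list[tuple[int, int, int, int]]:
        """Sense codons reachable from codon ``i`` by one nucleotide change.

        Returns tuples ``(j, c, a, b)``: target codon index ``j``, codon
        position ``c`` (0..2), source nucleotide ``a`` and target
        nucleotide ``b`` (0..3). Changes producing stop codons are
        excluded, so every codon has between 7 and 9 sense neighbors.
        """
        codon = self.sense_codons[i]
        out = []
        for c in range(3):
            a = NUCLEOTIDES.index(codon[c])
            for b, nt in enumerate(NUCLEOTIDES):
                if b == a:
                    continue
                target = codon[:c] + nt + codon[c + 1:]
                j = self._codon_to_index.get(target)
                if j is not None:
                    out.append((j, c, a, b))
        return out

    def neighbor_table(self) -> list[tuple[int, int, int, int, int]]:
        """All ordered single-nucleotide sense pairs as ``(i, j, c, a, b)``."""
        rows = []
        for i in range(self.n_codons):
            for j, c, a, b in self.single_nt_neighbors(i):
                rows.append((i, j, c, a, b))
        return rows


UNIVERSAL_CODE = GeneticCode.universal()
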
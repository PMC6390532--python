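"""Amino acid fitness profile sets for the finite mixture model.

Two sources of profiles are supported: the built-in biochemically
grouped construction (eight disjoint groups of residues, with a
*peakedness* parameter controlling how much probability mass the group
members share), and whitespace-delimited tables of K rows x 20
frequencies, the de facto layout of published empirical mixture sets
(C10/C20/C40/C60 style), optionally with a leading weight column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .codons import AMINO_ACIDS

# Entries below this are floored (then renormalized) so log-fitnesses stay finite.
PROFILE_FLOOR = 1e-10

# The eight biochemical groups, in construction order.
BIOCHEMICAL_GROUPS: tuple[tuple[str, str], ...] = (
    ("small_nonpolar", "AGST"),
    ("aromatic", "FWY"),
    ("nonpolar_aliphatic", "ILVM"),
    ("polar_positive", "HKR"),
    ("polar_negative", "DE"),
    ("polar_neutral", "NQ"),
    ("proline", "P"),
    ("cysteine", "C"),
)


@dataclass(frozen=True)
class AminoAcidProfile:
    """A 20-vector of amino acid fitnesses/propensities (sums to 1).

    Indexed alphabetically by one-letter amino acid code, consistent
    with :data:`mutselpip.codons.AMINO_ACIDS`.
    """

    psi: np.ndarray
    label: str = ""

    def __post_init__(self):
        psi = np.asarray(self.psi, dtype=float)
        if psi.shape != (20,):
            raise ValueError("profile must have exactly 20 entries")
        if np.any(psi < 0):
            raise ValueError("profile entries must be non-negative")
        psi = np.maximum(psi, PROFILE_FLOOR)
        psi = psi / psi.sum()
        object.__setattr__(self, "psi", psi)

    @property
    def log_psi(self) -> np.ndarray:
        return np.log(self.psi)

    def __getitem__(self, aa: str | int) -> float:
        if isinstance(aa, str):
            aa = AMINO_ACIDS.index(aa)
        return float(self.psi[aa])


@dataclass(frozen=True)
class ProfileSet:
    """An ordered finite mixture of K amino acid profiles.

    ``weights`` (optional) are the prior allocation probabilities w_k;
    when absent the collapsed sampler integrates them out under a flat
    Dirichlet.
    """

    components: tuple[AminoAcidProfile, ...]
    weights: np.ndarray | None = None
    peakedness: float | None = None
    source: str = "file"

    def __post_init__(self):
        if len(self.components) < 1:
            raise ValueError("a profile set needs at least one component")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (len(self.components),):
                raise ValueError("weights length must equal number of components")
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("weights must be non-negative and sum to 1")
            object.__setattr__(self, "weights", w)

    @property
    def K(self) -> int:
        return len(self.components)

    def matrix(self) -> np.ndarray:
        """K x 20 array of profile values."""
        return np.stack([p.psi for p in self.components])

    def __len__(self) -> int:
        return self.K

    def __getitem__(self, k: int) -> AminoAcidProfile:
        return self.components[k]


def mutsel_bc(peakedness: float) -> ProfileSet:
    """Construct the eight biochemically grouped profiles.

    For a group g of size ``|g|``, each member amino acid receives
    ``peakedness / |g|`` and each of the remaining ``20 - |g|`` residues
    receives ``(1 - peakedness) / (20 - |g|)``. Groups are disjoint, so
    at high peakedness a change of component is a biologically clear
    preference shift.

    Parameters
    ----------
    peakedness : float in (0, 1]
        Total probability mass shared equally by the group members.
        At 1.0 the off-group entries are floored to keep logs finite.
    """
    if not 0.0 < peakedness <= 1.0:
        raise ValueError(f"peakedness must be in (0, 1], got {peakedness}")
    comps = []
    for name, members in BIOCHEMICAL_GROUPS:
        psi = np.full(20, (1.0 - peakedness) / (20 - len(members)))
        for aa in members:
            psi[AMINO_ACIDS.index(aa)] = peakedness / len(members)
        comps.append(AminoAcidProfile(psi, label=name))
    return ProfileSet(tuple(comps), peakedness=peakedness, source="mutsel_bc")


class ProfileTableError(ValueError):
    """Malformed profile table file."""


def load_profile_table(path: str | Path) -> ProfileSet:
    """Read a whitespace-delimited K x 20 (or K x 21 with weights) profile table.

    Lines starting with ``#`` are comments. Rows whose sum is within
    1e-4 of 1 are renormalized; larger deviations are format errors.
    A 21-field row is interpreted as a leading mixture weight followed
    by the 20 frequencies.
    """
    rows: list[np.ndarray] = []
    weights: list[float] = []
    n_fields: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) not in (20, 21):
                raise ProfileTableError(
                    f"line {lineno}: expected 20 or 21 fields, got {len(fields)}"
                )
            if n_fields is None:
                n_fields = len(fields)
            elif len(fields) != n_fields:
                raise ProfileTableError(f"line {lineno}: inconsistent field count")
            try:
                vals = np.array([float(x) for x in fields])
            except ValueError as exc:
                raise ProfileTableError(f"line {lineno}: {exc}") from None
            if len(fields) == 21:
                weights.append(vals[0])
                vals = vals[1:]
            if np.any(vals < 0):
                raise ProfileTableError(f"line {lineno}: negative entry")
            if abs(vals.sum() - 1.0) > 1e-4:
                raise ProfileTableError(
                    f"line {lineno}: row sums to {vals.sum():.6f}, not 1"
                )
            rows.append(vals / vals.sum())
    if not rows:
        raise ProfileTableError("no profile rows found")
    comps = tuple(
        AminoAcidProfile(r, label=f"component_{k+1}") for k, r in enumerate(rows)
    )
    w = None
    if weights:
        w = np.asarray(weights)
        if np.any(w < 0):
            raise ProfileTableError("negative weight")
        w = w / w.sum()
    return ProfileSet(comps, weights=w, source="file")


def save_profile_table(pset: ProfileSet, path: str | Path) -> None:
    """Write a profile set in the format accepted by :func:`load_profile_table`."""
    with open(path, "w") as fh:
        fh.write("# amino acid columns: " + " ".join(AMINO_ACIDS) + "\n")
        if pset.weights is not None:
            fh.write("# first column: mixture weight\n")
        for k, comp in enumerate(pset.components):
            fields = []
            if pset.weights is not None:
                fields.append(repr(float(pset.weights[k])))
            fields.extend(repr(float(v)) for v in comp.psi)
            fh.write(" ".join(fields) + "\n")
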
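"""Overlapping peptide tiling and MHC-II binding-core registers.

Epitope screens synthesise every k-mer window of a candidate autoantigen at
a fixed offset (classically 15-mers offset by three residues) and assay each
window for HLA binding.  This module generates those tiles with 1-based
inclusive coordinates and canonical ``<parent>_<start>-<end>`` names, and
maps a 9-mer binding core (e.g. one read off a peptide--HLA crystal
structure) onto register positions P1..P9 with absolute residue indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = [
    "ProteinRecord",
    "PeptideTile",
    "CoreRegister",
    "tile_protein",
    "locate_core",
]

# 20 canonical residues plus X for unknown; peptide-synthesis alphabet.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteinRecord:
    """A parent protein to be tiled.

    Parameters
    ----------
    id : str
        Stable identifier (e.g. a FASTA accession).
    name : str
        Display name, e.g. ``SmB/B'``.
    sequence : str
        Amino-acid sequence, single-letter IUPAC; only the 20 canonical
        letters plus ``X`` are accepted.
    """

    id: str
    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"protein {self.id!r}: illegal residue(s) {sorted(bad)!r}; "
                "only the 20 canonical amino acids plus X are allowed"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideTile:
    """A k-mer window on a parent protein, 1-based inclusive coordinates."""

    parent_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"tile {self.name}: span {self.start}-{self.end} does not "
                f"match sequence length {len(self.sequence)}"
            )

    @property
    def name(self) -> str:
        return f"{self.parent_id}_{self.start}-{self.end}"


@dataclass(frozen=True)
class CoreRegister:
    """A 9-mer binding core placed within a peptide tile.

    ``positions`` maps register labels ``"P1"``..``"P9"`` to
    ``(residue letter, absolute residue index on the parent)``.
    """

    core_sequence: str
    offset_in_peptide: int  # 1-based start of the core within the tile
    positions: dict[str, tuple[str, int]] = field(default_factory=dict)


def tile_protein(protein: ProteinRecord, k: int = 15, offset: int = 3) -> list[PeptideTile]:
    """Generate overlapping k-mer tiles of ``protein``.

    Tiles start at residues 1, 1+offset, 1+2*offset, ... for as long as a
    full window fits; trailing residues not reachable by a full window are
    dropped (matching fixed-length peptide synthesis).  The number of tiles
    is ``floor((L - k) / offset) + 1``.

    Parameters
    ----------
    k : int
        Window length in residues (default 15).
    offset : int
        Step between consecutive tile starts (default 3).

    Raises
    ------
    ValueError
        If the sequence is shorter than ``k`` or the parameters are invalid.
    """
    if k < 1:
        raise ValueError(f"window length k must be >= 1, got {k}")
    if offset < 1:
        raise ValueError(f"offset must be >= 1, got {offset}")
    L = len(protein)
    if L < k:
        raise ValueError(
            f"protein {protein.id!r} has length {L} < window length {k}; "
            "cannot tile"
        )
    tiles = []
    for start in range(1, L - k + 2, offset):
        end = start + k - 1
        tiles.append(
            PeptideTile(
                parent_id=protein.id,
                start=start,
                end=end,
                sequence=protein.sequence[start - 1 : end],
            )
        )
    return tiles


def locate_core(tile: PeptideTile, core: str) -> CoreRegister:
    """Place a 9-mer binding core within ``tile``.

    The leftmost occurrence is used; if the core occurs more than once a
    warning is emitted.  Register positions P1..P9 are annotated with the
    residue letter and the absolute (parent) residue index.

    Raises
    ------
    ValueError
        If ``core`` is not a 9-mer or does not occur in the tile.
    """
    if len(core) != 9:
        raise ValueError(f"binding core must be a 9-mer, got {len(core)}-mer {core!r}")
    idx = tile.sequence.find(core)
    if idx < 0:
        raise ValueError(f"core {core!r} not found in tile {tile.name} ({tile.sequence})")
    if tile.sequence.find(core, idx + 1) >= 0:
        warnings.warn(
            f"core {core!r} occurs more than once in tile {tile.name}; "
            "using the leftmost match",
            stacklevel=2,
        )
    offset_in_peptide = idx + 1
    positions = {
        f"P{i + 1}": (core[i], tile.start + idx + i) for i in range(9)
    }
    return CoreRegister(
        core_sequence=core,
        offset_in_peptide=offset_in_peptide,
        positions=positions,
    )
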
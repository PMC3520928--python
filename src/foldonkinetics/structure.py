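"""Native structure parsing, foldon partitions and native contact sets.

The native-similarity coordinate q is built from Gaussians centred on the
native Calpha-Calpha distances of a contact set; each contact pair carries a
sequence-separation-dependent width.  This module owns the structural side of
that definition: which pairs count as native contacts, their native
distances, and their widths.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb


class StructureError(ValueError):
    """Raised for malformed or unusable structural input."""


@dataclass(frozen=True)
class NativeStructure:
    """One Calpha coordinate per residue of a single chain.

    Residues are renumbered 1..n internally; the original author numbering
    is kept in ``author_ids`` for reporting.
    """

    ca_coords: np.ndarray  # (n, 3), Angstrom
    author_ids: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        coords = np.asarray(self.ca_coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise StructureError("ca_coords must have shape (n, 3)")
        if coords.shape[0] < 2:
            raise StructureError("structure must contain at least 2 residues")
        object.__setattr__(self, "ca_coords", coords)
        if not self.author_ids:
            object.__setattr__(
                self, "author_ids", tuple(range(1, coords.shape[0] + 1))
            )
        elif len(self.author_ids) != coords.shape[0]:
            raise StructureError("author_ids length must match coordinates")

    @property
    def n_residues(self) -> int:
        return self.ca_coords.shape[0]

    @property
    def residue_index(self) -> np.ndarray:
        """Internal 1-based residue indices."""
        return np.arange(1, self.n_residues + 1)


@dataclass(frozen=True)
class FoldonPartition:
    """Ordered, contiguous, non-overlapping residue segments covering 1..n."""

    segments: tuple[tuple[int, int], ...]  # 1-based inclusive
    names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        segs = tuple((int(a), int(b)) for a, b in self.segments)
        if not segs:
            raise StructureError("partition needs at least one segment")
        expect = 1
        for start, end in segs:
            if start != expect:
                raise StructureError(
                    f"segments must be contiguous from 1: got start {start}, "
                    f"expected {expect}"
                )
            if end < start:
                raise StructureError(f"zero-length segment ({start}, {end})")
            expect = end + 1
        object.__setattr__(self, "segments", segs)
        if not self.names:
            object.__setattr__(
                self, "names", tuple(f"F{k + 1}" for k in range(len(segs)))
            )
        elif len(self.names) != len(segs):
            raise StructureError("names length must match segments")

    @property
    def n_foldons(self) -> int:
        return len(self.segments)

    @property
    def n_residues(self) -> int:
        return self.segments[-1][1]

    def foldon_of(self, residue: int) -> int:
        """0-based foldon index containing a 1-based residue."""
        for k, (start, end) in enumerate(self.segments):
            if start <= residue <= end:
                return k
        raise StructureError(f"residue {residue} outside partition")

    def membership(self) -> np.ndarray:
        """Foldon index (0-based) for each residue, shape (n_residues,)."""
        out = np.empty(self.n_residues, dtype=int)
        for k, (start, end) in enumerate(self.segments):
            out[start - 1 : end] = k
        return out


@dataclass(frozen=True)
class ContactSet:
    """Native contact pairs with native distances and Gaussian widths."""

    pairs: np.ndarray  # (m, 2) int, 1-based, i < j
    native_distance: np.ndarray  # (m,) Angstrom
    width: np.ndarray  # (m,) Angstrom
    min_seq_sep: int = 1

    def __post_init__(self) -> None:
        pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        dist = np.asarray(self.native_distance, dtype=float).ravel()
        width = np.asarray(self.width, dtype=float).ravel()
        if not (len(pairs) == len(dist) == len(width)):
            raise StructureError("pairs, distances and widths must align")
        if len(pairs) and np.any(pairs[:, 0] >= pairs[:, 1]):
            raise StructureError("pairs must satisfy i < j")
        if len(pairs) and np.any(pairs[:, 1] - pairs[:, 0] < self.min_seq_sep):
            raise StructureError("pair violates minimum sequence separation")
        if np.any(width <= 0):
            raise StructureError("widths must be strictly positive")
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "native_distance", dist)
        object.__setattr__(self, "width", width)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def read_structure(pdb_text: str, chain: str = "A") -> NativeStructure:
    """Extract one Calpha per residue of ``chain`` from PDB text.

    Residues are renumbered 1..n in file order.  Alternate locations are
    resolved by highest occupancy (ties by first).  A residue of the chain
    that carries atoms but no Calpha is an error.
    """
    pdb_file = pdb.PDBFile.read(io.StringIO(pdb_text))
    atoms = pdb_file.get_structure(model=1, altloc="occupancy")
    atoms = atoms[atoms.chain_id == chain]
    atoms = atoms[~atoms.hetero]
    if atoms.array_length() == 0:
        raise StructureError(f"no ATOM records for chain {chain!r}")

    starts = struc.get_residue_starts(atoms)
    coords = []
    author_ids = []
    for k, start in enumerate(starts):
        stop = starts[k + 1] if k + 1 < len(starts) else atoms.array_length()
        res = atoms[start:stop]
        ca = res[res.atom_name == "CA"]
        res_id = int(res.res_id[0])
        if ca.array_length() == 0:
            raise StructureError(
                f"residue {res.res_name[0]} {res_id} of chain {chain!r} "
                "has no CA atom"
            )
        coords.append(ca.coord[0])
        author_ids.append(res_id)
    return NativeStructure(
        ca_coords=np.asarray(coords, dtype=float),
        author_ids=tuple(author_ids),
    )


def default_width(seq_sep: np.ndarray, sigma0: float = 1.0,
                  exponent: float = 0.15) -> np.ndarray:
    """Sequence-separation-dependent width sigma0 * (1 + |i-j|)**exponent."""
    return sigma0 * (1.0 + np.asarray(seq_sep, dtype=float)) ** exponent


def build_contact_set(
    structure: NativeStructure,
    cutoff: float = 9.5,
    min_seq_sep: int = 3,
    sigma0: float = 1.0,
    sigma_exponent: float = 0.15,
) -> ContactSet:
    """All residue pairs within ``cutoff`` (Calpha-Calpha) and with sequence
    separation >= ``min_seq_sep``, plus their Gaussian widths."""
    if cutoff <= 0:
        raise StructureError("cutoff must be positive")
    if min_seq_sep < 1:
        raise StructureError("min_seq_sep must be >= 1")
    n = structure.n_residues
    coords = structure.ca_coords
    ii, jj = np.triu_indices(n, k=min_seq_sep)
    dist = np.linalg.norm(coords[ii] - coords[jj], axis=1)
    keep = dist <= cutoff
    pairs = np.column_stack([ii[keep] + 1, jj[keep] + 1])
    dist = dist[keep]
    width = default_width(pairs[:, 1] - pairs[:, 0], sigma0, sigma_exponent)
    return ContactSet(
        pairs=pairs,
        native_distance=dist,
        width=width,
        min_seq_sep=min_seq_sep,
    )


def define_foldons(
    spec: list[int] | list[tuple[int, int]], n_residues: int
) -> FoldonPartition:
    """Build a partition from segment lengths or explicit (start, end) ranges.

    Lengths must sum to ``n_residues``; explicit ranges must tile
    1..n_residues in order.  Foldon 1 is N-terminal.
    """
    if not spec:
        raise StructureError("foldon spec is empty")
    first = spec[0]
    if isinstance(first, (tuple, list)):
        segments = tuple((int(a), int(b)) for a, b in spec)  # type: ignore[misc]
    else:
        lengths = [int(x) for x in spec]  # type: ignore[arg-type]
        if any(l <= 0 for l in lengths):
            raise StructureError("zero-length foldon segment")
        if sum(lengths) != n_residues:
            raise StructureError(
                f"foldon lengths sum to {sum(lengths)}, expected {n_residues}"
            )
        segments = []
        pos = 1
        for l in lengths:
            segments.append((pos, pos + l - 1))
            pos += l
        segments = tuple(segments)
    partition = FoldonPartition(segments=segments)
    if partition.n_residues != n_residues:
        raise StructureError(
            f"partition covers {partition.n_residues} residues, "
            f"expected {n_residues}"
        )
    return partition


def write_contact_tsv(contacts: ContactSet) -> str:
    """Serialize a contact set as TSV (i, j, r_native_angstrom, sigma_angstrom)."""
    lines = ["i\tj\tr_native_angstrom\tsigma_angstrom"]
    for (i, j), r, s in zip(
        contacts.pairs, contacts.native_distance, contacts.width
    ):
        lines.append(f"{i}\t{j}\t{r:.10g}\t{s:.10g}")
    return "\n".join(lines) + "\n"


def read_contact_tsv(text: str, min_seq_sep: int = 1) -> ContactSet:
    rows = [ln.split("\t") for ln in text.strip().splitlines()[1:]]
    if not rows:
        return ContactSet(
            pairs=np.empty((0, 2), dtype=int),
            native_distance=np.empty(0),
            width=np.empty(0),
            min_seq_sep=min_seq_sep,
        )
    arr = np.asarray(rows, dtype=float)
    return ContactSet(
        pairs=arr[:, :2].astype(int),
        native_distance=arr[:, 2],
        width=arr[:, 3],
        min_seq_sep=min_seq_sep,
    )
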
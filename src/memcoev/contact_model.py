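"""Contact maps and per-residue structural classes.

A contact map is the spatial substrate of the coevolution dynamics: site ``i``
feels a transient rate boost from a recent substitution at site ``k`` only if
the two sites are in contact.  Contacts are defined geometrically (Cα–Cα
distance below a threshold) when built from coordinates, or generatively by
the synthetic-map fixture generator which emulates globular-protein maps
(backbone band, α-helix ``i → i+3 / i+4`` periodicity, sparse random
long-range pairs).

Indexing is 0-based and half-open throughout; 1-based indices appear only in
human-readable reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidInputError

#: Default Cα–Cα contact threshold (Å) used for divergence simulations.
DEFAULT_SIMULATION_THRESHOLD = 10.0
#: Default Cα–Cα contact threshold (Å) used for avalanche analyses.
DEFAULT_AVALANCHE_THRESHOLD = 8.5

#: Along-chain offsets added inside α-helical spans by the synthetic generator
#: (one-turn periodicity of an α-helix).
HELIX_OFFSETS = (3, 4)


class ContactMap:
    """Symmetric binary adjacency over ``L`` protein sites, zero diagonal.

    Parameters
    ----------
    matrix
        Square boolean (or 0/1) array.  Must be symmetric with an all-zero
        diagonal; a site never boosts its own substitution rate.
    """

    __slots__ = ("_matrix", "_fmatrix")

    def __init__(self, matrix) -> None:
        m = np.asarray(matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise InvalidInputError("contact matrix must be square")
        m = m.astype(bool)
        if m.diagonal().any():
            raise InvalidInputError("self-contacts are not allowed (diagonal must be 0)")
        if not np.array_equal(m, m.T):
            raise InvalidInputError("contact matrix must be symmetric")
        m.setflags(write=False)
        self._matrix = m
        self._fmatrix = None

    @property
    def L(self) -> int:
        """Number of sites."""
        return self._matrix.shape[0]

    @property
    def matrix(self) -> np.ndarray:
        """Read-only boolean adjacency matrix."""
        return self._matrix

    @property
    def fmatrix(self) -> np.ndarray:
        """Float64 view of the adjacency, cached for fast mat-vec products."""
        if self._fmatrix is None:
            f = self._matrix.astype(np.float64)
            f.setflags(write=False)
            self._fmatrix = f
        return self._fmatrix

    def contact(self, i: int, k: int) -> int:
        return int(self._matrix[i, k])

    def degrees(self) -> np.ndarray:
        """Number of contacts per site."""
        return self._matrix.sum(axis=1)

    def edges(self) -> list[tuple[int, int]]:
        """Sorted list of contacting pairs ``(i, k)`` with ``i < k``."""
        ii, kk = np.nonzero(np.triu(self._matrix, k=1))
        return list(zip(ii.tolist(), kk.tolist()))

    @classmethod
    def from_edges(cls, L: int, edges: Iterable[tuple[int, int]]) -> "ContactMap":
        m = np.zeros((L, L), dtype=bool)
        for i, k in edges:
            if not (0 <= i < L and 0 <= k < L):
                raise InvalidInputError(f"edge ({i}, {k}) out of range for L={L}")
            if i == k:
                raise InvalidInputError(f"self-contact ({i}, {i}) not allowed")
            m[i, k] = m[k, i] = True
        return cls(m)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ContactMap):
            return NotImplemented
        return np.array_equal(self._matrix, other._matrix)

    def __hash__(self):
        return hash((self.L, self._matrix.tobytes()))

    def __repr__(self) -> str:
        return f"ContactMap(L={self.L}, n_edges={len(self.edges())})"


@dataclass(frozen=True)
class SiteClasses:
    """Per-site structured/unstructured labels for the two-class model.

    ``structured`` is a boolean array: ``True`` marks residues involved in
    secondary structure (assigned upstream, e.g. by STRIDE); those sites have
    zero baseline rate in the two-class model and mutate only through the
    coupling term.
    """

    structured: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.structured, dtype=bool)
        arr.setflags(write=False)
        object.__setattr__(self, "structured", arr)

    @property
    def L(self) -> int:
        return self.structured.shape[0]

    def to_codes(self) -> list[str]:
        return ["S" if s else "U" for s in self.structured]

    @classmethod
    def from_codes(cls, codes: Sequence[str]) -> "SiteClasses":
        bad = sorted({c for c in codes} - {"S", "U"})
        if bad:
            raise InvalidInputError(f"unknown class codes: {bad} (expected S/U)")
        return cls(np.array([c == "S" for c in codes], dtype=bool))


def contact_map_from_coordinates(coords, threshold: float = DEFAULT_SIMULATION_THRESHOLD) -> ContactMap:
    """Build a contact map from ordered 3-D Cα coordinates (Å).

    Sites ``i != k`` are in contact iff their Euclidean distance is *strictly*
    below ``threshold``.
    """
    c = np.asarray(coords, dtype=float)
    if c.size == 0:
        raise InvalidInputError("coordinate list is empty")
    if c.ndim != 2 or c.shape[1] != 3:
        raise InvalidInputError(f"expected an (n, 3) coordinate array, got shape {c.shape}")
    if not np.isfinite(c).all():
        raise InvalidInputError("coordinates contain non-finite values")
    if threshold <= 0:
        raise InvalidInputError("threshold must be positive")
    diff = c[:, None, :] - c[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    m = dist < threshold
    np.fill_diagonal(m, False)
    return ContactMap(m)


def ca_coordinates_from_pdb(path, chain_id: str | None = None) -> np.ndarray:
    """Read Cα coordinates of one chain from a PDB-format file.

    Uses the first model; the first chain unless ``chain_id`` is given; only
    standard residues (blank hetero flag) carrying a CA atom.  Disordered
    atoms resolve to Biopython's default (highest-occupancy) altloc.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise InvalidInputError(f"no models in PDB file {path}") from None
    chain = None
    for c in model:
        if chain_id is None or c.id == chain_id:
            chain = c
            break
    if chain is None:
        raise InvalidInputError(f"chain {chain_id!r} not found in {path}")
    coords = [
        res["CA"].get_coord()
        for res in chain
        if res.id[0] == " " and "CA" in res
    ]
    if not coords:
        raise InvalidInputError(f"no Cα atoms found in chain {chain.id} of {path}")
    return np.asarray(coords, dtype=float)


def contact_map_from_pdb(path, chain_id: str | None = None,
                         threshold: float = DEFAULT_SIMULATION_THRESHOLD) -> ContactMap:
    """Convenience wrapper: PDB file -> Cα coordinates -> contact map."""
    return contact_map_from_coordinates(ca_coordinates_from_pdb(path, chain_id), threshold)


def synthetic_contact_map(
    L: int,
    helix_spans: Sequence[tuple[int, int]] = (),
    long_range_pairs_per_site: float = 1.0,
    backbone_width: int = 2,
    seed: int | np.random.SeedSequence | None = 0,
) -> tuple[ContactMap, SiteClasses]:
    """Generate a globular-protein-like contact map plus class labels.

    The map is the union of

    * a backbone band: all pairs with ``1 <= |i - k| <= backbone_width``;
    * α-helix periodicity contacts at offsets 3 and 4 for pairs lying fully
      inside each half-open helix span;
    * Poisson-distributed random long-range pairs, ``long_range_pairs_per_site``
      expected contacts per site, drawn without replacement among pairs with
      offset beyond both the band and the helix periodicity.

    Residues inside helix spans are labeled structured, all others
    unstructured.  Deterministic given ``seed``.
    """
    if L < 10:
        raise InvalidInputError("L must be at least 10")
    if backbone_width < 0:
        raise InvalidInputError("backbone_width must be non-negative")
    if long_range_pairs_per_site < 0:
        raise InvalidInputError("long_range_pairs_per_site must be non-negative")
    spans = sorted(tuple(s) for s in helix_spans)
    prev_end = -1
    for a, b in spans:
        if not (0 <= a < b <= L):
            raise InvalidInputError(f"helix span ({a}, {b}) outside [0, {L})")
        if a < prev_end:
            raise InvalidInputError(f"helix spans overlap at ({a}, {b})")
        prev_end = b

    rng = np.random.default_rng(seed)
    m = np.zeros((L, L), dtype=bool)

    idx = np.arange(L)
    for w in range(1, backbone_width + 1):
        m[idx[:-w], idx[w:]] = True

    structured = np.zeros(L, dtype=bool)
    for a, b in spans:
        structured[a:b] = True
        for off in HELIX_OFFSETS:
            i = np.arange(a, max(a, b - off))
            m[i, i + off] = True

    min_long = max(backbone_width, max(HELIX_OFFSETS))
    n_pairs = rng.poisson(long_range_pairs_per_site * L / 2.0)
    if n_pairs > 0:
        ii, kk = np.triu_indices(L, k=min_long + 1)
        take = min(n_pairs, ii.size)
        chosen = rng.choice(ii.size, size=take, replace=False)
        m[ii[chosen], kk[chosen]] = True

    m = m | m.T
    return ContactMap(m), SiteClasses(structured)


def submap(cmap: ContactMap, start: int, length: int) -> tuple[ContactMap, np.ndarray]:
    """Induced contact map on sites ``[start, start + length)``.

    Returns the submap and the array mapping submap indices to parent
    indices.  Used to measure identity on a protein portion while the full
    chain evolves.
    """
    if length < 1 or start < 0 or start + length > cmap.L:
        raise InvalidInputError(
            f"window [{start}, {start + length}) out of range for L={cmap.L}"
        )
    sl = slice(start, start + length)
    return ContactMap(cmap.matrix[sl, sl]), np.arange(start, start + length)


# ---------------------------------------------------------------------------
# Plain-text serialization: edge lists with an "L <n>" header; S/U label files.

def write_contact_map(cmap: ContactMap, path) -> None:
    lines = [f"L {cmap.L}"]
    lines += [f"{i} {k}" for i, k in cmap.edges()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_contact_map(path) -> ContactMap:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines or not lines[0].startswith("L"):
        raise InvalidInputError(f"{path}: expected header line 'L <n>'")
    try:
        L = int(lines[0].split()[1])
    except (IndexError, ValueError):
        raise InvalidInputError(f"{path}: malformed header {lines[0]!r}") from None
    edges = []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != 2:
            raise InvalidInputError(f"{path}: malformed edge line {ln!r}")
        edges.append((int(parts[0]), int(parts[1])))
    return ContactMap.from_edges(L, edges)


def write_site_classes(classes: SiteClasses, path) -> None:
    Path(path).write_text("\n".join(classes.to_codes()) + "\n")


def read_site_classes(path) -> SiteClasses:
    codes = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return SiteClasses.from_codes(codes)
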
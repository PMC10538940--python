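"""Chemical features: SMILES standardization, Morgan fingerprints, Tanimoto distance.

Every model, clustering, and selection step in the pipeline operates on
fixed-length binary Morgan (circular substructure) fingerprints.  Compounds
are standardized by stripping salt counter-ions and canonicalizing the
SMILES before fingerprinting, so e.g. a hydrochloride salt and its free base
map to the same feature vector.

Fingerprints are kept as sorted on-bit index tuples (they are very sparse:
a typical drug-like molecule sets ~40-60 of 1024 bits).  Bulk operations
(nearest-active queries, clustering, model features) go through dense
``numpy`` matrices built with :func:`to_dense_matrix`.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.SaltRemover import SaltRemover

RDLogger.DisableLog("rdApp.*")

DEFAULT_N_BITS = 1024
DEFAULT_RADIUS = 2

__all__ = [
    "Fingerprint",
    "Molecule",
    "parse_and_standardize",
    "morgan_fingerprint",
    "fingerprint_from_smiles",
    "tanimoto_similarity",
    "tanimoto_distance",
    "nearest_active",
    "bulk_nearest_distance",
    "to_dense_matrix",
    "fingerprint_from_dense",
    "bulk_tanimoto_similarity",
    "write_fingerprint_cache",
    "read_fingerprint_cache",
    "read_smiles_file",
    "write_smiles_file",
]


@dataclass(frozen=True)
class Fingerprint:
    """Binary substructure fingerprint as a sorted tuple of on-bit indices.

    Equality is bitwise: two fingerprints are equal iff they have the same
    length and the same on-bits.
    """

    on_bits: tuple[int, ...]
    n_bits: int = DEFAULT_N_BITS

    def __post_init__(self) -> None:
        if self.n_bits <= 0:
            raise ValueError("n_bits must be positive")
        bits = tuple(sorted(set(int(b) for b in self.on_bits)))
        if bits and (bits[0] < 0 or bits[-1] >= self.n_bits):
            raise ValueError(f"bit index out of range [0, {self.n_bits})")
        object.__setattr__(self, "on_bits", bits)

    @property
    def popcount(self) -> int:
        return len(self.on_bits)

    def to_dense(self, dtype=np.uint8) -> np.ndarray:
        dense = np.zeros(self.n_bits, dtype=dtype)
        if self.on_bits:
            dense[list(self.on_bits)] = 1
        return dense


@dataclass(frozen=True)
class Molecule:
    """A standardized structure: canonical SMILES plus a validity flag.

    ``valid`` is False only when the input could not be parsed; invalid
    molecules are carried through (never silently dropped) so downstream
    bookkeeping can account for them.
    """

    smiles: str
    valid: bool = True
    source: str = field(default="", compare=False)


def parse_and_standardize(smiles: str, salt_list: Sequence[str] | None = None) -> Molecule:
    """Parse a SMILES, strip salt counter-ions, and canonicalize.

    Parameters
    ----------
    smiles
        Input structure string.  Must be non-empty.
    salt_list
        Optional list of counter-ion SMARTS patterns.  By default the
        standard salt catalog of the toolkit (RDKit ``SaltRemover``) is used.

    Returns
    -------
    Molecule
        Canonical molecule; ``valid=False`` for unparseable input.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise ValueError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return Molecule(smiles=smiles, valid=False, source=smiles)
    if salt_list is None:
        remover = SaltRemover()
    else:
        remover = SaltRemover(defnData="\n".join(salt_list))
    stripped = remover.StripMol(mol, dontRemoveEverything=True)
    return Molecule(smiles=Chem.MolToSmiles(stripped), valid=True, source=smiles)


def morgan_fingerprint(
    mol: Molecule,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
    use_chirality: bool = False,
    compound_id: str | None = None,
) -> Fingerprint:
    """Hash a standardized molecule to a binary Morgan fingerprint.

    Deterministic: the same canonical SMILES always yields the same bits.
    Raises for invalid molecules, naming ``compound_id`` when given.
    """
    if not mol.valid:
        label = compound_id if compound_id is not None else mol.source or mol.smiles
        raise ValueError(f"cannot fingerprint invalid molecule: {label!r}")
    rdmol = Chem.MolFromSmiles(mol.smiles)
    if rdmol is None:  # pragma: no cover - canonical SMILES always reparse
        raise ValueError(f"canonical SMILES failed to reparse: {mol.smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, fpSize=n_bits, includeChirality=use_chirality
    )
    bv = gen.GetFingerprint(rdmol)
    return Fingerprint(on_bits=tuple(bv.GetOnBits()), n_bits=n_bits)


def fingerprint_from_smiles(
    smiles: str,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
    salt_list: Sequence[str] | None = None,
    use_chirality: bool = False,
    compound_id: str | None = None,
) -> Fingerprint:
    """Convenience: standardize then fingerprint in one call."""
    mol = parse_and_standardize(smiles, salt_list=salt_list)
    return morgan_fingerprint(
        mol, radius=radius, n_bits=n_bits, use_chirality=use_chirality, compound_id=compound_id
    )


def tanimoto_similarity(a: Fingerprint, b: Fingerprint) -> float:
    """Jaccard similarity of the on-bit sets.

    Two empty fingerprints are defined as similarity 1 (distance 0); empty
    versus non-empty is similarity 0.  This avoids 0/0 and keeps the
    distance monotone.
    """
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint width mismatch: {a.n_bits} != {b.n_bits}")
    sa, sb = set(a.on_bits), set(b.on_bits)
    union = len(sa | sb)
    if union == 0:
        return 1.0
    return len(sa & sb) / union


def tanimoto_distance(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto (Jaccard) distance: ``1 - tanimoto_similarity``."""
    return 1.0 - tanimoto_similarity(a, b)


def nearest_active(
    query: Fingerprint, references: Sequence[tuple[str, Fingerprint]]
) -> tuple[float, str]:
    """Distance to, and id of, the nearest reference fingerprint.

    Ties are broken by the smallest reference index.
    """
    if not references:
        raise ValueError("reference set is empty")
    best_d, best_id = np.inf, None
    for ref_id, ref_fp in references:
        d = tanimoto_distance(query, ref_fp)
        if d < best_d:
            best_d, best_id = d, ref_id
    return float(best_d), best_id


def to_dense_matrix(fps: Sequence[Fingerprint], dtype=np.uint8) -> np.ndarray:
    """Stack fingerprints into an ``(n, n_bits)`` dense matrix."""
    if not fps:
        raise ValueError("no fingerprints")
    n_bits = fps[0].n_bits
    mat = np.zeros((len(fps), n_bits), dtype=dtype)
    for i, fp in enumerate(fps):
        if fp.n_bits != n_bits:
            raise ValueError("inconsistent fingerprint widths")
        if fp.on_bits:
            mat[i, list(fp.on_bits)] = 1
    return mat


def fingerprint_from_dense(row: np.ndarray) -> Fingerprint:
    """Inverse of a :func:`to_dense_matrix` row."""
    return Fingerprint(on_bits=tuple(int(i) for i in np.flatnonzero(row)), n_bits=len(row))


def bulk_tanimoto_similarity(queries: np.ndarray, refs: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto similarity between dense 0/1 matrices.

    Returns an ``(n_queries, n_refs)`` float array.  Empty-vs-empty pairs
    are similarity 1, matching :func:`tanimoto_similarity`.
    """
    q = queries.astype(np.float32, copy=False)
    r = refs.astype(np.float32, copy=False)
    inter = q @ r.T
    pop_q = q.sum(axis=1, keepdims=True)
    pop_r = r.sum(axis=1, keepdims=True).T
    union = pop_q + pop_r - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 1.0)
    return sim


def bulk_nearest_distance(
    query_matrix: np.ndarray, ref_matrix: np.ndarray, block: int = 2048
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-reference Tanimoto distance for each query row.

    Blocked so memory stays ``O(block * n_refs)``.  Returns (distances,
    argmin indices); ties resolve to the smallest reference index.
    """
    if ref_matrix.shape[0] == 0:
        raise ValueError("reference set is empty")
    n = query_matrix.shape[0]
    dist = np.empty(n, dtype=np.float64)
    idx = np.empty(n, dtype=np.int64)
    for start in range(0, n, block):
        stop = min(start + block, n)
        sim = bulk_tanimoto_similarity(query_matrix[start:stop], ref_matrix)
        best = sim.argmax(axis=1)  # argmax takes the first max -> smallest index
        dist[start:stop] = 1.0 - sim[np.arange(stop - start), best]
        idx[start:stop] = best
    return dist, idx


# --- fingerprint cache ------------------------------------------------------
# Bit-packed binary layout, designed for streaming very large libraries:
#   bytes 0-3   magic b"VSFP"
#   bytes 4-7   uint32 little-endian: n_bits
#   bytes 8-15  uint64 little-endian: n_rows
#   then n_rows rows of ceil(n_bits / 8) bytes each (numpy packbits order).

_CACHE_MAGIC = b"VSFP"


def write_fingerprint_cache(path, fps: Iterable[Fingerprint], n_bits: int = DEFAULT_N_BITS) -> int:
    """Write fingerprints to the packed cache format; returns the row count."""
    n_rows = 0
    row_bytes = (n_bits + 7) // 8
    with open(path, "wb") as fh:
        fh.write(_CACHE_MAGIC)
        fh.write(struct.pack("<I", n_bits))
        header_pos = fh.tell()
        fh.write(struct.pack("<Q", 0))
        for fp in fps:
            if fp.n_bits != n_bits:
                raise ValueError("fingerprint width does not match cache header")
            packed = np.packbits(fp.to_dense())
            assert packed.size == row_bytes
            fh.write(packed.tobytes())
            n_rows += 1
        fh.seek(header_pos)
        fh.write(struct.pack("<Q", n_rows))
    return n_rows


def read_fingerprint_cache(path, batch: int | None = None) -> Iterator[Fingerprint]:
    """Stream fingerprints back from a packed cache file."""
    with open(path, "rb") as fh:
        magic = fh.read(4)
        if magic != _CACHE_MAGIC:
            raise ValueError(f"not a fingerprint cache file: {path}")
        (n_bits,) = struct.unpack("<I", fh.read(4))
        (n_rows,) = struct.unpack("<Q", fh.read(8))
        row_bytes = (n_bits + 7) // 8
        chunk_rows = batch or 8192
        remaining = n_rows
        while remaining > 0:
            take = min(chunk_rows, remaining)
            raw = np.frombuffer(fh.read(take * row_bytes), dtype=np.uint8)
            rows = np.unpackbits(raw.reshape(take, row_bytes), axis=1)[:, :n_bits]
            for row in rows:
                yield fingerprint_from_dense(row)
            remaining -= take


def read_smiles_file(path) -> list[tuple[str, str]]:
    """Read a ``.smi`` file ("SMILES<whitespace>ID" per line) -> [(smiles, id)]."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            cid = parts[1].strip() if len(parts) > 1 else f"line{lineno}"
            out.append((smiles, cid))
    return out


def write_smiles_file(path, entries: Iterable[tuple[str, str]]) -> None:
    """Write [(smiles, id)] as a ``.smi`` file."""
    with open(path, "w") as fh:
        for smiles, cid in entries:
            fh.write(f"{smiles}\t{cid}\n")
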
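"""Coordinate handling for bead and atom models.

Holds the minimal structural toolkit the scoring pipeline needs: a
fixed-column PDB reader/writer covering the ATOM/HETATM subset, optimal
superposition RMSD (Kabsch), the maximum intramolecular diameter D_max,
and evolutionary-coupling (EC) restraint tables with residue-pair
distance evaluation.  EC pairs are residue pairs inferred to co-evolve
across a protein family; spatial proximity of such pairs in a model is
used as a native-likeness signal.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from .errors import PDBFormatError, SaxsGuideError

__all__ = [
    "Structure",
    "ECRestraintSet",
    "parse_pdb",
    "write_pdb",
    "kabsch_rmsd",
    "residue_pair_distances",
    "ec_filter",
    "max_diameter",
    "read_ec_table",
    "write_ec_table",
]


@dataclass(frozen=True)
class Structure:
    """Labeled point scatterers with coordinates in Angstrom.

    ``labels`` carries the element-or-bead tag per scatterer (beads use
    'CA' so they interoperate with C-alpha selections), ``residue_index``
    is 1-based as in PDB files, and ``chain_id`` a single character per
    scatterer.
    """

    coords: np.ndarray
    labels: Tuple[str, ...] = None  # type: ignore[assignment]
    residue_index: np.ndarray = None  # type: ignore[assignment]
    chain_id: Tuple[str, ...] = None  # type: ignore[assignment]

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise SaxsGuideError("coords must be an (n, 3) array")
        n = coords.shape[0]
        if not np.all(np.isfinite(coords)):
            raise SaxsGuideError("coordinates must be finite")
        labels = tuple(self.labels) if self.labels is not None else ("CA",) * n
        resi = (
            np.arange(1, n + 1)
            if self.residue_index is None
            else np.asarray(self.residue_index, dtype=int)
        )
        chains = tuple(self.chain_id) if self.chain_id is not None else ("A",) * n
        if len(labels) != n or resi.shape != (n,) or len(chains) != n:
            raise SaxsGuideError("labels/residue_index/chain_id must match coords")
        if np.any(resi < 1):
            raise SaxsGuideError("residue indices must be >= 1 (1-based)")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "residue_index", resi)
        object.__setattr__(self, "chain_id", chains)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def subset(self, idx) -> "Structure":
        idx = np.asarray(idx)
        return Structure(
            self.coords[idx],
            tuple(self.labels[i] for i in idx),
            self.residue_index[idx],
            tuple(self.chain_id[i] for i in idx),
        )

    def ca_only(self) -> "Structure":
        idx = [i for i, lab in enumerate(self.labels) if lab == "CA"]
        if not idx:
            raise SaxsGuideError("structure has no CA scatterers")
        return self.subset(idx)


# ---------------------------------------------------------------------------
# PDB fixed-column subset


def parse_pdb(source: Union[str, IO], ca_only: bool = False) -> Structure:
    """Parse ATOM/HETATM records from a PDB stream (first model only).

    Only the fixed-column subset needed here is read: atom name, chain id,
    residue number and coordinates.  Malformed records raise
    :class:`PDBFormatError` naming the line.
    """
    if isinstance(source, str):
        stream: IO = io.StringIO(source) if "\n" in source else open(source)
    else:
        stream = source
    coords: List[List[float]] = []
    labels: List[str] = []
    resi: List[int] = []
    chains: List[str] = []
    try:
        for lineno, line in enumerate(stream, start=1):
            rec = line[:6]
            if rec == "ENDMDL":
                break
            if rec not in ("ATOM  ", "HETATM"):
                continue
            try:
                name = line[12:16].strip()
                chain = line[21].strip() or "A"
                rnum = int(line[22:26])
                xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            except (ValueError, IndexError) as exc:
                raise PDBFormatError(f"line {lineno}: malformed record: {exc}")
            if ca_only and name != "CA":
                continue
            coords.append(xyz)
            labels.append(name)
            resi.append(rnum)
            chains.append(chain)
    finally:
        if isinstance(source, str) and "\n" not in source:
            stream.close()
    if not coords:
        raise PDBFormatError("no ATOM/HETATM records found")
    return Structure(np.array(coords), tuple(labels), np.array(resi), tuple(chains))


def write_pdb(structure: Structure, dest: Optional[Union[str, IO]] = None) -> str:
    """Write a structure as ATOM records (fixed columns, 3-decimal coords)."""
    lines = []
    for i in range(structure.n_atoms):
        name = structure.labels[i]
        # short names are right-padded starting at column 14 per convention
        name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
        x, y, z = structure.coords[i]
        lines.append(
            f"ATOM  {i + 1:>5d} {name_field}"
            f" ALA {structure.chain_id[i][:1]}{structure.residue_index[i]:>4d}"
            f"    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
        )
    text = "\n".join(lines) + "\nEND\n"
    if dest is not None:
        if hasattr(dest, "write"):
            dest.write(text)
        else:
            with open(dest, "w") as fh:
                fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Superposition and distances


def kabsch_rmsd(a: Structure, b: Structure, subset=None) -> float:
    """Minimal RMSD between two structures over rigid rotations+translations.

    A proper rotation (determinant +1) is enforced, so mirror images do
    not superpose to zero.  ``subset`` restricts the comparison to the
    given scatterer indices (applied to both structures).
    """
    P = a.coords if subset is None else a.coords[np.asarray(subset)]
    Q = b.coords if subset is None else b.coords[np.asarray(subset)]
    if P.shape != Q.shape:
        raise SaxsGuideError("structures must have equally sized subsets")
    if P.shape[0] < 3:
        raise SaxsGuideError("RMSD superposition needs at least 3 points")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    rot, _ = Rotation.align_vectors(Pc, Qc)
    # evaluate residuals explicitly: the reported rssd loses precision to
    # cancellation when the sets are near-congruent
    resid = Pc - rot.apply(Qc)
    return float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))


def max_diameter(s: Structure) -> float:
    """Maximum intramolecular pairwise distance D_max in Angstrom."""
    if s.n_atoms < 2:
        raise SaxsGuideError("max_diameter needs at least 2 scatterers")
    return float(pdist(s.coords).max())


# ---------------------------------------------------------------------------
# Evolutionary-coupling restraints


@dataclass(frozen=True)
class ECRestraintSet:
    """Evolutionarily coupled residue pairs with coupling scores.

    Each pair is ``(chain_i, residue_i, chain_j, residue_j)`` with 1-based
    residue numbers; inter-chain pairs are resolved by (chain, residue).
    """

    pairs: Tuple[Tuple[str, int, str, int], ...]
    scores: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        pairs = tuple(
            (str(c1), int(r1), str(c2), int(r2)) for c1, r1, c2, r2 in self.pairs
        )
        scores = (
            np.ones(len(pairs))
            if self.scores is None
            else np.asarray(self.scores, dtype=float)
        )
        if scores.shape != (len(pairs),):
            raise SaxsGuideError("scores must match the number of pairs")
        if not np.all(np.isfinite(scores)):
            raise SaxsGuideError("EC scores must be finite")
        if any(r1 < 1 or r2 < 1 for _, r1, _, r2 in pairs):
            raise SaxsGuideError("residue numbers must be positive")
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return len(self.pairs)


def ec_filter(
    table: ECRestraintSet, threshold: float = 0.3, top_n: Optional[int] = None
) -> ECRestraintSet:
    """Keep pairs with score strictly above ``threshold``, ranked by score.

    The comparison is strict (score > threshold); the survivors are sorted
    by descending score and optionally truncated to the ``top_n`` best.
    """
    scores = table.scores
    keep = np.where(scores > threshold)[0]
    order = keep[np.argsort(-scores[keep], kind="stable")]
    if top_n is not None:
        order = order[:top_n]
    return ECRestraintSet(
        tuple(table.pairs[i] for i in order), scores[order].copy()
    )


def residue_pair_distances(
    s: Structure, pairs: ECRestraintSet, atom_rule: str = "CA"
):
    """Distances between designated scatterers of EC pairs, plus their mean.

    ``atom_rule='CA'`` selects the CA (or bead) scatterer of each residue.
    Returns ``(distances, mean)``; a referenced residue without a matching
    scatterer raises an error naming the pair.
    """
    if atom_rule != "CA":
        raise SaxsGuideError(f"unsupported atom_rule {atom_rule!r}")
    lookup = {}
    for i in range(s.n_atoms):
        if s.labels[i] == "CA":
            lookup.setdefault((s.chain_id[i], int(s.residue_index[i])), i)
    out = np.empty(len(pairs))
    for k, (c1, r1, c2, r2) in enumerate(pairs.pairs):
        try:
            i = lookup[(c1, r1)]
            j = lookup[(c2, r2)]
        except KeyError as exc:
            raise SaxsGuideError(
                f"pair {c1}{r1}-{c2}{r2}: residue {exc.args[0]} has no CA scatterer"
            )
        out[k] = np.linalg.norm(s.coords[i] - s.coords[j])
    mean = float(out.mean()) if len(pairs) else float("nan")
    return out, mean


# ---------------------------------------------------------------------------
# EC table I/O: "chain_i res_i chain_j res_j score", '#' comments


def read_ec_table(source: Union[str, IO]) -> ECRestraintSet:
    if isinstance(source, str):
        stream: IO = open(source)
        close = True
    else:
        stream, close = source, False
    pairs = []
    scores = []
    try:
        for line in stream:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            tok = line.replace(",", " ").split()
            if len(tok) != 5:
                raise SaxsGuideError(f"EC table line needs 5 fields: {line!r}")
            pairs.append((tok[0], int(tok[1]), tok[2], int(tok[3])))
            scores.append(float(tok[4]))
    finally:
        if close:
            stream.close()
    return ECRestraintSet(tuple(pairs), np.array(scores))


def write_ec_table(table: ECRestraintSet, dest: Union[str, IO], header: str = "") -> None:
    text = "".join(f"# {ln}\n" for ln in header.splitlines()) if header else ""
    text += "# chain_i res_i chain_j res_j score\n"
    for (c1, r1, c2, r2), sc in zip(table.pairs, table.scores):
        text += f"{c1} {r1} {c2} {r2} {sc:.6g}\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        with open(dest, "w") as fh:
            fh.write(text)
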
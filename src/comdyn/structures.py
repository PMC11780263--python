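"""One-bead-per-residue structure handling and interstate residue mapping.

A transporter conformational state is represented as a :class:`BeadStructure`:
one backbone bead per residue, placed at the Cα position, with coordinates in
nanometres.  Two states of the same (or a homologous) protein are related by a
:class:`ResidueMap`, a partial bijection between residue identifiers.
Inside/outside helix windows used by the order parameters are described by
:class:`SegmentDef` entries loaded from a YAML config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from biotite.structure import AtomArray
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)

#: scale factor between PDB Ångström coordinates and internal nanometres
ANGSTROM_TO_NM = 0.1

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}

ResidueKey = tuple[str, int]  # (chain_id, resid)


class StructureError(ValueError):
    """Raised for malformed or inconsistent structural input."""


@dataclass
class BeadStructure:
    """Ordered backbone beads, one per residue, coordinates in nm."""

    chain_ids: np.ndarray  # (n,) str
    resids: np.ndarray  # (n,) int
    resnames: np.ndarray  # (n,) str, 3-letter codes
    coords: np.ndarray  # (n, 3) float, nm
    label: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.resids)
        if self.coords.shape != (n, 3):
            raise StructureError(
                f"coords shape {self.coords.shape} does not match {n} beads"
            )
        if n and not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        for chain in self.chains:
            r = self.resids[self.chain_ids == chain]
            if not np.all(np.diff(r) > 0):
                raise StructureError(
                    f"resids not strictly increasing in chain {chain!r}"
                )

    # -- accessors ---------------------------------------------------------

    @property
    def n_beads(self) -> int:
        return len(self.resids)

    def __len__(self) -> int:
        return self.n_beads

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(c)
        return list(seen)

    @property
    def keys(self) -> list[ResidueKey]:
        return list(zip(self.chain_ids, (int(r) for r in self.resids)))

    def index_table(self) -> dict[ResidueKey, int]:
        """Map (chain_id, resid) -> bead index."""
        return {k: i for i, k in enumerate(self.keys)}

    def index_of(self, chain_id: str, resid: int) -> int:
        try:
            return self.index_table()[(chain_id, resid)]
        except KeyError:
            raise StructureError(
                f"residue {resid} of chain {chain_id!r} not in structure"
            ) from None

    def sequence(self, chain_id: str) -> str:
        """One-letter sequence of a chain (unknown residues become 'X')."""
        mask = self.chain_ids == chain_id
        if not mask.any():
            raise StructureError(f"chain {chain_id!r} not in structure")
        return "".join(_THREE_TO_ONE.get(rn, "X") for rn in self.resnames[mask])

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "BeadStructure":
        return replace(
            self, coords=np.asarray(coords, dtype=float),
            label=self.label if label is None else label,
        )


# ---------------------------------------------------------------------------
# PDB input / output


def _deduplicate_resids(
    chain_ids: np.ndarray, resids: np.ndarray, ins_codes: np.ndarray
) -> np.ndarray:
    """Assign synthetic monotone resids where insertion codes (or duplicated
    numbers) would break the one-bead-per-(chain, resid) invariant."""
    out = resids.copy()
    for chain in np.unique(chain_ids):
        idx = np.flatnonzero(chain_ids == chain)
        prev = None
        for k in idx:
            r = out[k]
            if prev is not None and r <= prev:
                new = prev + 1
                logger.info(
                    "chain %s residue %d%s renumbered to %d",
                    chain, r, ins_codes[k].strip() or "", new,
                )
                out[k] = new
            prev = out[k]
    return out


def read_structure(
    path: str | Path,
    chain: str | None = None,
    label: str = "",
    model: int = 1,
) -> BeadStructure:
    """Read a PDB file into a one-bead-per-residue backbone representation.

    One bead is placed at each Cα position; HETATM records are ignored and
    alternate locations are resolved by highest occupancy.  Coordinates are
    converted from Å to nm.

    Parameters
    ----------
    path:
        PDB file with at least one Cα ATOM record.
    chain:
        Restrict to this chain; default is all chains.
    label:
        Free-form state label stored on the result (e.g. ``"IO"``).
    model:
        Model number for multi-model files (default: first).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=model, altloc="occupancy")
    mask = (atoms.atom_name == "CA") & ~atoms.hetero
    if chain is not None:
        mask &= atoms.chain_id == chain
    atoms = atoms[mask]
    if atoms.array_length() == 0:
        where = f"chain {chain!r} of {path}" if chain else str(path)
        raise StructureError(f"no C-alpha atoms found in {where}")
    ins = (
        atoms.ins_code
        if "ins_code" in atoms.get_annotation_categories()
        else np.array([""] * atoms.array_length(), dtype=object)
    )
    resids = _deduplicate_resids(atoms.chain_id, atoms.res_id.astype(int), ins)
    return BeadStructure(
        chain_ids=atoms.chain_id.astype(object),
        resids=resids,
        resnames=atoms.res_name.astype(object),
        coords=atoms.coord * ANGSTROM_TO_NM,
        label=label,
        source=str(path),
    )


def _to_atom_array(s: BeadStructure, coords_nm: np.ndarray) -> AtomArray:
    n = s.n_beads
    arr = AtomArray(n)
    arr.chain_id = np.asarray(s.chain_ids, dtype="U4")
    arr.res_id = s.resids
    arr.res_name = np.asarray(s.resnames, dtype="U5")
    arr.atom_name = np.full(n, "CA", dtype="U6")
    arr.element = np.full(n, "C", dtype="U2")
    arr.hetero = np.zeros(n, dtype=bool)
    arr.coord = np.asarray(coords_nm, dtype=np.float32) / ANGSTROM_TO_NM
    return arr


def write_structure(s: BeadStructure, path: str | Path) -> None:
    """Write the bead structure as a Cα-only PDB file (nm -> Å)."""
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(s, s.coords))
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Residue mapping


@dataclass
class ResidueMap:
    """Partial bijection between residues of two states.

    ``pairs`` holds ((chain_a, resid_a), (chain_b, resid_b)) tuples; each
    residue appears at most once per side.
    """

    pairs: list[tuple[ResidueKey, ResidueKey]]
    coverage_a: float = 0.0
    coverage_b: float = 0.0

    def __post_init__(self) -> None:
        a_side = [p[0] for p in self.pairs]
        b_side = [p[1] for p in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise StructureError("residue map is not a partial bijection")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def resid_pairs(self) -> list[tuple[int, int]]:
        return [(a[1], b[1]) for a, b in self.pairs]

    def inverted(self) -> "ResidueMap":
        return ResidueMap(
            pairs=[(b, a) for a, b in self.pairs],
            coverage_a=self.coverage_b,
            coverage_b=self.coverage_a,
        )

    def bead_index_map(self, a: BeadStructure, b: BeadStructure) -> dict[int, int]:
        """Map bead indices of structure ``a`` to bead indices of ``b``."""
        ta, tb = a.index_table(), b.index_table()
        out = {}
        for ka, kb in self.pairs:
            if ka in ta and kb in tb:
                out[ta[ka]] = tb[kb]
        return out


def _aligned_pairs(seq_a: str, seq_b: str) -> list[tuple[int, int]]:
    """Positions (0-based) paired by a global end-gap-free BLOSUM62 alignment."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    try:
        aligner.open_end_gap_score = 0.0
        aligner.extend_end_gap_score = 0.0
    except AttributeError:  # older Biopython naming
        aligner.end_open_gap_score = 0.0
        aligner.end_extend_gap_score = 0.0
    aln = aligner.align(seq_a, seq_b)[0]
    pairs: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    return pairs


def map_residues(
    a: BeadStructure,
    b: BeadStructure,
    mode: str = "alignment",
    spans: Sequence[tuple] | None = None,
    warn_coverage: float = 0.5,
) -> ResidueMap:
    """Establish residue correspondence between two states.

    Modes
    -----
    ``identity``
        Pair residues sharing (chain, resid); suitable when both states are
        the same protein with consistent numbering.
    ``alignment``
        Pair residues at aligned columns of a global (end-gap-free) BLOSUM62
        sequence alignment, chain by chain in order of appearance; suitable
        for homologs such as GLUT1/GLUT3.
    ``explicit``
        Pair residues from user-supplied spans
        ``(chain_a, start_a, end_a, chain_b, start_b)`` of equal length,
        e.g. a conserved-segment table.
    """
    pairs: list[tuple[ResidueKey, ResidueKey]] = []
    if mode == "identity":
        tb = set(b.index_table())
        for key in a.keys:
            if key in tb:
                pairs.append((key, key))
    elif mode == "alignment":
        for ca, cb in zip(a.chains, b.chains):
            ra = a.resids[a.chain_ids == ca]
            rb = b.resids[b.chain_ids == cb]
            for ia, ib in _aligned_pairs(a.sequence(ca), b.sequence(cb)):
                pairs.append(((ca, int(ra[ia])), (cb, int(rb[ib]))))
    elif mode == "explicit":
        if not spans:
            raise StructureError("mode='explicit' requires spans")
        for chain_a, start_a, end_a, chain_b, start_b in spans:
            for off in range(end_a - start_a + 1):
                pairs.append(
                    ((chain_a, start_a + off), (chain_b, start_b + off))
                )
        ta, tb = a.index_table(), b.index_table()
        missing = [
            p for p in pairs if p[0] not in ta or p[1] not in tb
        ]
        if missing:
            raise StructureError(
                f"explicit spans reference {len(missing)} residues absent "
                f"from the structures (first: {missing[0]})"
            )
    else:
        raise ValueError(f"unknown mapping mode {mode!r}")

    if not pairs:
        raise StructureError("residue mapping produced no pairs")
    cov_a = len(pairs) / a.n_beads
    cov_b = len(pairs) / b.n_beads
    if min(cov_a, cov_b) < warn_coverage:
        logger.warning(
            "residue map coverage low: %.2f (A) / %.2f (B)", cov_a, cov_b
        )
    return ResidueMap(pairs=pairs, coverage_a=cov_a, coverage_b=cov_b)


def alignment_identity(a: BeadStructure, b: BeadStructure, rmap: ResidueMap) -> float:
    """Fraction of mapped residue pairs with identical residue type."""
    ta, tb = a.index_table(), b.index_table()
    same = total = 0
    for ka, kb in rmap.pairs:
        if ka in ta and kb in tb:
            total += 1
            same += a.resnames[ta[ka]] == b.resnames[tb[kb]]
    return same / total if total else 0.0


# ---------------------------------------------------------------------------
# Segment definitions


@dataclass(frozen=True)
class SegmentDef:
    """A 10-residue helix window used as one end of an order parameter."""

    tm_id: int
    side: str  # "in" or "out"
    chain_id: str
    start: int
    end: int  # inclusive

    def __post_init__(self) -> None:
        if self.side not in ("in", "out"):
            raise StructureError(f"segment side must be in/out, got {self.side!r}")
        if self.end < self.start:
            raise StructureError(f"segment TM{self.tm_id}/{self.side}: end < start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def name(self) -> str:
        return f"TM{self.tm_id}/{self.side}"

    def resids(self) -> range:
        return range(self.start, self.end + 1)

    def bead_indices(self, s: BeadStructure) -> np.ndarray:
        table = s.index_table()
        idx = []
        for r in self.resids():
            key = (self.chain_id, r)
            if key not in table:
                raise StructureError(
                    f"segment {self.name}: residue {r} of chain "
                    f"{self.chain_id!r} absent from structure"
                )
            idx.append(table[key])
        return np.asarray(idx, dtype=int)


def load_segments(
    config: str | Path | Iterable[dict],
    structure: BeadStructure,
    length: int = 10,
) -> list[SegmentDef]:
    """Load and validate segment definitions from YAML (or a dict list).

    Each entry needs keys ``tm``, ``side``, ``chain``, ``start``, ``end``.
    Every (tm, side) pair must be unique, spans must have exactly ``length``
    residues, and every residue must exist in ``structure``.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            entries = yaml.safe_load(fh)
        if isinstance(entries, dict) and "segments" in entries:
            entries = entries["segments"]
    else:
        entries = list(config)
    segs: list[SegmentDef] = []
    seen: set[tuple[int, str]] = set()
    for e in entries:
        seg = SegmentDef(
            tm_id=int(e["tm"]), side=str(e["side"]),
            chain_id=str(e["chain"]), start=int(e["start"]), end=int(e["end"]),
        )
        if seg.length != length:
            raise StructureError(
                f"segment {seg.name}: span has {seg.length} residues, "
                f"expected {length}"
            )
        key = (seg.tm_id, seg.side)
        if key in seen:
            raise StructureError(f"duplicate segment {seg.name}")
        seen.add(key)
        seg.bead_indices(structure)  # existence check
        segs.append(seg)
    return segs


def write_segments(segments: Sequence[SegmentDef], path: str | Path) -> None:
    """Write segment definitions to a YAML config."""
    entries = [
        {"tm": s.tm_id, "side": s.side, "chain": s.chain_id,
         "start": s.start, "end": s.end}
        for s in segments
    ]
    with open(path, "w") as fh:
        yaml.safe_dump({"segments": entries}, fh, sort_keys=False)
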
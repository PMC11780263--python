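"""Inside/outside inter-helix distance order parameters.

The functional motion of a rocker-switch transporter is tracked by distances
between pairs of transmembrane (TM) helices, measured separately at the
intracellular ("in") and extracellular ("out") ends: opening of the inside
cavity shows as growing inside distances with shrinking outside distances,
and vice versa.  Each order parameter is the distance between the unweighted
centroids of two 10-residue helix windows (:class:`~comdyn.structures.SegmentDef`),
evaluated per frame of a :class:`Frameset`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from biotite.structure import stack
from biotite.structure.io.pdb import PDBFile

from .structures import (
    ANGSTROM_TO_NM,
    BeadStructure,
    SegmentDef,
    StructureError,
    _to_atom_array,
)

#: ring of central helices around the transport cavity, in adjacency order
DEFAULT_RING: tuple[int, ...] = (2, 1, 5, 8, 7, 11)


@dataclass
class Frameset:
    """An ordered set of coordinate frames sharing one bead table."""

    structure: BeadStructure
    coords: np.ndarray  # (n_frames, n_beads, 3) nm
    times: np.ndarray | None = None  # ps, optional

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[0] < 1:
            raise StructureError("frameset needs >= 1 frame of (n_beads, 3) coords")
        if self.coords.shape[1:] != (self.structure.n_beads, 3):
            raise StructureError(
                f"frame shape {self.coords.shape[1:]} does not match "
                f"{self.structure.n_beads} beads"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    @classmethod
    def from_structures(cls, structures: Sequence[BeadStructure]) -> "Frameset":
        ref = structures[0]
        return cls(structure=ref, coords=np.stack([s.coords for s in structures]))


@dataclass
class DistanceSeries:
    """Per-frame values of one order parameter, in nm."""

    pair_label: str  # e.g. "TM5/TM8(in)"
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise StructureError(f"{self.pair_label}: non-finite distances")
        if np.any(self.values < 0):
            raise StructureError(f"{self.pair_label}: negative distances")

    def __len__(self) -> int:
        return len(self.values)


def segment_distance(
    frames: Frameset, a: SegmentDef, b: SegmentDef
) -> DistanceSeries:
    """Per-frame Euclidean distance between two segments' centroids.

    The centroid is the unweighted mean of the backbone bead positions over
    the segment's residues.  Both segments must sit on the same membrane
    side.
    """
    if a.side != b.side:
        raise StructureError(
            f"segments {a.name} and {b.name} are on different sides"
        )
    ia = a.bead_indices(frames.structure)
    ib = b.bead_indices(frames.structure)
    ca = frames.coords[:, ia].mean(axis=1)
    cb = frames.coords[:, ib].mean(axis=1)
    return DistanceSeries(
        pair_label=f"TM{a.tm_id}/TM{b.tm_id}({a.side})",
        values=np.linalg.norm(ca - cb, axis=1),
    )


def ring_distances(
    frames: Frameset,
    segments: Sequence[SegmentDef],
    ring: Sequence[int] = DEFAULT_RING,
    extra_pairs: Sequence[tuple[int, int]] = (),
) -> list[DistanceSeries]:
    """Order parameters around the helix ring, both sides.

    One series per adjacent helix pair around ``ring`` (closed: the last
    helix pairs back to the first) and per side — 12 series for the default
    six-helix ring — plus any ``extra_pairs`` of cross-rim helices (e.g.
    TM5/TM11), also on both sides.
    """
    by_key = {(s.tm_id, s.side): s for s in segments}
    adjacent = [(ring[k], ring[(k + 1) % len(ring)]) for k in range(len(ring))]
    out: list[DistanceSeries] = []
    for tm_x, tm_y in list(adjacent) + list(extra_pairs):
        for side in ("in", "out"):
            try:
                seg_x = by_key[(tm_x, side)]
                seg_y = by_key[(tm_y, side)]
            except KeyError as exc:
                raise StructureError(
                    f"missing segment TM{exc.args[0][0]}/{exc.args[0][1]}"
                ) from None
            out.append(segment_distance(frames, seg_x, seg_y))
    return out


# ---------------------------------------------------------------------------
# Frame and series I/O


def write_frames(frames: Frameset, path: str | Path) -> None:
    """Write a frameset as a multi-model Cα-only PDB file."""
    arrays = [
        _to_atom_array(frames.structure, frames.coords[f])
        for f in range(frames.n_frames)
    ]
    pdb = PDBFile()
    pdb.set_structure(stack(arrays))
    pdb.write(str(path))


def read_frames(path: str | Path, template: BeadStructure | None = None) -> Frameset:
    """Read a multi-model Cα-only PDB file into a frameset."""
    from .structures import read_structure

    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    ref = template or read_structure(path, model=1)
    coords = np.stack(
        [
            pdb.get_structure(model=m, altloc="occupancy").coord * ANGSTROM_TO_NM
            for m in range(1, n_models + 1)
        ]
    )
    # restrict to the CA records the template kept
    atoms = pdb.get_structure(model=1, altloc="occupancy")
    mask = (atoms.atom_name == "CA") & ~atoms.hetero
    return Frameset(structure=ref, coords=coords[:, mask])


def read_xyz_frames(path: str | Path, structure: BeadStructure) -> Frameset:
    """Read a whitespace XYZ-per-frame stream (n_beads lines of ``x y z`` in
    nm per frame, frames concatenated; blank lines and ``#`` comments
    ignored)."""
    rows = np.loadtxt(path, comments="#", ndmin=2)
    if rows.shape[1] != 3:
        raise StructureError("xyz stream must have 3 columns")
    n = structure.n_beads
    if rows.shape[0] % n:
        raise StructureError(
            f"{rows.shape[0]} coordinate rows is not a multiple of {n} beads"
        )
    return Frameset(structure=structure, coords=rows.reshape(-1, n, 3))


def series_to_frame(series: Sequence[DistanceSeries]) -> pd.DataFrame:
    """Tabulate distance series: one column per order parameter, one row per
    frame."""
    return pd.DataFrame({s.pair_label: s.values for s in series})


def write_series(series: Sequence[DistanceSeries], path: str | Path) -> None:
    series_to_frame(series).to_csv(path, sep="\t", index=False)


def read_series(path: str | Path) -> list[DistanceSeries]:
    df = pd.read_csv(path, sep="\t")
    return [DistanceSeries(pair_label=c, values=df[c].to_numpy()) for c in df.columns]
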
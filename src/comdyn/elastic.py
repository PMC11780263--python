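"""MARTINI-style backbone elastic networks and the common-constraints filter.

An elastic network (EN) is the set of harmonic distance restraints between
backbone beads whose separation falls inside a cutoff shell; it is what keeps
a coarse-grained protein folded, at the price of pinning it to the
conformational state it was built from.  The common-constraints ("ComDYN")
filter removes every restraint whose reference distance differs between two
conformational states by more than a threshold (default 1 Å = 0.1 nm),
leaving only the restraints both states agree on — a network that preserves
the fold while permitting the interstate transition.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structures import BeadStructure, ResidueMap

logger = logging.getLogger(__name__)


class TopologyError(ValueError):
    """Raised for malformed topology files or inconsistent networks."""


@dataclass(frozen=True)
class ENParams:
    """Elastic-network build and filter parameters.

    Defaults follow the standard martinize elastic-network convention:
    cutoff shell 0.5–0.9 nm, force constant 500 kJ·mol⁻¹·nm⁻², restraints
    only between beads at least ``min_seq_sep`` residues apart in sequence
    (closer neighbours are held by bonded terms, not the EN).  The
    ``comdyn_threshold`` is the maximum interstate reference-distance
    difference a restraint may show and still count as "common" (0.1 nm).
    """

    lower_cutoff: float = 0.5  # nm
    upper_cutoff: float = 0.9  # nm
    force_constant: float = 500.0  # kJ mol^-1 nm^-2
    min_seq_sep: int = 3  # residues
    comdyn_threshold: float = 0.1  # nm

    def __post_init__(self) -> None:
        if not 0 <= self.lower_cutoff < self.upper_cutoff:
            raise ValueError("require 0 <= lower_cutoff < upper_cutoff")
        if self.force_constant <= 0:
            raise ValueError("force_constant must be positive")
        if self.comdyn_threshold <= 0:
            raise ValueError("comdyn_threshold must be positive")


@dataclass
class ElasticNetwork:
    """Harmonic pair restraints {(i, j, d0, k)} over a bead structure."""

    i: np.ndarray  # (m,) bead indices, i < j
    j: np.ndarray
    d0: np.ndarray  # (m,) reference distances, nm
    k: np.ndarray  # (m,) force constants, kJ mol^-1 nm^-2
    params: ENParams = field(default_factory=ENParams)
    state_label: str = ""

    def __post_init__(self) -> None:
        self.i = np.asarray(self.i, dtype=int)
        self.j = np.asarray(self.j, dtype=int)
        self.d0 = np.asarray(self.d0, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        if not (len(self.i) == len(self.j) == len(self.d0) == len(self.k)):
            raise TopologyError("constraint arrays have mismatched lengths")
        if len(self.i) and not np.all(self.i < self.j):
            raise TopologyError("constraints must satisfy i < j")
        if len(set(zip(self.i, self.j))) != len(self.i):
            raise TopologyError("duplicate constraint pairs")

    def __len__(self) -> int:
        return len(self.i)

    @property
    def pairs(self) -> set[tuple[int, int]]:
        return set(zip(self.i.tolist(), self.j.tolist()))

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"i": self.i, "j": self.j, "d0": self.d0, "k": self.k}
        )

    def subset(self, mask: np.ndarray, state_label: str | None = None) -> "ElasticNetwork":
        return ElasticNetwork(
            i=self.i[mask], j=self.j[mask], d0=self.d0[mask], k=self.k[mask],
            params=self.params,
            state_label=self.state_label if state_label is None else state_label,
        )


@dataclass
class ComdynResult:
    """Outcome of the common-constraints filter for one state's network."""

    filtered: ElasticNetwork
    n_input: int
    n_kept: int
    dropped: pd.DataFrame  # columns i, j, delta (nm; NaN if unmapped), reason

    @property
    def kept_fraction(self) -> float:
        return self.n_kept / self.n_input if self.n_input else 0.0


def build_network(
    s: BeadStructure,
    params: ENParams | None = None,
    state_label: str | None = None,
) -> ElasticNetwork:
    """Build the elastic network of a single conformational state.

    All and only bead pairs with ``lower_cutoff <= d <= upper_cutoff`` and
    sequence separation >= ``min_seq_sep`` (pairs on different chains are
    always eligible) receive a restraint with ``d0`` set to the observed
    distance.
    """
    params = params or ENParams()
    if s.n_beads < 2:
        raise TopologyError("need at least 2 beads to build a network")
    tree = cKDTree(s.coords)
    pairs = tree.query_pairs(r=params.upper_cutoff, output_type="ndarray")
    if len(pairs):
        pairs.sort(axis=1)
        # deterministic ordering regardless of tree internals
        order = np.lexsort((pairs[:, 1], pairs[:, 0]))
        pairs = pairs[order]
        d = np.linalg.norm(s.coords[pairs[:, 0]] - s.coords[pairs[:, 1]], axis=1)
        same_chain = s.chain_ids[pairs[:, 0]] == s.chain_ids[pairs[:, 1]]
        seq_sep = np.abs(s.resids[pairs[:, 0]] - s.resids[pairs[:, 1]])
        keep = (d >= params.lower_cutoff) & (
            ~same_chain | (seq_sep >= params.min_seq_sep)
        )
        pairs, d = pairs[keep], d[keep]
    else:
        pairs = np.empty((0, 2), dtype=int)
        d = np.empty(0)
    return ElasticNetwork(
        i=pairs[:, 0], j=pairs[:, 1], d0=d,
        k=np.full(len(d), params.force_constant),
        params=params,
        state_label=s.label if state_label is None else state_label,
    )


def comdyn_filter(
    net: ElasticNetwork,
    own: BeadStructure,
    other: BeadStructure,
    rmap: ResidueMap,
    params: ENParams | None = None,
    unmapped: str = "drop",
    strict: bool = False,
) -> ComdynResult:
    """Keep only restraints whose reference distance agrees between states.

    A restraint (i, j, d0) built on ``own`` is kept iff both beads map into
    ``other`` and ``|d0 - d_other| <= comdyn_threshold`` where ``d_other`` is
    the distance between the mapped beads in the other state.  Restraints
    with an unmapped endpoint are dropped by default (their interstate
    similarity cannot be verified); ``unmapped="keep"`` retains them.
    ``strict=True`` uses a strict ``<`` comparison instead of ``<=``.

    The filter is applied per state: filtering the A-state network against B
    and the B-state network against A generally keeps different numbers of
    restraints.
    """
    params = params or net.params
    if len(rmap) == 0:
        raise TopologyError("empty residue map")
    index_map = rmap.bead_index_map(own, other)

    mapped = np.array(
        [(ii in index_map) and (jj in index_map) for ii, jj in zip(net.i, net.j)],
        dtype=bool,
    ) if len(net) else np.empty(0, dtype=bool)
    delta = np.full(len(net), np.nan)
    if mapped.any():
        oi = np.array([index_map[ii] for ii in net.i[mapped]])
        oj = np.array([index_map[jj] for jj in net.j[mapped]])
        d_other = np.linalg.norm(other.coords[oi] - other.coords[oj], axis=1)
        delta[mapped] = np.abs(net.d0[mapped] - d_other)

    thr = params.comdyn_threshold
    similar = (delta < thr) if strict else (delta <= thr)
    similar &= mapped
    keep = similar | (~mapped if unmapped == "keep" else False)

    reasons = np.where(~mapped, "unmapped", np.where(similar, "", "delta"))
    dropped = pd.DataFrame(
        {
            "i": net.i[~keep],
            "j": net.j[~keep],
            "delta": delta[~keep],
            "reason": reasons[~keep],
        }
    )
    filtered = net.subset(keep, state_label=f"{net.state_label}:comdyn")
    logger.info(
        "comdyn filter kept %d of %d constraints (%.1f%%)",
        len(filtered), len(net), 100 * len(filtered) / max(len(net), 1),
    )
    return ComdynResult(
        filtered=filtered, n_input=len(net), n_kept=len(filtered),
        dropped=dropped,
    )


def intersect_networks(
    res_a: ComdynResult,
    res_b: ComdynResult,
    own_a: BeadStructure,
    own_b: BeadStructure,
    rmap: ResidueMap,
) -> tuple[ElasticNetwork, ElasticNetwork]:
    """Optional symmetric mode: keep only restraints present (after
    filtering) in both states' networks under the residue map."""
    fwd = rmap.bead_index_map(own_a, own_b)
    pairs_b = res_b.filtered.pairs
    mask_a = np.array(
        [
            (ii in fwd and jj in fwd)
            and (tuple(sorted((fwd[ii], fwd[jj]))) in pairs_b)
            for ii, jj in zip(res_a.filtered.i, res_a.filtered.j)
        ],
        dtype=bool,
    ) if len(res_a.filtered) else np.empty(0, dtype=bool)
    inv = {v: k for k, v in fwd.items()}
    pairs_a = res_a.filtered.pairs
    mask_b = np.array(
        [
            (ii in inv and jj in inv)
            and (tuple(sorted((inv[ii], inv[jj]))) in pairs_a)
            for ii, jj in zip(res_b.filtered.i, res_b.filtered.j)
        ],
        dtype=bool,
    ) if len(res_b.filtered) else np.empty(0, dtype=bool)
    return res_a.filtered.subset(mask_a), res_b.filtered.subset(mask_b)


# ---------------------------------------------------------------------------
# GROMACS itp bonded-section I/O

_HEADER_RE = re.compile(
    r";\s*comdyn params:\s*lower=(?P<lower>\S+)\s+upper=(?P<upper>\S+)"
    r"\s+k=(?P<k>\S+)\s+min_seq_sep=(?P<sep>\S+)\s+threshold=(?P<thr>\S+)"
)


def write_topology(
    net: ElasticNetwork, path: str | Path, funct: int = 1
) -> None:
    """Write the network as a GROMACS itp bonded section.

    Data lines are ``i j funct d0 k`` with 1-based atom indices, ``d0`` in nm
    to 5 decimals and ``funct`` 1 (harmonic bond) or 6 (harmonic restraint
    that generates no exclusions).  A header comment records the build
    parameters and the constraint count.
    """
    if funct not in (1, 6):
        raise TopologyError(f"unsupported funct {funct}")
    p = net.params
    lines = [
        f"; elastic network for state {net.state_label!r}: {len(net)} constraints",
        f"; comdyn params: lower={p.lower_cutoff:g} upper={p.upper_cutoff:g} "
        f"k={p.force_constant:g} min_seq_sep={p.min_seq_sep} "
        f"threshold={p.comdyn_threshold:g}",
        "[ bonds ]",
        ";  i    j  funct    d0(nm)        k",
    ]
    for ii, jj, d0, kk in zip(net.i, net.j, net.d0, net.k):
        lines.append(f"{ii + 1} {jj + 1} {funct} {d0:.5f} {kk:g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_topology(path: str | Path) -> ElasticNetwork:
    """Parse a bonded section written by :func:`write_topology`."""
    params = None
    i, j, d0, k = [], [], [], []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(";"):
            m = _HEADER_RE.match(line)
            if m:
                params = ENParams(
                    lower_cutoff=float(m["lower"]),
                    upper_cutoff=float(m["upper"]),
                    force_constant=float(m["k"]),
                    min_seq_sep=int(m["sep"]),
                    comdyn_threshold=float(m["thr"]),
                )
            continue
        if line.startswith("["):
            continue
        fields = line.split()
        if len(fields) != 5:
            raise TopologyError(f"{path}:{lineno}: expected 5 fields, got {len(fields)}")
        try:
            ii, jj, funct = int(fields[0]), int(fields[1]), int(fields[2])
            d, kk = float(fields[3]), float(fields[4])
        except ValueError as exc:
            raise TopologyError(f"{path}:{lineno}: {exc}") from None
        if funct not in (1, 6):
            raise TopologyError(f"{path}:{lineno}: unknown funct {funct}")
        i.append(ii - 1)
        j.append(jj - 1)
        d0.append(d)
        k.append(kk)
    return ElasticNetwork(
        i=np.array(i, dtype=int), j=np.array(j, dtype=int),
        d0=np.array(d0), k=np.array(k),
        params=params or ENParams(),
    )
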
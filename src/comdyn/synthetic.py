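"""Synthetic two-state transporter bundles and mixture order-parameter series.

The generator emulates, at toy scale, the rocker-switch geometry of an
MFS-fold transporter: a ring of mobile transmembrane helices whose
intracellular ("in", z = 0) ends close while the extracellular ("out") ends
open, embedded in a static scaffold that stands in for the rest of the
protein.  Helices are idealized straight bead rods (one bead per residue);
the two states differ by a rigid radial tilt of each mobile helix, so the
in-end ring radius shrinks from state A to state B while the out-end radius
grows — the rocker-switch motion.

The scaffold has two kinds of static columns, mirroring the two kinds of
tertiary contact a real two-state protein offers:

* "valley" columns, placed between mobile helices at the radius that makes
  them equidistant from each mobile bead's two state positions.  Elastic
  constraints to them cost almost nothing anywhere along the A-to-B path
  but wall off motion beyond either state; the common-constraints filter
  keeps them.
* "pin" columns, placed radially outside each mobile helix.  Their
  distances to the arm beads change nearly one-to-one with the tilt, so a
  single-state network pins the helix through them while the
  common-constraints filter drops them — they are the state-specific
  contacts whose removal makes the interstate transition samplable.

All geometry is closed-form, so every EN-eligible pair's interstate
distance change and every segment centroid distance is known exactly and
ships as a "truth" table computed by brute-force enumeration, independent
of the elastic-network code path.

Gaussian-mixture distance series emulate wild-type-like (two-basin) versus
mutant-like (single-basin or displaced) sampling with analytically known
overlap and shift.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .elastic import ENParams
from .order_params import DistanceSeries
from .structures import BeadStructure, ResidueMap, SegmentDef, map_residues

#: helix numbering around the central transport-cavity ring, adjacency order
RING_TM_IDS: tuple[int, ...] = (2, 1, 5, 8, 7, 11)


@dataclass(frozen=True)
class BundleSpec:
    """Geometry of a synthetic two-state helix bundle.

    ``radius_a``/``radius_b`` are the mobile-helix ring radii at the "in"
    end (z = 0); ``splay_a``/``splay_b`` tilt each helix radially so the
    "out"-end radius becomes ``radius + length * tan(splay)``.  The default
    splays are chosen so both states share the mid-height ring radius: the
    interstate motion is then a pure rocker tilt of each helix about its
    midpoint, closing inside while opening outside.  With the default
    martinize-convention elastic-network parameters this drops the
    state-specific pin contacts (interstate distance change up to
    0.25 nm) while keeping the near-invariant valley and intra-helix
    constraints.
    """

    n_helices: int = 6
    residues_per_helix: int = 24
    helix_rise: float = 0.15  # nm per residue
    radius_a: float = 1.0  # nm, "in"-end ring radius, state A (inside open)
    radius_b: float = 0.8  # nm, state B (inside closed)
    splay_a: float = 0.0  # degrees, radial tilt, state A
    splay_b: float = 6.6139  # degrees; default shares the mid-height radius
    noise_sigma: float = 0.0  # nm, isotropic positional noise
    seed: int = 0
    segment_length: int = 10
    scaffold: bool = True
    valley_spacing: float = 0.29  # nm, z-spacing of valley-column beads
    pin_offset: float = 0.75  # nm, radial gap of the pin anchors

    def __post_init__(self) -> None:
        if self.n_helices < 1 or self.residues_per_helix < 1:
            raise ValueError("counts must be >= 1")
        if self.radius_a <= 0 or self.radius_b <= 0:
            raise ValueError("ring radii must be positive")
        if self.residues_per_helix < 2 * self.segment_length:
            raise ValueError(
                "helices must be long enough for disjoint in/out segments"
            )

    @property
    def length(self) -> float:
        return (self.residues_per_helix - 1) * self.helix_rise

    @property
    def tm_ids(self) -> tuple[int, ...]:
        base = RING_TM_IDS if self.n_helices <= len(RING_TM_IDS) else tuple(
            range(1, self.n_helices + 1)
        )
        return base[: self.n_helices]

    def radius_profile(self, state: str) -> tuple[float, float]:
        """(in-end radius, radial slope) of one state's helices."""
        radius = self.radius_a if state == "A" else self.radius_b
        splay = self.splay_a if state == "A" else self.splay_b
        return radius, float(np.tan(np.radians(splay)))


@dataclass
class BundleFixture:
    """Everything the rest of the pipeline needs, plus ground truth."""

    state_a: BeadStructure
    state_b: BeadStructure
    residue_map: ResidueMap
    segments: list[SegmentDef]
    truth_pairs_a: pd.DataFrame  # EN-eligible pairs of state A's network
    truth_pairs_b: pd.DataFrame
    truth_segments: pd.DataFrame  # centroid distances per ring pair and side
    spec: BundleSpec

    @property
    def scaffold_indices(self) -> np.ndarray:
        """Bead indices of the static scaffold (lowercase chain ids)."""
        return np.flatnonzero(
            [str(c).islower() for c in self.state_a.chain_ids]
        )


def _helix_axes(spec: BundleSpec) -> list[np.ndarray]:
    return [
        np.array([np.cos(t), np.sin(t)])
        for t in 2.0 * np.pi * np.arange(spec.n_helices) / spec.n_helices
    ]


def _mobile_coords(spec: BundleSpec, state: str) -> np.ndarray:
    radius, slope = spec.radius_profile(state)
    z = np.arange(spec.residues_per_helix) * spec.helix_rise
    r = radius + z * slope
    coords = []
    for u in _helix_axes(spec):
        coords.append(np.column_stack([r * u[0], r * u[1], z]))
    return np.vstack(coords)


def _scaffold_coords(spec: BundleSpec) -> tuple[np.ndarray, list[int]]:
    """Static scaffold beads, identical in both states.

    Returns coordinates plus per-column bead counts (one chain each).
    Valley columns sit between mobile helices at the radius that is
    equidistant from an end bead's state-A and state-B positions,
    ``(r_A + r_B) / (2 cos(pi/n))``, separately for the in and out halves
    (the helices swing inward below mid-height and outward above it).
    Pin anchors are single beads straight outside each helix end, where
    every mobile-helix contact changes by more than the common-constraints
    threshold between the states.
    """
    ra, sa = spec.radius_profile("A")
    rb, sb = spec.radius_profile("B")
    half_angle = np.pi / spec.n_helices
    mid_z = spec.length / 2.0
    n_half = max(int(round(mid_z / spec.valley_spacing)) + 1, 2)
    z_lo = np.linspace(0.0, mid_z, n_half)
    z_hi = np.linspace(mid_z, spec.length, n_half)
    r_mid = 0.5 * ((ra + sa * mid_z) + (rb + sb * mid_z))

    columns: list[np.ndarray] = []
    for h in range(spec.n_helices):
        theta = 2.0 * np.pi * h / spec.n_helices
        # valley columns at the bisecting azimuth, one per z-half, tilted
        # so each bead bisects the two state positions at its own height
        for z_col in (z_lo, z_hi):
            r_valley = ((ra + sa * z_col) + (rb + sb * z_col)) / (
                2.0 * np.cos(half_angle)
            )
            u = np.array([np.cos(theta + half_angle), np.sin(theta + half_angle)])
            columns.append(
                np.column_stack([r_valley * u[0], r_valley * u[1], z_col])
            )
        # single-bead pin anchors at each end of the helix
        u = np.array([np.cos(theta), np.sin(theta)])
        r_pin = r_mid + spec.pin_offset
        for z_pin in (0.0, spec.length):
            columns.append(np.array([[r_pin * u[0], r_pin * u[1], z_pin]]))
    return np.vstack(columns), [len(c) for c in columns]


def _as_structure(
    spec: BundleSpec, mobile: np.ndarray, scaffold: np.ndarray | None,
    scaffold_counts: list[int], label: str,
) -> BeadStructure:
    chains: list[str] = []
    resids: list[int] = []
    for h in range(spec.n_helices):
        chains.extend(string.ascii_uppercase[h % 26] * spec.residues_per_helix)
        resids.extend(range(1, spec.residues_per_helix + 1))
    coords = mobile
    if scaffold is not None:
        for c, count in enumerate(scaffold_counts):
            chains.extend([string.ascii_lowercase[c % 26]] * count)
            resids.extend(range(1, count + 1))
        coords = np.vstack([mobile, scaffold])
    return BeadStructure(
        chain_ids=np.array(chains, dtype=object),
        resids=np.array(resids),
        resnames=np.array(["ALA"] * len(resids), dtype=object),
        coords=coords,
        label=label,
        source="synthetic",
    )


def _eligible_pair_truth(
    own: BeadStructure, other: BeadStructure, params: ENParams
) -> pd.DataFrame:
    """Brute-force enumeration of EN-eligible pairs of ``own`` with their
    interstate distance changes (identity residue correspondence)."""
    n = own.n_beads
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(own.coords[i] - own.coords[j]))
            if not params.lower_cutoff <= d <= params.upper_cutoff:
                continue
            if (
                own.chain_ids[i] == own.chain_ids[j]
                and abs(int(own.resids[i]) - int(own.resids[j])) < params.min_seq_sep
            ):
                continue
            d_other = float(np.linalg.norm(other.coords[i] - other.coords[j]))
            delta = abs(d - d_other)
            rows.append(
                {
                    "i": i, "j": j, "d_own": d, "d_other": d_other,
                    "delta": delta, "kept": delta <= params.comdyn_threshold,
                }
            )
    return pd.DataFrame(rows, columns=["i", "j", "d_own", "d_other", "delta", "kept"])


def _segment_truth(
    spec: BundleSpec, state_a: BeadStructure, state_b: BeadStructure,
    segments: list[SegmentDef],
) -> pd.DataFrame:
    by_key = {(s.tm_id, s.side): s for s in segments}
    ring = spec.tm_ids
    rows = []
    for k in range(len(ring)):
        tm_x, tm_y = ring[k], ring[(k + 1) % len(ring)]
        for side in ("in", "out"):
            sx, sy = by_key[(tm_x, side)], by_key[(tm_y, side)]
            dists = {}
            for name, s in (("d_a", state_a), ("d_b", state_b)):
                cx = s.coords[sx.bead_indices(s)].mean(axis=0)
                cy = s.coords[sy.bead_indices(s)].mean(axis=0)
                dists[name] = float(np.linalg.norm(cx - cy))
            rows.append(
                {"pair_label": f"TM{tm_x}/TM{tm_y}({side})", **dists}
            )
    return pd.DataFrame(rows)


def make_two_state_bundle(
    spec: BundleSpec | None = None, params: ENParams | None = None
) -> BundleFixture:
    """Generate the two-state bundle fixture with ground-truth tables.

    Both states share topology and residue numbering (identity residue
    map); the scaffold is identical in both.  Output is deterministic for
    a fixed ``spec.seed``.
    """
    spec = spec or BundleSpec()
    params = params or ENParams()
    rng = np.random.default_rng(spec.seed)
    mob_a = _mobile_coords(spec, "A")
    mob_b = _mobile_coords(spec, "B")
    if spec.scaffold:
        scaf, counts = _scaffold_coords(spec)
    else:
        scaf, counts = None, []
    if spec.noise_sigma > 0:
        mob_a = mob_a + rng.normal(0, spec.noise_sigma, mob_a.shape)
        mob_b = mob_b + rng.normal(0, spec.noise_sigma, mob_b.shape)
    state_a = _as_structure(spec, mob_a, scaf, counts, label="A")
    state_b = _as_structure(spec, mob_b, scaf, counts, label="B")
    rmap = map_residues(state_a, state_b, mode="identity")

    segments = []
    m = spec.residues_per_helix
    for h, tm in enumerate(spec.tm_ids):
        cid = string.ascii_uppercase[h % 26]
        segments.append(
            SegmentDef(tm_id=tm, side="in", chain_id=cid,
                       start=1, end=spec.segment_length)
        )
        segments.append(
            SegmentDef(tm_id=tm, side="out", chain_id=cid,
                       start=m - spec.segment_length + 1, end=m)
        )
    return BundleFixture(
        state_a=state_a,
        state_b=state_b,
        residue_map=rmap,
        segments=segments,
        truth_pairs_a=_eligible_pair_truth(state_a, state_b, params),
        truth_pairs_b=_eligible_pair_truth(state_b, state_a, params),
        truth_segments=_segment_truth(spec, state_a, state_b, segments),
        spec=spec,
    )


def interpolated_frames(
    state_a: BeadStructure,
    state_b: BeadStructure,
    n_frames: int = 11,
    noise_sigma: float = 0.0,
    seed: int = 0,
):
    """Linear interpolation A -> B (optionally with isotropic noise): a
    minimal stand-in for a transition trajectory."""
    from .order_params import Frameset

    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n_frames)[:, None, None]
    coords = (1 - t) * state_a.coords[None] + t * state_b.coords[None]
    if noise_sigma > 0:
        coords = coords + rng.normal(0, noise_sigma, coords.shape)
    return Frameset(structure=state_a, coords=coords)


def make_mutant_like_series(
    basin_centers: list[float],
    weights: list[float],
    sigma: float = 0.05,
    n: int = 2000,
    seed: int = 0,
    pair_label: str = "TM5/TM11(in)",
) -> DistanceSeries:
    """Gaussian-mixture distance series with known basin structure.

    A two-component mixture emulates wild-type-like sampling of both
    conformational basins; a single (or displaced) component emulates a
    mutant trapped in, or shifted to, one basin.  ``weights`` must sum
    to 1.
    """
    centers = np.asarray(basin_centers, float)
    w = np.asarray(weights, float)
    if len(centers) != len(w) or len(centers) == 0:
        raise ValueError("centers and weights must be non-empty and matched")
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(centers), size=n, p=w)
    values = rng.normal(centers[comp], sigma)
    if np.any(values <= 0):
        raise ValueError("mixture generated non-physical (<= 0) distances")
    return DistanceSeries(pair_label=pair_label, values=values)
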
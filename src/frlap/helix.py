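"""Helical chromophore lattice for FRL-AP nanotubes.

FRL-AP (the far-red-light allophycocyanin ApcD4-ApcB3) assembles as a
helical nanotube in which every (αβ) protomer carries two phycocyanobilin
(PCB) chromophores: a β-PCB lining the inside of the tube and an α-PCB on
an outer layer.  The helical symmetry is seven protomers per 720° repeat
rising 72.6 Å, i.e. a screw transform of 102.857° / 10.371 Å per protomer.

This module places one point-dipole site per PCB from those symmetry
parameters plus a small set of placement parameters (two cylinder radii and
the azimuthal/axial offset of the β site relative to the α site within a
protomer), and answers the distance/adjacency queries the Förster-rate
construction needs.  The default placement is calibrated (see
``scripts/calibrate_placement.py``) so that

* the closest chromophore pair is β(i)–α(i+1) of adjacent protomers at an
  edge-to-edge proxy distance of ~12 Å,
* the subunit contact topology matches the structure: each α-subunit
  touches the β of its own protomer, of the protomer before it, and of the
  protomer four prior (one helical level below),
* the single unpaired chromophore at each end of the tube sits ~35 Å from
  every other PCB.

Chromophores are treated as points; "edge-to-edge" distances are
approximated by centre distances minus a fixed bilin half-extent per
chromophore (default 4.5 Å each).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "HelicalParams",
    "PlacementParams",
    "ChromophoreSite",
    "ChromophoreLattice",
    "build_nanotube",
    "axial_span",
    "pairwise_distances",
    "edge_to_edge_distances",
    "contact_topology",
    "terminal_sites",
    "DEFAULT_HELIX",
    "DEFAULT_PLACEMENT",
    "DEFAULT_CONTACT_CUTOFF",
]

#: Contact cutoff (Å, centre-to-centre) separating the calibrated contact
#: shell (≤ ~34.4 Å) from the next-nearest shell (≥ ~35.8 Å).
DEFAULT_CONTACT_CUTOFF = 35.0


@dataclass(frozen=True)
class HelicalParams:
    """Helical symmetry: ``protomers_per_repeat`` protomers span
    ``degrees_per_repeat`` degrees over ``rise_per_repeat`` Å."""

    protomers_per_repeat: int = 7
    degrees_per_repeat: float = 720.0
    rise_per_repeat: float = 72.6
    handedness: str = "right"

    def __post_init__(self) -> None:
        if self.protomers_per_repeat < 1:
            raise ValueError("protomers_per_repeat must be >= 1")
        if self.rise_per_repeat <= 0:
            raise ValueError("rise_per_repeat must be > 0")
        if self.degrees_per_repeat == 0:
            raise ValueError("degrees_per_repeat must be nonzero")
        if self.handedness not in ("left", "right"):
            raise ValueError("handedness must be 'left' or 'right'")

    @property
    def twist_per_protomer_deg(self) -> float:
        return self.degrees_per_repeat / self.protomers_per_repeat

    @property
    def rise_per_protomer(self) -> float:
        return self.rise_per_repeat / self.protomers_per_repeat


@dataclass(frozen=True)
class PlacementParams:
    """Within-protomer chromophore placement.

    The α-PCB of protomer 0 defines the reference frame (azimuth
    ``alpha_offset_deg``, height ``alpha_offset_z``, default both 0); the
    β-PCB sits on the inner cylinder at the given azimuthal/axial offsets.

    Transition dipoles follow a declared geometric convention: each dipole
    is expressed in the site's local cylindrical frame (radial r̂,
    tangential t̂, axial ẑ) by a pitch angle out of the tangent plane
    toward ẑ and a tilt angle from t̂ toward r̂, per subunit class.
    Pitch = tilt = 0 puts the dipole tangent to the site's cylinder and
    perpendicular to the helix axis.
    """

    alpha_radius: float = 30.757
    beta_radius: float = 20.5
    alpha_offset_deg: float = 0.0
    alpha_offset_z: float = 0.0
    beta_offset_deg: float = 64.423
    beta_offset_z: float = 18.280
    alpha_pitch_deg: float = 4.0
    beta_pitch_deg: float = 150.0
    alpha_tilt_deg: float = 22.0
    beta_tilt_deg: float = 30.0
    bilin_half_extent: float = 4.5

    def __post_init__(self) -> None:
        if not self.beta_radius < self.alpha_radius:
            raise ValueError("beta_radius must be < alpha_radius "
                             "(β-PCBs line the inside of the tube)")
        if self.alpha_radius <= 0 or self.beta_radius <= 0:
            raise ValueError("radii must be positive")


DEFAULT_HELIX = HelicalParams()
DEFAULT_PLACEMENT = PlacementParams()


@dataclass(frozen=True)
class ChromophoreSite:
    site_id: int
    protomer_index: int
    subunit_class: str  # "alpha" | "beta"
    position: np.ndarray  # (3,) Å
    dipole: np.ndarray  # (3,) unit vector
    site_energy_label: str = ""


@dataclass
class ChromophoreLattice:
    """Ordered chromophore sites of an ``n_protomers``-long nanotube.

    Sites are ordered protomer-by-protomer, α before β, so
    ``site_id = 2*protomer + (0 if alpha else 1)``.
    """

    sites: list[ChromophoreSite]
    helix: HelicalParams
    placement: PlacementParams

    @property
    def n_protomers(self) -> int:
        return len(self.sites) // 2

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sites])

    @property
    def dipoles(self) -> np.ndarray:
        return np.array([s.dipole for s in self.sites])

    @property
    def classes(self) -> np.ndarray:
        return np.array([s.subunit_class for s in self.sites])

    def site(self, protomer: int, subunit_class: str) -> ChromophoreSite:
        return self.sites[2 * protomer + (0 if subunit_class == "alpha" else 1)]

    def alpha_indices(self) -> np.ndarray:
        return np.arange(0, len(self.sites), 2)

    def beta_indices(self) -> np.ndarray:
        return np.arange(1, len(self.sites), 2)


def _site_geometry(kind: str, protomer: int, helix: HelicalParams,
                   placement: PlacementParams) -> tuple[np.ndarray, np.ndarray]:
    hand = 1.0 if helix.handedness == "right" else -1.0
    if kind == "alpha":
        radius = placement.alpha_radius
        off_deg, off_z = placement.alpha_offset_deg, placement.alpha_offset_z
        pitch_deg, tilt_deg = placement.alpha_pitch_deg, placement.alpha_tilt_deg
    else:
        radius = placement.beta_radius
        off_deg, off_z = placement.beta_offset_deg, placement.beta_offset_z
        pitch_deg, tilt_deg = placement.beta_pitch_deg, placement.beta_tilt_deg
    theta = hand * np.deg2rad(protomer * helix.twist_per_protomer_deg + off_deg)
    z = protomer * helix.rise_per_protomer + off_z
    pos = np.array([radius * np.cos(theta), radius * np.sin(theta), z])
    # transition dipole in the local (radial, tangential, axial) frame
    pitch, tilt = np.deg2rad(pitch_deg), np.deg2rad(tilt_deg)
    radial = np.array([np.cos(theta), np.sin(theta), 0.0])
    tangent = hand * np.array([-np.sin(theta), np.cos(theta), 0.0])
    dipole = (np.cos(pitch) * np.cos(tilt) * tangent
              + np.cos(pitch) * np.sin(tilt) * radial
              + np.sin(pitch) * np.array([0.0, 0.0, 1.0]))
    return pos, dipole / np.linalg.norm(dipole)


def build_nanotube(helix: HelicalParams = DEFAULT_HELIX,
                   placement: PlacementParams = DEFAULT_PLACEMENT,
                   n_protomers: int = 13) -> ChromophoreLattice:
    """Generate the 2·``n_protomers``-site chromophore lattice.

    Protomer 0 sits at the configured reference position; each subsequent
    protomer is generated by the per-protomer screw transform.
    """
    if n_protomers < 1:
        raise ValueError("n_protomers must be >= 1")
    sites: list[ChromophoreSite] = []
    for p in range(n_protomers):
        for kind in ("alpha", "beta"):
            pos, dip = _site_geometry(kind, p, helix, placement)
            sites.append(ChromophoreSite(
                site_id=len(sites), protomer_index=p, subunit_class=kind,
                position=pos, dipole=dip, site_energy_label=kind))
    return ChromophoreLattice(sites=sites, helix=helix, placement=placement)


def axial_span(lattice: ChromophoreLattice, first: int, last: int) -> float:
    """Axial distance (Å) between two protomer reference points."""
    n = lattice.n_protomers
    if not (0 <= first <= last <= n):
        # ``last`` may equal n so that one full repeat (0, protomers_per_repeat)
        # can be queried on a single-repeat lattice.
        raise IndexError(f"protomer indices ({first}, {last}) out of range "
                         f"for {n} protomers")
    return (last - first) * lattice.helix.rise_per_protomer


def pairwise_distances(lattice: ChromophoreLattice) -> np.ndarray:
    """Symmetric centre-to-centre site distance table (Å)."""
    pos = lattice.positions
    if len(pos) < 2:
        raise ValueError("need at least 2 sites")
    diff = pos[:, None, :] - pos[None, :, :]
    return np.linalg.norm(diff, axis=-1)


def edge_to_edge_distances(lattice: ChromophoreLattice) -> np.ndarray:
    """Edge-to-edge proxy: centre distances minus one bilin half-extent per
    chromophore (diagonal kept at zero)."""
    d = pairwise_distances(lattice) - 2.0 * lattice.placement.bilin_half_extent
    np.fill_diagonal(d, 0.0)
    return d


def contact_topology(lattice: ChromophoreLattice,
                     cutoff: float = DEFAULT_CONTACT_CUTOFF,
                     ) -> dict[tuple[int, str], list[tuple[int, str]]]:
    """Per-subunit contact lists from the site distance table.

    Returns ``{(protomer, class): [(protomer_offset, class), ...]}`` sorted
    by offset.  With the calibrated placement and default cutoff, interior
    α-subunits contact β at offsets {0, −1, −4} and interior β-subunits
    contact β at {−1, +1} and α at {0, +1, +4}.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    dist = pairwise_distances(lattice)
    out: dict[tuple[int, str], list[tuple[int, str]]] = {}
    for s in lattice.sites:
        key = (s.protomer_index, s.subunit_class)
        partners = []
        for t_idx in np.nonzero(dist[s.site_id] <= cutoff)[0]:
            t = lattice.sites[int(t_idx)]
            if t.site_id == s.site_id:
                continue
            partners.append((t.protomer_index - s.protomer_index,
                             t.subunit_class))
        out[key] = sorted(partners)
    return out


def terminal_sites(lattice: ChromophoreLattice,
                   rel_tol: float = 0.05) -> list[ChromophoreSite]:
    """Sites whose nearest-other-site distance is (near-)maximal.

    Each nanotube end carries one unpaired chromophore — an α-PCB at one
    end and a β-PCB at the other — whose nearest neighbour is the ~35 Å
    intra-protomer/β–β shell instead of the ~21 Å close pair.  All sites
    within ``rel_tol`` of the maximal nearest-neighbour distance are
    returned (both sites of a single-protomer lattice tie).
    """
    dist = pairwise_distances(lattice)
    np.fill_diagonal(dist, np.inf)
    nearest = dist.min(axis=1)
    return [lattice.sites[i] for i in np.nonzero(
        nearest >= (1.0 - rel_tol) * nearest.max())[0]]


def mirrored(lattice: ChromophoreLattice) -> ChromophoreLattice:
    """Same lattice with opposite handedness (all azimuths negated)."""
    helix = replace(lattice.helix,
                    handedness="left" if lattice.helix.handedness == "right"
                    else "right")
    return build_nanotube(helix, lattice.placement, lattice.n_protomers)
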
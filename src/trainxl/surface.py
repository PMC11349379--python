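"""Solvent accessibility, state-specific burial and polymer geometry.

Two conformational states of the same polymer can present different
surfaces: a residue patch exposed in the extended state may be buried under
a neighbouring complex in the compact state.  This module computes
per-residue solvent-accessible surface area (SASA) in full-assembly
context, the accessible-in-one-state/buried-in-the-other differential, and
coarse polymer metrics (repeat length along the principal axis, IFTB:IFTA
stoichiometry, repeat-unit contact graph).

SASA uses the Shrake–Rupley construction: a deterministic Fibonacci point
lattice on each atom's solvent-expanded sphere, with points occluded by any
neighbouring expanded sphere removed.  It is exact in the limit of many
points and deterministic for a fixed point count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .core import AssemblyModel, ChainMap

# van der Waals radii (Å) by element; fallback 1.7 (carbon-like)
VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
             "P": 1.80, "SE": 1.90}
_DEFAULT_RADIUS = 1.70

# Theoretical maximum SASA (Å²) per residue, Tien et al.-style reference
# values for full-atom standard residues.  Residues not listed here (for
# instance coarse-grained bead residues) fall back to the SASA of the
# residue computed in isolation, which makes relative accessibility an
# exposure fraction.
MAX_SASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

REL_CAP = 1.2  # cap on reported relative accessibility


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def atom_radii(model: AssemblyModel) -> np.ndarray:
    return np.array([VDW_RADII.get(str(e).upper(), _DEFAULT_RADIUS)
                     for e in model.elements])


@dataclass
class AccessibilityProfile:
    """Per-residue SASA and relative accessibility for one state."""

    sasa: dict[tuple[str, int], float]
    relative: dict[tuple[str, int], float]
    state: str = ""


def atom_sasa(coords: np.ndarray, radii: np.ndarray,
              probe_radius: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Shrake–Rupley SASA per atom (Å²)."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n == 0:
        raise ValueError("cannot compute SASA of a zero-atom model")
    sphere = _fibonacci_sphere(n_points)
    expanded = radii + probe_radius
    tree = cKDTree(coords)
    out = np.empty(n)
    for i in range(n):
        r_i = expanded[i]
        neighbors = [j for j in tree.query_ball_point(coords[i], r_i + expanded.max())
                     if j != i]
        pts = coords[i] + r_i * sphere
        if neighbors:
            nb = np.array(neighbors)
            # point is buried if inside any neighbour's expanded sphere
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (expanded[nb] ** 2)[None, :]).any(axis=1)
            exposed = n_points - int(buried.sum())
        else:
            exposed = n_points
        out[i] = 4.0 * np.pi * r_i * r_i * exposed / n_points
    return out


def sasa(model: AssemblyModel, probe_radius: float = 1.4,
         n_points: int = 960, state: str = "") -> AccessibilityProfile:
    """Per-residue SASA in full-assembly context, plus relative accessibility.

    Relative accessibility divides by a reference maximum: a Tien-style
    table value for standard residues, otherwise the SASA of the residue
    computed in isolation.  Reported values are capped at 1.2.
    """
    per_atom = atom_sasa(model.coords, atom_radii(model), probe_radius,
                         n_points)
    groups: dict[tuple[str, int], list[int]] = {}
    for i, (c, r) in enumerate(zip(model.chain_ids, model.res_ids)):
        groups.setdefault((str(c), int(r)), []).append(i)
    radii = atom_radii(model)
    sasa_by_res: dict[tuple[str, int], float] = {}
    rel: dict[tuple[str, int], float] = {}
    for key, idx in groups.items():
        s = float(per_atom[idx].sum())
        sasa_by_res[key] = s
        res_name = str(model.res_names[idx[0]]).upper()
        ref = MAX_SASA.get(res_name)
        if ref is None:
            ref = float(atom_sasa(model.coords[idx], radii[idx],
                                  probe_radius, n_points).sum())
        rel[key] = min(REL_CAP, s / ref) if ref > 0 else 0.0
    return AccessibilityProfile(sasa=sasa_by_res, relative=rel, state=state)


# ---------------------------------------------------------------------------
# Burial differential
# ---------------------------------------------------------------------------

@dataclass
class BurialDifferential:
    """Residues accessible in one state but buried in the other.

    Residue keys are (protein, copy, author residue number); the two sets
    are disjoint by construction.
    """

    accessible_in_a: set[tuple[str, int, int]]
    accessible_in_b: set[tuple[str, int, int]]
    buried_cutoff: float
    accessible_cutoff: float

    def __post_init__(self) -> None:
        if self.accessible_in_a & self.accessible_in_b:
            raise ValueError("differential sets must be disjoint")


def _keyed_by_identity(profile: AccessibilityProfile,
                       chainmap: ChainMap | None
                       ) -> dict[tuple[str, int, int], float]:
    out = {}
    for (chain, res), rel in profile.relative.items():
        if chainmap is None:
            out[(chain, 0, res)] = rel
        elif chain in chainmap.entries:
            e = chainmap.entries[chain]
            out[(e.protein, e.copy, res)] = rel
    return out


def burial_differential(profile_a: AccessibilityProfile,
                        profile_b: AccessibilityProfile,
                        chainmap_a: ChainMap | None = None,
                        chainmap_b: ChainMap | None = None,
                        buried_cutoff: float = 0.10,
                        accessible_cutoff: float = 0.25
                        ) -> BurialDifferential:
    """State-specific accessibility differential.

    A residue joins ``accessible_in_a`` iff its relative accessibility is
    >= ``accessible_cutoff`` in state A and < ``buried_cutoff`` in state B
    (and conversely for ``accessible_in_b``).  Residues are matched across
    states by (protein, copy, author residue number); with no chain maps
    given, by chain identifier.  Exactly antisymmetric under state swap.
    """
    if buried_cutoff > accessible_cutoff:
        raise ValueError("buried cutoff must not exceed accessible cutoff")
    rel_a = _keyed_by_identity(profile_a, chainmap_a)
    rel_b = _keyed_by_identity(profile_b, chainmap_b)
    common = rel_a.keys() & rel_b.keys()
    if not common:
        raise ValueError("no residues matched between the two states")
    acc_a = {k for k in common
             if rel_a[k] >= accessible_cutoff and rel_b[k] < buried_cutoff}
    acc_b = {k for k in common
             if rel_b[k] >= accessible_cutoff and rel_a[k] < buried_cutoff}
    return BurialDifferential(acc_a, acc_b, buried_cutoff, accessible_cutoff)


# ---------------------------------------------------------------------------
# Patch clustering and contact graph
# ---------------------------------------------------------------------------

def patch_cluster(residues: Sequence[tuple[str, int]], model: AssemblyModel,
                  linkage_cutoff: float = 6.0) -> list[list[tuple[str, int]]]:
    """Single-linkage spatial clustering of residues into surface patches.

    Residues are given as (chain, author number); two residues link when
    their minimal heavy-atom distance is below the cutoff.  Patches are
    returned sorted by residue count, largest first.
    """
    residues = list(residues)
    if not residues:
        raise ValueError("residue set must be non-empty")
    groups: dict[tuple[str, int], list[int]] = {}
    for i, (c, r) in enumerate(zip(model.chain_ids, model.res_ids)):
        groups.setdefault((str(c), int(r)), []).append(i)
    heavy = model.elements != "H"
    atom_idx = []
    owner = []
    for k, key in enumerate(residues):
        for i in groups.get(key, []):
            if heavy[i]:
                atom_idx.append(i)
                owner.append(k)
    if not atom_idx:
        raise ValueError("no heavy atoms found for the residue set")
    coords = model.coords[atom_idx]
    owner = np.array(owner)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(linkage_cutoff, output_type="ndarray")
    n = len(residues)
    if len(pairs):
        ri, rj = owner[pairs[:, 0]], owner[pairs[:, 1]]
        adj = coo_matrix((np.ones(len(ri)), (ri, rj)), shape=(n, n))
    else:
        adj = coo_matrix((n, n))
    n_comp, labels = connected_components(adj, directed=False)
    patches: list[list[tuple[str, int]]] = [[] for _ in range(n_comp)]
    for k, lab in enumerate(labels):
        patches[lab].append(residues[k])
    patches.sort(key=len, reverse=True)
    return patches


def contact_graph(model: AssemblyModel, units: Mapping[str, int],
                  contact_cutoff: float = 5.0
                  ) -> tuple[dict[int, set[int]], dict[int, int]]:
    """Repeat-unit adjacency: units touch when any heavy-atom pair is close.

    ``units`` maps chain identifiers to repeat-unit labels.  Returns the
    adjacency (unit -> set of contacting units) and the degree per unit.
    Fewer than two units yields an empty graph.
    """
    unit_labels = sorted(set(units.values()))
    adjacency: dict[int, set[int]] = {u: set() for u in unit_labels}
    if len(unit_labels) < 2:
        return adjacency, {u: 0 for u in unit_labels}
    heavy = model.elements != "H"
    atom_unit = np.array([units.get(str(c), -1) for c in model.chain_ids])
    keep = heavy & (atom_unit >= 0)
    coords = model.coords[keep]
    atom_unit = atom_unit[keep]
    tree = cKDTree(coords)
    pairs = tree.query_pairs(contact_cutoff, output_type="ndarray")
    if len(pairs):
        ui, uj = atom_unit[pairs[:, 0]], atom_unit[pairs[:, 1]]
        for a, b in set(map(tuple, np.column_stack([ui, uj]))):
            if a != b:
                adjacency[int(a)].add(int(b))
                adjacency[int(b)].add(int(a))
    degrees = {u: len(v) for u, v in adjacency.items()}
    return adjacency, degrees


# ---------------------------------------------------------------------------
# Train-level metrics
# ---------------------------------------------------------------------------

@dataclass
class TrainMetrics:
    stoichiometry: float       # IFTB complexes per IFTA complex
    repeat_length: float       # Å between consecutive repeat anchors
    axial_extent: float        # Å, full extent along the polymer axis
    n_units: int
    axis: np.ndarray = field(repr=False, default_factory=lambda: np.zeros(3))


def principal_axis(model: AssemblyModel) -> np.ndarray:
    """First principal component of the Cα coordinates (unit vector)."""
    ca = model.atom_names == "CA"
    coords = model.coords[ca] if ca.any() else model.coords
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    return axis if axis[np.argmax(np.abs(axis))] >= 0 else -axis


def train_metrics(model: AssemblyModel, chainmap: ChainMap) -> TrainMetrics:
    """Polymer stoichiometry and repeat geometry along the principal axis.

    One repeating unit is anchored by one IFTA complex; the repeat length
    is the mean spacing of IFTA1 chain centroids projected on the principal
    axis.  Stoichiometry counts IFTB subcomplex instances against IFTA
    subcomplex instances (a complex contributes one instance of each of its
    two subcomplexes).
    """
    labels = [e.subcomplex for e in chainmap.entries.values()]
    n_a = (labels.count("IFTA1") + labels.count("IFTA2")) / 2.0
    n_b = (labels.count("IFTB1") + labels.count("IFTB2")) / 2.0
    if n_a == 0:
        raise ValueError("chain map carries no IFTA subcomplex labels")
    axis = principal_axis(model)
    proj = model.coords @ axis
    extent = float(proj.max() - proj.min())
    anchors = []
    for chain, entry in chainmap.entries.items():
        if entry.subcomplex == "IFTA1":
            mask = model.chain_mask(chain)
            if mask.any():
                anchors.append(float((model.coords[mask] @ axis).mean()))
    anchors.sort()
    n_units = len(anchors)
    if n_units >= 2:
        repeat = float((anchors[-1] - anchors[0]) / (n_units - 1))
    else:
        repeat = extent
    return TrainMetrics(stoichiometry=n_b / n_a, repeat_length=repeat,
                        axial_extent=extent, n_units=n_units, axis=axis)
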
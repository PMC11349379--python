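"""Synthetic two-state polymer assemblies with known ground truth.

The generator emulates the geometry of IFT trains at coarse-grained,
Cα-bead level so that every pipeline stage can be exercised against a
planted truth:

* **State A** ("anterograde-like"): two stacked sub-polymers with distinct
  repeat distances, 115 Å for the IFTA row and 65 Å for the IFTB row,
  built from compact pseudo-domains.
* **State B** ("retrograde-like"): an extended polymer whose repeating
  units (one IFTA complex + two IFTB complexes, a 2:1 IFTB:IFTA
  stoichiometry) alternate orientation along the axis, giving exact 2-fold
  rotational symmetry perpendicular to the polymer axis.  The visible
  repeat (default 450 Å) spans a configurable number of units (default 2),
  so consecutive units sit 225 Å apart.  A continuous central thread links
  consecutive units and peripheral arms bridge second neighbours, so an
  interior unit touches four surrounding units.

Both states share chain naming, protein identities and residue numbering;
the conformational change is encoded purely in coordinates.  Planted
cross-links carry constructed (not sampled) distances: the truth table is
computed from the emitted coordinates by brute-force enumeration over all
protein copies, independently of the validation stage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np

from .core import AssemblyModel, ChainInfo, ChainMap, CrossLinkRecord
from .fitting import Pose, simulate_density
from .surface import sasa

CONFIDENT_PLDDT = 90.0
FLEXIBLE_PLDDT = 30.0

# protein names per subcomplex (one representative protein per chain)
PROTEINS = {"IFTA1": "IFT144", "IFTA2": "IFT139",
            "IFTB1": "IFT88", "IFTB2": "IFT172"}

BEAD_RES_NAME = "UNK"
BEAD_STEP = 4.0  # Å between consecutive beads on thread-like domains


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the two-state generator.

    ``spacing_a`` is the (IFTA, IFTB) repeat pair of the stacked state;
    ``visible_repeat_b`` over ``units_per_visible_repeat`` sets the unit
    spacing of the extended state.  Cross-links are planted to hit the
    target satisfied fraction per state at the 35 Å criterion, with every
    planted distance at least ``margin`` Å away from the threshold.

    With alternating unit orientation the extended state has an exact
    two-fold axis between the two central units only when ``n_units`` is
    even; odd unit counts are allowed (e.g. for contact-graph studies) but
    then ``c2_rmsd`` will not vanish.
    """

    n_units: int = 4
    atoms_per_domain: int = 30
    spacing_a: tuple[float, float] = (115.0, 65.0)
    visible_repeat_b: float = 450.0
    units_per_visible_repeat: int = 2
    n_crosslinks: int = 48
    satisfied_fraction_a: float = 0.75
    satisfied_fraction_b: float = 0.90
    threshold: float = 35.0
    margin: float = 5.0
    flexible_fraction: float = 0.15
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("need at least one repeating unit")
        if min(self.spacing_a) <= 0 or self.visible_repeat_b <= 0:
            raise ValueError("spacings must be positive")
        for f in (self.satisfied_fraction_a, self.satisfied_fraction_b):
            if not 0.0 <= f <= 1.0:
                raise ValueError("satisfied fractions must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")

    @property
    def spacing_b(self) -> float:
        return self.visible_repeat_b / self.units_per_visible_repeat


@dataclass
class TruthRow:
    """Planted classification of one cross-link in both states."""

    record: CrossLinkRecord
    distance_a: float
    distance_b: float
    satisfied_a: bool
    satisfied_b: bool

    def to_dict(self) -> dict:
        return {"protein1": self.record.protein_a,
                "residue1": self.record.residue_a,
                "protein2": self.record.protein_b,
                "residue2": self.record.residue_b,
                "distance_a": round(float(self.distance_a), 6),
                "distance_b": round(float(self.distance_b), 6),
                "satisfied_a": bool(self.satisfied_a),
                "satisfied_b": bool(self.satisfied_b)}


@dataclass
class TwoStateResult:
    model_a: AssemblyModel
    model_b: AssemblyModel
    chainmap: ChainMap
    crosslinks: list[CrossLinkRecord]
    truth: list[TruthRow]
    units: dict[str, int]                 # chain -> repeat-unit index
    c2_pairing: dict[str, str]            # chain -> C2 image chain (state B)
    spec: SyntheticSpec


# ---------------------------------------------------------------------------
# Domain primitives
# ---------------------------------------------------------------------------

def _thread(start: np.ndarray, end: np.ndarray, step: float = BEAD_STEP
            ) -> np.ndarray:
    """Straight bead string from start to end (inclusive), ~step spacing."""
    start, end = np.asarray(start, float), np.asarray(end, float)
    n = max(2, int(np.round(np.linalg.norm(end - start) / step)) + 1)
    return start + np.linspace(0.0, 1.0, n)[:, None] * (end - start)

def _coil(center: np.ndarray, radius: float, n: int,
          rng: np.random.Generator, step: float = 3.8) -> np.ndarray:
    """Compact random coil: a reflected random walk inside a sphere."""
    center = np.asarray(center, float)
    pos = np.zeros(3)
    out = [pos.copy()]
    for _ in range(n - 1):
        d = rng.normal(size=3)
        d *= step / np.linalg.norm(d)
        nxt = pos + d
        r = np.linalg.norm(nxt)
        if r > radius:
            nxt *= (2 * radius - r) / r  # reflect at the sphere boundary
        pos = nxt
        out.append(pos.copy())
    return np.asarray(out) + center


def _rz180(coords: np.ndarray) -> np.ndarray:
    """Two-fold rotation about the z axis through the origin."""
    out = coords.copy()
    out[:, 0] *= -1.0
    out[:, 1] *= -1.0
    return out


# ---------------------------------------------------------------------------
# Unit templates
# ---------------------------------------------------------------------------

def _unit_template_b(spec: SyntheticSpec,
                     rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Local chain coordinates of one extended-state repeating unit.

    The IFTA1 chain is a central thread overhanging the unit cell so that
    consecutive (orientation-flipped) units interlock; the two IFTB1 arms
    reach one full unit spacing to either side so that same-orientation
    second neighbours touch.  IFTA2/IFTB2 are compact decorating coils.
    """
    s = spec.spacing_b
    ov = 12.0  # thread overhang past the half cell
    n = spec.atoms_per_domain
    return {
        "A1": _thread([-s / 2 - ov, 2.0, 0.0], [s / 2 + ov, 2.0, 0.0]),
        "A2": _coil([0.0, 12.0, 8.0], 8.0, n, rng),
        "B1a": _thread([-s - 14.0, -10.0, -2.0], [-s / 2 + 20.0, -10.0, -2.0]),
        "B1b": _thread([s / 2 - 20.0, -10.0, 2.0], [s + 14.0, -10.0, 2.0]),
        "B2a": _coil([-s / 2, -22.0, 0.0], 8.0, n, rng),
        "B2b": _coil([s / 2, -22.0, 4.0], 8.0, n, rng),
    }


def _unit_conformation_a(spec: SyntheticSpec, sizes: dict[str, int],
                         rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Local chain coordinates in the compact stacked state.

    Every chain keeps its bead count from the extended state (same
    residues, different conformation): threads collapse into compact
    coils, mirroring the global rearrangement between the two polymer
    forms.
    """
    centers = {"A1": [0.0, 45.0, 0.0], "A2": [0.0, 62.0, 6.0],
               "B1a": [-32.0, 0.0, 0.0], "B1b": [32.0, 0.0, 0.0],
               "B2a": [-32.0, -18.0, 0.0], "B2b": [32.0, -18.0, 4.0]}
    return {key: _coil(centers[key], 11.0, sizes[key], rng)
            for key in sizes}


_CHAIN_KINDS = {"A1": ("IFTA1", 1), "A2": ("IFTA2", 1),
                "B1a": ("IFTB1", 2), "B1b": ("IFTB1", 2),
                "B2a": ("IFTB2", 2), "B2b": ("IFTB2", 2)}


def _chain_id(kind: str, unit: int) -> str:
    return f"{kind}u{unit}"


# ---------------------------------------------------------------------------
# Two-state generation
# ---------------------------------------------------------------------------

def _build_model(chain_coords: dict[str, np.ndarray],
                 confidences: dict[str, np.ndarray],
                 source: str) -> AssemblyModel:
    chain_ids, res_ids, bf, coords = [], [], [], []
    for cid, xyz in chain_coords.items():
        chain_ids.extend([cid] * len(xyz))
        res_ids.extend(range(1, len(xyz) + 1))
        bf.extend(confidences[cid])
        coords.append(xyz)
    n = len(chain_ids)
    return AssemblyModel(
        chain_ids=np.array(chain_ids, dtype=object),
        res_ids=np.array(res_ids),
        res_names=np.array([BEAD_RES_NAME] * n, dtype=object),
        atom_names=np.array(["CA"] * n, dtype=object),
        elements=np.array(["C"] * n, dtype=object),
        coords=np.concatenate(coords),
        b_factors=np.array(bf),
        source=source,
    )


def generate_two_state(spec: SyntheticSpec) -> TwoStateResult:
    """Generate the paired compact/extended models with planted truth.

    Raises ``ValueError`` with a diagnostic when the requested satisfied
    fractions cannot be realized jointly from the lattice geometry.
    """
    rng = np.random.default_rng(spec.seed)
    template_b = _unit_template_b(spec, rng)
    sizes = {k: len(v) for k, v in template_b.items()}
    template_a = _unit_conformation_a(spec, sizes, rng)

    n = spec.n_units
    coords_a: dict[str, np.ndarray] = {}
    coords_b: dict[str, np.ndarray] = {}
    units: dict[str, int] = {}
    chainmap_entries: dict[str, ChainInfo] = {}
    copy_counter: dict[str, int] = {}

    for u in range(n):
        x_b = (u - (n - 1) / 2.0) * spec.spacing_b
        parity = u % 2
        for kind, (sub, _) in _CHAIN_KINDS.items():
            cid = _chain_id(kind, u)
            units[cid] = u
            protein = PROTEINS[sub]
            copy = copy_counter.get(protein, 0)
            copy_counter[protein] = copy + 1
            chainmap_entries[cid] = ChainInfo(protein=protein, copy=copy,
                                              subcomplex=sub)
            # state B: alternate unit orientation -> exact C2 of the polymer
            local_b = template_b[kind]
            placed_b = _rz180(local_b) if parity else local_b.copy()
            placed_b[:, 0] += x_b
            coords_b[cid] = placed_b
            # state A: stacked rows, IFTA repeat and IFTB repeat differ
            local_a = template_a[kind].copy()
            if kind.startswith("A"):
                local_a[:, 0] += u * spec.spacing_a[0]
            else:
                m = 2 * u + (0 if kind.endswith("a") else 1)
                local_a[:, 0] = (template_a[kind][:, 0]
                                 - template_a[kind][:, 0].mean()
                                 + m * spec.spacing_a[1])
            coords_a[cid] = local_a
    chainmap = ChainMap(entries=chainmap_entries)

    # confidence: mostly confident, one contiguous flexible segment per chain
    confidences: dict[str, np.ndarray] = {}
    for cid, size in ((c, len(coords_b[c])) for c in coords_b):
        conf = np.full(size, CONFIDENT_PLDDT)
        n_flex = int(round(spec.flexible_fraction * size))
        if n_flex > 0:
            start = int(rng.integers(0, size - n_flex + 1))
            conf[start:start + n_flex] = FLEXIBLE_PLDDT
        confidences[cid] = conf

    model_a = _build_model(coords_a, confidences, source="synthetic:state_a")
    model_b = _build_model(coords_b, confidences, source="synthetic:state_b")

    crosslinks, truth = _plant_crosslinks(spec, model_a, model_b, chainmap,
                                          rng)

    if spec.noise_sd > 0:
        model_a = replace(model_a, coords=model_a.coords + rng.normal(
            0.0, spec.noise_sd, model_a.coords.shape))
        model_b = replace(model_b, coords=model_b.coords + rng.normal(
            0.0, spec.noise_sd, model_b.coords.shape))

    pairing = {_chain_id(kind, u): _chain_id(kind, n - 1 - u)
               for u in range(n) for kind in _CHAIN_KINDS}
    return TwoStateResult(model_a=model_a, model_b=model_b,
                          chainmap=chainmap, crosslinks=crosslinks,
                          truth=truth, units=units, c2_pairing=pairing,
                          spec=spec)


def brute_force_min_distance(model: AssemblyModel, chainmap: ChainMap,
                             record: CrossLinkRecord) -> float:
    """Exhaustive minimum Cα–Cα distance over all copy-pair combinations.

    Ground-truth oracle kept independent of the validation stage: plain
    nested loops over every site pair, excluding the self pairing when
    both endpoints name the same residue of the same protein.
    """
    ca = model.ca_index()
    same = (record.protein_a.strip().casefold()
            == record.protein_b.strip().casefold()
            and record.residue_a == record.residue_b)
    best = np.inf
    for chain_a in chainmap.chains_for_protein(record.protein_a):
        ia = ca.get((chain_a, record.residue_a))
        if ia is None:
            continue
        for chain_b in chainmap.chains_for_protein(record.protein_b):
            if same and chain_a == chain_b:
                continue
            ib = ca.get((chain_b, record.residue_b))
            if ib is None:
                continue
            d = float(np.linalg.norm(model.coords[ia] - model.coords[ib]))
            best = min(best, d)
    return best


def _plant_crosslinks(spec: SyntheticSpec, model_a: AssemblyModel,
                      model_b: AssemblyModel, chainmap: ChainMap,
                      rng: np.random.Generator
                      ) -> tuple[list[CrossLinkRecord], list[TruthRow]]:
    """Select residue pairs whose constructed distances meet the targets.

    Candidates are sampled, their true min-over-copies distances computed
    in both states, margin-filtered, binned by their (state A, state B)
    satisfaction pattern, and drawn to meet both per-state satisfied
    fractions exactly.
    """
    n = spec.n_crosslinks
    k_a = int(round(spec.satisfied_fraction_a * n))
    k_b = int(round(spec.satisfied_fraction_b * n))

    keys = model_b.residue_keys()
    by_chain: dict[str, list[int]] = {}
    for chain, res in keys:
        by_chain.setdefault(chain, []).append(res)
    chains = sorted(by_chain)

    bins: dict[tuple[bool, bool], list[TruthRow]] = {
        (True, True): [], (True, False): [], (False, True): [],
        (False, False): []}
    seen: set[tuple[str, int, str, int]] = set()
    n_candidates = 60 * n
    for _ in range(n_candidates):
        if rng.random() < 0.5:  # intra-chain pair biases toward short links
            chain_a = chain_b = chains[rng.integers(len(chains))]
        else:
            chain_a = chains[rng.integers(len(chains))]
            chain_b = chains[rng.integers(len(chains))]
        res_a = int(rng.choice(by_chain[chain_a]))
        res_b = int(rng.choice(by_chain[chain_b]))
        prot_a = chainmap.entries[chain_a].protein
        prot_b = chainmap.entries[chain_b].protein
        if (prot_a, res_a) == (prot_b, res_b):
            continue
        key = tuple(sorted([(prot_a, res_a), (prot_b, res_b)]))
        flat = (key[0][0], key[0][1], key[1][0], key[1][1])
        if flat in seen:
            continue
        seen.add(flat)
        record = CrossLinkRecord(prot_a, res_a, prot_b, res_b)
        d_a = brute_force_min_distance(model_a, chainmap, record)
        d_b = brute_force_min_distance(model_b, chainmap, record)
        if not (np.isfinite(d_a) and np.isfinite(d_b)):
            continue
        if (abs(d_a - spec.threshold) < spec.margin
                or abs(d_b - spec.threshold) < spec.margin):
            continue
        sat_a, sat_b = d_a < spec.threshold, d_b < spec.threshold
        bins[(sat_a, sat_b)].append(TruthRow(record, d_a, d_b, sat_a, sat_b))

    # solve the two marginals over the four satisfaction-pattern bins
    chosen: list[TruthRow] | None = None
    lo = max(0, k_a + k_b - n)
    hi = min(k_a, k_b)
    for n_ss in range(hi, lo - 1, -1):
        n_sv = k_a - n_ss          # satisfied in A only
        n_vs = k_b - n_ss          # satisfied in B only
        n_vv = n - n_ss - n_sv - n_vs
        need = {(True, True): n_ss, (True, False): n_sv,
                (False, True): n_vs, (False, False): n_vv}
        if all(len(bins[k]) >= v for k, v in need.items()):
            chosen = []
            for k, v in need.items():
                chosen.extend(bins[k][:v])
            break
    if chosen is None:
        avail = {k: len(v) for k, v in bins.items()}
        raise ValueError(
            "cannot realize satisfied fractions "
            f"A={spec.satisfied_fraction_a} B={spec.satisfied_fraction_b} "
            f"with {n} links given candidate pools {avail}; the lattice "
            "geometry does not produce enough links of the required kind")
    order = rng.permutation(len(chosen))
    chosen = [chosen[i] for i in order]
    return [row.record for row in chosen], chosen


def c2_rmsd(model_b: AssemblyModel, pairing: dict[str, str]) -> float:
    """RMSD between the C2-rotated extended state and its chain-permuted self.

    The two-fold operator is a 180° rotation about the z axis through the
    assembly centre (the generator builds state B centred on the origin).
    """
    rotated = _rz180(model_b.coords)
    index: dict[tuple[str, int], int] = {}
    for i, (c, r) in enumerate(zip(model_b.chain_ids, model_b.res_ids)):
        index[(str(c), int(r))] = i
    sq = 0.0
    for i, (c, r) in enumerate(zip(model_b.chain_ids, model_b.res_ids)):
        j = index[(pairing[str(c)], int(r))]
        sq += float(((rotated[i] - model_b.coords[j]) ** 2).sum())
    return float(np.sqrt(sq / model_b.n_atoms))


# ---------------------------------------------------------------------------
# Occlusion planting
# ---------------------------------------------------------------------------

_FACES = {"+x": np.array([1.0, 0, 0]), "-x": np.array([-1.0, 0, 0]),
          "+y": np.array([0, 1.0, 0]), "-y": np.array([0, -1.0, 0]),
          "+z": np.array([0, 0, 1.0]), "-z": np.array([0, 0, -1.0])}

BLOCK_CHAIN = "BLOCK"


@dataclass
class OcclusionResult:
    model: AssemblyModel                   # original plus blocking domain
    occluded: list[tuple[str, int]]        # (chain, residue) planted list


def plant_occlusion(model: AssemblyModel, face: str,
                    accessible_cutoff: float = 0.25,
                    depth: float = 4.0, offset: float = 1.0,
                    n_directions: int = 64,
                    dedupe_step: float = 1.2,
                    clash_distance: float = 2.6,
                    probe_radius: float = 1.4,
                    n_points: int = 960) -> OcclusionResult:
    """Mold a blocking pseudo-domain over one face of the assembly.

    The selected face is the set of solvent-exposed residues whose Cα
    projection along the face normal lies within ``depth`` Å of the
    assembly's extremum.  The blocking domain is built at contact
    distance: for every exposed direction of a selected residue (found
    with the same Fibonacci-sphere construction the SASA stage uses), a
    block bead is placed ``offset`` Å beyond the solvent-accessible
    surface, so the domain wraps the face the way a docked binding
    partner would and genuinely buries the residues underneath it.  The
    returned occluded list is that set of face residues -- the geometric
    shadow of the planted domain.  Raises when the face selector is
    unknown or selects nothing.
    """
    from .surface import _fibonacci_sphere, atom_radii

    if face not in _FACES:
        raise ValueError(f"unknown face selector {face!r}; "
                         f"use one of {sorted(_FACES)}")
    normal = _FACES[face]
    profile = sasa(model, probe_radius=probe_radius, n_points=n_points)
    ca = model.ca_index()
    proj_atoms = model.coords @ normal
    top = proj_atoms.max()
    candidates = []
    for (chain, res), rel in profile.relative.items():
        if chain == BLOCK_CHAIN or rel < accessible_cutoff:
            continue
        idx = ca.get((chain, res))
        if idx is None:
            continue
        if proj_atoms[idx] >= top - depth:
            candidates.append((chain, res, idx))
    if not candidates:
        raise ValueError(f"face {face!r} selects no exposed residues")

    radii = atom_radii(model)
    expanded = radii + probe_radius
    from scipy.spatial import cKDTree
    tree = cKDTree(model.coords)
    dirs = _fibonacci_sphere(n_directions)
    raw: list[np.ndarray] = []
    for _, _, idx in candidates:
        r_i = expanded[idx]
        pts = model.coords[idx] + r_i * dirs
        neighbors = [j for j in tree.query_ball_point(
            model.coords[idx], r_i + expanded.max()) if j != idx]
        if neighbors:
            nb = np.array(neighbors)
            d2 = ((pts[:, None, :] - model.coords[nb][None, :, :]) ** 2
                  ).sum(axis=2)
            exposed_mask = ~(d2 < (expanded[nb] ** 2)[None, :]).any(axis=1)
        else:
            exposed_mask = np.ones(len(pts), dtype=bool)
        scale = (r_i + offset) / r_i
        raw.extend(model.coords[idx] + scale * r_i * dirs[exposed_mask])
    if not raw:
        raise ValueError(f"face {face!r} residues have no exposed surface")
    block = np.asarray(raw)
    # deduplicate on a coarse grid, then drop beads clashing with the model
    cells = np.round(block / dedupe_step).astype(int)
    _, keep = np.unique(cells, axis=0, return_index=True)
    block = block[np.sort(keep)]
    dist, _ = tree.query(block, k=1)
    block = block[dist >= clash_distance]

    n_block = len(block)
    blocked = AssemblyModel(
        chain_ids=np.array([BLOCK_CHAIN] * n_block, dtype=object),
        res_ids=np.arange(1, n_block + 1),
        res_names=np.array([BEAD_RES_NAME] * n_block, dtype=object),
        atom_names=np.array(["CA"] * n_block, dtype=object),
        elements=np.array(["C"] * n_block, dtype=object),
        coords=block,
        b_factors=np.full(n_block, CONFIDENT_PLDDT),
        source="synthetic:block",
    )
    combined = AssemblyModel.concat([model, blocked])
    occluded = [(chain, res) for chain, res, _ in candidates]
    return OcclusionResult(model=combined, occluded=occluded)


# ---------------------------------------------------------------------------
# Rigid-fit cases
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitCaseSpec:
    """Parameters for planted rigid-body fitting problems."""

    n_bodies: int = 3
    atoms_per_body: int = 28
    resolution: float = 18.0
    voxel: float = 4.0
    n_crosslinks: int = 2
    crosslink_max: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution < 2 * self.voxel:
            raise ValueError("resolution must be at least twice the voxel")


@dataclass
class FitCase:
    bodies: list[AssemblyModel]            # centred, canonical orientation
    planted_poses: list[Pose]
    grid: object                           # DensityGrid of the planted layout
    crosslinks: list[CrossLinkRecord]
    chainmap: ChainMap
    spec: FitCaseSpec


def _body_shape(kind: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """Distinct chiral anisotropic bead shapes.

    Orientation recovery from a 15–30 Å map requires bodies without
    (approximate) internal symmetry: each shape is a corner of unequal
    arms or a one-handed helix, so no flip or mirror reproduces its
    density.
    """
    s = BEAD_STEP
    if kind % 3 == 0:      # three unequal orthogonal arms from one corner
        n1, n2 = n // 2, n // 3
        arms = [_thread([0, 0, 0], [n1 * s, 0, 0], s),
                _thread([0, 0, 0], [0, n2 * s, 0], s),
                _thread([0, 0, 0], [0, 0, (n - n1 - n2) * s], s)]
        pts = np.concatenate(arms)[:n]
    elif kind % 3 == 1:    # bent rod with a short out-of-plane hook
        n1, n2 = (2 * n) // 3, n // 4
        arms = [_thread([0, 0, 0], [n1 * s, 0, 0], s),
                _thread([n1 * s, 0, 0], [n1 * s, n2 * s, 0], s),
                _thread([n1 * s, n2 * s, 0],
                        [n1 * s, n2 * s, (n - n1 - n2) * s], s)]
        pts = np.concatenate(arms)[:n]
    else:                  # one-handed conical spiral (no dyad axis)
        t = np.linspace(0.0, 2.4 * np.pi, n)
        radius = 12.0 - 7.0 * t / t.max()  # taper breaks the helix dyad
        pitch = 18.0
        pts = np.column_stack([radius * np.cos(t), radius * np.sin(t),
                               pitch * t / (2 * np.pi)])
    pts = pts + rng.normal(0.0, 0.4, pts.shape)
    return pts - pts.mean(axis=0)


def generate_fit_case(spec: FitCaseSpec) -> FitCase:
    """Planted multi-body fitting problem with a simulated map.

    Bodies are returned unposed (centred at the origin); the map is
    simulated from the planted configuration at the requested resolution;
    inter-body cross-links are drawn from bead pairs proximal in the
    planted layout.
    """
    rng = np.random.default_rng(spec.seed)
    from scipy.spatial.transform import Rotation

    bodies, posed, poses = [], [], []
    entries: dict[str, ChainInfo] = {}
    gap = 16.0  # clearance between consecutive bodies along the packing axis
    next_free_x = 0.0
    for k in range(spec.n_bodies):
        cid = f"R{k}"
        coords = _body_shape(k, spec.atoms_per_body, rng)
        nb = len(coords)
        body = AssemblyModel(
            chain_ids=np.array([cid] * nb, dtype=object),
            res_ids=np.arange(1, nb + 1),
            res_names=np.array([BEAD_RES_NAME] * nb, dtype=object),
            atom_names=np.array(["CA"] * nb, dtype=object),
            elements=np.array(["C"] * nb, dtype=object),
            coords=coords,
            b_factors=np.full(nb, CONFIDENT_PLDDT),
            source=f"synthetic:body{k}",
        )
        rot = Rotation.random(random_state=np.random.RandomState(
            int(rng.integers(2 ** 31)))).as_matrix()
        rotated = (coords - coords.mean(axis=0)) @ rot.T
        # pack bodies along x with a fixed clearance: each subcomplex then
        # owns a distinct density region, as deposited subcomplexes do,
        # while staying close enough for interface cross-links
        shift_x = next_free_x - rotated[:, 0].min() if k else 0.0
        offset = np.array([shift_x, rng.uniform(-6.0, 6.0),
                           rng.uniform(-6.0, 6.0)])
        next_free_x = (rotated[:, 0] + offset[0]).max() + gap
        pose = Pose(rot, offset, body_id=cid)
        bodies.append(body)
        poses.append(pose)
        posed.append(body.transformed(np.eye(3), -body.coords.mean(axis=0))
                     .transformed(pose.rotation, pose.translation))
        entries[cid] = ChainInfo(protein=f"BODY{k}", copy=0)
    chainmap = ChainMap(entries=entries)
    combined = AssemblyModel.concat(posed)
    grid = simulate_density(combined, spec.resolution, spec.voxel,
                            padding=spec.resolution)

    crosslinks: list[CrossLinkRecord] = []
    if spec.n_bodies > 1 and spec.n_crosslinks > 0:
        # prefer peripheral bead pairs (far from both body centroids): a
        # cross-link at an arm tip pins orientation, one near the centroid
        # does not; cycle over body pairs so every interface is restrained
        by_pair: dict[tuple[int, int], list[tuple[float, int, int]]] = {}
        for i in range(spec.n_bodies):
            for j in range(i + 1, spec.n_bodies):
                di = posed[i].coords[:, None, :] - posed[j].coords[None, :, :]
                dist = np.sqrt((di ** 2).sum(axis=2))
                ci = np.linalg.norm(posed[i].coords
                                    - posed[i].coords.mean(axis=0), axis=1)
                cj = np.linalg.norm(posed[j].coords
                                    - posed[j].coords.mean(axis=0), axis=1)
                ii, jj = np.nonzero(dist < spec.crosslink_max)
                cand = sorted(((float(ci[a] + cj[b]), int(a), int(b))
                               for a, b in zip(ii, jj)), reverse=True)
                if cand:
                    by_pair[(i, j)] = cand
        order = sorted(by_pair)
        k = 0
        while len(crosslinks) < spec.n_crosslinks and any(by_pair.values()):
            pair = order[k % len(order)]
            k += 1
            if by_pair[pair]:
                _, a, b = by_pair[pair].pop(0)
                crosslinks.append(CrossLinkRecord(f"BODY{pair[0]}", a + 1,
                                                  f"BODY{pair[1]}", b + 1))
    return FitCase(bodies=bodies, planted_poses=poses, grid=grid,
                   crosslinks=crosslinks, chainmap=chainmap, spec=spec)
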
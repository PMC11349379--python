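"""Core data containers shared by every pipeline stage.

The central object is :class:`AssemblyModel`, a flat per-atom table of a
(possibly multi-copy) molecular assembly with author residue numbering and a
per-residue confidence score (pLDDT convention, stored in the B-factor column
of deposited files).  A :class:`ChainMap` attaches biological identity --
protein name, copy index and subcomplex label -- to each chain, which is what
lets cross-link endpoints written as (protein, residue) be resolved onto the
correct set of chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

SUBCOMPLEX_LABELS = ("IFTA1", "IFTA2", "IFTB1", "IFTB2", "other")


class FormatError(ValueError):
    """Raised when an input file does not parse under its declared format."""


class SchemaError(ValueError):
    """Raised when tabular input is missing required columns."""


# ---------------------------------------------------------------------------
# Assembly model
# ---------------------------------------------------------------------------

@dataclass
class AssemblyModel:
    """Flat per-atom representation of an assembly.

    All arrays have one entry per atom.  ``res_ids`` carry author numbering
    (the numbering used in cross-link tables and in figure labels such as
    K720); ``b_factors`` carry per-atom B-factors, interpreted downstream as
    pLDDT-style confidence in [0, 100] when the model derives from a
    structure prediction.
    """

    chain_ids: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    coords: np.ndarray
    b_factors: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        n = len(self.chain_ids)
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        self.res_ids = np.asarray(self.res_ids, dtype=np.int64)
        self.res_names = np.asarray(self.res_names, dtype=object)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float).reshape(n, 3)
        self.b_factors = np.asarray(self.b_factors, dtype=float)
        for arr in (self.res_ids, self.res_names, self.atom_names,
                    self.elements, self.b_factors):
            if len(arr) != n:
                raise ValueError("per-atom arrays have inconsistent lengths")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    # -- basic queries ------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.chain_ids)

    def chains(self) -> list[str]:
        """Chain identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(c)
        return list(seen)

    def chain_mask(self, chain_id: str) -> np.ndarray:
        return self.chain_ids == chain_id

    def residue_keys(self) -> list[tuple[str, int]]:
        """(chain, author residue number) pairs in atom order, deduplicated."""
        seen: dict[tuple[str, int], None] = {}
        for c, r in zip(self.chain_ids, self.res_ids):
            seen.setdefault((c, int(r)))
        return list(seen)

    def residue_confidence(self) -> dict[tuple[str, int], float]:
        """Per-residue confidence = mean B-factor over the residue's atoms."""
        sums: dict[tuple[str, int], list[float]] = {}
        for c, r, b in zip(self.chain_ids, self.res_ids, self.b_factors):
            sums.setdefault((c, int(r)), []).append(float(b))
        return {k: float(np.mean(v)) for k, v in sums.items()}

    def ca_index(self) -> dict[tuple[str, int], int]:
        """Map (chain, residue) -> atom index of its Cα (first CA atom)."""
        out: dict[tuple[str, int], int] = {}
        for i, (c, r, a) in enumerate(
                zip(self.chain_ids, self.res_ids, self.atom_names)):
            if a == "CA":
                out.setdefault((c, int(r)), i)
        return out

    # -- manipulation -------------------------------------------------------

    def subset(self, mask: np.ndarray) -> "AssemblyModel":
        return AssemblyModel(
            chain_ids=self.chain_ids[mask],
            res_ids=self.res_ids[mask],
            res_names=self.res_names[mask],
            atom_names=self.atom_names[mask],
            elements=self.elements[mask],
            coords=self.coords[mask],
            b_factors=self.b_factors[mask],
            source=self.source,
        )

    def transformed(self, rotation: np.ndarray,
                    translation: np.ndarray) -> "AssemblyModel":
        """Return a copy with coordinates ``R @ x + t``."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        return replace(self, coords=self.coords @ rotation.T + translation)

    @staticmethod
    def concat(models: Sequence["AssemblyModel"]) -> "AssemblyModel":
        return AssemblyModel(
            chain_ids=np.concatenate([m.chain_ids for m in models]),
            res_ids=np.concatenate([m.res_ids for m in models]),
            res_names=np.concatenate([m.res_names for m in models]),
            atom_names=np.concatenate([m.atom_names for m in models]),
            elements=np.concatenate([m.elements for m in models]),
            coords=np.concatenate([m.coords for m in models]),
            b_factors=np.concatenate([m.b_factors for m in models]),
            source=";".join(dict.fromkeys(m.source for m in models if m.source)),
        )

    def validate(self) -> None:
        """Check container invariants; raise ``ValueError`` on violation."""
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        for (chain, res), atoms in _group_residue_atoms(self).items():
            names = [self.atom_names[i] for i in atoms]
            if len(names) != len(set(names)):
                raise ValueError(
                    f"duplicate atom names in residue {chain}:{res}")


def _group_residue_atoms(model: AssemblyModel) -> dict[tuple[str, int], list[int]]:
    groups: dict[tuple[str, int], list[int]] = {}
    for i, (c, r) in enumerate(zip(model.chain_ids, model.res_ids)):
        groups.setdefault((c, int(r)), []).append(i)
    return groups


# ---------------------------------------------------------------------------
# Chain mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainInfo:
    protein: str
    copy: int
    subcomplex: str = "other"

    def __post_init__(self) -> None:
        if self.subcomplex not in SUBCOMPLEX_LABELS:
            raise ValueError(
                f"subcomplex {self.subcomplex!r} not one of {SUBCOMPLEX_LABELS}")


def _norm_protein(name: str) -> str:
    return name.strip().casefold()


@dataclass
class ChainMap:
    """Chain identifier -> (protein name, copy index, subcomplex label)."""

    entries: dict[str, ChainInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pairs = [(e.protein, e.copy) for e in self.entries.values()]
        if len(pairs) != len(set(pairs)):
            raise ValueError("(protein, copy) pairs must be unique")

    def chains_for_protein(self, protein: str) -> list[str]:
        """Chains carrying ``protein``; name match is case-insensitive."""
        key = _norm_protein(protein)
        return [c for c, e in self.entries.items()
                if _norm_protein(e.protein) == key]

    def validate_model(self, model: AssemblyModel) -> None:
        """Every chain of the model must be mapped; raise listing strays."""
        unmapped = [c for c in model.chains() if c not in self.entries]
        if unmapped:
            raise ValueError(f"chains not in chain map: {unmapped}")

    def to_dict(self) -> dict[str, dict]:
        return {c: {"protein": e.protein, "copy": e.copy,
                    "subcomplex": e.subcomplex}
                for c, e in self.entries.items()}

    @classmethod
    def from_dict(cls, data: Mapping[str, Mapping]) -> "ChainMap":
        entries = {}
        for chain, spec in data.items():
            entries[str(chain)] = ChainInfo(
                protein=str(spec["protein"]),
                copy=int(spec.get("copy", 0)),
                subcomplex=str(spec.get("subcomplex", "other")),
            )
        return cls(entries=entries)


# ---------------------------------------------------------------------------
# Cross-links
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossLinkRecord:
    """A residue-pair cross-link, endpoints in author numbering."""

    protein_a: str
    residue_a: int
    protein_b: str
    residue_b: int
    score: float | None = None

    def __post_init__(self) -> None:
        if self.residue_a <= 0 or self.residue_b <= 0:
            raise ValueError("residue numbers must be positive")
        if not self.protein_a.strip() or not self.protein_b.strip():
            raise ValueError("protein names must be non-empty")

    @property
    def link_class(self) -> str:
        """'self' for intra-protein links, 'heteromeric' otherwise."""
        if _norm_protein(self.protein_a) == _norm_protein(self.protein_b):
            return "self"
        return "heteromeric"

    def swapped(self) -> "CrossLinkRecord":
        return CrossLinkRecord(self.protein_b, self.residue_b,
                               self.protein_a, self.residue_a, self.score)


# ---------------------------------------------------------------------------
# Density grids
# ---------------------------------------------------------------------------

@dataclass
class DensityGrid:
    """Real-space scalar grid.

    ``data[i, j, k]`` sits at ``origin + (i, j, k) * voxel`` (Å); axes are
    stored X-fastest-last, i.e. index order (x, y, z).
    """

    data: np.ndarray
    voxel: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.voxel = np.broadcast_to(
            np.asarray(self.voxel, dtype=float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("grid must be 3-D with positive dimensions")
        if np.any(self.voxel <= 0):
            raise ValueError("voxel size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at Cartesian points; 0 outside the grid."""
        pts = (np.asarray(points, float).reshape(-1, 3) - self.origin) / self.voxel
        out = np.zeros(len(pts))
        shape = np.array(self.data.shape)
        inside = np.all((pts >= 0) & (pts <= shape - 1), axis=1)
        if not inside.any():
            return out
        p = pts[inside]
        i0 = np.floor(p).astype(int)
        i0 = np.minimum(i0, shape - 2)
        f = p - i0
        d = self.data
        ix, iy, iz = i0.T
        fx, fy, fz = f.T
        c = (d[ix, iy, iz] * (1 - fx) * (1 - fy) * (1 - fz)
             + d[ix + 1, iy, iz] * fx * (1 - fy) * (1 - fz)
             + d[ix, iy + 1, iz] * (1 - fx) * fy * (1 - fz)
             + d[ix, iy, iz + 1] * (1 - fx) * (1 - fy) * fz
             + d[ix + 1, iy + 1, iz] * fx * fy * (1 - fz)
             + d[ix + 1, iy, iz + 1] * fx * (1 - fy) * fz
             + d[ix, iy + 1, iz + 1] * (1 - fx) * fy * fz
             + d[ix + 1, iy + 1, iz + 1] * fx * fy * fz)
        out[inside] = c
        return out


# ---------------------------------------------------------------------------
# Threshold policy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdPolicy:
    """Classification thresholds for cross-link validation.

    ``threshold``: maximum permissible Cα–Cα span of the linker in Å
    (default 35, the accepted DSSO lysine–lysine limit; satisfaction is a
    strict ``d < threshold``).  ``confidence_cutoff``: pLDDT below which a
    residue counts as flexible and can rescue a violated link (default 50).
    ``rescue_window``: how many residues up/downstream of an endpoint (same
    chain) are inspected for low confidence (default 0 = endpoint only).
    """

    threshold: float = 35.0
    confidence_cutoff: float = 50.0
    rescue_window: int = 0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if not 0.0 <= self.confidence_cutoff <= 100.0:
            raise ValueError("confidence cutoff must lie in [0, 100]")
        if self.rescue_window < 0:
            raise ValueError("rescue window must be >= 0")
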
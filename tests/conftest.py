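"""Shared fixtures: synthetic assemblies generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from trainxl.core import AssemblyModel, ChainInfo, ChainMap, CrossLinkRecord
from trainxl.synth import (FitCaseSpec, SyntheticSpec, generate_fit_case,
                           generate_two_state)


@pytest.fixture(scope="session")
def two_state():
    """Default-condition two-state assembly (noise-free)."""
    return generate_two_state(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def two_state_noisy():
    """Same conditions with 1 Å coordinate noise."""
    return generate_two_state(SyntheticSpec(seed=11, noise_sd=1.0))


@pytest.fixture(scope="session")
def small_two_state():
    """Two-unit assembly for SASA-heavy tests."""
    return generate_two_state(SyntheticSpec(n_units=2, seed=4,
                                            n_crosslinks=24))


@pytest.fixture(scope="session")
def fit_case_single():
    return generate_fit_case(FitCaseSpec(n_bodies=1, seed=5))


@pytest.fixture(scope="session")
def fit_case_three():
    return generate_fit_case(FitCaseSpec(n_bodies=3, seed=0))


def make_random_assembly(rng: np.random.Generator,
                         n_proteins: int = 3,
                         max_copies: int = 5,
                         n_residues: int = 8
                         ) -> tuple[AssemblyModel, ChainMap]:
    """Small random multi-copy assembly for oracle-equivalence tests."""
    chain_ids, res_ids, coords = [], [], []
    entries = {}
    for p in range(n_proteins):
        protein = f"PROT{p}"
        for copy in range(int(rng.integers(1, max_copies + 1))):
            cid = f"{protein}_{copy}"
            entries[cid] = ChainInfo(protein=protein, copy=copy)
            n_res = int(rng.integers(2, n_residues + 1))
            base = rng.uniform(-60, 60, 3)
            for r in range(1, n_res + 1):
                chain_ids.append(cid)
                res_ids.append(r)
                coords.append(base + rng.normal(0, 8, 3))
    n = len(chain_ids)
    model = AssemblyModel(
        chain_ids=np.array(chain_ids, dtype=object),
        res_ids=np.array(res_ids),
        res_names=np.array(["UNK"] * n, dtype=object),
        atom_names=np.array(["CA"] * n, dtype=object),
        elements=np.array(["C"] * n, dtype=object),
        coords=np.array(coords),
        b_factors=np.full(n, 90.0),
    )
    return model, ChainMap(entries=entries)


def brute_force_oracle(model: AssemblyModel, chainmap: ChainMap,
                       record: CrossLinkRecord) -> float:
    """Exhaustive minimum Cα–Cα distance over every copy-pair combination.

    Independent of the library path: collects candidate sites by a linear
    scan over atoms, then enumerates all pairs with plain loops.
    """
    def sites(protein: str, residue: int) -> list[tuple[str, int]]:
        out = []
        for i in range(model.n_atoms):
            if model.atom_names[i] != "CA":
                continue
            if int(model.res_ids[i]) != residue:
                continue
            chain = str(model.chain_ids[i])
            entry = chainmap.entries.get(chain)
            if entry is None:
                continue
            if entry.protein.strip().lower() != protein.strip().lower():
                continue
            out.append((chain, i))
        return out

    same = (record.protein_a.strip().lower()
            == record.protein_b.strip().lower()
            and record.residue_a == record.residue_b)
    best = np.inf
    for chain_a, i in sites(record.protein_a, record.residue_a):
        for chain_b, j in sites(record.protein_b, record.residue_b):
            if same and chain_a == chain_b:
                continue
            best = min(best, float(np.linalg.norm(
                model.coords[i] - model.coords[j])))
    return best
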
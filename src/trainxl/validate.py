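"""Cross-link mapping, distance classification and two-state comparison.

A residue-pair cross-link names only (protein, residue) endpoints; on a
polymeric assembly each protein exists in several copies, so an endpoint
resolves to a *set* of Cα sites.  Following standard practice for multi-copy
assemblies, the reported distance is the minimum Cα–Cα distance over all
copy pairs -- the most permissive structurally consistent assignment.
Classification against the linker threshold is strict (satisfied iff
d < threshold); for the default 35 Å DSSO criterion a 35.0 Å link counts as
violated.  Violated links may still be explained by local flexibility: if an
endpoint residue (or a neighbour within the rescue window on the same chain)
has confidence below the cutoff, the link is flagged as rescued.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .core import (AssemblyModel, ChainMap, CrossLinkRecord, ThresholdPolicy)

SATISFIED = "satisfied"
VIOLATED = "violated"
UNMAPPED = "unmapped"


@dataclass
class DistanceReport:
    """Outcome of mapping one cross-link onto one model."""

    record: CrossLinkRecord
    distance: float | None
    chain_a: str | None
    chain_b: str | None
    classification: str
    rescued: bool = False
    rescue_reason: str | None = None

    def __post_init__(self) -> None:
        if self.classification != UNMAPPED:
            if self.distance is None or self.distance < 0:
                raise ValueError("mapped link must carry a distance >= 0")
        if self.rescued and self.classification != VIOLATED:
            raise ValueError("only violated links can be rescued")


def resolve_endpoints(model: AssemblyModel, chainmap: ChainMap,
                      record: CrossLinkRecord
                      ) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    """All Cα sites for each endpoint, as (chain, atom index) lists.

    An endpoint yields one site per copy of its protein that actually has a
    Cα at the author residue number; an empty list marks the endpoint (and
    thus the link) as unmapped.
    """
    ca = model.ca_index()

    def sites(protein: str, residue: int) -> list[tuple[str, int]]:
        out = []
        for chain in chainmap.chains_for_protein(protein):
            idx = ca.get((chain, residue))
            if idx is not None:
                out.append((chain, idx))
        return out

    return (sites(record.protein_a, record.residue_a),
            sites(record.protein_b, record.residue_b))


def min_ca_distance(model: AssemblyModel, chainmap: ChainMap,
                    record: CrossLinkRecord,
                    policy: ThresholdPolicy | None = None) -> DistanceReport:
    """Minimum Cα–Cα distance over all copy pairs, classified.

    When both endpoints are the same (protein, residue), the pairing of a
    site with itself on the same chain is excluded (the trivial zero), so
    such links report the shortest inter-copy distance.
    """
    policy = policy or ThresholdPolicy()
    sites_a, sites_b = resolve_endpoints(model, chainmap, record)
    same_residue = (record.protein_a.strip().casefold()
                    == record.protein_b.strip().casefold()
                    and record.residue_a == record.residue_b)
    best: tuple[float, str, str] | None = None
    for chain_a, ia in sites_a:
        for chain_b, ib in sites_b:
            if same_residue and chain_a == chain_b:
                continue
            d = float(np.linalg.norm(model.coords[ia] - model.coords[ib]))
            if best is None or d < best[0]:
                best = (d, chain_a, chain_b)
    if best is None:
        return DistanceReport(record, None, None, None, UNMAPPED)
    dist, chain_a, chain_b = best
    return DistanceReport(record, dist, chain_a, chain_b,
                          classify(dist, policy))


def classify(distance: float, policy: ThresholdPolicy) -> str:
    """Strict threshold rule: satisfied iff distance < threshold."""
    if distance < 0:
        raise ValueError("distance must be >= 0")
    return SATISFIED if distance < policy.threshold else VIOLATED


def flexibility_rescue(report: DistanceReport, model: AssemblyModel,
                       policy: ThresholdPolicy) -> DistanceReport:
    """Flag violated links explained by low-confidence (flexible) residues.

    A violated link is rescued when an endpoint residue of the minimizing
    chain pair -- or any residue within ``policy.rescue_window`` of it on
    the same chain -- has per-residue confidence below the cutoff.
    Satisfied and unmapped links pass through unchanged.
    """
    if report.classification != VIOLATED:
        return report
    conf = model.residue_confidence()
    endpoints = [(report.chain_a, report.record.residue_a),
                 (report.chain_b, report.record.residue_b)]
    for chain, residue in endpoints:
        if chain is None:
            continue
        for offset in range(-policy.rescue_window, policy.rescue_window + 1):
            c = conf.get((chain, residue + offset))
            if c is not None and c < policy.confidence_cutoff:
                reason = (f"{chain}:{residue + offset} confidence "
                          f"{c:.1f} < {policy.confidence_cutoff:g}")
                return replace(report, rescued=True, rescue_reason=reason)
    return report


def validate_crosslinks(model: AssemblyModel, chainmap: ChainMap,
                        records: Sequence[CrossLinkRecord],
                        policy: ThresholdPolicy | None = None
                        ) -> list[DistanceReport]:
    """Map, classify and rescue a whole table of cross-links."""
    policy = policy or ThresholdPolicy()
    chainmap.validate_model(model)
    out = []
    for record in records:
        report = min_ca_distance(model, chainmap, record, policy)
        out.append(flexibility_rescue(report, model, policy))
    return out


def distance_histogram(reports: Sequence[DistanceReport],
                       bin_width: float = 5.0
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of mapped Cα–Cα distances with fixed-width bins from 0.

    Returns (counts, bin_edges).  Unmapped links are excluded; the counts
    sum to the number of mapped reports.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    dists = [r.distance for r in reports if r.classification != UNMAPPED]
    if not dists:
        raise ValueError("no mapped reports to histogram")
    n_bins = int(np.floor(max(dists) / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(dists, bins=edges)
    return counts, edges


@dataclass
class StateComparison:
    """Per-link pairing of the two conformational states."""

    record: CrossLinkRecord
    report_a: DistanceReport
    report_b: DistanceReport

    @property
    def delta(self) -> float | None:
        """d_B - d_A; None when the link is unmapped in either state."""
        if (self.report_a.classification == UNMAPPED
                or self.report_b.classification == UNMAPPED):
            return None
        return self.report_b.distance - self.report_a.distance


def compare_states(model_a: AssemblyModel, model_b: AssemblyModel,
                   chainmap_a: ChainMap, chainmap_b: ChainMap,
                   records: Sequence[CrossLinkRecord],
                   policy: ThresholdPolicy | None = None
                   ) -> list[StateComparison]:
    """Map the same cross-link table onto two states and pair the results."""
    reports_a = validate_crosslinks(model_a, chainmap_a, records, policy)
    reports_b = validate_crosslinks(model_b, chainmap_b, records, policy)
    return [StateComparison(rec, ra, rb)
            for rec, ra, rb in zip(records, reports_a, reports_b)]


def satisfied_fraction(reports: Sequence[DistanceReport],
                       count_rescued: bool = False) -> float:
    """Fraction of mapped links that satisfy the threshold.

    Unmapped links are excluded from the denominator.  With
    ``count_rescued`` the flexibility-rescued violations count as
    explained and join the numerator.
    """
    mapped = [r for r in reports if r.classification != UNMAPPED]
    if not mapped:
        raise ValueError("no mapped reports")
    good = sum(1 for r in mapped
               if r.classification == SATISFIED or (count_rescued and r.rescued))
    return good / len(mapped)
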
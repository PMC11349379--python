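"""Cross-link mapping, classification, rescue and state comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trainxl.core import (AssemblyModel, ChainInfo, ChainMap,
                          CrossLinkRecord, ThresholdPolicy)
from trainxl.validate import (SATISFIED, UNMAPPED, VIOLATED, classify,
                              compare_states, distance_histogram,
                              flexibility_rescue, min_ca_distance,
                              resolve_endpoints, satisfied_fraction,
                              validate_crosslinks)

from conftest import brute_force_oracle, make_random_assembly


def _line_model(positions, confidences=None, chains=None):
    """Cα beads along x, one residue each; helper for hand-built cases."""
    n = len(positions)
    chains = chains or ["A"] * n
    conf = confidences if confidences is not None else [90.0] * n
    coords = np.zeros((n, 3))
    coords[:, 0] = positions
    return AssemblyModel(
        chain_ids=np.array(chains, dtype=object),
        res_ids=np.arange(1, n + 1),
        res_names=np.array(["UNK"] * n, dtype=object),
        atom_names=np.array(["CA"] * n, dtype=object),
        elements=np.array(["C"] * n, dtype=object),
        coords=coords,
        b_factors=np.array(conf, dtype=float),
    )


class TestResolveAndMinDistance:
    def test_multi_copy_endpoint_yields_one_site_per_copy(self):
        # e.g. inner and outer copies of the same protein in one assembly
        model = _line_model([0, 50], chains=["in", "out"])
        model = AssemblyModel(**{**model.__dict__,
                                 "res_ids": np.array([7, 7])})
        cm = ChainMap(entries={"in": ChainInfo("IFT172", 0),
                               "out": ChainInfo("IFT172", 1)})
        sites_a, _ = resolve_endpoints(model, cm,
                                       CrossLinkRecord("IFT172", 7,
                                                       "IFT172", 7))
        assert len(sites_a) == 2

    def test_absent_residue_or_protein_is_unmapped(self):
        model = _line_model([0, 10])
        cm = ChainMap(entries={"A": ChainInfo("IFT80", 0)})
        missing_res = min_ca_distance(model, cm,
                                      CrossLinkRecord("IFT80", 99,
                                                      "IFT80", 1))
        assert missing_res.classification == UNMAPPED
        missing_prot = min_ca_distance(model, cm,
                                       CrossLinkRecord("IFT27", 1,
                                                       "IFT80", 1))
        assert missing_prot.classification == UNMAPPED

    def test_same_residue_self_pairing_excluded(self):
        # two copies 42 Å apart: the zero self-distance must be excluded
        model = _line_model([0.0, 42.0], chains=["c1", "c2"])
        model = AssemblyModel(**{**model.__dict__,
                                 "res_ids": np.array([5, 5])})
        cm = ChainMap(entries={"c1": ChainInfo("IFT52", 0),
                               "c2": ChainInfo("IFT52", 1)})
        rec = CrossLinkRecord("IFT52", 5, "IFT52", 5)
        report = min_ca_distance(model, cm, rec)
        assert report.distance == pytest.approx(42.0)
        assert report.classification == VIOLATED

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_on_random_assemblies(self, seed):
        rng = np.random.default_rng(seed)
        model, cm = make_random_assembly(rng)
        for _ in range(10):
            rec = CrossLinkRecord(f"PROT{rng.integers(3)}",
                                  int(rng.integers(1, 9)),
                                  f"PROT{rng.integers(3)}",
                                  int(rng.integers(1, 9)))
            report = min_ca_distance(model, cm, rec)
            oracle = brute_force_oracle(model, cm, rec)
            if report.classification == UNMAPPED:
                assert not np.isfinite(oracle)
            else:
                assert report.distance == pytest.approx(oracle, abs=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_distance_symmetric_under_endpoint_swap(self, seed):
        rng = np.random.default_rng(100 + seed)
        model, cm = make_random_assembly(rng)
        for _ in range(10):
            rec = CrossLinkRecord(f"PROT{rng.integers(3)}",
                                  int(rng.integers(1, 9)),
                                  f"PROT{rng.integers(3)}",
                                  int(rng.integers(1, 9)))
            fwd = min_ca_distance(model, cm, rec)
            rev = min_ca_distance(model, cm, rec.swapped())
            assert fwd.classification == rev.classification
            if fwd.classification != UNMAPPED:
                assert fwd.distance == pytest.approx(rev.distance)


class TestClassify:
    def test_strict_threshold_boundary(self):
        policy = ThresholdPolicy(threshold=35.0)
        assert classify(34.99, policy) == SATISFIED
        assert classify(35.0, policy) == VIOLATED
        # the magnitude of the famous inter-complex outlier
        assert classify(151.0, policy) == VIOLATED

    @given(st.lists(st.floats(0, 200), min_size=1, max_size=50),
           st.floats(1, 100), st.floats(0, 50))
    @settings(max_examples=50, deadline=None)
    def test_raising_threshold_never_loses_satisfied(self, dists, thr, bump):
        low = ThresholdPolicy(threshold=thr)
        high = ThresholdPolicy(threshold=thr + bump)
        n_low = sum(classify(d, low) == SATISFIED for d in dists)
        n_high = sum(classify(d, high) == SATISFIED for d in dists)
        assert n_high >= n_low


class TestRescue:
    def _violated_report(self, model, cm):
        rec = CrossLinkRecord("P", 1, "P", 2)
        return min_ca_distance(model, cm, rec)

    def test_low_confidence_endpoint_rescues(self):
        model = _line_model([0.0, 80.0], confidences=[30.0, 90.0])
        cm = ChainMap(entries={"A": ChainInfo("P", 0)})
        report = flexibility_rescue(self._violated_report(model, cm),
                                    model, ThresholdPolicy())
        assert report.rescued and "confidence 30.0" in report.rescue_reason

    def test_confident_endpoints_not_rescued(self):
        model = _line_model([0.0, 80.0], confidences=[55.0, 90.0])
        cm = ChainMap(entries={"A": ChainInfo("P", 0)})
        report = flexibility_rescue(self._violated_report(model, cm),
                                    model, ThresholdPolicy())
        assert not report.rescued

    def test_window_reaches_flexible_neighbour(self):
        # endpoint confident but the residue next to it sits on a
        # low-confidence loop, as for links into flexible regions
        model = _line_model([0.0, 80.0, 81.0], confidences=[90, 90, 20])
        cm = ChainMap(entries={"A": ChainInfo("P", 0)})
        base = self._violated_report(model, cm)
        assert not flexibility_rescue(
            base, model, ThresholdPolicy(rescue_window=0)).rescued
        assert flexibility_rescue(
            base, model, ThresholdPolicy(rescue_window=1)).rescued

    def test_satisfied_links_pass_through(self):
        model = _line_model([0.0, 5.0], confidences=[10.0, 10.0])
        cm = ChainMap(entries={"A": ChainInfo("P", 0)})
        report = flexibility_rescue(self._violated_report(model, cm),
                                    model, ThresholdPolicy())
        # distance 5 < 35: satisfied, so no rescue flag despite low pLDDT
        assert report.classification == SATISFIED and not report.rescued


class TestHistogram:
    def test_fixed_width_binning(self):
        model = _line_model([0, 10, 20, 70])
        cm = ChainMap(entries={"A": ChainInfo("P", 0)})
        recs = [CrossLinkRecord("P", 1, "P", i) for i in (2, 3, 4)]
        reports = validate_crosslinks(model, cm, recs)
        counts, edges = distance_histogram(reports, bin_width=25.0)
        assert list(counts) == [2, 0, 1]
        assert edges[1] - edges[0] == pytest.approx(25.0)

    @given(st.lists(st.floats(0.1, 180), min_size=1, max_size=40),
           st.floats(1, 30))
    @settings(max_examples=50, deadline=None)
    def test_counts_conserve_mapped_links(self, dists, width):
        model = _line_model([0.0] + list(np.cumsum(dists)))
        cm = ChainMap(entries={"A": ChainInfo("P", 0)})
        recs = [CrossLinkRecord("P", 1, "P", i + 2)
                for i in range(len(dists))]
        reports = validate_crosslinks(model, cm, recs)
        counts, _ = distance_histogram(reports, bin_width=width)
        assert counts.sum() == len(dists)


class TestCompareStates:
    def test_identical_models_give_zero_delta(self, two_state):
        cmps = compare_states(two_state.model_b, two_state.model_b,
                              two_state.chainmap, two_state.chainmap,
                              two_state.crosslinks)
        assert all(c.delta == pytest.approx(0.0) for c in cmps)

    def test_delta_matches_generator_truth(self, two_state):
        cmps = compare_states(two_state.model_a, two_state.model_b,
                              two_state.chainmap, two_state.chainmap,
                              two_state.crosslinks)
        for cmp_, truth in zip(cmps, two_state.truth):
            assert cmp_.delta == pytest.approx(
                truth.distance_b - truth.distance_a, abs=1e-6)


def test_satisfied_fraction_excludes_unmapped(two_state):
    records = list(two_state.crosslinks) + [
        CrossLinkRecord("NOSUCH", 1, "NOSUCH", 2)]
    reports = validate_crosslinks(two_state.model_b, two_state.chainmap,
                                  records)
    assert reports[-1].classification == UNMAPPED
    frac = satisfied_fraction(reports)
    expected = np.mean([t.satisfied_b for t in two_state.truth])
    assert frac == pytest.approx(expected)
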
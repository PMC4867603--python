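"""Kinase-substrate filtering, hypergeometric enrichment, and KSEA."""

import math
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from phosnet import kinase as kin
from phosnet.errors import ConsistencyError, ParameterError


def exact_upper_tail(k, K, n, N) -> float:
    """Independent oracle: exact tail by counting draws with math.comb."""
    total = comb(N, n)
    hits = sum(
        comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)
    )
    return float(Fraction(hits, total))


class TestHypergeometricUpperTail:
    def test_worked_example(self):
        # (C(4,3)C(6,2) + C(4,4)C(6,1)) / C(10,5) = 66/252
        assert kin.hypergeometric_upper_tail(3, 4, 5, 10) == pytest.approx(
            66 / 252, abs=1e-12
        )

    def test_zero_overlap_gives_one(self):
        assert kin.hypergeometric_upper_tail(0, 4, 5, 10) == 1.0

    def test_category_equals_universe_gives_one(self):
        assert kin.hypergeometric_upper_tail(5, 10, 5, 10) == 1.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ParameterError):
            kin.hypergeometric_upper_tail(5, 4, 5, 10)
        with pytest.raises(ParameterError):
            kin.hypergeometric_upper_tail(1, 11, 5, 10)

    def test_agrees_with_enumeration_for_all_small_universes(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        got = kin.hypergeometric_upper_tail(k, K, n, N)
                        want = exact_upper_tail(k, K, n, N) if k > 0 else 1.0
                        assert got == pytest.approx(want, abs=1e-12), (k, K, n, N)


def ksr_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["kinase", "site_id", "source", "networkin_score", "netphorest_probability"],
    )


class TestFilterKsrs:
    def test_strict_inequality_boundaries(self):
        ksrs = ksr_frame(
            [
                ("K1", "P1:S1", "networkin", 2.0, 0.05),   # both at/below -> removed
                ("K1", "P1:S2", "networkin", 2.0, 0.11),   # prob passes -> kept
                ("K1", "P1:S3", "networkin", 2.01, 0.0),   # score passes -> kept
            ]
        )
        out = kin.filter_ksrs(ksrs, {"K1"})
        assert list(out["site_id"]) == ["P1:S2", "P1:S3"]

    def test_igps_rows_pass_unconditionally(self):
        ksrs = ksr_frame([("K1", "P1:S1", "igps", np.nan, np.nan)])
        assert len(kin.filter_ksrs(ksrs, {"K1"})) == 1

    def test_empty_detected_kinases_empties_output(self):
        ksrs = ksr_frame([("K1", "P1:S1", "igps", np.nan, np.nan)])
        assert kin.filter_ksrs(ksrs, set()).empty

    def test_synthetic_threshold_labels_recovered(self, default_study):
        ksr = default_study.ksr
        out = kin.filter_ksrs(ksr, set(ksr["kinase"]))
        want = ksr[ksr["above_threshold"]]
        got = set(zip(out["kinase"], out["site_id"]))
        assert got == set(zip(want["kinase"], want["site_id"]))


class TestEnrichKinases:
    def test_kinase_absent_from_groups_is_null(self):
        ksrs = pd.DataFrame(
            {"kinase": ["K1"] * 3, "substrate": ["u1", "u2", "u3"], "source": ["igps"] * 3}
        )
        background = {f"u{i}" for i in range(1, 21)}
        res = kin.enrich_kinases(ksrs, {"u10", "u11"}, {"u12", "u13"}, background)
        assert all(r.p_value == 1.0 and not r.significant for r in res)
        assert all(r.assigned_condition is None for r in res)

    def test_down_only_enrichment_assigns_lfd(self):
        # a kinase whose substrates sit in the down group is called LFD-active
        background = {f"u{i}" for i in range(40)}
        down = {f"u{i}" for i in range(8)}
        ksrs = pd.DataFrame(
            {"kinase": ["K1"] * 8, "substrate": sorted(down), "source": ["igps"] * 8}
        )
        res = kin.enrich_kinases(ksrs, set(), down, background, alpha=1e-4)
        by_group = {r.group: r for r in res}
        assert by_group["down"].significant
        assert by_group["down"].assigned_condition == "LFD"
        assert not by_group["up"].significant

    def test_substrate_relabeling_invariance(self):
        background = {f"u{i}" for i in range(30)}
        up = {f"u{i}" for i in range(6)}
        ksrs = pd.DataFrame(
            {"kinase": ["K1"] * 6, "substrate": sorted(up), "source": ["igps"] * 6}
        )
        res1 = kin.enrich_kinases(ksrs, up, set(), background)
        relabel = {u: f"x{u}" for u in background}
        res2 = kin.enrich_kinases(
            ksrs.assign(substrate=[relabel[s] for s in ksrs["substrate"]]),
            {relabel[u] for u in up},
            set(),
            {relabel[u] for u in background},
        )
        assert [r.p_value for r in res1] == [r.p_value for r in res2]

    def test_empty_background_rejected(self):
        with pytest.raises(ParameterError):
            kin.enrich_kinases(pd.DataFrame(columns=["kinase", "substrate", "source"]),
                               set(), set(), set())

    def test_null_false_positive_rate_is_tiny(self):
        # no planted kinases: over 50 seeded repeats the fraction of
        # kinase x group tests below 1e-4 stays <= 1e-3
        from phosnet.simulate import SimulationConfig, simulate_all
        from phosnet.workflows import run_pipeline

        tests = hits = 0
        for seed in range(1, 51):
            cfg = SimulationConfig(seed=seed, n_active_kinases=0)
            study = simulate_all(cfg)
            res = run_pipeline(study, with_network=False, with_enrichment=False)
            tests += len(res.kinase_results)
            hits += sum(r.significant for r in res.kinase_results)
        assert tests > 0
        assert hits / tests <= 1e-3


class TestKseaScore:
    def test_worked_example(self):
        all_vals = [1, -1, 1, -1, 2, -2]
        subs = [1, 1, 2]
        z = kin.ksea_score(subs, all_vals)
        assert z == pytest.approx((4 / 3) * math.sqrt(3) / math.sqrt(2), abs=1e-9)

    def test_substrates_at_grand_mean_give_zero(self):
        assert kin.ksea_score([0.5, 0.5], [0.5, 0.5, 0.5, 0.5, 1.0, 0.0]) == pytest.approx(0.0)

    def test_negating_values_negates_z(self):
        all_vals = [0.3, -1.2, 2.0, 0.1, -0.6]
        subs = [2.0, 0.3]
        assert kin.ksea_score([-v for v in subs], [-v for v in all_vals]) == pytest.approx(
            -kin.ksea_score(subs, all_vals)
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ParameterError):
            kin.ksea_score([], [1.0, 2.0])
        with pytest.raises(ParameterError):
            kin.ksea_score([1.0], [1.0, 1.0, 1.0])


class TestAssignActivity:
    def _ambiguous(self, kinase="K1"):
        return kin.KinaseResult(
            kinase=kinase, source="igps", group="up", k=5, K=5, n=10, N=50,
            p_value=1e-6, significant=True, assigned_condition="ambiguous",
        )

    def test_identity_without_ambiguous_kinases(self):
        r = kin.KinaseResult("K1", "igps", "up", 5, 5, 10, 50, 1e-6, True,
                             assigned_condition="HFD")
        assert kin.assign_activity([r], {}) == [r]

    def test_negative_z_assigns_lfd(self):
        (out,) = kin.assign_activity([self._ambiguous()], {"K1": -2.1})
        assert out.assigned_condition == "LFD"
        assert out.ksea_z == -2.1

    def test_missing_z_raises(self):
        with pytest.raises(ConsistencyError):
            kin.assign_activity([self._ambiguous()], {})

    def test_up_dominant_substrates_assign_hfd(self):
        # hand-computed z: substrates {2, 2, -1} vs all {2, 2, -1, -0.5, 0, 0.5}
        all_vals = [2, 2, -1, -0.5, 0, 0.5]
        z = kin.ksea_score([2, 2, -1], all_vals)
        assert z > 0
        (out,) = kin.assign_activity([self._ambiguous()], {"K1": z})
        assert out.assigned_condition == "HFD"
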
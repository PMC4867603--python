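"""Generator behaviour: determinism, planted-signal bookkeeping, noise rates."""

import math

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal

from phosnet import quant
from phosnet.errors import ConfigurationError, ConsistencyError
from phosnet.simulate import (
    SimulationConfig,
    simulate_all,
    simulate_interactome,
    simulate_ksr_tables,
    simulate_phospho_dataset,
    write_study,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_sites=0),
            dict(n_replicates_per_condition=0),
            dict(baseline_rate=0.0),
            dict(effect_fold=0.5),
            dict(frac_differential=1.5),
            dict(floc_fraction=-0.1),
            dict(ppi_modules=((0, 0.5),)),
            dict(ppi_modules=((50, 0.9), (50, 0.9)), n_proteins=76),
            dict(dispersion=0.0),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kwargs).validate()


class TestPhosphoDataset:
    def test_same_seed_gives_byte_identical_outputs(self, tmp_path):
        a = simulate_all(SimulationConfig(seed=42))
        b = simulate_all(SimulationConfig(seed=42))
        assert_frame_equal(a.psms, b.psms)
        assert_frame_equal(a.ksr, b.ksr)
        for key in a.edges:
            assert_frame_equal(a.edges[key], b.edges[key])
        assert a.truth.to_json() == b.truth.to_json()
        d1, d2 = tmp_path / "a", tmp_path / "b"
        for study, d in ((a, d1), (b, d2)):
            write_study(study, d)
        for f in sorted(d1.iterdir()):
            assert f.read_bytes() == (d2 / f.name).read_bytes()

    def test_different_seed_changes_counts(self):
        a, _ = simulate_phospho_dataset(SimulationConfig(seed=1))
        b, _ = simulate_phospho_dataset(SimulationConfig(seed=2))
        assert len(a) != len(b) or not a.equals(b)

    def test_no_planted_signal_and_no_mislocalization(self):
        cfg = SimulationConfig(seed=7, frac_differential=0.0, floc_fraction=0.0)
        psms, truth = simulate_phospho_dataset(cfg)
        assert truth.differential_sites == {}
        assert truth.mislocalized_spectra == set()
        catalog = {(s.protein, f"{s.residue}{s.position}") for s in truth.sites}
        observed = set(zip(psms["protein"], psms["site_list"]))
        assert observed <= catalog
        assert (psms["flr"] <= 0.01).all()

    def test_planted_differential_count_is_exact(self):
        cfg = SimulationConfig(seed=1, n_sites=200, frac_differential=0.1, effect_fold=4)
        _, truth = simulate_phospho_dataset(cfg)
        assert len(truth.differential_sites) == 20
        assert all(sid in {s.site_id for s in truth.sites} for sid in truth.differential_sites)

    def test_mean_count_matches_baseline_rate(self):
        cfg = SimulationConfig(
            seed=1, baseline_rate=5.0, frac_differential=0.0, floc_fraction=0.0
        )
        psms, truth = simulate_phospho_dataset(cfg)
        matrix = quant.count_spectra(quant.psms_from_frame(psms))
        mean = matrix.counts.to_numpy().mean()
        n = cfg.n_sites * 2 * cfg.n_replicates_per_condition
        tol = 5.0 * 3.0 / math.sqrt(n)
        assert abs(mean - 5.0) <= tol

    def test_matrix_dimensions_follow_config(self):
        cfg = SimulationConfig(seed=2, floc_fraction=0.0, n_sites=120)
        psms, _ = simulate_phospho_dataset(cfg)
        matrix = quant.count_spectra(quant.psms_from_frame(psms))
        assert matrix.counts.shape == (120, 6)

    def test_mislocalization_fraction_near_nominal(self):
        cfg = SimulationConfig(seed=3, floc_fraction=0.2)
        psms, truth = simulate_phospho_dataset(cfg)
        assert len(psms) >= 10_000
        observed = len(truth.mislocalized_spectra) / len(psms)
        assert abs(observed - 0.2) <= 0.02

    def test_mislocalized_psms_carry_high_flr(self):
        cfg = SimulationConfig(seed=4, floc_fraction=0.3)
        psms, truth = simulate_phospho_dataset(cfg)
        bad = psms["spectrum_id"].isin(truth.mislocalized_spectra)
        assert (psms.loc[bad, "flr"] > 0.01).all()
        assert (psms.loc[~bad, "flr"] <= 0.01).all()


class TestKsrTables:
    def test_requires_phospho_dataset_first(self):
        from phosnet.simulate import GroundTruth

        with pytest.raises(ConsistencyError):
            simulate_ksr_tables(SimulationConfig(), GroundTruth())

    def test_no_active_kinases_means_no_planted_rows(self):
        cfg = SimulationConfig(seed=1, n_active_kinases=0)
        _, truth = simulate_phospho_dataset(cfg)
        ksr = simulate_ksr_tables(cfg, truth)
        assert truth.active_kinases == {}
        assert not ksr["planted"].any()

    def test_active_kinase_meets_direction_quota(self):
        cfg = SimulationConfig(
            seed=1, n_sites=300, frac_differential=0.2, substrates_per_kinase=30
        )
        _, truth = simulate_phospho_dataset(cfg)
        ksr = simulate_ksr_tables(cfg, truth)
        # 30 up sites available, quota = 0.8 * 30 = 24
        for kinase, cond in truth.active_kinases.items():
            direction = "up" if cond == "HFD" else "down"
            planted = ksr[(ksr["kinase"] == kinase) & ksr["planted"]]
            group = {
                s for s, d in truth.differential_sites.items() if d == direction
            }
            assert len(set(planted["site_id"]) & group) >= 24

    def test_igps_rows_have_no_scores_networkin_rows_have_both(self, default_study):
        ksr = default_study.ksr
        igps = ksr[ksr["source"] == "igps"]
        nwk = ksr[ksr["source"] == "networkin"]
        assert igps["networkin_score"].isna().all()
        assert igps["netphorest_probability"].isna().all()
        assert nwk["networkin_score"].notna().all()
        assert nwk["netphorest_probability"].notna().all()


class TestInteractome:
    def test_zero_background_single_module_is_complete_graph(self):
        cfg = SimulationConfig(
            seed=1, ppi_modules=((5, 1.0),), ppi_background_edge_prob=0.0
        )
        edges, truth = simulate_interactome(cfg)
        pairs = set()
        for df in edges.values():
            pairs |= {tuple(sorted(p)) for p in zip(df["node_a"], df["node_b"])}
        (module,) = truth.module_nodes
        expected = {
            tuple(sorted((a, b)))
            for i, a in enumerate(module)
            for b in module[i + 1 :]
        }
        assert pairs == expected
        assert len(pairs) == 10  # K5

    def test_string_scores_within_range(self, default_study):
        scores = default_study.edges["string_db"]["combined_score"]
        assert ((scores >= 0.15) & (scores <= 1.0)).all()

    def test_planted_modules_are_disjoint_and_sized(self, default_study):
        mods = default_study.truth.module_nodes
        assert [len(m) for m in mods] == [8, 8]
        assert not (set(mods[0]) & set(mods[1]))


class TestAnnotations:
    def test_planted_terms_cover_direction_proteins(self, default_study):
        truth = default_study.truth
        protein_of = {s.site_id: s.protein for s in truth.sites}
        for term, direction in truth.term_groups.items():
            _, genes = default_study.annotations[term]
            dir_proteins = {
                protein_of[s]
                for s, d in truth.differential_sites.items()
                if d == direction
            }
            assert dir_proteins <= set(genes)

    def test_gene_sets_have_requested_size(self, default_study):
        for _, genes in default_study.annotations.values():
            assert len(genes) == default_study.config.genes_per_term
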
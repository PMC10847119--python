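"""Determinism and round-trip contracts of the synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest

from immunoquant.affinity import fit_scatchard
from immunoquant.differential import run_de
from immunoquant.repertoire import aggregate_clonotypes, filter_contigs
from immunoquant.simulate import (
    GeneratorConfig,
    gen_counts,
    gen_in_vivo,
    gen_repertoire,
    gen_reveal_dataset,
    gen_titration,
    generate,
)
from immunoquant.stability import RevealMeasurement, stability_score


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        pd.testing.assert_frame_equal(
            gen_reveal_dataset(seed=9, noise_cv=0.1), gen_reveal_dataset(seed=9, noise_cv=0.1)
        )
        s1, s2 = gen_titration(seed=9, noise_cv=0.1), gen_titration(seed=9, noise_cv=0.1)
        assert s1.mfi == s2.mfi
        pd.testing.assert_frame_equal(gen_repertoire(seed=9), gen_repertoire(seed=9))
        c1, g1 = gen_counts(seed=9, n_genes=30)
        c2, g2 = gen_counts(seed=9, n_genes=30)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_series_equal(g1, g2)
        for a, b in zip(gen_in_vivo(seed=9), gen_in_vivo(seed=9)):
            pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        assert gen_titration(seed=1, noise_cv=0.1).mfi != gen_titration(seed=2, noise_cv=0.1).mfi

    def test_config_dispatch(self):
        cfg = GeneratorConfig(seed=3, scenario="titration", parameters={"kd": 2.0})
        series = generate(cfg)
        assert series.concentrations[-1] == 5.0
        with pytest.raises(ValueError, match="unknown scenario"):
            generate(GeneratorConfig(seed=0, scenario="nope"))


class TestRevealGenerator:
    def test_noiseless_decay_law(self):
        df = gen_reveal_dataset(seed=0, half_lives=[12.0], y0=[100.0])
        assert df.iloc[0]["y24"] == pytest.approx(25.0)

    def test_scoring_recovers_half_lives_exactly(self):
        h = np.array([2.0, 6.0, 12.0, 30.0, 90.0])
        df = gen_reveal_dataset(seed=0, half_lives=h, y0=[50.0] * 5)
        recovered = [
            stability_score(
                RevealMeasurement(r.peptide_name, r.y0, r.y24, r.t)
            ).t_half
            for r in df.itertuples()
        ]
        assert recovered == pytest.approx(list(h), rel=1e-10)

    def test_names_follow_tiling_convention(self):
        df = gen_reveal_dataset(seed=0, n_peptides=3, parent_id="SmBB")
        assert df["peptide_name"].tolist() == ["SmBB_1-15", "SmBB_4-18", "SmBB_7-21"]

    def test_default_screen_size(self):
        assert len(gen_reveal_dataset(seed=0)) == 145

    def test_invalid_half_life_rejected(self):
        with pytest.raises(ValueError):
            gen_reveal_dataset(seed=0, half_lives=[0.0])


class TestTitrationGenerator:
    def test_default_design_has_eight_points(self):
        series = gen_titration(seed=0)
        assert len(series.concentrations) == 8
        assert series.concentrations[0] == 0.0 and series.concentrations[-1] == 5.0

    def test_noiseless_roundtrip(self):
        fit = fit_scatchard(gen_titration(seed=0, kd=1.0, bmax=100.0))
        assert fit.kd == pytest.approx(1.0, rel=1e-9)

    def test_median_kd_recovery_cv5(self):
        """Noise CV 5% over 200 seeds: median recovered kd within 10%."""
        kds = []
        for seed in range(200):
            fit = fit_scatchard(gen_titration(seed=seed, kd=1.0, bmax=1000.0, noise_cv=0.05))
            if not fit.non_binding:
                kds.append(fit.kd)
        assert abs(np.median(kds) - 1.0) < 0.10


class TestRepertoireGenerator:
    def test_zero_background_gives_planted_count(self):
        contigs = gen_repertoire(seed=0, clone_sizes=(4, 2), n_singletons=0)
        out = aggregate_clonotypes(filter_contigs(contigs))
        assert len(out) == 2 and out["clone_count"].tolist() == [4, 2]

    def test_low_umi_duplicates_removed_without_changing_counts(self):
        clean = gen_repertoire(seed=13, clone_sizes=(6, 3), n_singletons=20)
        dirty = gen_repertoire(
            seed=13, clone_sizes=(6, 3), n_singletons=20, n_low_umi_duplicates=10,
            n_unpaired=5, n_nonproductive=5,
        )
        assert len(dirty) > len(clean)
        out_clean = aggregate_clonotypes(filter_contigs(clean))
        out_dirty = aggregate_clonotypes(filter_contigs(dirty))
        assert out_dirty["clone_count"].tolist() == out_clean["clone_count"].tolist()

    def test_every_planted_cell_is_paired(self):
        contigs = gen_repertoire(seed=1, clone_sizes=(5,), n_singletons=10)
        per_cell = contigs.groupby("barcode")["chain"].nunique()
        assert (per_cell == 2).all()


class TestCountsGenerator:
    def test_shapes_and_labels(self):
        counts, groups = gen_counts(seed=0, n_genes=50, n_cells_a=4, n_cells_b=6)
        assert counts.shape == (50, 10)
        assert (groups == "clonotype").sum() == 4
        assert (counts.values >= 0).all()

    def test_planted_fold_change_enriches_top_of_ranking(self):
        counts, groups = gen_counts(seed=2, n_genes=200, n_de_genes=10, fold_change=4.0)
        res = run_de(counts, groups)
        assert res.head(10)["gene"].str.startswith("DEG").sum() >= 8


class TestInVivoGenerator:
    def test_zero_probability_means_no_necrosis(self):
        groups = {"g": dict(n_mice=3, necrosis_p=0.0, cells_mean=20.0, mesangial_p=0.0,
                            hpf_p=0.0, proteinuria_mean=0.0)}
        glom, hpf, prot = gen_in_vivo(seed=0, groups=groups)
        assert (glom["pas_positive_fraction"] < 0.5).all()
        assert not hpf[["infiltrate", "tubular_dilation", "necrosis", "protein_casts"]].any().any()
        assert (prot["score"] == 0).all()

    def test_group_mean_within_three_se(self):
        p = 0.5
        groups = {"g": dict(n_mice=5, necrosis_p=p, cells_mean=30.0, mesangial_p=0.1,
                            hpf_p=0.1, proteinuria_mean=1.0)}
        glom, _, _ = gen_in_vivo(seed=4, groups=groups, n_glomeruli=50)
        frac = (glom["pas_positive_fraction"] >= 0.5).mean()
        se = np.sqrt(p * (1 - p) / len(glom))
        assert abs(frac - p) <= 3 * se

    def test_schema_matches_analysis_inputs(self):
        glom, hpf, prot = gen_in_vivo(seed=0)
        assert {"kidney_id", "group", "pas_positive_fraction", "cell_count",
                "max_clumped_nuclei", "bowman_cell_layers"} <= set(glom.columns)
        assert {"infiltrate", "tubular_dilation", "necrosis", "protein_casts"} <= set(hpf.columns)
        # default cohort: three disease groups of 5 mice, healthy group of 4
        assert prot.groupby("group")["kidney_id"].count().to_dict() == {
            "healthy": 4, "no_treg": 5, "ptreg": 5, "sm_treg": 5,
        }
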
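"""Renal-injury scoring rules, kidney summaries and proteinuria mapping."""

import numpy as np
import pytest

from immunoquant.histology import (
    GlomerulusObservation,
    HpfObservation,
    proteinuria_score,
    score_glomerulus,
    summarize_groups,
    summarize_kidney,
)
from immunoquant.simulate import gen_in_vivo


def glom(kidney_id="k1", pas=0.0, cells=20, clump=0, layers=1):
    return GlomerulusObservation(
        kidney_id=kidney_id,
        pas_positive_fraction=pas,
        cell_count=cells,
        max_clumped_nuclei=clump,
        bowman_cell_layers=layers,
    )


class TestScoreGlomerulus:
    def test_necrosis_threshold_inclusive_at_half(self):
        assert score_glomerulus(glom(pas=0.5)).necrotic
        assert not score_glomerulus(glom(pas=0.49)).necrotic

    def test_below_crescent_and_clump_thresholds(self):
        flags = score_glomerulus(glom(layers=1, clump=2))
        assert not flags.crescent and not flags.mesangial_proliferative

    def test_clump_of_three_is_proliferative(self):
        assert score_glomerulus(glom(clump=3)).mesangial_proliferative

    def test_two_cell_layers_is_crescent(self):
        assert score_glomerulus(glom(layers=2)).crescent

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            glom(pas=1.2)


class TestSummarizeKidney:
    def make_kidney(self, n_necrotic=5, n_total=20, n_hpf=20, hpf_injured=0):
        glomeruli = [glom(pas=0.8) for _ in range(n_necrotic)] + [
            glom(pas=0.1) for _ in range(n_total - n_necrotic)
        ]
        hpfs = [HpfObservation("k1", infiltrate=True) for _ in range(hpf_injured)] + [
            HpfObservation("k1") for _ in range(n_hpf - hpf_injured)
        ]
        return glomeruli, hpfs

    def test_percent_necrotic(self):
        summary = summarize_kidney(*self.make_kidney(n_necrotic=5, n_total=20))
        assert summary.pct_necrotic_glomeruli == pytest.approx(25.0)
        assert summary.qc_flags == ()

    def test_no_injury_gives_zero_tubulointerstitial(self):
        summary = summarize_kidney(*self.make_kidney(hpf_injured=0))
        assert summary.tubulointerstitial_pct == 0.0

    def test_any_flag_counts_the_field(self):
        glomeruli, _ = self.make_kidney()
        hpfs = [HpfObservation("k1", protein_casts=True)] + [
            HpfObservation("k1") for _ in range(19)
        ]
        summary = summarize_kidney(glomeruli, hpfs)
        assert summary.tubulointerstitial_pct == pytest.approx(5.0)

    def test_short_samples_are_qc_flagged_not_rejected(self):
        glomeruli = [glom(pas=0.8) for _ in range(5)]
        hpfs = [HpfObservation("k1") for _ in range(3)]
        summary = summarize_kidney(glomeruli, hpfs)
        assert len(summary.qc_flags) == 2
        assert summary.pct_necrotic_glomeruli == 100.0

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            summarize_kidney([], [HpfObservation("k1")])

    def test_mixed_kidneys_rejected(self):
        with pytest.raises(ValueError, match="multiple kidneys"):
            summarize_kidney([glom(), glom(kidney_id="k2")], [HpfObservation("k1")])

    def test_order_invariance_and_bounds(self):
        glomeruli, hpfs = self.make_kidney(n_necrotic=7, hpf_injured=4)
        a = summarize_kidney(glomeruli, hpfs)
        b = summarize_kidney(glomeruli[::-1], hpfs[::-1])
        assert a == b
        for pct in (
            a.pct_necrotic_glomeruli,
            a.pct_mesangial_proliferation,
            a.pct_crescents,
            a.tubulointerstitial_pct,
        ):
            assert 0.0 <= pct <= 100.0

    def test_monte_carlo_recovery_of_necrosis_probability(self):
        """A synthetic kidney generated with necrosis probability p scores
        within 3 binomial SE of 100p."""
        p = 0.3
        rng = np.random.default_rng(21)
        n = 400
        glomeruli = [
            glom(pas=0.8 if rng.random() < p else 0.1) for _ in range(n)
        ]
        hpfs = [HpfObservation("k1") for _ in range(20)]
        summary = summarize_kidney(glomeruli, hpfs)
        se = 100 * np.sqrt(p * (1 - p) / n)
        assert abs(summary.pct_necrotic_glomeruli - 100 * p) <= 3 * se


class TestSummarizeGroups:
    def test_group_means(self):
        glom_df, hpf_df, _ = gen_in_vivo(seed=5)
        summaries = []
        groups = {}
        for kid, sub in glom_df.groupby("kidney_id"):
            obs = [
                GlomerulusObservation(
                    kidney_id=kid,
                    pas_positive_fraction=r.pas_positive_fraction,
                    cell_count=r.cell_count,
                    max_clumped_nuclei=r.max_clumped_nuclei,
                    bowman_cell_layers=r.bowman_cell_layers,
                )
                for r in sub.itertuples()
            ]
            hsub = hpf_df[hpf_df["kidney_id"] == kid]
            hpfs = [
                HpfObservation(
                    kidney_id=kid,
                    infiltrate=r.infiltrate,
                    tubular_dilation=r.tubular_dilation,
                    necrosis=r.necrosis,
                    protein_casts=r.protein_casts,
                )
                for r in hsub.itertuples()
            ]
            summaries.append(summarize_kidney(obs, hpfs))
            groups[kid] = sub["group"].iloc[0]
        table = summarize_groups(summaries, groups)
        assert set(table["group"]) == {"no_treg", "ptreg", "sm_treg", "healthy"}
        by_group = table.set_index("group")
        # disease severity ordering is preserved through scoring
        assert (
            by_group.loc["sm_treg", "pct_necrotic_glomeruli"]
            < by_group.loc["ptreg", "pct_necrotic_glomeruli"]
            < 100.0
        )
        assert by_group.loc["healthy", "pct_necrotic_glomeruli"] < 10.0

    def test_missing_group_label_rejected(self):
        summary = summarize_kidney(
            [glom() for _ in range(20)], [HpfObservation("k1") for _ in range(20)]
        )
        with pytest.raises(ValueError, match="without a group"):
            summarize_groups([summary], {})


class TestProteinuriaScore:
    @pytest.mark.parametrize(
        "reading, expected",
        [
            ("negative", 0),
            ("trace", 0),
            (0.0, 0),
            (0.29, 0),
            (0.30, 1),
            (0.99, 1),
            (1.0, 2),
            (2.9, 2),
            (3.0, 3),
            (19.9, 3),
            (20.0, 4),
            (50.0, 4),
        ],
    )
    def test_mapping(self, reading, expected):
        assert proteinuria_score(reading) == expected

    def test_monotone_in_g_per_l(self):
        grid = np.linspace(0, 30, 301)
        scores = [proteinuria_score(v) for v in grid]
        assert scores == sorted(scores)

    def test_negative_value_rejected(self):
        with pytest.raises(ValueError):
            proteinuria_score(-0.1)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unrecognised"):
            proteinuria_score("cloudy")
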
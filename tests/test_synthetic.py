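"""Generators: determinism, planted-truth consistency, statistical contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from translatome import seqfeatures as sf
from translatome import synthetic as syn
from translatome.preprocess import compute_m_values


class TestDesignValidation:
    def test_fraction_sum_constraint(self):
        with pytest.raises(ValueError):
            syn.SimulationDesign(frac_up=0.7, frac_down=0.5)

    def test_counts_positive(self):
        with pytest.raises(ValueError):
            syn.SimulationDesign(n_genes=0)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            syn.SimulationDesign(noise_sd=-0.1)


class TestGenTranscripts:
    def test_determinism(self):
        d = syn.SimulationDesign(n_genes=40, seed=5)
        r1, t1 = syn.gen_transcripts(d)
        r2, t2 = syn.gen_transcripts(d)
        assert [(r.gene_id, r.utr5, r.cds, r.utr3) for r in r1] == [
            (r.gene_id, r.utr5, r.cds, r.utr3) for r in r2
        ]
        pd.testing.assert_frame_equal(t1.features, t2.features)

    def test_probability_zero_means_motif_free(self):
        spec = syn.FeatureSpec(
            p_top=0.0, p_top_like=0.0, p_uorf=0.0, p_are=0.0, p_tisu=0.0,
            p_structured=0.0,
        )
        d = syn.SimulationDesign(n_genes=60, seed=3)
        recs, truth = syn.gen_transcripts(
            d, feature_specs={"up": spec, "down": spec, "null": spec}
        )
        for r in recs:
            assert sf.scan_top(r.utr5) == "none"
            assert sf.find_uorfs(r.utr5, r.cds) == []
            assert sf.scan_are(r.utr3) == 0
        assert not truth.features["tisu"].any()

    def test_planted_flags_confirmed_by_scanners(self, small_transcripts):
        recs, truth = small_transcripts
        feat = sf.annotate_transcripts(recs, tisu_genes=syn.tisu_gene_list(truth))
        tf = truth.features
        for col in ("top_class", "n_uorf", "n_are", "utr5_len"):
            assert (feat[col] == tf[col]).all(), col
        assert (feat["tisu"] == tf["tisu"]).all()

    def test_are_fraction_matches_binomial(self):
        p_are = 0.3
        spec = syn.FeatureSpec(p_are=p_are)
        d = syn.SimulationDesign(n_genes=1000, seed=17)
        _, truth = syn.gen_transcripts(
            d, feature_specs={"up": spec, "down": spec, "null": spec}
        )
        frac = (truth.features["n_are"] > 0).mean()
        sd = np.sqrt(p_are * (1 - p_are) / 1000)
        assert abs(frac - p_are) < 3 * sd

    def test_cds_structure(self, small_transcripts):
        recs, _ = small_transcripts
        for r in recs:
            assert r.cds.startswith("ATG")
            assert r.cds[-3:] in sf.STOP_CODONS
            assert len(r.cds) % 3 == 0

    def test_infeasible_cap_names_gene(self):
        spec = syn.FeatureSpec(p_uorf=1.0, max_uorf=2, utr5_len_mean=30.0,
                               utr5_len_sd=1.0, utr5_len_max=12)
        d = syn.SimulationDesign(n_genes=5, seed=0)
        with pytest.raises(syn.FeasibilityError, match="g\\d"):
            syn.gen_transcripts(
                d, feature_specs={"up": spec, "down": spec, "null": spec}
            )

    def test_regulation_fractions_match_design(self):
        d = syn.SimulationDesign(n_genes=200, frac_up=0.1, frac_down=0.05, seed=1)
        truth = syn.assign_regulation(d)
        assert (truth.regulation == "up").sum() == 20
        assert (truth.regulation == "down").sum() == 10
        assert len(truth.regulation) == 200


class TestGenArrayExperiment:
    def test_determinism(self):
        d = syn.SimulationDesign(n_genes=50, seed=2)
        truth = syn.assign_regulation(d)
        e1 = syn.gen_array_experiment(d, truth)
        e2 = syn.gen_array_experiment(d, truth)
        pd.testing.assert_frame_equal(e1.red, e2.red)
        pd.testing.assert_frame_equal(e1.green, e2.green)

    def test_design_layout(self, small_experiment):
        exp, _ = small_experiment
        assert len(exp.array_ids) == (8 + 2) * 3
        assert (exp.meta["group"] == "tumour").sum() == 24
        # default: second repeat of every sample is dye-swapped
        swapped = exp.meta[exp.meta["dye_swap"]]
        assert set(swapped["replicate"]) == {2}

    def test_dye_swap_twin_exchanges_channels(self):
        base = dict(n_genes=30, seed=4)
        d_plain = syn.SimulationDesign(dye_swap_repeats=(), **base)
        d_swap = syn.SimulationDesign(dye_swap_repeats=(0, 1, 2), **base)
        truth = syn.assign_regulation(d_plain)
        e1 = syn.gen_array_experiment(d_plain, truth)
        e2 = syn.gen_array_experiment(d_swap, truth)
        np.testing.assert_array_equal(e1.red.values, e2.green.values)
        np.testing.assert_array_equal(e1.green.values, e2.red.values)

    def test_zero_effect_indistinguishable_groups(self):
        from translatome.preprocess import NormexpParams

        d = syn.SimulationDesign(n_genes=500, seed=8, effect_log2=0.0, frac_up=0.1)
        truth = syn.assign_regulation(d)
        exp = syn.gen_array_experiment(d, truth)
        # correct with the generator's true parameters so the comparison
        # reflects the generative contract, not per-array fitting noise
        p = NormexpParams(d.background_mean, d.background_sd, d.signal_rate)
        params = {a: {"red": p, "green": p} for a in exp.array_ids}
        m = compute_m_values(exp, params=params)
        tum = m.values[m.tumour_arrays].values.ravel()
        ctl = m.values[m.control_arrays].values.ravel()
        assert stats.ks_2samp(tum, ctl).pvalue > 0.01

    def test_null_pvalues_uniform_handoff(self):
        """Null-calibration handoff into the rank-product stage."""
        from translatome import rankprod as rp

        d = syn.SimulationDesign(n_genes=500, seed=13, frac_up=0.0, frac_down=0.0)
        truth = syn.assign_regulation(d)
        m = compute_m_values(syn.gen_array_experiment(d, truth))
        res = rp.rank_product_test(m, n_perm=500, seed=13)
        assert stats.kstest(res.table["pval_up"], "uniform").pvalue > 0.01


class TestGenParticleField:
    def test_pure_class_mix(self):
        grids, truth = syn.gen_particle_field(
            n_fields=2, particles_per_field=6, class_mix=(1.0, 0.0, 0.0), seed=1
        )
        assert (truth["class"] == "elongated").all()
        assert len(truth) == 12

    def test_truth_area_is_pixel_size_invariant(self):
        _, t1 = syn.gen_particle_field(n_fields=1, particles_per_field=5,
                                       pixel_size_um=0.02, seed=6)
        _, t2 = syn.gen_particle_field(n_fields=1, particles_per_field=5,
                                       pixel_size_um=0.01, seed=6)
        np.testing.assert_allclose(t1["area_um2"], t2["area_um2"])

    def test_truth_satisfies_class_definitions(self):
        _, truth = syn.gen_particle_field(n_fields=3, particles_per_field=12, seed=2)
        el = truth[truth["class"] == "elongated"]
        assert (el["axis_ratio"] > 3).all()
        en = truth[truth["class"] == "enlarged"]
        assert (en["circularity"] > 0.8).all() and (en["area_um2"] > 0.5).all()
        ot = truth[truth["class"] == "other"]
        assert ((ot["axis_ratio"] <= 3) & (
            (ot["circularity"] <= 0.8) | (ot["area_um2"] <= 0.5)
        )).all()

    def test_labels_do_not_overlap(self):
        grids, truth = syn.gen_particle_field(n_fields=1, particles_per_field=10,
                                              seed=3)
        n = truth["particle_id"].max()
        assert set(np.unique(grids[0])) == set(range(n + 1))

    def test_field_too_small_errors(self):
        with pytest.raises(RuntimeError, match="too small"):
            syn.gen_particle_field(n_fields=1, particles_per_field=50,
                                   field_shape_px=(64, 64), seed=0)

    def test_bad_mix_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_particle_field(class_mix=(0.5, 0.2, 0.2), seed=0)


def test_go_map_covers_genes_and_plants_enrichment():
    d = syn.SimulationDesign(n_genes=300, seed=9)
    truth = syn.assign_regulation(d)
    annot = syn.gen_go_map(truth, seed=9)
    up = set(truth.regulation.index[truth.regulation == "up"])
    term = "GO:0000001"  # planted enriched term
    rate_up = np.mean([term in annot.get(g, set()) for g in up])
    rest = set(truth.regulation.index) - up
    rate_rest = np.mean([term in annot.get(g, set()) for g in rest])
    assert rate_up > rate_rest
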
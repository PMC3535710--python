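"""Generator contracts: determinism, planted structure, parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from cpgmut import methylome, rates, regions, synth
from cpgmut.core import METH_CLASSES


def _cfg(**kw):
    kw.setdefault("genome_length", 50_000)
    kw.setdefault("seed", 11)
    return synth.SynthConfig(**kw)


class TestGenerateGenome:
    def test_length_and_gc(self):
        g, ann = synth.generate_genome(_cfg(genome_length=100_000,
                                            gc_background=0.5))
        seq = g["chr1"]
        assert len(seq) == 100_000
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(100_000))
        assert len(ann) == 0

    def test_deterministic_for_fixed_seed(self):
        g1, _ = synth.generate_genome(_cfg())
        g2, _ = synth.generate_genome(_cfg())
        assert g1 == g2

    def test_cgi_block_enriched_over_background(self):
        blk = synth.CGIBlock(start=10_000, length=2_000, gc=0.6,
                             cpg_enrichment=0.25)
        g, _ = synth.generate_genome(_cfg(cgi_blocks=(blk,)))
        seq = g["chr1"]
        inside = regions.cpg_oe(seq[10_000:12_000])
        outside = regions.cpg_oe(seq[20_000:22_000])
        assert inside > outside
        assert regions.gc_content(seq[10_000:12_000]) == pytest.approx(0.6, abs=0.05)

    def test_overlapping_same_strand_genes_rejected(self):
        gms = (synth.GeneModel("+", 100, 2000, ((100, 500),)),
               synth.GeneModel("+", 1500, 4000, ((1500, 1900),)))
        with pytest.raises(ValueError, match="overlapping"):
            synth.generate_genome(_cfg(gene_models=gms))

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            synth.generate_genome(_cfg(noncpg_rate=1.5))


class TestGenerateMethylome:
    def test_point_mass_at_zero_means_no_methylated_reads(self):
        cfg = _cfg(level_mixture=((1.0, 0.0),))
        g, _ = synth.generate_genome(cfg)
        calls, truth = synth.generate_methylome(g, cfg)
        cg = calls[calls["context"] == "CG"]
        assert (cg["mc_reads"] == 0).all()

    def test_point_mass_at_one_saturates_reads(self):
        cfg = _cfg(level_mixture=((1.0, 1.0),))
        g, _ = synth.generate_genome(cfg)
        calls, _ = synth.generate_methylome(g, cfg)
        cg = calls[calls["context"] == "CG"]
        assert (cg["mc_reads"] == cg["total_reads"]).all()

    def test_mixture_mean_recovered(self):
        cfg = _cfg(genome_length=200_000,
                   level_mixture=((0.5, 0.3), (0.5, 0.9)))
        g, _ = synth.generate_genome(cfg)
        _, truth = synth.generate_methylome(g, cfg)
        lv = truth.loc[truth["context"] == "CG", "true_level"]
        assert len(lv) > 10_000
        se = lv.std() / np.sqrt(len(lv) / 2)  # dinucleotide sharing halves n
        assert lv.mean() == pytest.approx(0.6, abs=3 * se)

    def test_strand_symmetry_of_planted_levels(self):
        cfg = _cfg()
        g, _ = synth.generate_genome(cfg)
        _, truth = synth.generate_methylome(g, cfg)
        cg = truth[truth["context"] == "CG"]
        plus = cg[cg["strand"] == "+"].set_index("pos")["true_level"]
        minus = cg[cg["strand"] == "-"].set_index("pos")["true_level"]
        # the minus-strand C sits one base right of its plus-strand partner
        shared = plus.index.intersection(minus.index - 1)
        assert len(shared) > 100
        assert np.allclose(plus.loc[shared].to_numpy(),
                           minus.loc[shared + 1].to_numpy())

    def test_every_cpg_gets_both_strand_calls(self):
        cfg = _cfg()
        g, _ = synth.generate_genome(cfg)
        calls, truth = synth.generate_methylome(g, cfg)
        assert len(calls) == len(truth)
        seq = g["chr1"]
        n_dinuc = sum(1 for i in range(len(seq) - 1) if seq[i:i+2] == "CG")
        assert (calls["context"] == "CG").sum() == 2 * n_dinuc

    def test_calls_sit_on_reference_cytosines(self):
        cfg = _cfg()
        g, _ = synth.generate_genome(cfg)
        calls, _ = synth.generate_methylome(g, cfg)
        for ctx in ("CG", "CHG", "CHH"):
            sub = calls[calls["context"] == ctx]
            kept, dropped = methylome.filter_reference_context(sub, g, ctx)
            assert dropped == 0

    def test_coverage_is_shifted_poisson(self):
        cfg = _cfg(coverage_mean=5.0)
        g, _ = synth.generate_genome(cfg)
        calls, _ = synth.generate_methylome(g, cfg)
        assert calls["total_reads"].min() >= 1
        assert calls["total_reads"].mean() == pytest.approx(5.0, rel=0.05)


class TestGenerateSnps:
    def test_zero_rates_give_empty_table(self):
        cfg = _cfg(class_snp_rate={c: 0.0 for c in METH_CLASSES},
                   noncpg_rate=0.0)
        g, _ = synth.generate_genome(cfg)
        calls, truth = synth.generate_methylome(g, cfg)
        snps, truth = synth.generate_snps(g, truth, cfg)
        assert len(snps) == 0 and not truth["snp"].any()

    def test_uniform_rate_count_within_binomial_ci(self):
        cfg = _cfg(genome_length=200_000,
                   class_snp_rate={c: 0.05 for c in METH_CLASSES},
                   noncpg_call_fraction=0.0)
        g, _ = synth.generate_genome(cfg)
        calls, truth = synth.generate_methylome(g, cfg)
        snps, _ = synth.generate_snps(g, truth, cfg)
        n = len(truth)
        expect = 0.05 * n
        assert abs(len(snps) - expect) < 3 * np.sqrt(expect * 0.95)

    def test_pure_transition_weight_forces_t_or_a(self):
        cfg = _cfg(transition_weight=1.0)
        g, _ = synth.generate_genome(cfg)
        _, truth = synth.generate_methylome(g, cfg)
        snps, _ = synth.generate_snps(g, truth, cfg)
        plus = snps[snps["ref"] == "C"]
        minus = snps[snps["ref"] == "G"]
        assert (plus["alt"] == "T").all()
        assert (minus["alt"] == "A").all()
        assert len(plus) and len(minus)

    def test_every_snp_sits_on_a_genomic_c_or_g(self):
        cfg = _cfg()
        g, _ = synth.generate_genome(cfg)
        _, truth = synth.generate_methylome(g, cfg)
        snps, truth = synth.generate_snps(g, truth, cfg)
        seq = g["chr1"]
        assert all(seq[p] in "CG" for p in snps["pos"])
        assert truth["snp"].sum() == len(snps)

    def test_planted_rate_recoverable_per_class(self):
        cfg = _cfg(genome_length=500_000)
        g, _ = synth.generate_genome(cfg)
        _, truth = synth.generate_methylome(g, cfg)
        snps, truth = synth.generate_snps(g, truth, cfg)
        cg = truth[truth["context"] == "CG"]
        for cls, grp in cg.groupby("true_class", observed=True):
            if len(grp) < 500:
                continue
            p = cfg.class_snp_rate[str(cls)]
            se = np.sqrt(p * (1 - p) / len(grp))
            assert grp["snp"].mean() == pytest.approx(p, abs=3 * se)


class TestGenerateOutgroup:
    def test_zero_rates_give_identity(self):
        cfg = _cfg(class_div_rate={c: 0.0 for c in METH_CLASSES},
                   background_div_rate=0.0)
        g, _ = synth.generate_genome(cfg)
        _, truth = synth.generate_methylome(g, cfg)
        outg, truth = synth.generate_outgroup(g, truth, cfg)
        assert outg == g and not truth["divergent"].any()

    def test_background_rate_recovered_off_cpg(self):
        cfg = _cfg(genome_length=150_000, background_div_rate=0.02,
                   class_div_rate={c: 0.0 for c in METH_CLASSES})
        g, _ = synth.generate_genome(cfg)
        _, truth = synth.generate_methylome(g, cfg)
        outg, truth = synth.generate_outgroup(g, truth, cfg)
        a = np.frombuffer(g["chr1"].encode(), np.uint8)
        b = np.frombuffer(outg["chr1"].encode(), np.uint8)
        mask = np.ones(len(a), bool)
        cg = truth.loc[truth["context"] == "CG", "pos"].to_numpy()
        mask[cg] = False
        n = int(mask.sum())
        rate = float((a != b)[mask].mean())
        se = np.sqrt(0.02 * 0.98 / n)
        assert rate == pytest.approx(0.02, abs=3 * se)

    def test_class_rate_recovered_at_cpg(self):
        cfg = _cfg(genome_length=300_000,
                   level_mixture=((1.0, 0.9),),
                   class_div_rate={**{c: 0.0 for c in METH_CLASSES},
                                   "high": 0.10},
                   background_div_rate=0.0)
        g, _ = synth.generate_genome(cfg)
        _, truth = synth.generate_methylome(g, cfg)
        _, truth = synth.generate_outgroup(g, truth, cfg)
        cg = truth[truth["context"] == "CG"]
        n = len(cg)
        se = np.sqrt(0.1 * 0.9 / n)
        assert cg["divergent"].mean() == pytest.approx(0.10, abs=3 * se)


class TestGenerateAlleleFreqs:
    def test_degenerate_coupling_is_constant(self):
        cfg = _cfg(freq_coupling=synth.FreqCoupling(0.0, 0.5, 0.0))
        g, _ = synth.generate_genome(cfg)
        _, truth = synth.generate_methylome(g, cfg)
        snps, truth = synth.generate_snps(g, truth, cfg)
        freqs, truth = synth.generate_allele_freqs(snps, truth, cfg)
        assert (freqs["freqA"] == 0.5).all()
        assert np.allclose(freqs["freqA"] + freqs["freqB"], 1.0)

    def test_certain_outgroup_gives_all_cytosine_ancestors(self):
        from cpgmut import alleles as al
        cfg = _cfg(outgroup_c_prob=1.0, outgroup_alt_prob=0.0)
        g, _ = synth.generate_genome(cfg)
        _, truth = synth.generate_methylome(g, cfg)
        snps, truth = synth.generate_snps(g, truth, cfg)
        freqs, _ = synth.generate_allele_freqs(snps, truth, cfg)
        anc = al.infer_ancestral(freqs)
        assert (anc == freqs["alleleA"]).all()  # alleleA is the cytosine base

    def test_target_r_realised_by_closed_form_slope(self):
        mixture = ((0.25, 0.2), (0.25, 0.4), (0.25, 0.6), (0.25, 0.8))
        slope = synth.slope_for_target_r(0.4, mixture, noise_sd=0.1,
                                         coverage_mean=50)
        cfg = _cfg(genome_length=400_000, coverage_mean=50.0,
                   level_mixture=mixture,
                   class_snp_rate={c: 0.2 for c in METH_CLASSES},
                   noncpg_call_fraction=0.0,
                   freq_coupling=synth.FreqCoupling(slope, 0.5 - slope * 0.5, 0.1))
        bundle = synth.generate_bundle(cfg)
        sub = bundle.truth.dropna(subset=["c_freq"])
        r = np.corrcoef(sub["true_level"], sub["c_freq"])[0, 1]
        # truth-level correlation exceeds the observed-level target because
        # the slope compensates for binomial read noise
        assert len(sub) > 5000
        assert r == pytest.approx(0.4, abs=0.08)


class TestBundleDeterminism:
    def test_same_seed_same_files(self, tmp_path):
        cfg = _cfg(genome_length=30_000)
        b1 = synth.generate_bundle(cfg, outdir=tmp_path / "a")
        b2 = synth.generate_bundle(cfg, outdir=tmp_path / "b")
        for name in b1.paths:
            f1 = b1.paths[name].read_bytes()
            f2 = b2.paths[name].read_bytes()
            assert f1 == f2, f"{name} differs between identical runs"

    def test_different_seed_different_genome(self):
        g1, _ = synth.generate_genome(_cfg(seed=1))
        g2, _ = synth.generate_genome(_cfg(seed=2))
        assert g1 != g2

    def test_truth_rows_match_calls(self):
        bundle = synth.generate_bundle(_cfg())
        assert len(bundle.truth) == len(bundle.calls)
        pd.testing.assert_frame_equal(
            bundle.truth[["chrom", "pos", "strand", "context"]],
            bundle.calls[["chrom", "pos", "strand", "context"]])

    def test_written_files_reparse_consistently(self, tmp_path):
        bundle = synth.generate_bundle(_cfg(genome_length=30_000),
                                       outdir=tmp_path)
        calls = methylome.read_methylome(bundle.paths["methylome"])
        pd.testing.assert_frame_equal(calls, bundle.calls)
        snps, counts = rates.read_snps(bundle.paths["snps"])
        assert counts["kept"] == len(bundle.snps)
        pairs = rates.read_alignment(bundle.paths["alignment"])
        assert len(pairs) > 25_000  # whole chromosome, minus N columns


class TestClassProportionConvergence:
    """Observed class proportions approach the mixture weights as coverage
    grows (mid-bin levels still leak across bin edges at finite reads)."""

    def _tv_distance(self, coverage):
        cfg = _cfg(genome_length=150_000, coverage_mean=coverage,
                   noncpg_call_fraction=0.0)
        g, _ = synth.generate_genome(cfg)
        calls, _ = synth.generate_methylome(g, cfg)
        obs = methylome.add_level_and_class(calls)["meth_class"] \
            .value_counts(normalize=True, sort=False)
        weights = dict(zip(METH_CLASSES, [0.30] + [0.14] * 5))
        return 0.5 * sum(abs(obs.get(c, 0.0) - weights[c])
                         for c in METH_CLASSES)

    def test_total_variation_shrinks_with_coverage(self):
        d5, d20, d100 = (self._tv_distance(c) for c in (5.0, 20.0, 100.0))
        assert d5 > d20 > d100
        assert d100 < 0.02
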
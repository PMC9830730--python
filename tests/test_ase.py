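"""ΔAAF cascade: SNV calling, SSR/mask filtration, group testing,
final-ASE selection, and consequence annotation with brute-force oracles."""

import numpy as np
import pytest
from Bio.Seq import Seq

from emboliseq.ase import (
    ASE_SD_THRESHOLD,
    SSR_MIN_REPEATS,
    annotate_consequence,
    build_region_masks,
    call_snvs,
    consequence_proportions,
    delta_aaf_test,
    detect_ssrs,
    filter_sites_by_mask,
    select_final_ases,
    _smallest_period,
)
from emboliseq.models import (
    AlleleSite,
    GenomeModel,
    RegionMask,
    TranscriptModel,
    revcomp,
)
from emboliseq.simulate import SimulationConfig, simulate_allele_counts


def _site(design, depths, alts, chrom="c", pos=100):
    samples = design.sample_ids
    ref = {s: depths[i] - alts[i] for i, s in enumerate(samples)}
    alt = {s: alts[i] for i, s in enumerate(samples)}
    return AlleleSite(chrom, pos, "A", "G", ref, alt)


class TestCallSnvs:
    def test_one_low_coverage_sample_rejects(self, design):
        depths = [10] * 11
        depths[3] = 9
        site = _site(design, depths, [5] * 11)
        assert call_snvs([site], design) == []

    def test_no_alt_support_rejects(self, design):
        site = _site(design, [10] * 11, [0] * 11)
        assert call_snvs([site], design) == []

    def test_supported_site_retained(self, design):
        alts = [0] * 11
        alts[0] = 5
        site = _site(design, [20] * 11, alts)
        assert call_snvs([site], design) == [site]


# ---------------------------------------------------------------------------
# SSR detection + brute-force oracle

def _oracle_ssrs(seq: str) -> set[tuple[int, int]]:
    """Independent scalar enumeration of leftmost maximal tandem runs."""
    out = set()
    n = len(seq)
    for k in range(1, 7):
        m = SSR_MIN_REPEATS[k]
        for i in range(n - k + 1):
            if i >= 1 and i - 1 + k < n and seq[i - 1] == seq[i - 1 + k]:
                continue  # periodicity extends left: not a run start
            motif = seq[i : i + k]
            if "N" in motif or _smallest_period(motif) != k:
                continue
            c = 1
            j = i + k
            while seq[j : j + k] == motif:
                c += 1
                j += k
            ext = 0
            while j + ext < n and ext < k - 1 and seq[j + ext] == motif[ext]:
                ext += 1
            count = (c * k + ext) // k
            if count >= m:
                out.add((i, i + count * k))
    return out


class TestDetectSsrs:
    def _intervals(self, seq):
        mask = detect_ssrs(GenomeModel(["c"], {"c": seq}))
        return set(mask.intervals.get("c", []))

    def test_mono_run_at_threshold(self):
        assert self._intervals("G" + "A" * 12 + "G") == {(1, 13)}

    def test_dinucleotide_below_threshold_ignored(self):
        assert self._intervals("G" + "AT" * 5 + "G") == set()

    def test_dinucleotide_at_threshold(self):
        assert self._intervals("G" + "AT" * 6 + "GG") == {(1, 13)}

    def test_nonprimitive_motifs_not_double_counted(self):
        ivs = self._intervals("C" + "A" * 24 + "C")
        assert ivs == {(1, 25)}

    def test_matches_bruteforce_oracle_on_random_sequences(self):
        rng = np.random.default_rng(0)
        for trial in range(300):
            seq = "".join(rng.choice(list("ACGT"), size=200))
            if trial % 3 == 0:  # inject repeats of varied motif size
                unit = ["A", "AT", "CAG", "ACGT", "AACGT", "ACGTAC"][trial % 6]
                reps = SSR_MIN_REPEATS[len(unit)] + int(rng.integers(0, 4))
                p = int(rng.integers(0, 150))
                seq = seq[:p] + unit * reps + seq[p:]
            assert self._intervals(seq) == _oracle_ssrs(seq), seq


class TestRegionMasks:
    def test_head_to_head_tss_within_window(self):
        left = TranscriptModel("g1", "t1", "c", "-", [(0, 500)])
        right = TranscriptModel("g2", "t2", "c", "+", [(1000, 1500)])
        masks = build_region_masks([left, right])
        assert masks["bidirectional"].contains("c", 700)

    def test_same_strand_genes_not_bidirectional(self):
        a = TranscriptModel("g1", "t1", "c", "+", [(0, 500)])
        b = TranscriptModel("g2", "t2", "c", "+", [(1000, 1500)])
        masks = build_region_masks([a, b])
        assert masks["bidirectional"].intervals == {}

    def test_intron_flanks_are_10bp_each_side(self):
        tm = TranscriptModel("g", "t", "c", "+", [(0, 100), (150, 250)])
        masks = build_region_masks([tm])
        assert masks["intron_flank"].intervals["c"] == [(100, 110), (140, 150)]

    def test_short_intron_fully_flanked(self):
        tm = TranscriptModel("g", "t", "c", "+", [(0, 100), (105, 200)])
        masks = build_region_masks([tm])
        for pos in range(100, 105):
            assert masks["intron_flank"].contains("c", pos)

    def test_no_pseudogene_biotype_empty_mask(self):
        tm = TranscriptModel("g", "t", "c", "+", [(0, 100)], "protein_coding")
        masks = build_region_masks([tm])
        assert masks["pseudogene"].intervals == {}

    def test_pseudogene_span_masked(self):
        tm = TranscriptModel("g", "t", "c", "+", [(0, 100)], "pseudogene")
        masks = build_region_masks([tm])
        assert masks["pseudogene"].contains("c", 50)


class TestMaskFiltration:
    def test_site_inside_mask_removed_boundary_half_open(self, design):
        mask = RegionMask("ssr", {"c": [(100, 200)]})
        inside = _site(design, [20] * 11, [5] * 11, pos=100)
        at_end = _site(design, [20] * 11, [5] * 11, pos=200)
        outside = _site(design, [20] * 11, [5] * 11, pos=99)
        kept = filter_sites_by_mask([inside, at_end, outside], [mask])
        assert [s.pos for s in kept] == [200, 99]

    def test_mask_order_does_not_change_final_set(self, design):
        masks = {
            "ssr": RegionMask("ssr", {"c": [(0, 50)]}),
            "pseudogene": RegionMask("pseudogene", {"c": [(40, 120)]}),
        }
        sites = [_site(design, [20] * 11, [5] * 11, pos=p) for p in (10, 45, 80, 150)]
        a = filter_sites_by_mask(sites, [masks["ssr"], masks["pseudogene"]])
        b = filter_sites_by_mask(sites, [masks["pseudogene"], masks["ssr"]])
        assert [s.pos for s in a] == [s.pos for s in b] == [150]


class TestDeltaAafTest:
    def test_extreme_case_sign(self, design):
        # PA-E all-ref, CTR all-alt -> ΔAAF = -1
        alts = [0] * 6 + [10] * 5
        site = _site(design, [10] * 11, alts)
        tab = delta_aaf_test([site], design)
        assert tab["delta_aaf"].iloc[0] == pytest.approx(-1.0)

    def test_identical_pooled_tables(self, design):
        site = _site(design, [20] * 11, [10] * 11)
        tab = delta_aaf_test([site], design)
        assert tab["pvalue"].iloc[0] == pytest.approx(1.0)
        assert tab["delta_aaf"].iloc[0] == pytest.approx(0.0)

    def test_dual_threshold_rule(self, design):
        tab = delta_aaf_test([], design)
        assert tab.empty
        # significance column follows |ΔAAF| > 0.3 AND FDR < 0.001 exactly
        cfg = SimulationConfig(seed=3, n_sites=300, frac_ase=0.5,
                               delta_aaf=0.5, site_depth=80)
        sites, _ = simulate_allele_counts(cfg)
        tab = delta_aaf_test(sites, cfg.design())
        manual = (tab["delta_aaf"].abs() > 0.3) & (tab["fdr"] < 0.001)
        assert (tab["is_significant"] == manual).all()

    def test_label_swap_negates_delta_aaf(self, design):
        cfg = SimulationConfig(seed=4, n_sites=50)
        sites, _ = simulate_allele_counts(cfg)
        a = delta_aaf_test(sites, cfg.design())
        b = delta_aaf_test(sites, cfg.design().swapped())
        assert np.allclose(a["delta_aaf"], -b["delta_aaf"], equal_nan=True)

    def test_chi2_alternative_agrees_roughly(self, design):
        cfg = SimulationConfig(seed=5, n_sites=100, frac_ase=0.3,
                               delta_aaf=0.6, site_depth=60)
        sites, _ = simulate_allele_counts(cfg)
        fisher = delta_aaf_test(sites, cfg.design(), method="fisher")
        chi2 = delta_aaf_test(sites, cfg.design(), method="chi2")
        agree = (fisher["is_significant"] == chi2["is_significant"]).mean()
        assert agree > 0.9


class TestFinalAseSelection:
    def _table(self):
        import pandas as pd

        return pd.DataFrame(
            {"chrom": ["c"] * 3, "pos": [1, 2, 3],
             "sd_case": [0.0, 0.5, 0.0], "sd_ctrl": [0.05, 0.5, 0.0],
             "is_significant": [True, True, False],
             "delta_aaf": [0.5, 0.5, 0.5], "fdr": [1e-5, 1e-5, 0.5]}
        )

    def test_low_sd_significant_site_retained_first(self):
        out = select_final_ases(self._table())
        assert list(out["pos"]) == [1]

    def test_high_sd_dropped(self):
        out = select_final_ases(self._table())
        assert 2 not in set(out["pos"])

    def test_nonsignificant_never_selected_even_at_sd_zero(self):
        out = select_final_ases(self._table())
        assert 3 not in set(out["pos"])

    def test_threshold_configurable(self):
        out = select_final_ases(self._table(), sd_threshold=1.0)
        assert list(out["pos"]) == [1, 2]


# ---------------------------------------------------------------------------
# consequence annotation + brute-force oracle

def _random_locus(rng):
    """Random plus-strand coding transcript on a random genome."""
    n_exons = int(rng.integers(2, 4))
    pos = int(rng.integers(5, 20))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(30, 90)) * 3
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(20, 60))
    glen = pos + 40
    seq = "".join(rng.choice(list("ACGT"), size=glen))
    cds_start = exons[0][0] + 6
    cds_len = sum(e - s for s, e in exons) - 12
    cds_len -= cds_len % 3
    # walk cds_len coding bases forward from cds_start through the exons
    remaining = cds_len
    cds_end = None
    for s, e in exons:
        lo = max(s, cds_start)
        if lo >= e:
            continue
        take = min(remaining, e - lo)
        remaining -= take
        if remaining == 0:
            cds_end = lo + take
            break
    tm = TranscriptModel("g", "t", "c", "+", exons, "protein_coding",
                         cds_start=cds_start, cds_end=cds_end)
    return GenomeModel(["c"], {"c": seq}), tm


def _oracle_consequence(genome, tm, pos, alt):
    """Translate-everything oracle for a plus-strand CDS substitution."""
    cds_exons = [(max(s, tm.cds_start), min(e, tm.cds_end))
                 for s, e in tm.exons if min(e, tm.cds_end) > max(s, tm.cds_start)]
    ref_cds = "".join(genome.fetch("c", s, e) for s, e in cds_exons)
    mutated = dict()
    flat = []
    for s, e in cds_exons:
        flat.extend(range(s, e))
    if pos not in flat:
        return None
    alt_cds = list(ref_cds)
    alt_cds[flat.index(pos)] = alt
    alt_cds = "".join(alt_cds)
    p_ref = str(Seq(ref_cds[: len(ref_cds) // 3 * 3]).translate())
    p_alt = str(Seq(alt_cds[: len(alt_cds) // 3 * 3]).translate())
    return "synonymous" if p_ref == p_alt else "missense"


class TestConsequenceAnnotation:
    def test_missense_codon_change(self):
        seq = "AAAA" + "ATGGATGAATAG" + "AAAA"
        g = GenomeModel(["c"], {"c": seq})
        tm = TranscriptModel("g1", "t1", "c", "+", [(0, 20)], "protein_coding",
                             cds_start=4, cds_end=16)
        site = AlleleSite("c", 9, "T", "A", {"s": 10}, {"s": 5})
        ann = annotate_consequence([site], [tm], g).iloc[0]
        assert ann["consequence"] == "missense"
        assert (ann["ref_codon"], ann["alt_codon"]) == ("GAT", "GAA")
        assert (ann["ref_aa"], ann["alt_aa"]) == ("D", "E")

    def test_wobble_synonymous(self):
        seq = "AAAA" + "ATGGGATAA" + "AAAA"
        g = GenomeModel(["c"], {"c": seq})
        tm = TranscriptModel("g1", "t1", "c", "+", [(0, 17)], "protein_coding",
                             cds_start=4, cds_end=13)
        # third position of GGA -> GGG: glycine either way
        site = AlleleSite("c", 9, "A", "G", {"s": 10}, {"s": 5})
        ann = annotate_consequence([site], [tm], g).iloc[0]
        assert ann["consequence"] == "synonymous"
        assert (ann["ref_aa"], ann["alt_aa"]) == ("G", "G")

    def test_positional_classes(self):
        tm = TranscriptModel("g1", "t1", "c", "+",
                             [(1000, 1100), (1200, 1300)], "protein_coding",
                             cds_start=1050, cds_end=1250)
        g = GenomeModel(["c"], {"c": "A" * 2000})
        expect = {
            500: "upstream", 1020: "five_prime_utr", 1150: "intron",
            1198: "splice_acceptor", 1199: "splice_acceptor",
            1280: "three_prime_utr", 1500: "downstream",
        }
        for pos, cls in expect.items():
            site = AlleleSite("c", pos, "A", "G", {"s": 10}, {"s": 5})
            ann = annotate_consequence([site], [tm], g).iloc[0]
            assert ann["consequence"] == cls, (pos, cls, ann["consequence"])

    def test_intergenic_excluded_from_tally(self):
        tm = TranscriptModel("g1", "t1", "c", "+", [(0, 100)])
        g = GenomeModel(["c"], {"c": "A" * 20000})
        site = AlleleSite("c", 15000, "A", "G", {"s": 10}, {"s": 5})
        ann = annotate_consequence([site], [tm], g)
        assert ann["consequence"].iloc[0] == "intergenic"
        props = consequence_proportions(ann)
        assert all(v == 0.0 for v in props.values())

    def test_matches_translation_oracle_on_random_cds(self):
        rng = np.random.default_rng(11)
        checked = 0
        for _ in range(300):
            genome, tm = _random_locus(rng)
            # pick a CDS position
            cds_positions = [
                p for s, e in tm.exons for p in range(s, e)
                if tm.cds_start <= p < tm.cds_end
            ]
            pos = int(rng.choice(cds_positions))
            ref = genome.fetch("c", pos, pos + 1)
            alt = rng.choice([b for b in "ACGT" if b != ref])
            expected = _oracle_consequence(genome, tm, pos, alt)
            site = AlleleSite("c", pos, ref, alt, {"s": 10}, {"s": 5})
            got = annotate_consequence([site], [tm], genome).iloc[0]["consequence"]
            assert got == expected, (pos, ref, alt)
            checked += 1
        assert checked == 300

    def test_strand_symmetry_exact(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            genome, tm = _random_locus(rng)
            L = genome.length("c")
            pos = int(rng.integers(tm.start - 5, tm.end + 5))
            pos = max(0, min(L - 1, pos))
            ref = genome.fetch("c", pos, pos + 1)
            alt = rng.choice([b for b in "ACGT" if b != ref])
            fwd = annotate_consequence(
                [AlleleSite("c", pos, ref, alt, {"s": 10}, {"s": 5})],
                [tm], genome).iloc[0]["consequence"]
            # mirror the whole locus
            rseq = revcomp(genome.sequences["c"])
            g2 = GenomeModel(["c"], {"c": rseq})
            rex = sorted((L - e, L - s) for s, e in tm.exons)
            tm2 = TranscriptModel("g", "t", "c", "-", rex, "protein_coding",
                                  cds_start=L - tm.cds_end,
                                  cds_end=L - tm.cds_start)
            site2 = AlleleSite("c", L - 1 - pos, revcomp(ref), revcomp(alt),
                               {"s": 10}, {"s": 5})
            rev = annotate_consequence([site2], [tm2], g2).iloc[0]["consequence"]
            assert fwd == rev, (pos, fwd, rev)


def test_null_sites_pass_rate_bounded(design):
    cfg = SimulationConfig(seed=50, n_sites=2000, frac_ase=0.0)
    sites, _ = simulate_allele_counts(cfg)
    tab = delta_aaf_test(sites, cfg.design())
    assert tab["is_significant"].mean() <= 0.001 + 0.002


def test_sensitivity_for_planted_delta_aaf(design):
    cfg = SimulationConfig(seed=51, n_sites=500, frac_ase=1.0,
                           delta_aaf=0.5, site_depth=30)
    sites, _ = simulate_allele_counts(cfg)
    tab = delta_aaf_test(sites, cfg.design())
    assert tab["is_significant"].mean() >= 0.9
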
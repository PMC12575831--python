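import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_counts
from psidelta.core_io import GeneModel, SequenceStore
from psidelta.psi_calling import (
    CallParams,
    LibrarySet,
    annotate_motif,
    assign_species,
    call_sites,
    deletion_ratio,
    differential_sites,
    pooled_t_test,
)
from psidelta.synthetic_data import PileupSimSpec, simulate_pileups

LIBS = LibrarySet("c", ("bs_1", "bs_2", "bs_3"), ("in_1", "in_2", "in_3"))


def brute_force_call(counts: pd.DataFrame, libs: LibrarySet, params: CallParams):
    """Plain per-site evaluation of the five predicates, no vectorization.

    Independent reference for call_sites; intentionally naive. Assumes
    plus-strand sites (reference base T = U).
    """
    by_key = {}
    for row in counts.itertuples(index=False):
        by_key.setdefault((row.chrom, row.pos0, row.ref_base), {})[row.library_id] = (
            row.depth, row.del_count,
        )
    called = []
    for (chrom, pos0, ref), libmap in sorted(by_key.items()):
        ok = True
        for lib in libs.treated_replicates:
            if lib not in libmap:
                ok = False  # criterion 5
                break
            depth, dels = libmap[lib]
            if depth <= params.min_depth:
                ok = False  # criterion 3
                break
            if not (dels / depth > params.min_treated_ratio and dels > params.min_del_count):
                ok = False  # criterion 1
                break
        if ok:
            for lib in libs.input_replicates:
                if lib not in libmap:
                    ok = False  # absent input -> fails depth
                    break
                depth, dels = libmap[lib]
                if depth <= params.min_depth:
                    ok = False
                    break
                if not dels / depth < params.max_input_ratio:
                    ok = False  # criterion 2
                    break
        if ok and ref != "T":
            ok = False  # criterion 4, plus strand
        if ok:
            called.append((chrom, pos0))
    return called


class TestDeletionRatio:
    @pytest.mark.parametrize("depth,dels,expected", [(100, 7, 0.07), (20, 0, 0.0), (3, 3, 1.0)])
    def test_values(self, depth, dels, expected):
        assert deletion_ratio(depth, dels) == pytest.approx(expected)

    def test_zero_depth_is_an_error(self):
        with pytest.raises(ZeroDivisionError):
            deletion_ratio(0, 0)


def _site_rows(pos0=100, treated=((100, 7), (100, 8), (100, 9)),
               inputs=((100, 1), (100, 1), (100, 1)), ref="T"):
    rows = []
    for lib, (d, x) in zip(LIBS.treated_replicates, treated):
        rows.append(("chr1", pos0, ref, d, x, lib))
    for lib, (d, x) in zip(LIBS.input_replicates, inputs):
        rows.append(("chr1", pos0, ref, d, x, lib))
    return rows


class TestCallSites:
    def test_clean_site_is_called_with_treated_ratios_as_fractions(self):
        sites = call_sites(make_counts(_site_rows()), LIBS)
        assert len(sites) == 1
        assert sites[0].per_replicate_fraction == pytest.approx([0.07, 0.08, 0.09])
        assert sites[0].mean_fraction == pytest.approx(0.08)
        assert all(sites[0].pass_flags.values())

    def test_deletion_count_threshold_is_strict(self):
        # one treated replicate at exactly del_count = 4 -> not called
        rows = _site_rows(treated=((100, 7), (100, 8), (60, 4)))
        assert call_sites(make_counts(rows), LIBS) == []
        # at 5 the site passes
        rows = _site_rows(treated=((100, 7), (100, 8), (60, 5)))
        assert len(call_sites(make_counts(rows), LIBS)) == 1

    def test_depth_threshold_is_strict(self):
        rows = _site_rows(inputs=((100, 1), (100, 1), (20, 0)))
        assert call_sites(make_counts(rows), LIBS) == []
        rows = _site_rows(inputs=((100, 1), (100, 1), (21, 0)))
        assert len(call_sites(make_counts(rows), LIBS)) == 1

    def test_input_ratio_threshold_is_strict(self):
        rows = _site_rows(inputs=((100, 2), (100, 1), (100, 1)))  # 0.02 not < 0.02
        assert call_sites(make_counts(rows), LIBS) == []
        rows = _site_rows(inputs=((1000, 19), (100, 1), (100, 1)))  # 0.019
        assert len(call_sites(make_counts(rows), LIBS)) == 1

    def test_treated_ratio_threshold_is_strict(self):
        rows = _site_rows(treated=((100, 5), (100, 8), (100, 9)))  # 0.05 not > 0.05
        assert call_sites(make_counts(rows), LIBS) == []

    def test_missing_treated_replicate_fails(self):
        rows = [r for r in _site_rows() if r[5] != "bs_2"]
        assert call_sites(make_counts(rows), LIBS) == []

    def test_missing_input_library_is_not_treated_as_clean(self):
        rows = [r for r in _site_rows() if r[5] != "in_3"]
        assert call_sites(make_counts(rows), LIBS) == []

    def test_minus_strand_u_site_needs_reference_a(self):
        gene = [GeneModel("g", "chr1", "-", 500, 50, "snRNA")]
        plus_a = call_sites(make_counts(_site_rows(ref="A")), LIBS)
        assert plus_a == []  # A on an (assumed) plus-strand site is not U
        minus_a = call_sites(make_counts(_site_rows(ref="A")), LIBS, gene_models=gene)
        assert len(minus_a) == 1 and minus_a[0].strand == "-"
        minus_t = call_sites(make_counts(_site_rows(ref="T")), LIBS, gene_models=gene)
        assert minus_t == []

    def test_output_sorted_by_position(self):
        rows = _site_rows(pos0=900) + _site_rows(pos0=100)
        sites = call_sites(make_counts(rows), LIBS)
        assert [s.pos0 for s in sites] == [100, 900]

    def test_oracle_equivalence_on_simulated_table(self):
        spec = PileupSimSpec(
            n_sites=400, true_fraction=np.linspace(0.01, 0.95, 400),
            depth_mean=40.0, conversion_rate=0.9, seed=5,
            decoy_non_u=40, decoy_low_depth=40, decoy_high_input=40,
        )
        counts, _ = simulate_pileups(spec)
        params = CallParams()
        expected = brute_force_call(counts, LIBS, params)
        got = [(s.chrom, s.pos0) for s in call_sites(counts, LIBS, params)]
        assert got == expected
        assert 0 < len(got) < 520

    @pytest.mark.parametrize(
        "tighter",
        [
            {"min_treated_ratio": 0.10},
            {"min_depth": 40},
            {"min_del_count": 8},
            {"max_input_ratio": 0.005},
        ],
    )
    def test_tightening_parameters_only_removes_sites(self, tighter):
        counts, _ = simulate_pileups(
            PileupSimSpec(n_sites=300, true_fraction=np.linspace(0.02, 0.9, 300),
                          depth_mean=35.0, seed=7)
        )
        base = {(s.chrom, s.pos0) for s in call_sites(counts, LIBS)}
        tight = {(s.chrom, s.pos0) for s in call_sites(counts, LIBS, CallParams(**tighter))}
        assert tight <= base


class TestDifferential:
    def test_identical_groups_are_null(self):
        res = differential_sites({"s": [0.5, 0.5, 0.5]}, {"s": [0.5, 0.5, 0.5]})
        assert res[0].t_statistic == 0.0
        assert res[0].p_value == 1.0
        assert not res[0].significant

    def test_matches_independent_pooled_t_reference(self):
        # closed-form pooled t with 4 df, computed independently and frozen
        res = differential_sites({"s": [0.70, 0.75, 0.80]}, {"s": [0.45, 0.50, 0.55]})[0]
        assert res.t_statistic == pytest.approx(6.123724356957942, rel=1e-9)
        assert res.p_value == pytest.approx(0.003602232609104011, rel=1e-9)
        assert res.significant and res.direction == "reduced"
        assert res.delta == pytest.approx(-0.25)

    def test_single_replicate_sites_excluded(self):
        res = differential_sites({"a": [0.5], "b": [0.4, 0.5, 0.6]},
                                 {"a": [0.6, 0.7], "b": [0.4, 0.5, 0.6]})
        assert [r.site for r in res] == ["b"]

    def test_zero_variance_unequal_means_degenerate(self):
        res = differential_sites({"s": [0.8, 0.8]}, {"s": [0.2, 0.2]})[0]
        assert res.p_value == 0.0 and res.degenerate

    def test_sorted_by_p_and_fdr_attached(self):
        res = differential_sites(
            {"a": [0.5, 0.51, 0.49], "b": [0.5, 0.52, 0.48]},
            {"a": [0.9, 0.91, 0.89], "b": [0.52, 0.50, 0.48]},
        )
        ps = [r.p_value for r in res]
        assert ps == sorted(ps)
        assert all(r.fdr is not None and r.fdr >= r.p_value for r in res)

    def test_null_rejection_rate_is_calibrated(self):
        # conditions simulated at identical fraction: type-I error ~ alpha
        rng = np.random.default_rng(12)
        n = 4000
        a = {f"s{i}": rng.normal(0.5, 0.05, 3) for i in range(n)}
        b = {f"s{i}": rng.normal(0.5, 0.05, 3) for i in range(n)}
        res = differential_sites(a, b)
        rate = sum(r.significant for r in res) / n
        assert 0.035 <= rate <= 0.065


class TestAnnotateMotif:
    @pytest.fixture()
    def seqs(self):
        #            0123456789
        return SequenceStore({"c": "AATGTAGAACTACAAGTGTACA"})
        # TGTAG at 2..6 (psi at 4, +); CTACA at 9..13 (revcomp TGTAG, psi at 11, -)
        # TGTAC at 16..20 -> R=C fails

    def test_plus_strand_ugua_r_matches(self, seqs):
        assert annotate_motif(seqs, "c", 4, "+")

    def test_minus_strand_reverse_complement_matches(self, seqs):
        assert annotate_motif(seqs, "c", 11, "-")

    def test_r_must_be_purine(self, seqs):
        assert not annotate_motif(seqs, "c", 18, "+")  # TGTAC

    def test_contig_edge_is_false_not_error(self, seqs):
        assert not annotate_motif(seqs, "c", 0, "+")

    def test_n_never_matches(self):
        seqs = SequenceStore({"c": "TGTNG" + "A" * 5})
        assert not annotate_motif(seqs, "c", 2, "+")


class TestAssignSpecies:
    MODELS = [
        GeneModel("t1", "c", "+", 100, 199, "tRNA"),
        GeneModel("m1", "c", "+", 50, 500, "protein_coding"),
        GeneModel("l1", "c", "-", 900, 700, "lncRNA"),
    ]
    EXONS = {"m1": [(50, 120), (400, 501)]}

    def test_trna_wins_over_intron(self):
        assert assign_species("c", 150, self.MODELS, self.EXONS) == "tRNA"

    def test_intron_of_coding_gene(self):
        assert assign_species("c", 300, self.MODELS, self.EXONS) == "intron"

    def test_exon_is_mrna(self):
        assert assign_species("c", 450, self.MODELS, self.EXONS) == "mRNA"

    def test_no_overlap_is_other(self):
        assert assign_species("c", 5000, self.MODELS) == "other"

    def test_lncrna(self):
        assert assign_species("c", 800, self.MODELS) == "lncRNA"


class TestPooledT:
    def test_matches_hand_computation(self):
        t, p, degenerate = pooled_t_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert t == pytest.approx(-math.sqrt(3) / math.sqrt(2), rel=1e-12)
        assert not degenerate
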
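"""Locus aggregation, conditional analysis and GWAS conditioning."""

import itertools

import numpy as np
import pytest

from oracles import brute_conditional_z
from twaskit.datatypes import GeneCorrelation, Locus, TwasResult
from twaskit.loci import (
    aggregate_loci,
    condition_gwas_on_expression,
    conditional_twas,
    conditional_z_score,
    map_to_gwas_loci,
    predicted_expression_correlation,
)
from twaskit.simulate import (
    SimulationConfig,
    gene_layout,
    simulate_gwas_z,
    simulate_reference_panel,
    simulate_weight_set,
)
from twaskit.twas import compute_ld, run_transcriptome_scan, z_to_p
from conftest import make_panel, make_weight_set


def gene(gid, chrom, start, end, z=6.0):
    return TwasResult(gene_id=gid, chrom=chrom, start=start, end=end,
                      twas_z=z, twas_p=z_to_p(z), top_gwas_snp="s",
                      top_gwas_z=z, top_eqtl_snp="s", top_eqtl_z=1.0,
                      n_snps_used=1, significant=True)


# -------------------------------------------------------------- aggregation

class TestAggregateLoci:
    def test_nearby_genes_merge(self):
        loci = aggregate_loci([gene("A", "1", 1_000_000, 1_010_000),
                               gene("B", "1", 1_400_000, 1_410_000)])
        assert len(loci) == 1 and loci[0].members == ["A", "B"]

    def test_chain_merging_is_transitive(self):
        # A-B and B-C within 500 kb, A-C not
        loci = aggregate_loci([gene("A", "1", 1_000_000, 1_000_100),
                               gene("B", "1", 1_400_000, 1_400_100),
                               gene("C", "1", 1_800_000, 1_800_100)])
        assert len(loci) == 1 and loci[0].members == ["A", "B", "C"]

    def test_distant_and_cross_chromosome_genes_split(self):
        loci = aggregate_loci([gene("A", "1", 1_000_000, 1_010_000),
                               gene("B", "1", 2_000_000, 2_010_000),
                               gene("C", "2", 1_000_000, 1_010_000)])
        assert [l.members for l in loci] == [["A"], ["B"], ["C"]]

    def test_lead_gene_is_max_abs_z(self):
        loci = aggregate_loci([gene("A", "1", 1_000_000, 1_010_000, z=5.0),
                               gene("B", "1", 1_100_000, 1_110_000, z=-7.0)])
        assert loci[0].lead_gene == "B"

    def test_matches_brute_force_transitive_closure(self):
        """Random instances vs union-find over the pairwise window relation."""
        rng = np.random.default_rng(21)
        for _ in range(50):
            n = int(rng.integers(1, 12))
            genes = []
            for i in range(n):
                s = int(rng.integers(0, 10_000_000))
                genes.append(gene(f"g{i}", str(rng.integers(1, 3)),
                                  s, s + int(rng.integers(1, 50_000))))
            loci = aggregate_loci(genes)
            # brute force: connected components of the <=500kb gap graph
            parent = list(range(n))

            def find(x):
                while parent[x] != x:
                    x = parent[x]
                return x

            for i, j in itertools.combinations(range(n), 2):
                a, b = genes[i], genes[j]
                gap = max(0, b.start - a.end, a.start - b.end)
                if a.chrom == b.chrom and gap <= 500_000:
                    parent[find(i)] = find(j)
            comps = {}
            for i in range(n):
                comps.setdefault(find(i), set()).add(genes[i].gene_id)
            ours = {frozenset(l.members) for l in loci}
            assert ours == {frozenset(c) for c in comps.values()}

    def test_idempotent_order_invariant_partition(self):
        rng = np.random.default_rng(22)
        genes = [gene(f"g{i}", "1", int(p), int(p) + 10_000)
                 for i, p in enumerate(
                     np.sort(rng.integers(0, 20_000_000, size=15)))]
        loci = aggregate_loci(genes)
        shuffled = list(genes)
        rng.shuffle(shuffled)
        assert [l.members for l in aggregate_loci(shuffled)] == \
               [l.members for l in loci]
        # partition property: member counts sum to input size, disjoint union
        members = [g for l in loci for g in l.members]
        assert sorted(members) == sorted(g.gene_id for g in genes)


# ------------------------------------------------ predicted expression corr

class TestOmega:
    def test_identical_weight_sets_fully_correlated(self, small_study):
        ws = small_study.weight_sets[0]
        twin = make_weight_set(gene_id="TWIN", chrom=ws.chrom, start=ws.start,
                               end=ws.end, snp_ids=ws.snp_ids, a1=ws.a1,
                               a2=ws.a2, w=ws.w)
        omega = predicted_expression_correlation([ws, twin], small_study.panel)
        assert omega.matrix[0, 1] == pytest.approx(1.0)

    def test_disjoint_independent_snps_near_zero(self):
        cfg = SimulationConfig(n_genes=2, n_ref_individuals=2000,
                               ld_decay_rho=0.0, seed=23)
        panel = simulate_reference_panel(cfg)
        genes = gene_layout(cfg)
        ws = [simulate_weight_set(g, panel, cfg, seed=s)
              for g, s in zip(genes, (1, 2))]
        omega = predicted_expression_correlation(ws, panel)
        assert abs(omega.matrix[0, 1]) < 0.1

    def test_two_gene_shared_snp_matches_hand_computation(self):
        d = np.array([[0, 2, 1], [1, 1, 1], [2, 0, 0], [1, 1, 2], [0, 1, 2]])
        panel = make_panel(d)
        a = make_weight_set(gene_id="A", snp_ids=["snp0", "snp1"],
                            w=[1.0, 0.5])
        b = make_weight_set(gene_id="B", snp_ids=["snp1", "snp2"],
                            w=[-0.3, 1.0])
        omega = predicted_expression_correlation([a, b], panel)
        Xs = panel.standardized(["snp0", "snp1", "snp2"])
        ga = Xs[:, 0] * 1.0 + Xs[:, 1] * 0.5
        gb = Xs[:, 1] * -0.3 + Xs[:, 2] * 1.0
        assert omega.matrix[0, 1] == pytest.approx(np.corrcoef(ga, gb)[0, 1])


# ------------------------------------------------------ conditional signals

class TestConditionalTwas:
    def locus(self, genes):
        return Locus(locus_id="L001", chrom="1", start=1, end=2,
                     members=genes, lead_gene=genes[0])

    def test_single_gene_locus_is_identity(self):
        omega = GeneCorrelation(gene_ids=["A"], matrix=np.eye(1))
        res = conditional_twas(self.locus(["A"]), {"A": 6.0}, omega)
        assert res[0].conditional_z == pytest.approx(6.0)
        assert res[0].independent

    def test_uncorrelated_genes_keep_marginal_z(self):
        omega = GeneCorrelation(gene_ids=["A", "B"], matrix=np.eye(2))
        res = conditional_twas(self.locus(["A", "B"]), {"A": 6.0, "B": 5.5},
                               omega, ridge=0.0)
        assert res[0].conditional_z == pytest.approx(6.0)
        assert res[1].conditional_z == pytest.approx(5.5)
        assert all(r.independent for r in res)

    def test_highly_correlated_pair_hand_example(self):
        """z=(6, 5.6), omega=0.9: the shadow gene conditions away."""
        omega = GeneCorrelation(gene_ids=["A", "B"],
                                matrix=np.array([[1.0, 0.9], [0.9, 1.0]]))
        res = conditional_twas(self.locus(["A", "B"]), {"A": 6.0, "B": 5.6},
                               omega, ridge=0.0)
        by = {r.gene_id: r for r in res}
        assert by["B"].conditional_z == pytest.approx(0.45883146774, abs=1e-6)
        assert not by["B"].independent
        assert by["A"].independent
        assert by["A"].conditional_z == pytest.approx(6.0)  # retained alone

    def test_conditional_p_consistent_with_z(self):
        omega = GeneCorrelation(gene_ids=["A", "B"],
                                matrix=np.array([[1.0, 0.5], [0.5, 1.0]]))
        res = conditional_twas(self.locus(["A", "B"]), {"A": 7.0, "B": 6.0},
                               omega)
        for r in res:
            assert r.conditional_p == pytest.approx(z_to_p(r.conditional_z))

    def test_matches_independent_mvn_conditioning_oracle(self):
        rng = np.random.default_rng(24)
        worst = 0.0
        for _ in range(100):
            k = int(rng.integers(2, 4))
            A = rng.standard_normal((50, k))
            omega = np.corrcoef(A.T)
            z = rng.standard_normal(k) * 3
            for i in range(k):
                others = [j for j in range(k) if j != i]
                ours = conditional_z_score(z, omega, i, others, ridge=0.0)
                worst = max(worst, abs(ours - brute_conditional_z(z, omega,
                                                                  i, others)))
        assert worst <= 1e-10


# ---------------------------------------------------- GWAS on expression

class TestConditionGwas:
    def test_uncorrelated_snp_unchanged(self):
        # two independent SNPs; gene model uses only snp0
        d = np.array([[0, 1], [1, 0], [2, 2], [1, 1], [0, 2], [2, 0]])
        panel = make_panel(d)
        V = np.eye(2)
        ws = make_weight_set(gene_id="A", snp_ids=["snp0"], w=[1.0])
        omega = GeneCorrelation(gene_ids=["A"], matrix=np.eye(1))
        recs, _ = condition_gwas_on_expression(
            ["snp0", "snp1"], np.array([5.0, 3.0]), [ws], V, omega,
            {"A": 5.0}, ridge=0.0)
        assert recs[1].conditional_z == pytest.approx(3.0)

    def test_predictor_snp_fully_explained(self):
        V = np.eye(1)
        ws = make_weight_set(gene_id="A", snp_ids=["snp0"], w=[1.0])
        omega = GeneCorrelation(gene_ids=["A"], matrix=np.eye(1))
        recs, explained = condition_gwas_on_expression(
            ["snp0"], np.array([6.0]), [ws], V, omega, {"A": 6.0}, ridge=0.0)
        assert recs[0].fully_explained_predictor
        assert explained

    def test_sentinel_is_max_abs_marginal(self):
        V = np.eye(2)
        ws = make_weight_set(gene_id="A", snp_ids=["snp0"], w=[1.0])
        omega = GeneCorrelation(gene_ids=["A"], matrix=np.eye(1))
        recs, _ = condition_gwas_on_expression(
            ["snp0", "snp1"], np.array([2.0, -4.0]), [ws], V, omega,
            {"A": 2.0}, ridge=0.0)
        assert [r.sentinel for r in recs] == [False, True]

    def test_mediated_locus_is_explained(self):
        """Conditioning on the mediating gene defuses the sentinel SNP."""
        cfg = SimulationConfig(n_genes=3, snps_per_gene=10,
                               n_ref_individuals=400, seed=25)
        panel = simulate_reference_panel(cfg)
        genes = gene_layout(cfg)
        rng = np.random.default_rng(26)
        ws = [simulate_weight_set(g, panel, cfg,
                                  seed=int(rng.integers(2**31)))
              for g in genes]
        lam = np.array([8.0, 0.0, 0.0])
        gwas = simulate_gwas_z(ws, panel, cfg, lam=lam, seed=27)
        scan = run_transcriptome_scan(ws, gwas, panel, mhc_region=None)
        nominated = max(scan.results, key=lambda r: abs(r.twas_z))
        assert nominated.gene_id == genes[0].gene_id
        cand = [scan.harmonized[nominated.gene_id].weights]
        omega = predicted_expression_correlation(cand, panel)
        snp_ids = cand[0].snp_ids
        ld = compute_ld(panel, snp_ids)
        zvec = np.array([gwas.record(s)[2] for s in snp_ids])
        recs, explained = condition_gwas_on_expression(
            snp_ids, zvec, cand, ld.V, omega,
            {nominated.gene_id: nominated.twas_z})
        sent = next(r for r in recs if r.sentinel)
        assert abs(sent.conditional_z) < abs(sent.marginal_z)
        assert explained


# ------------------------------------------------------------ GWAS mapping

class TestMapToGwasLoci:
    def locus(self, chrom="1", start=1_000_000, end=1_050_000):
        return Locus(locus_id="L001", chrom=chrom, start=start, end=end,
                     members=["A"], lead_gene="A")

    def test_locus_inside_interval_is_known(self):
        out = map_to_gwas_loci([self.locus()], [("1", 900_000, 2_000_000)])
        assert out[0].known

    def test_boundary_arithmetic(self):
        near = map_to_gwas_loci([self.locus()],
                                [("1", 1_549_000, 1_600_000)])  # 499 kb away
        far = map_to_gwas_loci([self.locus()],
                               [("1", 1_551_000, 1_600_000)])   # 501 kb away
        assert near[0].known and not far[0].known

    def test_empty_interval_list_all_novel(self):
        out = map_to_gwas_loci([self.locus()], [])
        assert not out[0].known and out[0].nearest_distance_bp is None

    def test_other_chromosome_never_matches(self):
        out = map_to_gwas_loci([self.locus(chrom="2")],
                               [("1", 1_000_000, 1_050_000)])
        assert not out[0].known
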
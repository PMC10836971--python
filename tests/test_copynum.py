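import numpy as np
import pytest
from Bio.Seq import reverse_complement
from scipy import stats

from passagefit import copynum as cn
from passagefit.errors import ConfigurationError, InvalidInputError


class TestTypes:
    def test_consensus_region_uppercases_and_validates(self):
        r = cn.ConsensusRegion("Tf2", "acgt" * 10)
        assert r.sequence == "ACGT" * 10
        with pytest.raises(InvalidInputError):
            cn.ConsensusRegion("Tf2", "ACGN")

    def test_panel_requires_five_genes(self, te_fixture):
        with pytest.raises(ConfigurationError):
            cn.SingleCopyPanel(tuple(te_fixture["panel"][:3]))

    def test_panel_disjointness_check(self, te_fixture):
        panel = cn.SingleCopyPanel(tuple(te_fixture["panel"]))
        panel.check_disjoint([te_fixture["region"]])
        contaminated = cn.SingleCopyPanel(
            tuple(te_fixture["panel"][:7]) + (("bad", te_fixture["tf2"][:200]),)
        )
        with pytest.raises(ConfigurationError):
            contaminated.check_disjoint([te_fixture["region"]])


class TestAssignReads:
    def test_verbatim_panel_read_assigned_to_its_gene(self, te_fixture):
        gene, seq = te_fixture["panel"][0]
        targets = [("Tf2", te_fixture["tf2"])] + te_fixture["panel"]
        res = cn.assign_reads([("r1", seq[100:200])], targets)
        assert res.per_target[gene] == 1
        assert res.coverage[gene][100:200].sum() == 100

    def test_diverged_families_distinguished(self, te_fixture):
        targets = [("Tf2", te_fixture["tf2"]), ("Tf1", te_fixture["tf1"])]
        reads = [
            ("tf2_read", te_fixture["tf2"][300:400]),
            ("tf1_read", te_fixture["tf1"][300:400]),
            ("tf1_rc", reverse_complement(te_fixture["tf1"][500:600])),
        ]
        res = cn.assign_reads(reads, targets)
        assert res.per_target["Tf2"] == 1
        assert res.per_target["Tf1"] == 2

    def test_random_read_unassigned(self, te_fixture):
        rng = np.random.default_rng(1)
        junk = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100)])
        res = cn.assign_reads(
            [("junk", junk)], [("Tf2", te_fixture["tf2"])] + te_fixture["panel"]
        )
        assert res.assigned == 0 and res.unassigned == 1

    def test_duplicate_targets_rejected(self, te_fixture):
        with pytest.raises(ConfigurationError):
            cn.assign_reads([], [("a", te_fixture["tf2"]), ("b", te_fixture["tf2"])])


class TestEstimateCopyNumber:
    def test_equal_depth_gives_one_copy(self):
        cov = {"Tf2": np.full(945, 30.0), "g1": np.full(1000, 30.0),
               "g2": np.full(1000, 30.0)}
        est = cn.estimate_copy_number(cov, ["Tf2"], ["g1", "g2"])
        assert est[0].copies == pytest.approx(1.0)

    def test_zero_te_reads_gives_zero_copies(self):
        cov = {"Tf2": np.zeros(945), "g1": np.full(1000, 30.0)}
        est = cn.estimate_copy_number(cov, ["Tf2"], ["g1"])
        assert est[0].copies == 0.0

    def test_zero_panel_depth_rejected(self):
        cov = {"Tf2": np.full(945, 30.0), "g1": np.zeros(1000)}
        with pytest.raises(InvalidInputError):
            cn.estimate_copy_number(cov, ["Tf2"], ["g1"])

    @pytest.mark.parametrize("copies", [0, 2, 5])
    def test_fixture_genome_sweep(self, te_fixture, copies):
        genome = te_fixture["make_genome"](copies)
        reads = te_fixture["make_reads"](genome, coverage=30, seed=copies)
        targets = [("Tf2", te_fixture["tf2"])] + te_fixture["panel"]
        res = cn.assign_reads(reads, targets)
        est = cn.estimate_copy_number(
            res.coverage, ["Tf2"], [g for g, _ in te_fixture["panel"]]
        )[0]
        if copies == 0:
            assert est.copies < 0.1
        else:
            assert est.copies == pytest.approx(copies, rel=0.1)

    def test_scale_invariance(self, te_fixture):
        genome = te_fixture["make_genome"](3)
        targets = [("Tf2", te_fixture["tf2"])] + te_fixture["panel"]
        panel_genes = [g for g, _ in te_fixture["panel"]]
        ests = []
        for coverage in (20, 40):
            res = cn.assign_reads(
                te_fixture["make_reads"](genome, coverage=coverage, seed=2), targets
            )
            ests.append(
                cn.estimate_copy_number(res.coverage, ["Tf2"], panel_genes)[0].copies
            )
        assert ests[0] == pytest.approx(ests[1], rel=0.1)


def _assembly_with_copies(te_fixture):
    rng = np.random.default_rng(77)

    def rs(n):
        return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])

    tf2 = te_fixture["tf2"]
    return [
        (
            "chr1",
            rs(3000) + tf2 + rs(2000) + tf2 + rs(1500)
            + tf2[: int(0.4 * len(tf2))]          # truncated to 40%
            + rs(2500) + tf2 + rs(1000),
        )
    ]


class TestAssemblyCopies:
    def test_three_full_plus_truncated_counts_three(self, te_fixture):
        asm = _assembly_with_copies(te_fixture)
        assert cn.count_assembly_copies(asm, te_fixture["region"]) == 3

    def test_zero_hit_assembly(self, te_fixture):
        rng = np.random.default_rng(5)
        asm = [("chr1", "".join(np.array(list("ACGT"))[rng.integers(0, 4, 5000)]))]
        assert cn.count_assembly_copies(asm, te_fixture["region"]) == 0

    def test_invariant_to_contig_order_and_strand(self, te_fixture):
        asm = _assembly_with_copies(te_fixture)
        split = [
            ("a", asm[0][1][:6000]),
            ("b", asm[0][1][6000:]),
        ]
        n_fwd = cn.count_assembly_copies(split, te_fixture["region"])
        flipped = [(n, reverse_complement(s)) for n, s in reversed(split)]
        assert cn.count_assembly_copies(flipped, te_fixture["region"]) == n_fwd

    def test_tandem_array_counts_per_copy(self, te_fixture):
        rng = np.random.default_rng(9)
        rs = lambda n: "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
        tf2 = te_fixture["tf2"]
        asm = [("chr1", rs(2000) + tf2 + tf2 + rs(2000))]
        assert cn.count_assembly_copies(asm, te_fixture["region"]) == 2


class TestCalibrate:
    def test_identity_line(self):
        slope, intercept, r = cn.calibrate([1.0, 5.0, 10.0], [1, 5, 10])
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0)
        assert r == pytest.approx(1.0)

    def test_near_linear_estimates(self):
        slope, intercept, r = cn.calibrate([1.1, 4.8, 10.3], [1, 5, 10])
        expected_r = stats.pearsonr([1, 5, 10], [1.1, 4.8, 10.3]).statistic
        assert r == pytest.approx(expected_r, abs=1e-12)
        assert r > 0.99

    def test_two_points_rejected(self):
        with pytest.raises(InvalidInputError):
            cn.calibrate([1.0, 2.0], [1, 2])

    def test_zero_variance_rejected(self):
        with pytest.raises(InvalidInputError):
            cn.calibrate([1.0, 1.0, 1.0], [1, 2, 3])


class TestCorrelatePhenotype:
    def test_perfect_anticorrelation(self):
        rho, p = cn.correlate_phenotype([1, 2, 3, 4, 5], [10, 8, 6, 4, 2],
                                        n_permutations=2000, seed=0)
        assert rho == pytest.approx(-1.0)
        assert p < 0.05

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(12)
        hits = 0
        for trial in range(20):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            rho, p = cn.correlate_phenotype(x, y, n_permutations=1000, seed=trial)
            hits += (abs(rho) < 0.35) and (p > 0.01)
        assert hits >= 19

    def test_ties_use_average_ranks(self):
        x = [1, 1, 2, 2, 3, 3]
        y = [2, 2, 1, 3, 3, 1]
        rho, _ = cn.correlate_phenotype(x, y, n_permutations=100, seed=0)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        brute = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(brute, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(InvalidInputError):
            cn.correlate_phenotype([1, 1, 1, 1], [1, 2, 3, 4])
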
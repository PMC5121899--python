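"""Homology, artefact, arm, seed/family and verdict logic."""

import pytest

from mircurate import curation
from mircurate.config import PipelineConfig
from mircurate.core_io import (
    ContractError,
    GenomeSequence,
    Library,
    Locus,
    MiRNACandidate,
    MiRNAGene,
    reverse_complement,
)
from mircurate.curation import (
    assign_conserved,
    designate_arms,
    detect_assembly_artifacts,
    extract_seed,
    five_prime_homogeneity,
    group_families,
)
from mircurate.expression import ArmExpression

from .conftest import TABLE2_MATURES

REF = [("Dme-Mir-1", "TGGAATGTAAAGAAGTATGGAG")]
CONTROL_LIBS = [
    Library("c1", "control", 1000),
    Library("c2", "control", 1000),
]


class TestConservedAssignment:
    def test_identical_22mer_is_conserved(self):
        out = assign_conserved([REF[0][1]], REF)
        assert out[REF[0][1]].reference_name == "Dme-Mir-1"

    def test_19_columns_one_mismatch_conserved_two_not(self):
        ref_seq = REF[0][1]
        cand_1mm = ref_seq[:10] + "C" + ref_seq[11:19]  # 19 cols, 1 mismatch
        assert len(cand_1mm) == 19
        assert assign_conserved([cand_1mm], REF)[cand_1mm] is not None
        cand_2mm = "C" + ref_seq[1:10] + "C" + ref_seq[11:19]
        assert assign_conserved([cand_2mm], REF)[cand_2mm] is None

    def test_18_perfect_columns_not_conserved(self):
        cand = REF[0][1][:18]
        assert assign_conserved([cand], REF)[cand] is None
        assert assign_conserved([REF[0][1][:19]], REF)[REF[0][1][:19]] is not None

    def test_best_match_tie_breaks(self):
        refs = [("b-ref", "A" * 22), ("a-ref", "A" * 22)]
        cand = "A" * 22
        assert assign_conserved([cand], refs)[cand].reference_name == "a-ref"

    def test_mismatch_counting_is_symmetric(self):
        a, b = REF[0][1], REF[0][1][:12] + "G" + REF[0][1][13:]
        la = curation._best_ungapped_window(a, b, 1)
        lb = curation._best_ungapped_window(b, a, 1)
        assert la == lb

    def test_empty_reference_rejected(self):
        with pytest.raises(ContractError):
            assign_conserved(["A" * 22], [])


def _dup_candidates(flank_identical=True):
    import numpy as np

    rng = np.random.default_rng(17)
    core = "".join(rng.choice(list("ACGT"), size=70))
    ctx1 = "".join(rng.choice(list("ACGT"), size=60))
    ctx2 = ctx1 if flank_identical else (ctx1[:30] + "A" + ctx1[31:])
    if not flank_identical and ctx2 == ctx1:
        ctx2 = ctx1[:30] + ("C" if ctx1[30] != "C" else "G") + ctx1[31:]
    seq = ctx1 + core + ctx1 + "T" * 40 + ctx2 + core + ctx2
    genome = {"c": GenomeSequence("c", seq)}
    s1 = len(ctx1)
    s2 = len(ctx1) * 2 + len(core) + 40 + len(ctx2)

    def cand(cid, s):
        return MiRNACandidate(
            cid, Locus("c", s, s + 70), core,
            Locus("c", s, s + 22), Locus("c", s + 48, s + 70),
        )

    return genome, [cand("locA", s1), cand("locB", s2)]


class TestArtifacts:
    def test_identical_context_flags_one_artifact(self):
        genome, cands = _dup_candidates(flank_identical=True)
        artifacts, pairs = detect_assembly_artifacts(cands, genome)
        assert artifacts == {"locB"}  # lowest coordinate retained
        assert pairs[0].kept_id == "locA"

    def test_single_base_context_difference_keeps_both(self):
        genome, cands = _dup_candidates(flank_identical=False)
        artifacts, _ = detect_assembly_artifacts(cands, genome)
        assert artifacts == set()

    def test_single_copy_unflagged(self):
        genome, cands = _dup_candidates()
        artifacts, _ = detect_assembly_artifacts(cands[:1], genome)
        assert artifacts == set()


def _expr(c1, c2):
    return ArmExpression("m", "5p", {"c1": c1, "c2": c2}, {"c1": 0.0, "c2": 0.0})


class TestArmDesignation:
    @pytest.mark.parametrize(
        "t5,t3,expect",
        [
            ((60, 40), (40, 20), "co-mature"),  # ratio 100/60 = 1.67
            ((60, 40), (25, 15), "5p"),  # ratio 2.5
            ((25, 25), (25, 25), "co-mature"),  # ratio 1
            ((60, 40), (30, 20), "5p"),  # ratio exactly 2.0: not co-mature
            ((0, 0), (30, 20), "3p"),  # floored minimum avoids division by 0
        ],
    )
    def test_ratio_rule(self, t5, t3, expect):
        assert designate_arms(_expr(*t5), _expr(*t3), CONTROL_LIBS) == expect

    def test_both_arms_zero_rejected(self):
        with pytest.raises(ContractError):
            designate_arms(_expr(0, 0), _expr(0, 0), CONTROL_LIBS)


class TestHomogeneity:
    @pytest.mark.parametrize(
        "hist,frac,passes",
        [
            ({0: 100}, 1.0, True),
            ({0: 50, 1: 50}, 0.5, False),
            ({0: 70, 1: 20, -1: 10}, 0.7, True),
        ],
    )
    def test_modal_fraction(self, hist, frac, passes):
        f, ok = five_prime_homogeneity(hist)
        assert f == pytest.approx(frac)
        assert ok is passes

    def test_no_reads_rejected(self):
        with pytest.raises(ContractError):
            five_prime_homogeneity({})


class TestSeeds:
    @pytest.mark.parametrize(
        "mature,seed",
        [
            ("ATGAAATGGACGATTGGCTGTG", "TGAAAT"),
            ("TACATAACCGCAATCACCGATT", "ACATAA"),
            ("TGTGATGTGCATGTGGGCTTTCC", "GTGATG"),
        ],
    )
    def test_published_seed_hexamers(self, mature, seed):
        assert extract_seed(mature) == seed

    def test_first_base_positions(self):
        assert extract_seed("GATTACA", (1, 1)) == "G"

    def test_too_short_mature_rejected(self):
        with pytest.raises(ContractError):
            extract_seed("ACGT", (2, 7))


class TestFamilies:
    def test_published_grouping(self, table2_genes):
        fams = group_families(table2_genes)
        assert len(fams) == 9
        assert sorted(len(f.members) for f in fams) == [1, 1, 1, 1, 1, 1, 2, 2, 3]
        bg5 = [f for f in fams if f.seed == "GTGATG"]
        assert len(bg5) == 1 and len(bg5[0].members) == 2

    def test_partition_property(self, table2_genes):
        fams = group_families(table2_genes)
        names = [g.name for f in fams for g in f.members]
        assert sorted(names) == sorted(g.name for g in table2_genes)
        for f in fams:
            assert all(
                extract_seed(g.mature_seq) == f.seed for g in f.members
            )

    def test_singleton_family(self):
        g = MiRNAGene("solo", "", "TGACTCCAGACCTTGTTGCTGA", "", "5p", "specific")
        fams = group_families([g])
        assert len(fams) == 1 and len(fams[0].members) == 1

    def test_novel_naming_follows_expression_rank(self):
        genes = [
            MiRNAGene("low", "", "TGACTCCAGACCTTGTTGCTGA", "", "5p", "specific"),
            MiRNAGene("high", "", "CATTCTTCCTAGAATGGTCCGT", "", "5p", "specific"),
        ]
        fams = group_families(genes, expression={"low": 10.0, "high": 900.0})
        assert fams[0].name == "MIR-bg1"
        assert fams[0].members[0].name == "high"

    def test_conserved_families_keep_reference_name(self):
        genes = [
            MiRNAGene("x", "MIR-1", "TGGAATGTAAAGAAGTATGGAG", "", "5p", "conserved"),
            MiRNAGene("y", "", "TACATAACCGCAATCACCGATT", "", "5p", "specific"),
        ]
        fams = group_families(genes)
        assert {f.name for f in fams} == {"MIR-1", "MIR-bg1"}


class TestVerdicts:
    def test_strict_fc_boundary(self, synthetic_dataset, curated):
        """A log2FC exactly at the threshold fails the knockdown criterion.

        The ratio 1/2 is exactly representable, so a threshold of -1 probes
        the strictness of the comparison without floating-point slack.
        """
        d = synthetic_dataset
        truth = d["truth"]
        cand = truth.true_loci[0].candidate
        e5, e3 = curated.expressions[cand.id]
        arm = truth.true_loci[0].mature_arm
        expr = e5 if arm == "5p" else e3
        halved = ArmExpression(
            cand.id, arm, expr.counts,
            {"control_1": 8.0, "control_2": 8.0,
             "depleted_1": 4.0, "depleted_2": 4.0},
        )
        from mircurate.expression import compute_log2fc

        fc = compute_log2fc(halved, d["libraries"], pseudocount=0.0)
        assert fc.log2fc == -1.0
        assert not fc.log2fc < -1.0  # the criterion comparison is strict

    def test_conserved_candidate_bypasses_novel_criteria(self, synthetic_dataset):
        d = synthetic_dataset
        truth = d["truth"]
        # a decoy that would fail the knockdown criterion; homology rescues it
        # (its arms are long enough for a 19-column alignment)
        decoy = next(
            p for p in truth.decoy_loci if p.decoy_mode == "dicer_independent"
        )
        ref = [("Ref-Mir-x", decoy.candidate.arm_seq("5p"))]
        res = curation.run_curation(
            d["genome_dict"],
            [p.candidate for p in truth.planted_loci],
            d["libraries"],
            d["reads"],
            reference_matures=ref,
        )
        assert res.verdicts[decoy.candidate.id].status == "conserved"

    def test_relaxing_thresholds_never_shrinks_accepted_set(
        self, synthetic_dataset, curated
    ):
        d = synthetic_dataset
        strict_accepted = set(curated.by_status("novel_bona_fide"))
        relaxed_cfg = PipelineConfig(
            fc_threshold=-0.2,
            energy_max=-15.0,
            min_pairs=15,
            overhang_tol=1,
            loop_min=4,
            loop_max=60,
            homogeneity_threshold=0.5,
        )
        relaxed = curation.run_curation(
            d["genome_dict"],
            [p.candidate for p in d["truth"].planted_loci],
            d["libraries"],
            d["reads"],
            cfg=relaxed_cfg,
        )
        assert strict_accepted <= set(relaxed.by_status("novel_bona_fide"))

    def test_missing_upstream_data_names_stage(self, synthetic_dataset, curated):
        d = synthetic_dataset
        cand = d["truth"].true_loci[0].candidate
        e5, e3 = curated.expressions[cand.id]
        with pytest.raises(ContractError, match="structure"):
            curation.apply_bona_fide_filter(
                cand, e5, e3, None, {0: 10}, d["libraries"]
            )
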
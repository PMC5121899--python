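"""The curation decision core.

Combines homology (conserved-miRNA assignment), assembly-artifact
detection, arm designation, 5' read homogeneity, seed-based family
grouping and the structural/expression criteria into a per-candidate
verdict:

* ``conserved``       - matches a reference mature (>=19 ungapped columns,
                        <=1 mismatch); validated by homology, so the novel
                        criteria are bypassed;
* ``novel_bona_fide`` - passes all criteria: both arms expressed, reduced
                        under Dicer depletion (log2FC < -0.5), homogeneous
                        5' ends, a single hairpin with free energy below
                        -22 kcal/mol, >16 mature/star pairs, 2-nt 3'
                        overhangs, read support in every control library,
                        and not an assembly artefact;
* ``artifact``        - one of a pair of loci with identical precursor and
                        identical +/-50 nt flanking context;
* ``rejected``        - everything else.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from . import expression as expr_mod
from . import structure
from .config import PipelineConfig
from .core_io import (
    CONTROL,
    ContractError,
    GenomeSequence,
    Library,
    Locus,
    MiRNACandidate,
    MiRNAGene,
    ReadRecord,
    extract_locus_sequence,
    normalize_sequence,
)

FLAG_NAMES = (
    "c1_both_arms",
    "c2_dicer_fc",
    "c3_5prime_homogeneity",
    "c4_hairpin",
    "c5_energy",
    "c6_pairing",
    "c7_overhang",
    "support_controls",
    "not_artifact",
)


@dataclass(frozen=True)
class CurationVerdict:
    candidate_id: str
    flags: Mapping[str, bool]
    status: str  # {conserved, novel_bona_fide, rejected, artifact}

    def __post_init__(self) -> None:
        missing = set(FLAG_NAMES) - set(self.flags)
        if missing:
            raise ContractError(f"missing verdict flags: {sorted(missing)}")
        if self.status == "novel_bona_fide" and not all(self.flags.values()):
            raise ContractError("novel_bona_fide requires all flags true")
        if self.status == "artifact" and self.flags["not_artifact"]:
            raise ContractError("artifact status contradicts not_artifact flag")


@dataclass(frozen=True)
class Family:
    name: str
    seed: str
    members: tuple[MiRNAGene, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ContractError(f"family {self.name} has no members")


@dataclass(frozen=True)
class ConservedMatch:
    reference_name: str
    length: int
    mismatches: int


# ---------------------------------------------------------------------------
# Homology
# ---------------------------------------------------------------------------


def _best_ungapped_window(a: str, b: str, max_mismatch: int) -> tuple[int, int]:
    """Longest ungapped local alignment of ``a`` vs ``b`` with <=max_mismatch.

    Returns (length, mismatches in that window); (0, 0) when nothing aligns.
    Considers every relative offset of the two sequences; within an offset,
    the classic two-pointer longest-window-with-<=k-mismatches scan.
    """
    best_len, best_mm = 0, 0
    for shift in range(-(len(b) - 1), len(a)):
        a_start = max(0, shift)
        b_start = max(0, -shift)
        overlap = min(len(a) - a_start, len(b) - b_start)
        if overlap <= best_len and overlap < 1:
            continue
        mism = [a[a_start + k] != b[b_start + k] for k in range(overlap)]
        left = 0
        mm_in_window = 0
        for right in range(overlap):
            mm_in_window += mism[right]
            while mm_in_window > max_mismatch:
                mm_in_window -= mism[left]
                left += 1
            length = right - left + 1
            if length > best_len or (length == best_len and mm_in_window < best_mm):
                best_len, best_mm = length, mm_in_window
    return best_len, best_mm


def assign_conserved(
    candidate_matures: Sequence[str],
    reference_matures: Sequence[tuple[str, str]],
    min_cols: int = 19,
    max_mismatch: int = 1,
) -> dict[str, ConservedMatch | None]:
    """Map each candidate mature to its best reference match, or ``None``.

    A candidate is conserved iff some ungapped local alignment to a
    reference spans >= ``min_cols`` columns ("longer than 18 nucleotides")
    with <= ``max_mismatch`` mismatches.  Best match = longest alignment;
    ties broken by fewer mismatches, then lexicographic reference name.
    """
    if not reference_matures:
        raise ContractError("reference catalogue is empty")
    refs = [(name, normalize_sequence(seq)) for name, seq in reference_matures]
    out: dict[str, ConservedMatch | None] = {}
    for cand in candidate_matures:
        cseq = normalize_sequence(cand)
        best: ConservedMatch | None = None
        for name, rseq in sorted(refs):
            length, mm = _best_ungapped_window(cseq, rseq, max_mismatch)
            if length < min_cols:
                continue
            match = ConservedMatch(name, length, mm)
            if best is None or (match.length, -match.mismatches) > (
                best.length,
                -best.mismatches,
            ):
                best = match
        out[cand] = best
    return out


def read_reference_catalogue(path) -> list[tuple[str, str, str]]:
    """Read a reference mature catalogue FASTA with ``name|family`` headers.

    Returns (name, family, sequence) triples.
    """
    from .core_io import read_sequences

    out = []
    for rec in read_sequences(path, "fasta"):
        if "|" in rec.id:
            name, family = rec.id.split("|", 1)
        else:
            name, family = rec.id, rec.id
        out.append((name, family, rec.sequence))
    return out


# ---------------------------------------------------------------------------
# Assembly artefacts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArtifactPair:
    kept_id: str
    artifact_id: str
    flank_used: int
    truncated: bool


def detect_assembly_artifacts(
    candidates: Sequence[MiRNACandidate],
    genome: Mapping[str, GenomeSequence],
    flank: int = 50,
) -> tuple[set[str], list[ArtifactPair]]:
    """Flag duplicated loci that are genome-assembly artefacts.

    Candidates sharing an identical precursor sequence are compared over the
    precursor plus ``flank`` nt of context on each side (transcript
    orientation); perfect identity of the extended precursors means one
    locus is an assembly artefact.  The lowest-coordinate locus is retained.
    Context running past a contig end is truncated symmetrically for the
    pair, and the truncation is recorded.
    """
    by_seq: dict[str, list[MiRNACandidate]] = {}
    for c in candidates:
        by_seq.setdefault(c.precursor_seq, []).append(c)
    artifacts: set[str] = set()
    pairs: list[ArtifactPair] = []

    def _avail(c: MiRNACandidate) -> tuple[int, int]:
        p = c.precursor_locus
        contig_len = len(genome[p.seq_id])
        if p.strand == "+":
            return p.start, contig_len - p.end
        return contig_len - p.end, p.start

    def _extended(c: MiRNACandidate, up: int, down: int) -> str:
        p = c.precursor_locus
        if p.strand == "+":
            ext = Locus(p.seq_id, p.start - up, p.end + down, "+")
        else:
            ext = Locus(p.seq_id, p.start - down, p.end + up, "-")
        return extract_locus_sequence(genome, ext)

    for group in by_seq.values():
        if len(group) < 2:
            continue
        group = sorted(group, key=lambda c: (c.precursor_locus.seq_id, c.precursor_locus.start))
        keeper = group[0]
        for other in group[1:]:
            up = min(flank, _avail(keeper)[0], _avail(other)[0])
            down = min(flank, _avail(keeper)[1], _avail(other)[1])
            truncated = up < flank or down < flank
            if _extended(keeper, up, down) == _extended(other, up, down):
                artifacts.add(other.id)
                pairs.append(ArtifactPair(keeper.id, other.id, min(up, down), truncated))
    return artifacts, pairs


# ---------------------------------------------------------------------------
# Arms, homogeneity, seeds, families
# ---------------------------------------------------------------------------


def designate_arms(
    expr5p: expr_mod.ArmExpression,
    expr3p: expr_mod.ArmExpression,
    control_libs: Sequence[Library],
    ratio_threshold: float = 2.0,
) -> str:
    """Designate the mature arm from control-library read totals.

    Ratio of the more- over the less-expressed arm (floored at one read)
    below ``ratio_threshold`` means both arms are co-mature; otherwise the
    higher-count arm is the mature one.
    """
    ids = [l.id for l in control_libs if l.condition == CONTROL]
    t5 = expr5p.total(ids)
    t3 = expr3p.total(ids)
    if t5 == 0 and t3 == 0:
        raise ContractError(
            f"{expr5p.candidate_id}: both arms have zero control counts"
        )
    ratio = max(t5, t3) / max(min(t5, t3), 1)
    if ratio < ratio_threshold:
        return "co-mature"
    return "5p" if t5 > t3 else "3p"


def five_prime_homogeneity(
    offsets: Mapping[int, int] | Iterable[tuple[int, int]],
    threshold: float = 0.66,
) -> tuple[float, bool]:
    """Fraction of arm reads starting at the modal 5' offset, and pass flag."""
    hist = dict(offsets)
    total = sum(hist.values())
    if total <= 0:
        raise ContractError("no reads on arm")
    fraction = max(hist.values()) / total
    return fraction, fraction >= threshold


def extract_seed(mature: str, positions: tuple[int, int] = (2, 7)) -> str:
    """Seed substring at 1-based inclusive ``positions`` (default 2-7)."""
    start, end = positions
    if len(mature) < end:
        raise ContractError(
            f"mature of length {len(mature)} shorter than seed end {end}"
        )
    return normalize_sequence(mature)[start - 1 : end]


def group_families(
    genes: Sequence[MiRNAGene],
    seed_positions: tuple[int, int] = (2, 7),
    species_code: str = "bg",
    expression: Mapping[str, float] | None = None,
) -> list[Family]:
    """Partition genes into families by exact seed identity.

    Conserved genes keep their reference family name; novel families are
    named ``MIR-<species_code><k>`` in descending order of their most
    expressed member (``expression`` maps gene name to a read total;
    without it, input order is used as the rank).
    """
    groups: dict[str, list[MiRNAGene]] = {}
    order: list[str] = []
    for g in genes:
        seed = extract_seed(g.mature_seq, seed_positions)
        if seed not in groups:
            groups[seed] = []
            order.append(seed)
        groups[seed].append(g)

    def _expr(g: MiRNAGene) -> float:
        return expression.get(g.name, 0.0) if expression else 0.0

    conserved_fams: list[Family] = []
    novel_groups: list[tuple[float, int, str, list[MiRNAGene]]] = []
    for rank, seed in enumerate(order):
        members = groups[seed]
        conserved = [g for g in members if g.conservation == "conserved" and g.family]
        if conserved:
            name = conserved[0].family
            conserved_fams.append(
                Family(name, seed, tuple(replace(g, family=name) for g in members))
            )
        else:
            top = max((_expr(g) for g in members), default=0.0)
            novel_groups.append((top, rank, seed, members))
    # Highest-expressed novel family gets the lowest number.
    novel_groups.sort(key=lambda t: (-t[0], t[1]))
    novel_fams = []
    for k, (_top, _rank, seed, members) in enumerate(novel_groups, start=1):
        name = f"MIR-{species_code}{k}"
        members = sorted(members, key=lambda g: (-_expr(g), g.name))
        novel_fams.append(
            Family(name, seed, tuple(replace(g, family=name) for g in members))
        )
    return conserved_fams + novel_fams


# ---------------------------------------------------------------------------
# The bona-fide verdict
# ---------------------------------------------------------------------------


def apply_bona_fide_filter(
    candidate: MiRNACandidate,
    expr5p: expr_mod.ArmExpression,
    expr3p: expr_mod.ArmExpression,
    fold: structure.HairpinFold,
    offset_hist: Mapping[int, int],
    libraries: Sequence[Library],
    conserved_match: ConservedMatch | None = None,
    is_artifact: bool = False,
    cfg: PipelineConfig | None = None,
) -> CurationVerdict:
    """Assemble the per-candidate verdict from all upstream computations.

    ``offset_hist`` is the 5'-offset histogram of reads on the mature arm.
    Conserved candidates bypass the novel-miRNA criteria (status
    ``conserved``) but an assembly artefact is an artefact regardless.
    """
    cfg = cfg or PipelineConfig()
    for stage, value in (
        ("expression (5p arm)", expr5p),
        ("expression (3p arm)", expr3p),
        ("structure (fold)", fold),
    ):
        if value is None:
            raise ContractError(f"missing upstream data from stage: {stage}")
    control = [l for l in libraries if l.condition == CONTROL]
    c1 = expr5p.total() >= 1 and expr3p.total() >= 1
    support = expr_mod.support_filter(expr5p, expr3p, control)
    if expr5p.total([l.id for l in control]) or expr3p.total([l.id for l in control]):
        mature_arm = designate_arms(expr5p, expr3p, control, cfg.comature_ratio)
    else:
        mature_arm = "5p" if expr5p.total() >= expr3p.total() else "3p"
    # co-mature: either arm may carry the knockdown signal; use the stronger.
    if mature_arm == "co-mature":
        mature_expr = max(
            (expr5p, expr3p), key=lambda e: e.total([l.id for l in control])
        )
    else:
        mature_expr = expr5p if mature_arm == "5p" else expr3p
    fc = expr_mod.compute_log2fc(mature_expr, libraries, cfg.pseudocount)
    c2 = fc.log2fc < cfg.fc_threshold
    if offset_hist and sum(offset_hist.values()) > 0:
        _frac, c3 = five_prime_homogeneity(offset_hist, cfg.homogeneity_threshold)
    else:
        c3 = False
    mature_iv = candidate.arm_interval(mature_expr.arm)
    star_iv = candidate.arm_interval("3p" if mature_expr.arm == "5p" else "5p")
    structural = structure.evaluate_hairpin_criteria(
        fold,
        mature_iv,
        star_iv,
        energy_max=cfg.energy_max,
        min_pairs=cfg.min_pairs,
        overhang=cfg.overhang,
        overhang_tol=cfg.overhang_tol,
        loop_range=cfg.loop_range,
    )
    flags = {
        "c1_both_arms": c1,
        "c2_dicer_fc": c2,
        "c3_5prime_homogeneity": c3,
        "support_controls": support,
        "not_artifact": not is_artifact,
        **structural,
    }
    if is_artifact:
        status = "artifact"
    elif conserved_match is not None:
        # Homology validates the locus; novel criteria are bypassed.
        flags.update(
            {k: True for k in ("c2_dicer_fc", "c3_5prime_homogeneity",
                               "c4_hairpin", "c5_energy", "c6_pairing",
                               "c7_overhang")}
        )
        status = "conserved"
    elif all(flags.values()):
        status = "novel_bona_fide"
    else:
        status = "rejected"
    return CurationVerdict(candidate.id, flags, status)


@dataclass
class CurationResult:
    verdicts: dict[str, CurationVerdict]
    mature_arms: dict[str, str]
    fold_changes: dict[str, float]
    folds: dict[str, structure.HairpinFold]
    expressions: dict[str, tuple[expr_mod.ArmExpression, expr_mod.ArmExpression]]
    conserved: dict[str, ConservedMatch | None]

    def by_status(self, status: str) -> list[str]:
        return sorted(i for i, v in self.verdicts.items() if v.status == status)


def run_curation(
    genome: Mapping[str, GenomeSequence],
    candidates: Sequence[MiRNACandidate],
    libraries: Sequence[Library],
    reads_by_library: Mapping[str, Sequence[ReadRecord]],
    reference_matures: Sequence[tuple[str, str]] = (),
    cfg: PipelineConfig | None = None,
) -> CurationResult:
    """Run the full per-candidate curation over a candidate set.

    Counts arm reads, folds precursors, detects artefacts, assigns
    conserved homologues (when a reference catalogue is given) and emits a
    :class:`CurationVerdict` per candidate.
    """
    cfg = cfg or PipelineConfig()
    artifact_ids, _pairs = detect_assembly_artifacts(
        candidates, genome, cfg.artifact_flank
    )
    conserved: dict[str, ConservedMatch | None] = {}
    if reference_matures:
        # The mature arm is unknown before expression; match both arms.
        by_arm_seq = assign_conserved(
            [c.arm_seq(a) for c in candidates for a in ("5p", "3p")],
            reference_matures,
            cfg.align_min_cols,
            cfg.align_max_mismatch,
        )
    verdicts: dict[str, CurationVerdict] = {}
    mature_arms: dict[str, str] = {}
    fold_changes: dict[str, float] = {}
    folds: dict[str, structure.HairpinFold] = {}
    expressions = {}
    control = [l for l in libraries if l.condition == CONTROL]
    for cand in candidates:
        e5, e3 = expr_mod.count_arm_reads(
            reads_by_library, libraries, cand, cfg.arm_tolerance, genome
        )
        fold = structure.fold_hairpin(cand.precursor_seq, backend=cfg.fold_backend)
        match = None
        if reference_matures:
            match = by_arm_seq.get(cand.arm_seq("5p")) or by_arm_seq.get(
                cand.arm_seq("3p")
            )
        conserved[cand.id] = match
        ctrl_ids = [l.id for l in control]
        if e5.total(ctrl_ids) or e3.total(ctrl_ids):
            arm = designate_arms(e5, e3, control, cfg.comature_ratio)
        else:
            arm = "5p" if e5.total() >= e3.total() else "3p"
        count_arm = arm if arm in ("5p", "3p") else (
            "5p" if e5.total(ctrl_ids) >= e3.total(ctrl_ids) else "3p"
        )
        hist = expr_mod.arm_offset_histogram(
            reads_by_library, cand, count_arm, cfg.arm_tolerance, genome
        )
        verdict = apply_bona_fide_filter(
            cand, e5, e3, fold, hist, libraries,
            conserved_match=match,
            is_artifact=cand.id in artifact_ids,
            cfg=cfg,
        )
        mature_expr = e5 if count_arm == "5p" else e3
        fc = expr_mod.compute_log2fc(mature_expr, libraries, cfg.pseudocount)
        verdicts[cand.id] = verdict
        mature_arms[cand.id] = arm
        fold_changes[cand.id] = fc.log2fc
        folds[cand.id] = fold
        expressions[cand.id] = (e5, e3)
    return CurationResult(
        verdicts, mature_arms, fold_changes, folds, expressions, conserved
    )
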
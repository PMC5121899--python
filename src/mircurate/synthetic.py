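"""Synthetic genomes and small-RNA libraries with a known ground truth.

A toy genome is seeded with true miRNA hairpins that satisfy every
structural criterion by construction (and by verification against the
folding backend), plus decoy loci each violating exactly one named
criterion:

* ``no_star_reads`` - a sound hairpin whose star arm is never sequenced;
* ``bad_fold``      - a second, disjoint stem-loop upstream of the duplex,
                      so the locus is not a single-terminal-loop hairpin;
* ``low_pairing``   - a duplex with only 16 mature/star base pairs;
* ``no_overhang``   - a blunt-ended duplex (no 2-nt 3' overhangs);
* ``dicer_independent`` - structurally perfect but sequenced at equal depth
                      in control and Dicer-depleted libraries.

Read libraries are then simulated: true-miRNA arms receive Poisson/
multinomial read counts at the requested depth in control libraries and at
``knockdown_factor`` times that depth after Dicer depletion; short
background blocks are tiled at >=10x coverage in every library (the
negative-control material) and additional reads are scattered across the
rest of the genome.  All randomness flows through a single seeded
generator, so identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import structure
from .core_io import (
    CONTROL,
    DICER_DEPLETED,
    ConfigurationError,
    GenomeSequence,
    Library,
    Locus,
    MiRNACandidate,
    ReadRecord,
    reverse_complement,
)

DECOY_MODES = (
    "no_star_reads",
    "bad_fold",
    "low_pairing",
    "no_overhang",
    "dicer_independent",
)

#: Verdict flags expected to fail for each decoy mode (all others pass).
EXPECTED_DECOY_FAILURES: dict[str, frozenset[str]] = {
    "no_star_reads": frozenset({"c1_both_arms", "support_controls"}),
    "bad_fold": frozenset({"c4_hairpin"}),
    "low_pairing": frozenset({"c6_pairing"}),
    "no_overhang": frozenset({"c7_overhang"}),
    "dicer_independent": frozenset({"c2_dicer_fc"}),
}


class CapacityError(ValueError):
    """The requested loci do not fit in the requested genome length."""


class GenerationError(RuntimeError):
    """Bounded random generation failed to satisfy its constraints."""


@dataclass(frozen=True)
class PlantedLocus:
    candidate: MiRNACandidate
    label: str  # {true_mirna, decoy}
    decoy_mode: str | None
    mature_arm: str  # {5p, 3p}


@dataclass
class SyntheticTruth:
    """Ground truth of a planted genome (loci, labels, simulation knobs)."""

    planted_loci: list[PlantedLocus]
    knockdown_factor: float
    rng_seed: int
    genome: GenomeSequence
    background_regions: list[Locus] = field(default_factory=list)

    @property
    def true_loci(self) -> list[PlantedLocus]:
        return [p for p in self.planted_loci if p.label == "true_mirna"]

    @property
    def decoy_loci(self) -> list[PlantedLocus]:
        return [p for p in self.planted_loci if p.label == "decoy"]

    def excluded_loci(self) -> list[Locus]:
        return [p.candidate.precursor_locus for p in self.planted_loci]


# ---------------------------------------------------------------------------
# Hairpin construction
# ---------------------------------------------------------------------------

_STEM_P = {"A": 0.2, "C": 0.3, "G": 0.3, "T": 0.2}  # GC-biased for energy


def _random_stem(rng: np.random.Generator, k: int) -> str:
    bases = list(_STEM_P)
    probs = list(_STEM_P.values())
    stem = list(rng.choice(bases, size=k, p=probs))
    # Guard the helix ends with G/C: keeps the designed closing pair strong
    # and prevents the overhang bases (A) from pairing with the termini.
    stem[0] = rng.choice(["G", "C"])
    stem[-1] = rng.choice(["G", "C"])
    return "".join(stem)


def _loop_seq(rng: np.random.Generator, length: int) -> str:
    # A/C only: cannot base-pair among themselves, so loops and overhangs
    # never compete with the designed stem.
    return "".join(rng.choice(["A", "C"], size=length))


@dataclass(frozen=True)
class _HairpinDesign:
    precursor: str
    iv5p: tuple[int, int]
    iv3p: tuple[int, int]


def _design_hairpin(
    rng: np.random.Generator,
    stem_len: int,
    with_overhangs: bool = True,
    extra_stem_loop: bool = False,
) -> _HairpinDesign:
    loop_total = int(rng.integers(8, 41))
    if with_overhangs:
        stem = _random_stem(rng, stem_len)
        e5 = "AA"
        e3 = "AA"
        loop_core = _loop_seq(rng, loop_total - len(e5))
        precursor = stem + e5 + loop_core + reverse_complement(stem) + e3
        iv5p = (0, stem_len + 2)
        iv3p = (stem_len + 2 + len(loop_core), len(precursor))
    else:  # blunt duplex: arms are exactly the paired stem
        stem = _random_stem(rng, stem_len)
        loop_core = _loop_seq(rng, loop_total)
        precursor = stem + loop_core + reverse_complement(stem)
        iv5p = (0, stem_len)
        iv3p = (stem_len + len(loop_core), len(precursor))
    if extra_stem_loop:
        extra = "G" * 7 + "AAAA" + "C" * 7 + "ACACAC"
        precursor = extra + precursor
        shift = len(extra)
        iv5p = (iv5p[0] + shift, iv5p[1] + shift)
        iv3p = (iv3p[0] + shift, iv3p[1] + shift)
    return _HairpinDesign(precursor, iv5p, iv3p)


def _structural_flags(design: _HairpinDesign) -> dict[str, bool]:
    fold = structure.fold_hairpin(design.precursor)
    return structure.evaluate_hairpin_criteria(fold, design.iv5p, design.iv3p)


_MODE_DESIGN = {
    # mode -> (stem_len range, with_overhangs, extra_stem_loop, expected-false structural flags)
    None: ((19, 24), True, False, frozenset()),
    "no_star_reads": ((19, 24), True, False, frozenset()),
    "dicer_independent": ((19, 24), True, False, frozenset()),
    "bad_fold": ((19, 24), True, True, frozenset({"c4_hairpin"})),
    "low_pairing": ((16, 17), True, False, frozenset({"c6_pairing"})),
    "no_overhang": ((19, 24), False, False, frozenset({"c7_overhang"})),
}

_MAX_DESIGN_TRIES = 50


def _build_verified_hairpin(
    rng: np.random.Generator, mode: str | None
) -> _HairpinDesign:
    (klo, khi), overhangs, extra, expect_false = _MODE_DESIGN[mode]
    for _ in range(_MAX_DESIGN_TRIES):
        k = int(rng.integers(klo, khi))
        design = _design_hairpin(rng, k, overhangs, extra)
        flags = _structural_flags(design)
        failed = {name for name, ok in flags.items() if not ok}
        if failed == set(expect_false):
            return design
    raise GenerationError(
        f"could not design a hairpin for mode {mode!r} in "
        f"{_MAX_DESIGN_TRIES} tries"
    )


# ---------------------------------------------------------------------------
# Genome planting
# ---------------------------------------------------------------------------

_MIN_SPACING = 100
_NEG_REGION_LEN = 300
_N_NEG_REGIONS = 4
_NEG_MARGIN = 50


def plant_mirna_loci(
    n_true: int,
    n_decoy: int,
    genome_length: int,
    rng_seed: int,
    knockdown_factor: float = 0.25,
    contig_id: str = "contig1",
) -> tuple[GenomeSequence, SyntheticTruth]:
    """Build a random genome containing planted miRNA and decoy loci.

    Loci are spaced >=100 nt apart; four 300-nt background blocks (future
    negative-control regions) are reserved >=50 nt away from any locus.
    Everything is a deterministic function of ``rng_seed``.
    """
    if not 0 < knockdown_factor <= 1:
        raise ConfigurationError("knockdown_factor must be in (0, 1]")
    rng = np.random.default_rng(rng_seed)
    modes: list[str | None] = [None] * n_true + [
        DECOY_MODES[i % len(DECOY_MODES)] for i in range(n_decoy)
    ]
    designs = [_build_verified_hairpin(rng, m) for m in modes]
    budget = (
        sum(len(d.precursor) for d in designs)
        + (len(designs) + 1) * (_MIN_SPACING + 100)
        + _N_NEG_REGIONS * (_NEG_REGION_LEN + 2 * _NEG_MARGIN + 50)
    )
    if budget > genome_length:
        raise CapacityError(
            f"genome_length {genome_length} too small; need >= {budget}"
        )
    genome_arr = rng.choice(list("ACGT"), size=genome_length)
    planted: list[PlantedLocus] = []
    cursor = 0
    occupied: list[Locus] = []
    for idx, (mode, design) in enumerate(zip(modes, designs)):
        cursor += _MIN_SPACING + int(rng.integers(0, 100))
        start = cursor
        end = start + len(design.precursor)
        strand = "+" if rng.random() < 0.5 else "-"
        genomic = (
            design.precursor if strand == "+" else reverse_complement(design.precursor)
        )
        genome_arr[start:end] = list(genomic)
        prec_locus = Locus(contig_id, start, end, strand)

        def _arm_locus(iv: tuple[int, int]) -> Locus:
            if strand == "+":
                return Locus(contig_id, start + iv[0], start + iv[1], strand)
            return Locus(contig_id, end - iv[1], end - iv[0], strand)

        label = "true_mirna" if mode is None and idx < n_true else "decoy"
        cid = f"{'mir' if label == 'true_mirna' else 'decoy'}_{idx:03d}"
        candidate = MiRNACandidate(
            id=cid,
            precursor_locus=prec_locus,
            precursor_seq=design.precursor,
            arm5p_locus=_arm_locus(design.iv5p),
            arm3p_locus=_arm_locus(design.iv3p),
            source_tags=frozenset({"synthetic"}),
        )
        mature_arm = "5p" if rng.random() < 0.5 else "3p"
        planted.append(PlantedLocus(candidate, label, mode, mature_arm))
        occupied.append(prec_locus)
        cursor = end
    # Reserve negative-control background blocks after the last locus.
    regions: list[Locus] = []
    for _ in range(_N_NEG_REGIONS):
        cursor += _NEG_MARGIN + int(rng.integers(0, 50))
        regions.append(Locus(contig_id, cursor, cursor + _NEG_REGION_LEN, "+"))
        cursor += _NEG_REGION_LEN
    if cursor + _NEG_MARGIN > genome_length:  # pragma: no cover - budget guards
        raise CapacityError("layout overflow; increase genome_length")
    genome = GenomeSequence(contig_id, "".join(genome_arr))
    truth = SyntheticTruth(
        planted_loci=planted,
        knockdown_factor=knockdown_factor,
        rng_seed=rng_seed,
        genome=genome,
        background_regions=regions,
    )
    return genome, truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

_STAR_FRACTION = 0.4
_OFFSET_WEIGHTS = {0: 0.85, 1: 0.15}  # 5' homogeneity ~0.85 at the mode
_TRIM_WEIGHTS = {0: 0.5, -1: 0.3, -2: 0.2}  # 3' length heterogeneity


def _arm_variants(
    candidate: MiRNACandidate, arm: str
) -> tuple[list[str], np.ndarray]:
    """Read-sequence variants for an arm and their sampling weights."""
    s, e = candidate.arm_interval(arm)
    prec = candidate.precursor_seq
    seqs: list[str] = []
    weights: list[float] = []
    for off, w_off in _OFFSET_WEIGHTS.items():
        for trim, w_trim in _TRIM_WEIGHTS.items():
            start = s + off
            end = e + trim
            if start < 0 or end > len(prec) or end - start < 16:
                continue
            seqs.append(prec[start:end])
            weights.append(w_off * w_trim)
    w = np.asarray(weights)
    return seqs, w / w.sum()


_SCATTER_BASE_COUNT = 15


def simulate_read_libraries(
    truth: SyntheticTruth,
    depth_per_locus: int,
    n_control: int = 2,
    n_depleted: int = 2,
    rng_seed: int = 0,
    n_scatter: int = 2000,
    scatter_mean_extra: float = 5.0,
) -> list[tuple[Library, list[ReadRecord]]]:
    """Simulate control and Dicer-depleted collapsed read libraries.

    Mature arms of planted loci draw ~``depth_per_locus`` reads in control
    libraries (star arms 40% of that); in depleted libraries both arms are
    scaled by ``truth.knockdown_factor`` except for ``dicer_independent``
    decoys, which keep full depth.  Background blocks are tiled so every
    base is covered >=10x in every library, and ``n_scatter`` additional
    collapsed read positions (count ``15 + Poisson(scatter_mean_extra)``,
    independent per library) are spread over the remaining genome so the
    planted miRNA reads stay a small fraction of each library and RPM
    renormalisation barely moves the negative-control baseline.
    """
    if depth_per_locus < 10:
        raise ConfigurationError("depth_per_locus must be >= 10")
    if n_control < 2:
        raise ConfigurationError("need >= 2 control libraries (support filter)")
    rng = np.random.default_rng(rng_seed)
    genome_seq = truth.genome.sequence
    # Scatter positions: fixed across libraries, away from loci and blocks.
    forbidden = [
        Locus(l.seq_id, max(0, l.start - 50), min(len(genome_seq), l.end + 50), "+")
        for l in truth.excluded_loci() + truth.background_regions
    ]
    scatter_pos: list[int] = []
    tries = 0
    while len(scatter_pos) < n_scatter and tries < 50 * n_scatter:
        tries += 1
        pos = int(rng.integers(0, len(genome_seq) - 30))
        probe = Locus(truth.genome.id, pos, pos + 30, "+")
        if any(probe.overlaps(f) for f in forbidden):
            continue
        scatter_pos.append(pos)
    scatter_lens = rng.integers(20, 31, size=len(scatter_pos))

    lib_specs = [(f"control_{i + 1}", CONTROL) for i in range(n_control)] + [
        (f"depleted_{i + 1}", DICER_DEPLETED) for i in range(n_depleted)
    ]
    out: list[tuple[Library, list[ReadRecord]]] = []
    for lib_id, condition in lib_specs:
        reads: list[ReadRecord] = []
        depleted = condition == DICER_DEPLETED
        for planted in truth.planted_loci:
            factor = 1.0
            if depleted and planted.decoy_mode != "dicer_independent":
                factor = truth.knockdown_factor
            star_arm = "3p" if planted.mature_arm == "5p" else "5p"
            arm_depths = {
                planted.mature_arm: depth_per_locus * factor,
                star_arm: depth_per_locus * _STAR_FRACTION * factor,
            }
            if planted.decoy_mode == "no_star_reads":
                arm_depths[star_arm] = 0.0
            for arm, depth in arm_depths.items():
                if depth <= 0:
                    continue
                seqs, weights = _arm_variants(planted.candidate, arm)
                total = int(rng.poisson(depth))
                if total == 0:
                    total = 1  # every arm of every planted locus is supported
                counts = rng.multinomial(total, weights)
                for seq, c in zip(seqs, counts):
                    if c > 0:
                        reads.append(ReadRecord(seq, int(c), lib_id))
        for region in truth.background_regions:
            for start in range(region.start, region.end - 30 + 1, 10):
                seq = genome_seq[start : start + 30]
                count = 10 + int(rng.poisson(2))
                reads.append(ReadRecord(seq, count, lib_id))
        for pos, rl in zip(scatter_pos, scatter_lens):
            seq = genome_seq[pos : pos + int(rl)]
            count = _SCATTER_BASE_COUNT + int(rng.poisson(scatter_mean_extra))
            reads.append(ReadRecord(seq, count, lib_id))
        total_mapped = sum(r.count for r in reads)
        out.append((Library(lib_id, condition, total_mapped), reads))
    return out


# ---------------------------------------------------------------------------
# Mock miRNA sequences
# ---------------------------------------------------------------------------


def generate_mock_sequences(
    n: int,
    length: int,
    rng_seed: int,
    exclude: Iterable[str] = (),
    seed_positions: tuple[int, int] = (2, 7),
) -> list[str]:
    """Uniform-random mock miRNA sequences avoiding known miRNAs.

    Draws ``n`` distinct sequences of ``length`` nt, none present in
    ``exclude`` and none sharing a seed (1-based ``seed_positions``,
    default 2-7) with any excluded sequence.  Raises
    :class:`GenerationError` when the exclusion constraints cannot be met
    within a bounded number of retries.
    """
    rng = np.random.default_rng(rng_seed)
    excluded = {s.upper().replace("U", "T") for s in exclude}
    lo, hi = seed_positions
    excluded_seeds = {s[lo - 1 : hi] for s in excluded if len(s) >= hi}
    out: list[str] = []
    seen: set[str] = set()
    tries = 0
    max_tries = max(200, 200 * n)
    while len(out) < n:
        if tries >= max_tries:
            raise GenerationError(
                f"could not generate {n} sequences within {max_tries} draws; "
                "exclusion set too restrictive"
            )
        tries += 1
        seq = "".join(rng.choice(list("ACGT"), size=length))
        if seq in seen or seq in excluded:
            continue
        if length >= hi and seq[lo - 1 : hi] in excluded_seeds:
            continue
        seen.add(seq)
        out.append(seq)
    return out
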
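"""Seed-match target prediction, prediction-set intersection and baselines.

The internal predictor is ONE deliberately simple algorithm: a target site
requires perfect Watson-Crick complementarity of the miRNA seed (positions
2-7) to the transcript, and the best ungapped duplex extension around the
seed must reach a hybridisation energy at or below the threshold (default
-12 kcal/mol), scored with the same nearest-neighbour stack table as the
folding module.  Externally computed prediction sets (e.g. from several
published algorithms) are ingested as pair lists and combined by strict
intersection; per-group mean target counts are compared with Welch tests
against a mock-miRNA baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from . import expression as expr_mod
from .core_io import ContractError, GenomeSequence, normalize_sequence, reverse_complement
from .structure import can_pair, stack_energy

_WC = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class TargetPair:
    mirna_id: str
    transcript_id: str
    site_position: int
    duplex_energy: float
    algorithm: str = "internal"

    @property
    def key(self) -> tuple[str, str]:
        return (self.mirna_id, self.transcript_id)


def _duplex_energy(mirna: str, transcript: str, anchor: int) -> float:
    """Stack energy of the ungapped duplex anchored at a seed hit.

    ``anchor`` is the transcript index pairing miRNA position 0; with
    antiparallel geometry, miRNA position p pairs transcript position
    ``anchor - p``.  Non-complementary positions interrupt the stacking
    runs (they contribute nothing).
    """
    energy = 0.0
    prev_paired = False
    prev = ("", "")
    for p in range(len(mirna)):
        t = anchor - p
        if 0 <= t < len(transcript) and can_pair(mirna[p], transcript[t]):
            if prev_paired:
                # stack read along the miRNA 5'->3': previous pair is outer
                energy += stack_energy(prev[0], prev[1], mirna[p], transcript[t])
            prev_paired = True
            prev = (mirna[p], transcript[t])
        else:
            prev_paired = False
    return energy


def predict_targets(
    mirna: str,
    transcripts: Sequence[GenomeSequence],
    energy_threshold: float = -12.0,
    mirna_id: str = "mirna",
    seed_positions: tuple[int, int] = (2, 7),
) -> list[TargetPair]:
    """Predict transcript targets of one miRNA.

    One :class:`TargetPair` per unique (miRNA, transcript) with the best
    (lowest-energy) qualifying site; sites must carry a perfect
    Watson-Crick seed match and duplex energy <= ``energy_threshold``.
    """
    if not transcripts:
        raise ContractError("transcripts list is empty")
    seq = normalize_sequence(mirna)
    lo, hi = seed_positions
    if len(seq) < hi:
        raise ContractError(f"miRNA shorter than seed end {hi}")
    seed = seq[lo - 1 : hi]
    site_query = reverse_complement(seed)
    out: list[TargetPair] = []
    for tr in transcripts:
        tseq = tr.sequence
        best: tuple[float, int] | None = None
        start = tseq.find(site_query)
        while start != -1:
            # revcomp(seed) sits at [start, start+len(seed)); miRNA position
            # p pairs transcript position (start + hi - 1) - p.
            energy = _duplex_energy(seq, tseq, start + hi - 1)
            if energy <= energy_threshold and (best is None or energy < best[0]):
                best = (energy, start)
            start = tseq.find(site_query, start + 1)
        if best is not None:
            out.append(TargetPair(mirna_id, tr.id, best[1], best[0]))
    return out


def predict_targets_many(
    mirnas: Mapping[str, str],
    transcripts: Sequence[GenomeSequence],
    energy_threshold: float = -12.0,
) -> list[TargetPair]:
    pairs: list[TargetPair] = []
    for mid, seq in mirnas.items():
        pairs.extend(
            predict_targets(seq, transcripts, energy_threshold, mirna_id=mid)
        )
    return pairs


def filter_pairs(
    pairs: Iterable[TargetPair], energy_threshold: float = -12.0
) -> list[TargetPair]:
    """Apply the energy threshold to externally computed pair lists on ingest."""
    return [p for p in pairs if p.duplex_energy <= energy_threshold]


def intersect_predictions(
    sets: Sequence[Iterable[TargetPair]],
) -> set[tuple[str, str]]:
    """(miRNA, transcript) pairs predicted by every algorithm."""
    if len(sets) < 2:
        raise ContractError("intersection needs at least 2 prediction sets")
    keyed = [{p.key for p in s} for s in sets]
    out = keyed[0]
    for k in keyed[1:]:
        out &= k
    return out


@dataclass(frozen=True)
class GroupTargetSummary:
    counts: Mapping[str, Mapping[str, int]]  # group -> mirna -> target count
    means: Mapping[str, float]
    p_values: Mapping[tuple[str, str], float]


def mean_targets_per_group(
    pairs: Iterable[tuple[str, str]] | Iterable[TargetPair],
    groups: Mapping[str, str],
) -> GroupTargetSummary:
    """Mean target counts per miRNA group with pairwise Welch comparisons.

    ``groups`` maps every miRNA id to its group label (e.g. conserved /
    specific / mock); miRNAs without any predicted target count as zero.
    Groups with fewer than 2 members are excluded from the tests with a
    warning.
    """
    per_mirna: dict[str, int] = {m: 0 for m in groups}
    for p in pairs:
        key = p.key if isinstance(p, TargetPair) else tuple(p)
        mirna = key[0]
        if mirna not in groups:
            raise ContractError(f"miRNA {mirna!r} not assigned to any group")
        per_mirna[mirna] += 1
    counts: dict[str, dict[str, int]] = {}
    for mirna, group in groups.items():
        counts.setdefault(group, {})[mirna] = per_mirna[mirna]
    means = {
        g: (sum(c.values()) / len(c) if c else float("nan"))
        for g, c in counts.items()
    }
    p_values: dict[tuple[str, str], float] = {}
    names = sorted(counts)
    for i, ga in enumerate(names):
        for gb in names[i + 1 :]:
            if len(counts[ga]) < 2 or len(counts[gb]) < 2:
                warnings.warn(
                    f"comparison {ga} vs {gb} skipped: group too small"
                )
                continue
            try:
                _t, p = expr_mod.welch_t_test(
                    list(counts[ga].values()), list(counts[gb].values())
                )
            except ContractError as exc:
                warnings.warn(f"comparison {ga} vs {gb} skipped: {exc}")
                continue
            p_values[(ga, gb)] = p
    return GroupTargetSummary(counts, means, p_values)
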
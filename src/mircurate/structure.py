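"""Precursor hairpin folding and the structural bona-fide criteria.

The internal folding backend computes the maximum-pairing pseudoknot-free
structure (dynamic programming, minimum hairpin loop of 3 unpaired bases)
and scores it with an embedded nearest-neighbour stack-energy table
(Turner-style 37 degC Watson-Crick values; stacks involving a G:U wobble are
approximated by a single constant).  This model is deliberately simple and
is NOT equivalent to a full thermodynamic folder; the ``external`` backend
delegates to the ViennaRNA ``RNAfold`` executable when higher fidelity is
needed, and the two are never silently interchanged.

Structural criteria evaluated here (thresholds are strict where noted):

* hairpin shape: exactly one terminal loop, of plausible length;
* folding free energy strictly below -22 kcal/mol;
* more than 16 nucleotides paired between the mature and star arms;
* a 2-nt 3' overhang on each arm of the duplex (Drosha/Dicer signature).
"""

from __future__ import annotations

import shutil
import subprocess
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .core_io import ConfigurationError, ContractError, normalize_sequence, as_rna


class BackendError(RuntimeError):
    """The requested external folding backend is unavailable or failed."""


# Watson-Crick nearest-neighbour stack free energies, kcal/mol at 37 degC,
# keyed by (outer pair, inner pair) where a pair is (5' base, 3' base) and
# the inner pair is (i+1, j-1) of the outer (i, j).  RNA alphabet.
_WC_STACKS: dict[tuple[str, str], float] = {
    ("AU", "AU"): -0.93, ("AU", "UA"): -1.10, ("AU", "CG"): -2.24, ("AU", "GC"): -2.08,
    ("UA", "AU"): -1.33, ("UA", "UA"): -0.93, ("UA", "CG"): -2.35, ("UA", "GC"): -2.11,
    ("CG", "AU"): -2.11, ("CG", "UA"): -2.08, ("CG", "CG"): -3.26, ("CG", "GC"): -2.36,
    ("GC", "AU"): -2.35, ("GC", "UA"): -2.24, ("GC", "CG"): -3.42, ("GC", "GC"): -3.26,
}

#: Stacks with at least one G:U wobble pair (flat approximation).
GU_STACK_ENERGY = -1.2

_CAN_PAIR = {"AT", "TA", "GC", "CG", "GT", "TG"}

MIN_HAIRPIN_LOOP = 3
MAX_FOLD_LENGTH = 400


def can_pair(a: str, b: str) -> bool:
    return a + b in _CAN_PAIR


def stack_energy(outer5: str, outer3: str, inner5: str, inner3: str) -> float:
    """Energy of stacking the inner pair on the outer pair (DNA letters in)."""
    outer = (outer5 + outer3).replace("T", "U")
    inner = (inner5 + inner3).replace("T", "U")
    try:
        return _WC_STACKS[(outer, inner)]
    except KeyError:
        return GU_STACK_ENERGY


@dataclass(frozen=True)
class HairpinFold:
    """A folded precursor with its structure metrics.

    ``mature_star_pairs`` and the two overhang fields are populated by
    :func:`annotate_arms` once the arm intervals are known; they are ``None``
    on a bare fold.
    """

    dot_bracket: str
    free_energy: float
    loop_length: int
    n_terminal_loops: int
    pairs: tuple[tuple[int, int], ...]
    mature_star_pairs: int | None = None
    overhang_3p_of_5p_arm: int | None = None
    overhang_3p_of_3p_arm: int | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def partner_array(self) -> list[int]:
        partner = [-1] * len(self.dot_bracket)
        for i, j in self.pairs:
            partner[i] = j
            partner[j] = i
        return partner


_INVALID = -1e9
_EPS = 1e-6


def _fold_internal(seq: str, min_loop: int) -> list[tuple[int, int]]:
    """Maximum-pairing pseudoknot-free structure, ties broken by minimum
    stack energy (so contiguous helices beat scattered isolated pairs).

    Two coupled DP tables over intervals [i..j]:

    * ``P``: best (pairs, energy) among structures where (i, j) is paired;
    * ``B``: best (pairs, energy) over all structures, via the classic
      "j unpaired, or j pairs some k" decomposition.

    Values are (pair count, stack energy); more pairs always wins, equal
    pair counts prefer the lower (more stabilising) energy.
    """
    n = len(seq)
    if n < min_loop + 2:
        return []
    pairable = np.zeros((n, n), dtype=bool)
    st = np.zeros((n, n))
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            if can_pair(seq[i], seq[j]):
                pairable[i, j] = True
                if i + 1 < j - 1 and can_pair(seq[i + 1], seq[j - 1]):
                    st[i, j] = stack_energy(seq[i], seq[j], seq[i + 1], seq[j - 1])
    Pp = np.full((n, n), _INVALID)
    Pe = np.zeros((n, n))
    # B tables use a +1 column offset: B*[i, j+1] describes interval [i..j],
    # so B*[i, i] is the empty interval.
    Bp = np.zeros((n + 1, n + 1))
    Be = np.zeros((n + 1, n + 1))
    for d in range(min_loop + 1, n):
        for i in range(n - d):
            j = i + d
            if pairable[i, j]:
                # close (i, j) over the best interior; credit the stack when
                # the interior itself closes (i+1, j-1)
                bp, be = Bp[i + 1, j] + 1, Be[i + 1, j]
                if d >= min_loop + 3 and Pp[i + 1, j - 1] > _INVALID / 2:
                    ap = Pp[i + 1, j - 1] + 1
                    ae = Pe[i + 1, j - 1] + st[i, j]
                    if ap > bp + 0.5 or (abs(ap - bp) < 0.5 and ae < be - _EPS):
                        bp, be = ap, ae
                Pp[i, j], Pe[i, j] = bp, be
            cur_p, cur_e = Bp[i, j], Be[i, j]  # j unpaired
            ks = np.arange(i, j - min_loop)
            pvec = Pp[ks, j]
            valid = pvec > _INVALID / 2
            if valid.any():
                totp = Bp[i, ks] + pvec
                tote = Be[i, ks] + Pe[ks, j]
                totp[~valid] = _INVALID
                mx = totp.max()
                cand = np.flatnonzero(totp >= mx - 0.5)
                emin = float(tote[cand].min())
                if mx > cur_p + 0.5 or (abs(mx - cur_p) < 0.5 and emin < cur_e - _EPS):
                    cur_p, cur_e = mx, emin
            Bp[i, j + 1], Be[i, j + 1] = cur_p, cur_e

    pairs: list[tuple[int, int]] = []
    work: list[tuple[int, int, str]] = [(0, n - 1, "B")]
    while work:
        i, j, kind = work.pop()
        if j <= i:
            continue
        if kind == "P":
            pairs.append((i, j))
            tp, te = Pp[i, j], Pe[i, j]
            if (
                j - i >= min_loop + 3
                and Pp[i + 1, j - 1] > _INVALID / 2
                and abs(Pp[i + 1, j - 1] + 1 - tp) < 0.5
                and abs(Pe[i + 1, j - 1] + st[i, j] - te) < _EPS
            ):
                work.append((i + 1, j - 1, "P"))
            else:
                work.append((i + 1, j - 1, "B"))
            continue
        tp, te = Bp[i, j + 1], Be[i, j + 1]
        if tp < 0.5:
            continue
        placed = False
        for k in range(i, j - min_loop):
            if (
                Pp[k, j] > _INVALID / 2
                and abs(Bp[i, k] + Pp[k, j] - tp) < 0.5
                and abs(Be[i, k] + Pe[k, j] - te) < _EPS
            ):
                work.append((i, k - 1, "B"))
                work.append((k, j, "P"))
                placed = True
                break
        if not placed:
            work.append((i, j - 1, "B"))
    return sorted(pairs)


def _structure_metrics(
    seq: str, pairs: Sequence[tuple[int, int]], loop_penalty: float
) -> tuple[float, int, int, str]:
    """(free_energy, loop_length, n_terminal_loops, dot_bracket)."""
    n = len(seq)
    partner = [-1] * n
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    dot = "".join(
        "(" if partner[k] > k else ")" if 0 <= partner[k] < k else "."
        for k in range(n)
    )
    energy = 0.0
    for i, j in pairs:
        if i + 1 < j - 1 and partner[i + 1] == j - 1:
            energy += stack_energy(seq[i], seq[j], seq[i + 1], seq[j - 1])
    if loop_penalty:
        enclosed = 0
        depth = 0
        for k in range(n):
            if partner[k] > k:
                depth += 1
            elif 0 <= partner[k] < k:
                depth -= 1
            elif depth > 0:
                enclosed += 1
        energy += loop_penalty * enclosed
    terminal_loops: list[int] = []
    for i, j in sorted(pairs):
        if all(partner[k] == -1 for k in range(i + 1, j)):
            terminal_loops.append(j - i - 1)
    loop_length = terminal_loops[0] if terminal_loops else 0
    return energy, loop_length, len(terminal_loops), dot


def _parse_dot_bracket(dot: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for k, ch in enumerate(dot):
        if ch == "(":
            stack.append(k)
        elif ch == ")":
            if not stack:
                raise BackendError(f"unbalanced dot-bracket {dot!r}")
            pairs.append((stack.pop(), k))
    if stack:
        raise BackendError(f"unbalanced dot-bracket {dot!r}")
    return sorted(pairs)


def _fold_external(seq: str) -> tuple[list[tuple[int, int]], float]:
    exe = shutil.which("RNAfold")
    if exe is None:
        raise BackendError("RNAfold executable not found on PATH")
    proc = subprocess.run(
        [exe, "--noPS"],
        input=as_rna(seq) + "\n",
        capture_output=True,
        text=True,
    )
    if proc.returncode != 0:
        raise BackendError(f"RNAfold failed: {proc.stderr.strip()}")
    lines = [l for l in proc.stdout.splitlines() if l.strip()]
    if len(lines) < 2:
        raise BackendError(f"unparseable RNAfold output: {proc.stdout!r}")
    structure_line = lines[1]
    dot = structure_line.split()[0]
    energy_str = structure_line[structure_line.rfind("(") + 1 : structure_line.rfind(")")]
    return _parse_dot_bracket(dot), float(energy_str)


def fold_hairpin(
    precursor: str,
    backend: str = "internal",
    min_loop: int = MIN_HAIRPIN_LOOP,
    loop_penalty: float = 0.0,
) -> HairpinFold:
    """Fold a precursor sequence and return its :class:`HairpinFold`.

    Candidate precursors are typically 40-400 nt; only the hard upper bound
    is enforced here so that short oracle sequences remain foldable.

    Parameters
    ----------
    backend:
        ``internal`` (maximum-pairing DP + stack energies) or ``external``
        (``RNAfold``; raises :class:`BackendError` if unavailable, never a
        silent fallback).
    loop_penalty:
        Energy added per unpaired base enclosed by at least one pair
        (internal backend only); default 0 so an isolated closing pair can
        never raise the energy.
    """
    seq = normalize_sequence(precursor)
    if not seq:
        raise ContractError("empty precursor")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ContractError(f"invalid characters in precursor: {sorted(bad)}")
    if len(seq) > MAX_FOLD_LENGTH:
        raise ContractError(
            f"precursor length {len(seq)} exceeds {MAX_FOLD_LENGTH}"
        )
    if backend == "internal":
        pairs = _fold_internal(seq, min_loop)
        energy, loop_len, n_term, dot = _structure_metrics(seq, pairs, loop_penalty)
    elif backend == "external":
        pairs, energy = _fold_external(seq)
        _, loop_len, n_term, dot = _structure_metrics(seq, pairs, 0.0)
    else:
        raise ConfigurationError(f"unknown folding backend {backend!r}")
    return HairpinFold(
        dot_bracket=dot,
        free_energy=energy,
        loop_length=loop_len,
        n_terminal_loops=n_term,
        pairs=tuple(pairs),
    )


def annotate_arms(
    fold: HairpinFold,
    mature_iv: tuple[int, int],
    star_iv: tuple[int, int],
) -> HairpinFold:
    """Fill in duplex metrics for the given precursor-relative arm intervals.

    ``mature_star_pairs`` counts bases of the mature interval paired with a
    base of the star interval.  An arm's 3' overhang is the number of its
    3'-terminal bases beyond its last base paired into the duplex (the
    whole arm length if nothing pairs).
    """
    ms, me = mature_iv
    ss, se = star_iv
    if ms < 0 or ss < 0 or me > len(fold.dot_bracket) or se > len(fold.dot_bracket):
        raise ContractError("arm interval outside the precursor")
    if max(ms, ss) < min(me, se):
        raise ContractError("mature and star intervals overlap")
    partner = fold.partner_array()

    def _in(iv: tuple[int, int], k: int) -> bool:
        return iv[0] <= k < iv[1]

    n_pairs = sum(
        1 for k in range(ms, me) if partner[k] >= 0 and _in(star_iv, partner[k])
    )

    def _overhang(iv: tuple[int, int], other: tuple[int, int]) -> int:
        last_paired = None
        for k in range(iv[0], iv[1]):
            if partner[k] >= 0 and _in(other, partner[k]):
                last_paired = k
        if last_paired is None:
            return iv[1] - iv[0]
        return iv[1] - 1 - last_paired

    iv5p, iv3p = (mature_iv, star_iv) if ms < ss else (star_iv, mature_iv)
    return replace(
        fold,
        mature_star_pairs=n_pairs,
        overhang_3p_of_5p_arm=_overhang(iv5p, iv3p),
        overhang_3p_of_3p_arm=_overhang(iv3p, iv5p),
    )


def evaluate_hairpin_criteria(
    fold: HairpinFold,
    mature_iv: tuple[int, int],
    star_iv: tuple[int, int],
    *,
    energy_max: float = -22.0,
    min_pairs: int = 17,
    overhang: int = 2,
    overhang_tol: int = 0,
    loop_range: tuple[int, int] = (8, 40),
) -> dict[str, bool]:
    """Evaluate the four structural criteria for one candidate.

    Returns flags ``c4_hairpin`` (single terminal loop of plausible length),
    ``c5_energy`` (strictly below ``energy_max``), ``c6_pairing`` (at least
    ``min_pairs`` mature/star pairs, i.e. "more than 16" at the default) and
    ``c7_overhang`` (each arm's 3' overhang equals ``overhang`` within
    ``overhang_tol``).
    """
    if fold.mature_star_pairs is None:
        fold = annotate_arms(fold, mature_iv, star_iv)
    lo, hi = loop_range
    c4 = fold.n_terminal_loops == 1 and lo <= fold.loop_length <= hi
    c5 = fold.free_energy < energy_max
    c6 = fold.mature_star_pairs >= min_pairs
    c7 = (
        abs(fold.overhang_3p_of_5p_arm - overhang) <= overhang_tol
        and abs(fold.overhang_3p_of_3p_arm - overhang) <= overhang_tol
    )
    return {
        "c4_hairpin": c4,
        "c5_energy": c5,
        "c6_pairing": c6,
        "c7_overhang": c7,
    }


def loop_length_stats(folds: Iterable[HairpinFold]) -> Counter:
    """Exact integer histogram of terminal-loop lengths."""
    folds = list(folds)
    if not folds:
        raise ContractError("loop_length_stats requires at least one fold")
    return Counter(f.loop_length for f in folds)
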
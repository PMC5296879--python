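"""Position liftover between two revisions of a protein sequence.

Global (Needleman-Wunsch style) alignment with affine gap penalties and a
fixed traceback tie-break (diagonal, then up, then left) so the resulting
position map is deterministic. A gap run of length L costs
``gap_open + (L - 1) * gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_model import PfsSnvError, VALID_RESIDUES

NEG_INF = float("-inf")

#: (match, mismatch, gap_open, gap_extend) — cheap, unambiguous defaults for
#: near-identical sequence revisions; overridable per call.
DEFAULT_SCORING = (1.0, -1.0, -2.0, -1.0)


@dataclass
class PositionMap:
    """Monotone 1-based position mapping from sequence a to sequence b."""

    accession: str
    pairs: list[tuple[int, int]]
    unmapped_a: set[int]
    #: positions of a aligned to a *different* residue in b (still mapped)
    mismatches_a: set[int] = field(default_factory=set)
    score: float = 0.0

    def __post_init__(self) -> None:
        last_a, last_b = 0, 0
        for pa, pb in self.pairs:
            if pa <= last_a or pb <= last_b:
                raise PfsSnvError("position map is not strictly monotone")
            last_a, last_b = pa, pb

    def to_b(self, position_a: int) -> int | None:
        return dict(self.pairs).get(position_a)


def _check_sequence(seq: str, name: str) -> None:
    if not seq:
        raise PfsSnvError(f"sequence {name} is empty")
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise PfsSnvError(f"sequence {name} has invalid characters {sorted(bad)}")


def align_positions(
    seq_a: str,
    seq_b: str,
    scoring: Sequence[float] = DEFAULT_SCORING,
    accession: str = "",
) -> PositionMap:
    """Globally align two sequences and return the residue position map.

    Aligned residue pairs (matching or not) become map pairs; residues of
    ``seq_a`` opposite a gap go to ``unmapped_a``. Traceback prefers
    diagonal over up (gap in b) over left (gap in a) so ties are resolved
    deterministically.
    """
    _check_sequence(seq_a, "a")
    _check_sequence(seq_b, "b")
    match, mismatch, gap_open, gap_extend = (float(x) for x in scoring)
    n, m = len(seq_a), len(seq_b)

    # Three-state affine DP: M ends in residue pair, X ends consuming a
    # (gap in b, "up"), Y ends consuming b (gap in a, "left").
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend

    for i in range(1, n + 1):
        ai = seq_a[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            s = match if ai == seq_b[j - 1] else mismatch
            Mi[j] = s + max(Mp[j - 1], Xp[j - 1], Yp[j - 1])
            Xi[j] = max(Mp[j] + gap_open, Xp[j] + gap_extend, Yp[j] + gap_open)
            Yi[j] = max(Mi[j - 1] + gap_open, Xi[j - 1] + gap_open, Yi[j - 1] + gap_extend)

    # Traceback with fixed state preference: M (diag) > X (up) > Y (left).
    i, j = n, m
    final = max(M[n][m], X[n][m], Y[n][m])
    if M[n][m] == final:
        state = "M"
    elif X[n][m] == final:
        state = "X"
    else:
        state = "Y"

    pairs: list[tuple[int, int]] = []
    unmapped_a: set[int] = set()
    mismatches_a: set[int] = set()
    while i > 0 or j > 0:
        if state == "M":
            pairs.append((i, j))
            if seq_a[i - 1] != seq_b[j - 1]:
                mismatches_a.add(i)
            s = match if seq_a[i - 1] == seq_b[j - 1] else mismatch
            target = M[i][j] - s
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            if M[i][j] == target:
                state = "M"
            elif X[i][j] == target:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            unmapped_a.add(i)
            target = X[i][j]
            i = i - 1
            if M[i][j] + gap_open == target:
                state = "M"
            elif X[i][j] + gap_extend == target:
                state = "X"
            else:
                state = "Y"
        else:  # Y: gap in a, consume b only
            target = Y[i][j]
            j = j - 1
            if M[i][j] + gap_open == target:
                state = "M"
            elif X[i][j] + gap_open == target:
                state = "X"
            else:
                state = "Y"

    pairs.reverse()
    return PositionMap(
        accession=accession,
        pairs=pairs,
        unmapped_a=unmapped_a,
        mismatches_a=mismatches_a,
        score=final,
    )


@dataclass(frozen=True)
class DroppedPosition:
    position: int
    reason: str


def lift_annotations(
    positions: Iterable[int], pmap: PositionMap, seq_a_length: int | None = None
) -> tuple[dict[int, int], list[DroppedPosition], set[int]]:
    """Translate sequence-a positions through a position map.

    Returns (lifted mapping a->b, dropped positions with reasons, flagged
    positions that lifted onto a mismatched residue).
    """
    lookup = dict(pmap.pairs)
    max_a = seq_a_length
    if max_a is None:
        max_a = max(
            [pa for pa, _ in pmap.pairs] + list(pmap.unmapped_a) + [0]
        )
    lifted: dict[int, int] = {}
    dropped: list[DroppedPosition] = []
    flagged: set[int] = set()
    for pos in positions:
        if not 1 <= pos <= max_a:
            raise PfsSnvError(f"position {pos} outside sequence a (length {max_a})")
        if pos in pmap.unmapped_a:
            dropped.append(DroppedPosition(pos, "unmapped"))
            continue
        lifted[pos] = lookup[pos]
        if pos in pmap.mismatches_a:
            flagged.add(pos)
    return lifted, dropped, flagged
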
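"""Secondary-structure prediction by base-pair maximization.

Candidate precursors are folded with a Nussinov-style dynamic program:
the returned structure is a nested (pseudoknot-free) set of base pairs of
maximum cardinality, counting Watson-Crick pairs and the G:U wobble, with
a minimum hairpin loop of 3 unpaired bases.  Pair count stands in for
folding free energy: on designed stem-loops it recovers the stem exactly,
it needs no thermodynamic parameter set, and it is fully deterministic
(ties are broken by pairing the 5'-most base with its 5'-most partner).

This is deliberately not a minimum-free-energy folder; the duplex
evaluation downstream only needs to know which bases pair with which.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import CANONICAL_PAIRS, check_alphabet

#: Minimum number of unpaired bases enclosed by a hairpin-closing pair.
MIN_LOOP = 3

#: fold_hairpin window bounds: precursors are ~250-nt excisions, so reject
#: inputs that cannot be (or are too long to be) a plant pre-miRNA window.
MIN_HAIRPIN_LEN = 40
MAX_HAIRPIN_LEN = 400


@dataclass(frozen=True)
class FoldResult:
    """A nested pairing of one sequence."""

    seq: str
    pairs: tuple[tuple[int, int], ...]   # (i, j) with i < j, 0-based
    partner: tuple[int, ...]             # partner index per base, -1 unpaired

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def dotbracket(self) -> str:
        chars = ["."] * len(self.seq)
        for i, j in self.pairs:
            chars[i] = "("
            chars[j] = ")"
        return "".join(chars)


def _pair_matrix(seq: str) -> np.ndarray:
    s = seq.upper()
    n = len(s)
    mat = np.zeros((n, n), dtype=bool)
    for a, b in CANONICAL_PAIRS:
        ia = np.frombuffer(s.encode(), dtype=np.uint8) == ord(a)
        ib = np.frombuffer(s.encode(), dtype=np.uint8) == ord(b)
        mat |= ia[:, None] & ib[None, :]
    return mat


def fold_sequence(seq: str) -> FoldResult:
    """Maximum base-pair nested fold of an arbitrary-length sequence.

    ``E[i][j]`` is the maximum pair count of the half-open slice
    ``seq[i:j]``; either base ``i`` is unpaired, or it pairs with some
    ``k`` at least ``MIN_LOOP + 1`` bases downstream, splitting the
    problem.  The inner maximization over split points is vectorized.
    """
    check_alphabet(seq, extra="N")
    s = seq.upper()
    n = len(s)
    if n == 0:
        return FoldResult(seq, (), ())
    can = _pair_matrix(s)
    E = np.zeros((n + 2, n + 1), dtype=np.int32)
    min_span = MIN_LOOP + 2  # a pair (i,k) needs k - i > MIN_LOOP
    for span in range(min_span, n + 1):
        for i in range(0, n - span + 1):
            j = i + span
            best = E[i + 1, j]
            ks = np.nonzero(can[i, i + MIN_LOOP + 1:j])[0]
            if ks.size:
                ks = ks + i + MIN_LOOP + 1
                cand = 1 + E[i + 1, ks] + E[ks + 1, j]
                best = max(best, int(cand.max()))
            E[i, j] = best

    # Deterministic traceback: prefer pairing the 5'-most base, and among
    # equally good partners prefer the most distal (3'-most) one — on a
    # stem-loop this reconstructs the outer stem rather than an
    # equal-count rearrangement.
    pairs: list[tuple[int, int]] = []
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        if j - i < min_span:
            continue
        target = E[i, j]
        if target == 0:
            continue
        paired = False
        for k in range(j - 1, i + MIN_LOOP, -1):
            if can[i, k] and 1 + E[i + 1, k] + E[k + 1, j] == target:
                pairs.append((i, k))
                stack.append((k + 1, j))
                stack.append((i + 1, k))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))

    pairs.sort()
    partner = [-1] * n
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    return FoldResult(seq, tuple(pairs), tuple(partner))


def fold_hairpin(seq: str) -> FoldResult:
    """Fold a candidate precursor window (40-400 nt)."""
    if not (MIN_HAIRPIN_LEN <= len(seq) <= MAX_HAIRPIN_LEN):
        raise ValueError(
            f"precursor window length {len(seq)} outside "
            f"[{MIN_HAIRPIN_LEN}, {MAX_HAIRPIN_LEN}]"
        )
    return fold_sequence(seq)


def enumerate_structures(seq: str):
    """Yield every nested pairing of ``seq`` (loop >= MIN_LOOP, G:U allowed).

    Exhaustive enumeration; exponential in sequence length and only
    intended for short sequences (<= ~25 nt) as a test oracle.  Each
    structure is a tuple of (i, j) pairs.
    """
    s = seq.upper()

    def gen(i: int, j: int):  # half-open [i, j)
        if i >= j:
            yield ()
            return
        # base i unpaired
        for rest in gen(i + 1, j):
            yield rest
        # base i paired with an admissible k
        for k in range(i + MIN_LOOP + 1, j):
            if (s[i], s[k]) in CANONICAL_PAIRS:
                for left in gen(i + 1, k):
                    for right in gen(k + 1, j):
                        yield ((i, k),) + left + right

    yield from gen(0, len(s))


def max_pairs_exhaustive(seq: str) -> int:
    """Maximum pair count over all enumerated structures (test oracle)."""
    return max(len(p) for p in enumerate_structures(seq))
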
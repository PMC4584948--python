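"""Small sequence helpers shared across modules.

All sequences are handled in DNA space (T, not U), matching the way
small-RNA reads come off the sequencer.
"""

from __future__ import annotations

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Watson-Crick pairs plus the G:U (G:T in DNA space) wobble.
CANONICAL_PAIRS = frozenset(
    [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")]
)

WOBBLE_PAIRS = frozenset([("G", "T"), ("T", "G")])


def revcomp(seq: str) -> str:
    """Reverse complement in DNA space."""
    return seq.translate(_COMP)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMP)


def can_pair(a: str, b: str) -> bool:
    """True if the two bases can form a Watson-Crick or G:U pair."""
    return (a.upper(), b.upper()) in CANONICAL_PAIRS


def check_alphabet(seq: str, extra: str = "N") -> None:
    allowed = set("ACGT") | set(extra)
    bad = set(seq.upper()) - allowed
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
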
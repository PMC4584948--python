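"""Plant miRNA target prediction by penalty-scored complementarity.

Plant miRNAs act through near-perfect complementarity to their targets,
so target sites can be found by scanning transcripts with a penalty
score: each mismatch costs 1.0, each G:U wobble 0.5 and each gap
(single-nucleotide bulge) 2.0, with penalties doubled over the
functionally critical miRNA positions 2-13 (positions 10-11 direct the
cleavage, so mismatches there are allowed but doubly penalized rather
than forbidden).  Windows scoring at or below the expectation cutoff
(default 3.0) are reported.  This mirrors the scoring family used by
psRNATarget-style servers; it is a documented re-implementation, not a
byte-identical clone.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from ._seq import WOBBLE_PAIRS, can_pair

MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5
GAP_PENALTY = 2.0
CORE_START, CORE_END = 2, 13     # 1-based miRNA positions, inclusive
CORE_WEIGHT = 2.0
DEFAULT_CUTOFF = 3.0


@dataclass(frozen=True)
class TargetHit:
    """One scored miRNA binding window on a transcript."""

    mirna_id: str
    transcript_id: str
    position: int              # 1-based window start on the transcript
    score: float
    alignment: tuple[str, str, str]   # miRNA 3'->5', match line, target 5'->3'
    cleavage_position: int     # transcript base opposite miRNA positions 10-11


def _position_weight(mirna_pos: int) -> float:
    """Penalty multiplier for a 1-based miRNA position."""
    return CORE_WEIGHT if CORE_START <= mirna_pos <= CORE_END else 1.0


def _pair_penalty(m_base: str, t_base: str) -> float:
    if can_pair(m_base, t_base):
        return WOBBLE_PENALTY if (m_base, t_base) in WOBBLE_PAIRS else 0.0
    return MISMATCH_PENALTY


def _score_ungapped(mirna: str, target_window: str) -> tuple[float, list[str]]:
    """Score an equal-length duplex; returns (score, match-line chars).

    The miRNA (5'->3') pairs antiparallel with the window (5'->3'), so
    miRNA position i faces window base len-1-i.
    """
    L = len(mirna)
    score = 0.0
    line = []
    for i in range(L):
        m = mirna[i]
        t = target_window[L - 1 - i]
        pen = _pair_penalty(m, t)
        score += pen * _position_weight(i + 1)
        line.append("|" if pen == 0.0 else "o" if pen == WOBBLE_PENALTY else " ")
    return score, line


def score_duplex_alignment(mirna: str, target_window: str
                           ) -> tuple[float, tuple[str, str, str]]:
    """Penalty score and alignment of a miRNA against one target window.

    Equal lengths are scored ungapped.  A length difference of one is
    scored with a single bulge (gap penalty 2.0, doubled in the core),
    choosing the bulge position that minimizes the total penalty.
    Larger length differences are an input error.
    """
    mirna = mirna.upper().replace("U", "T")
    window = target_window.upper().replace("U", "T")
    diff = len(window) - len(mirna)
    if diff == 0:
        score, line = _score_ungapped(mirna, window)
        m_disp, t_disp = mirna[::-1], window
    elif abs(diff) == 1:
        best = None
        longer, shorter = (window, mirna) if diff == 1 else (mirna, window)
        for skip in range(len(longer)):
            reduced = longer[:skip] + longer[skip + 1:]
            if diff == 1:
                s, line = _score_ungapped(mirna, reduced)
                gap_mirna_pos = len(mirna) - skip  # miRNA base facing the bulge
            else:
                s, line = _score_ungapped(reduced, window)
                gap_mirna_pos = skip + 1
            gap_mirna_pos = min(max(gap_mirna_pos, 1), len(mirna))
            s += GAP_PENALTY * _position_weight(gap_mirna_pos)
            if best is None or s < best[0]:
                best = (s, line, skip)
        score, line, _ = best
        m_disp, t_disp = mirna[::-1], window
    else:
        raise ValueError("window and miRNA lengths differ by more than 1")
    return score, (m_disp, "".join(line[::-1]), t_disp)


def scan_transcripts(mirna: str, transcripts: dict[str, str] | str | Path,
                     cutoff: float = DEFAULT_CUTOFF, mirna_id: str = "",
                     allow_bulge: bool = True) -> list[TargetHit]:
    """All target windows scoring <= cutoff, across all transcripts.

    Every window of the miRNA's length (and, with ``allow_bulge``,
    length +/- 1) is scored; hits are sorted by score, then transcript
    id, then position.  Deterministic by construction.
    """
    if not isinstance(transcripts, dict):
        transcripts = {rec.id: str(rec.seq).upper()
                       for rec in SeqIO.parse(str(transcripts), "fasta")}
    mirna = mirna.upper().replace("U", "T")
    L = len(mirna)
    lengths = [L] + ([L + 1, L - 1] if allow_bulge else [])
    hits = []
    for tid in sorted(transcripts):
        seq = transcripts[tid].upper().replace("U", "T")
        best_at: dict[int, TargetHit] = {}
        for wlen in lengths:
            for start in range(0, len(seq) - wlen + 1):
                window = seq[start:start + wlen]
                score, aln = score_duplex_alignment(mirna, window)
                if score > cutoff:
                    continue
                # transcript base opposite miRNA positions 10-11: 10 bases
                # in from the window's 3' end
                cleave = start + wlen - 10
                hit = TargetHit(mirna_id or mirna, tid, start + 1, score,
                                aln, cleave)
                prev = best_at.get(start)
                if prev is None or score < prev.score:
                    best_at[start] = hit
        hits.extend(best_at.values())
    hits.sort(key=lambda h: (h.score, h.transcript_id, h.position))
    return hits


def hits_to_rows(hits: list[TargetHit]) -> list[dict]:
    return [
        {"mirna_id": h.mirna_id, "transcript_id": h.transcript_id,
         "position": h.position, "score": h.score,
         "mirna_3to5": h.alignment[0], "match": h.alignment[1],
         "target_5to3": h.alignment[2], "cleavage_position": h.cleavage_position}
        for h in hits
    ]
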
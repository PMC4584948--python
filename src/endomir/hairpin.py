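"""Hairpin annotation: miRNA/miRNA* duplex calling on folded precursors.

Candidate precursor windows (~250 nt around an abundant tag) are folded
by base-pair maximization; an abundant small RNA on one arm is accepted
as a miRNA if a star partner exists on the opposite arm with the
canonical 2-nt 3' overhangs, at most 4 unpaired mature positions and no
asymmetric bulge larger than 2 nt — the community criteria for plant
miRNA annotation.  High-confidence novel calls additionally require a
21-nt length, a 5'-terminal U, and abundance above 100 RPM.  When two
non-overlapping duplexes are processed from one hairpin, the loop-distal
duplex keeps the base name and the loop-proximal one is suffixed ".1"
(tandem miRNAs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .design import LibraryDesign
from .fold import FoldResult, fold_sequence
from .preprocess import SmallRNATag
from .quantify import map_tags, rpm_normalize

#: Duplex-acceptance tolerances (plant miRNA annotation criteria).
MAX_UNPAIRED_MATURE = 4
MAX_ASYM_BULGE = 2
OVERHANG = 2  # nt, 3' overhang on both duplex ends

#: High-confidence novel-miRNA filter.
HC_LENGTH = 21
HC_FIVEP_BASE = "T"
HC_MIN_RPM = 100.0
HC_MIN_LIBRARIES = 1


@dataclass
class Duplex:
    """An accepted miRNA/miRNA* duplex on a folded precursor.

    Coordinates are 0-based half-open on the precursor; ``arm`` is the
    arm carrying the mature.  ``tandem_rank`` is 0 for the loop-distal
    (primary) duplex and 1 for a loop-proximal ".1" duplex.
    """

    precursor_id: str
    mature_start: int
    mature_end: int
    star_start: int
    star_end: int
    arm: str
    tandem_rank: int = 0

    @property
    def mature_span(self) -> tuple[int, int]:
        return (self.mature_start, self.mature_end)

    @property
    def star_span(self) -> tuple[int, int]:
        return (self.star_start, self.star_end)


@dataclass
class DuplexVerdict:
    duplex: Duplex | None
    reason: str | None

    @property
    def accepted(self) -> bool:
        return self.duplex is not None


def evaluate_duplex(fold: FoldResult, mature_start: int, mature_end: int,
                    precursor_id: str = "",
                    max_unpaired: int = MAX_UNPAIRED_MATURE,
                    max_bulge: int = MAX_ASYM_BULGE) -> DuplexVerdict:
    """Check a mature placement against the duplex criteria.

    The star region is read off the pairing: linearly extrapolating the
    mature's pairing line to its (possibly unpaired) termini and applying
    the 2-nt 3' overhang on both duplex ends.  Star read support is the
    caller's business — it is recorded, never required.
    """
    n = len(fold.seq)
    a, b = mature_start, mature_end
    if not (0 <= a < b <= n):
        raise ValueError("mature placement outside the precursor window")
    partner = fold.partner
    paired = [k for k in range(a, b) if partner[k] >= 0]
    if any(a <= partner[k] < b for k in paired):
        return DuplexVerdict(None, "loop-spanning")
    sides = {partner[k] >= b for k in paired}
    if len(sides) > 1:
        return DuplexVerdict(None, "loop-spanning")
    if (b - a) - len(paired) > max_unpaired:
        return DuplexVerdict(None, "too many unpaired mature positions")
    arm = "5p" if sides.pop() else "3p"

    for k1, k2 in zip(paired, paired[1:]):
        asym = abs((partner[k1] - partner[k2]) - (k2 - k1))
        if asym > max_bulge:
            return DuplexVerdict(None, "asymmetric bulge too large")

    k_first, k_last = paired[0], paired[-1]
    # extrapolated pairing line q(k), slope -1, anchored at each terminus
    q_b1 = partner[k_last] - ((b - 1) - k_last)
    q_a = partner[k_first] + (k_first - a)
    star_start = q_b1 + OVERHANG
    star_end = q_a + OVERHANG + 1
    if not (0 <= star_start < star_end <= n):
        return DuplexVerdict(None, "star outside the precursor window")
    if max(a, star_start) < min(b, star_end):
        return DuplexVerdict(None, "star overlaps mature")
    return DuplexVerdict(
        Duplex(precursor_id, a, b, star_start, star_end, arm), None)


def loop_midpoint(fold: FoldResult) -> float:
    """Midpoint of the terminal loop: center of the innermost pair."""
    if not fold.pairs:
        return len(fold.seq) / 2.0
    i, j = min(fold.pairs, key=lambda p: p[1] - p[0])
    return (i + j) / 2.0


def _loop_distance(duplex: Duplex, mid: float) -> float:
    def dist(span: tuple[int, int]) -> float:
        lo, hi = span
        if lo <= mid < hi:
            return 0.0
        return min(abs(mid - lo), abs(mid - (hi - 1)))
    return min(dist(duplex.mature_span), dist(duplex.star_span))


@dataclass
class TandemPair:
    """A loop-distal primary duplex and its loop-proximal ".1" partner."""

    precursor_id: str
    primary: Duplex
    proximal: Duplex


def detect_tandem(fold: FoldResult, duplexes: list[Duplex]) -> list[TandemPair]:
    """Rank co-resident duplexes by loop proximity and pair them.

    With >= 2 non-overlapping duplexes on one hairpin, the loop-distal
    duplex keeps the base name (rank 0) and each loop-proximal one is
    ranked 1 (suffix ".1").  Overlapping duplexes never reach this point:
    the caller merges them into a single duplex region first.
    """
    if len(duplexes) < 2:
        for d in duplexes:
            d.tandem_rank = 0
        return []
    mid = loop_midpoint(fold)
    ordered = sorted(duplexes, key=lambda d: (-_loop_distance(d, mid),
                                              d.mature_start))
    pairs = []
    ordered[0].tandem_rank = 0
    for proximal in ordered[1:]:
        proximal.tandem_rank = 1
        pairs.append(TandemPair(ordered[0].precursor_id, ordered[0], proximal))
    return pairs


@dataclass
class NovelCall:
    """One annotated miRNA with its filter verdict."""

    mirna_id: str
    precursor_id: str
    mature_seq: str
    star_seq: str
    duplex: Duplex
    max_rpm: float
    passes_filter: bool
    dotbracket: str = ""
    star_support: int = 0
    rpm: dict[str, float] = field(default_factory=dict)


def high_confidence_filter(seq: str, rpm_by_library: dict[str, float],
                           length: int = HC_LENGTH,
                           fivep_base: str = HC_FIVEP_BASE,
                           min_rpm: float = HC_MIN_RPM,
                           min_libraries: int = HC_MIN_LIBRARIES) -> bool:
    """High-confidence novel-miRNA predicate.

    True iff the mature is exactly ``length`` nt, starts with the 5'
    base U (T in DNA space), and exceeds ``min_rpm`` in at least
    ``min_libraries`` libraries (default: any one library; configurable
    up to all-of-n).
    """
    if len(seq) != length or (seq and seq[0].upper() != fivep_base):
        return False
    hot = sum(1 for v in rpm_by_library.values() if v > min_rpm)
    return hot >= min_libraries


def _overlap(x: tuple[int, int], y: tuple[int, int]) -> bool:
    return max(x[0], y[0]) < min(x[1], y[1])


def annotate_precursors(tags: list[SmallRNATag], totals: dict[str, int],
                        references: dict[str, str] | str | Path,
                        design: LibraryDesign,
                        min_tag_len: int = 20, max_tag_len: int = 24,
                        min_candidate_rpm: float = 10.0,
                        filter_kwargs: dict | None = None
                        ) -> tuple[list[NovelCall], list[TandemPair]]:
    """Full annotation pass: place tags, fold, call duplexes, filter.

    Overlapping accepted duplex regions are merged keeping the most
    abundant tag; a duplex whose mature lands on another accepted
    duplex's star arm is folded into that duplex (the more abundant arm
    is called mature), which also records star read support.
    """
    from Bio import SeqIO  # local: references may be a path

    if not isinstance(references, dict):
        references = {rec.id: str(rec.seq).upper()
                      for rec in SeqIO.parse(str(references), "fasta")}
    abundance = {t.seq: t.total for t in tags}
    # cheap prefilter: a tag can only place if it occurs somewhere in the
    # (separator-joined) reference set
    combined = "#".join(references.values())
    candidates = [t for t in tags
                  if min_tag_len <= len(t.seq) <= max_tag_len
                  and t.seq in combined]
    rpm_of = {
        t.seq: {lib: rpm_normalize(c, totals[lib])
                for lib, c in t.counts.items()}
        for t in candidates
    }
    candidates = [t for t in candidates
                  if max(rpm_of[t.seq].values(), default=0.0) >= min_candidate_rpm]
    placements = map_tags(candidates, references, max_mismatch=0)

    folds: dict[str, FoldResult] = {}
    accepted: dict[str, list[tuple[Duplex, str]]] = {}
    for p in sorted(placements,
                    key=lambda p: (-abundance[p.seq], p.reference_id, p.start)):
        if p.reference_id not in folds:
            folds[p.reference_id] = fold_sequence(references[p.reference_id])
        verdict = evaluate_duplex(folds[p.reference_id], p.start, p.end,
                                  precursor_id=p.reference_id)
        if not verdict.accepted:
            continue
        dup = verdict.duplex
        bucket = accepted.setdefault(p.reference_id, [])
        merged = False
        for prev, _seq in bucket:
            if _overlap(dup.mature_span, prev.mature_span) or \
               _overlap(dup.mature_span, prev.star_span):
                merged = True  # same duplex region; first (most abundant) wins
                break
        if not merged:
            bucket.append((dup, p.seq))

    calls: list[NovelCall] = []
    tandem_pairs: list[TandemPair] = []
    fkw = filter_kwargs or {}
    for rid in sorted(accepted):
        dups = [d for d, _ in accepted[rid]]
        seqs = {id(d): s for d, s in accepted[rid]}
        tandem_pairs.extend(detect_tandem(folds[rid], dups))
        for d in sorted(dups, key=lambda d: d.tandem_rank):
            mseq = seqs[id(d)]
            sseq = folds[rid].seq[d.star_start:d.star_end]
            rpm_row = rpm_of[mseq]
            name = rid if d.tandem_rank == 0 else f"{rid}.1"
            calls.append(NovelCall(
                mirna_id=name,
                precursor_id=rid,
                mature_seq=mseq,
                star_seq=sseq,
                duplex=d,
                max_rpm=max(rpm_row.values(), default=0.0),
                passes_filter=high_confidence_filter(mseq, rpm_row, **fkw),
                dotbracket=folds[rid].dotbracket,
                star_support=abundance.get(sseq, 0),
                rpm=rpm_row,
            ))
    return calls, tandem_pairs


def calls_to_frame(calls: list[NovelCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        d = c.duplex
        rows.append({
            "mirna_id": c.mirna_id, "precursor_id": c.precursor_id,
            "mature_seq": c.mature_seq, "star_seq": c.star_seq,
            "mature_start": d.mature_start + 1, "mature_end": d.mature_end,
            "star_start": d.star_start + 1, "star_end": d.star_end,
            "arm": d.arm, "tandem_rank": d.tandem_rank,
            "max_rpm": c.max_rpm, "star_support": c.star_support,
            "passes_filter": c.passes_filter,
        })
    return pd.DataFrame(rows)


def calls_to_gff3(calls: list[NovelCall], path: str | Path) -> None:
    """GFF3 output: miRNA_primary_transcript, miRNA and miRNA_star rows."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        seen = set()
        for c in calls:
            d = c.duplex
            if c.precursor_id not in seen:
                seen.add(c.precursor_id)
                fh.write(f"{c.precursor_id}\tendomir\tmiRNA_primary_transcript\t"
                         f"1\t{len(c.dotbracket)}\t.\t+\t.\t"
                         f"ID={c.precursor_id}\n")
            attrs = (f"ID={c.mirna_id};Parent={c.precursor_id};"
                     f"tandem_rank={d.tandem_rank}")
            fh.write(f"{c.precursor_id}\tendomir\tmiRNA\t{d.mature_start + 1}\t"
                     f"{d.mature_end}\t.\t+\t.\t{attrs}\n")
            fh.write(f"{c.precursor_id}\tendomir\tmiRNA_star\t{d.star_start + 1}\t"
                     f"{d.star_end}\t.\t+\t.\tID={c.mirna_id}*;"
                     f"Parent={c.precursor_id};tandem_rank={d.tandem_rank}\n")
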
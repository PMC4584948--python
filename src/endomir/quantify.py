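"""Tag placement, RPM normalization and expression-profile assembly.

Tags are placed on reference sequences by exhaustive scanning (exact by
default, optionally allowing substitutions), normalized to reads per
million (RPM) over each library's retained-read total, matched to known
mature miRNAs, and assembled into per-miRNA profiles across the
reciprocal-cross design with per-stage and per-tissue means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from ._seq import check_alphabet, revcomp
from .design import ENDOSPERM_DAPS, KERNEL_DAPS, LibraryDesign
from .preprocess import SmallRNATag


@dataclass(frozen=True)
class Placement:
    """One occurrence of a tag on a reference (0-based, half-open)."""

    seq: str
    reference_id: str
    start: int
    end: int
    strand: str          # "+" or "-"
    mismatches: int = 0

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.seq):
            raise ValueError("placement span does not match tag length")


def _scan(tag: str, ref: str, max_mismatch: int) -> list[tuple[int, int]]:
    """All (start, n_mismatch) occurrences of ``tag`` in ``ref``."""
    hits = []
    L = len(tag)
    if max_mismatch == 0:
        pos = ref.find(tag)
        while pos >= 0:
            hits.append((pos, 0))
            pos = ref.find(tag, pos + 1)
        return hits
    for pos in range(len(ref) - L + 1):
        mm = sum(a != b for a, b in zip(tag, ref[pos:pos + L]))
        if mm <= max_mismatch:
            hits.append((pos, mm))
    return hits


def map_tags(tags: list[SmallRNATag] | list[str],
             references: dict[str, str] | str | Path,
             max_mismatch: int = 0, both_strands: bool = False
             ) -> list[Placement]:
    """Place tags on references, reporting every occurrence.

    ``references`` is a {id: sequence} mapping or a FASTA path.  By
    default only the sense strand is scanned (precursor mapping); genome
    scans set ``both_strands=True``.
    """
    if not isinstance(references, dict):
        references = {rec.id: str(rec.seq).upper()
                      for rec in SeqIO.parse(str(references), "fasta")}
    if not references:
        raise ValueError("no reference sequences given")
    placements: list[Placement] = []
    for tag in tags:
        seq = tag.seq if isinstance(tag, SmallRNATag) else tag
        seq = seq.upper()
        check_alphabet(seq)
        for rid, ref in references.items():
            for start, mm in _scan(seq, ref, max_mismatch):
                placements.append(Placement(seq, rid, start, start + len(seq), "+", mm))
            if both_strands:
                for start, mm in _scan(revcomp(seq), ref, max_mismatch):
                    placements.append(
                        Placement(seq, rid, start, start + len(seq), "-", mm))
    return placements


def rpm_normalize(count: float, library_total: int) -> float:
    """Reads-per-million: count / library total x 1e6."""
    if library_total <= 0:
        raise ZeroDivisionError("RPM undefined for a zero-read library")
    return count / library_total * 1e6


@dataclass
class ExpressionProfile:
    """Per-miRNA RPM across libraries with stage and tissue means."""

    mirna_id: str
    seq: str
    rpm: dict[str, float]                              # library -> RPM
    stage_means: dict[tuple[str, int], float] = field(default_factory=dict)
    tissue_means: dict[tuple[str, str], float] = field(default_factory=dict)

    def combined_stage(self, dap: int) -> float:
        """Stage mean with reciprocal crosses combined (sum of reads)."""
        return sum(v for (c, d), v in self.stage_means.items() if d == dap)


def _finalize(profile: ExpressionProfile, design: LibraryDesign) -> None:
    for cross in {l.cross for l in design.libraries}:
        for dap in KERNEL_DAPS + ENDOSPERM_DAPS:
            libs = design.libraries_for(cross=cross, dap=dap)
            if libs:
                profile.stage_means[(cross, dap)] = sum(
                    profile.rpm.get(l.library_id, 0.0) for l in libs) / len(libs)
        for tissue in ("kernel", "endosperm"):
            libs = design.libraries_for(cross=cross, tissue=tissue)
            if libs:
                profile.tissue_means[(cross, tissue)] = sum(
                    profile.rpm.get(l.library_id, 0.0) for l in libs) / len(libs)


def assemble_profiles(tags: list[SmallRNATag], totals: dict[str, int],
                      design: LibraryDesign,
                      known_matures: dict[str, str] | str | Path | None = None,
                      max_mismatch: int = 0) -> list[ExpressionProfile]:
    """Assemble per-miRNA expression profiles from tag counts.

    Tags identical to (or within ``max_mismatch`` of) a known mature
    sequence are summed under that miRNA id; all other tags keep their
    own sequence as id.  RPM uses each library's retained-read total.
    """
    for lib in {l for t in tags for l in t.counts}:
        if lib not in design.library_ids:
            raise KeyError(f"library {lib!r} not in design")
        if lib not in totals:
            raise KeyError(f"no total for library {lib!r}")
    matures: dict[str, str] = {}
    if known_matures is not None:
        if isinstance(known_matures, dict):
            matures = {k: v.upper() for k, v in known_matures.items()}
        else:
            matures = {rec.id: str(rec.seq).upper()
                       for rec in SeqIO.parse(str(known_matures), "fasta")}

    def match_mirna(seq: str) -> str | None:
        for mid, mseq in matures.items():
            if len(mseq) == len(seq):
                mm = sum(a != b for a, b in zip(seq, mseq))
                if mm <= max_mismatch:
                    return mid
        return None

    grouped: dict[str, tuple[str, dict[str, float]]] = {}
    for tag in tags:
        mid = match_mirna(tag.seq)
        key = mid if mid is not None else tag.seq
        seq = matures[mid] if mid is not None else tag.seq
        _, counts = grouped.setdefault(key, (seq, {}))
        for lib, c in tag.counts.items():
            counts[lib] = counts.get(lib, 0.0) + c
        grouped[key] = (seq, counts)

    profiles = []
    for key in sorted(grouped):
        seq, counts = grouped[key]
        rpm = {lib: rpm_normalize(c, totals[lib]) for lib, c in counts.items()}
        prof = ExpressionProfile(key, seq, rpm)
        _finalize(prof, design)
        profiles.append(prof)
    return profiles


def profiles_to_frame(profiles: list[ExpressionProfile],
                      design: LibraryDesign) -> pd.DataFrame:
    """miRNA x library RPM matrix."""
    return pd.DataFrame(
        {lib: [p.rpm.get(lib, 0.0) for p in profiles]
         for lib in design.library_ids},
        index=pd.Index([p.mirna_id for p in profiles], name="mirna_id"))


def stage_means_frame(profiles: list[ExpressionProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for (cross, dap), v in sorted(p.stage_means.items()):
            rows.append({"mirna_id": p.mirna_id, "cross": cross,
                         "dap": dap, "mean_rpm": v})
    return pd.DataFrame(rows)


def placements_to_bed(placements: list[Placement], path: str | Path) -> None:
    """Write placements as BED6 (0-based half-open, like all BED)."""
    with open(path, "w") as fh:
        for p in placements:
            fh.write(f"{p.reference_id}\t{p.start}\t{p.end}\t{p.seq}\t"
                     f"{p.mismatches}\t{p.strand}\n")
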
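"""Read preprocessing: adapter trimming, length filtering, tag collapsing.

Small-RNA reads arrive 3'-adapter-ligated; the insert is whatever lies 5'
of the left-most adapter occurrence.  After trimming, reads shorter than
15 nt are discarded and survivors are collapsed to unique tags carrying
per-library counts — the atomic expression unit for everything downstream.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

MIN_TAG_LEN = 15
MAX_TAG_LEN = 30


@dataclass
class SmallRNATag:
    """A collapsed unique read sequence with per-library counts."""

    seq: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.seq)


def _trim_once(read: str, adapter: str, min_overlap: int) -> tuple[str, bool]:
    pos = read.find(adapter)
    if pos >= 0:
        return read[:pos], True
    # any >= min_overlap adapter prefix at the 3' end starts with the
    # adapter's first min_overlap bases, so a cheap containment check on
    # the read tail rules out almost all non-matching reads
    if adapter[:min_overlap] in read[-(len(adapter) - 1):]:
        for k in range(min(len(adapter) - 1, len(read)), min_overlap - 1, -1):
            if read.endswith(adapter[:k]):
                return read[:-k], True
    return read, False


def trim_adapter(read: str, adapter: str, min_overlap: int = 5
                 ) -> tuple[str, bool]:
    """Strip the 3' adapter from one read.

    Returns ``(insert, trimmed)``.  The insert is the sequence 5' of the
    left-most full adapter occurrence; failing that, a >= ``min_overlap``
    prefix of the adapter at the read's 3' end counts as a partial match.
    Trimming is applied to a fixed point, so the operation is idempotent
    even when the insert itself happens to end in an adapter prefix.
    Reads without any match are returned unchanged with ``trimmed=False``
    (kept: collapsing keeps spurious untrimmed tags at negligible counts).
    """
    if not adapter:
        raise ValueError("adapter sequence must be non-empty")
    if min_overlap < 5:
        raise ValueError("min_overlap must be >= 5")
    read = read.upper()
    adapter = adapter.upper()
    out, any_trim = _trim_once(read, adapter, min_overlap)
    while True:
        out2, hit = _trim_once(out, adapter, min_overlap)
        if not hit or out2 == out:
            break
        out = out2
    return out, any_trim


def collapse_and_filter(reads_by_library: dict[str, Iterable[str]],
                        min_len: int = MIN_TAG_LEN,
                        max_len: int = MAX_TAG_LEN) -> list[SmallRNATag]:
    """Collapse trimmed reads into unique tags with per-library counts.

    Reads outside [min_len, max_len] are dropped.  Tags are returned
    sorted by total abundance (descending), then sequence, for
    deterministic output.
    """
    tally: dict[str, Counter] = {}
    for lib, reads in reads_by_library.items():
        for r in reads:
            r = r.upper()
            if min_len <= len(r) <= max_len:
                tally.setdefault(r, Counter())[lib] += 1
    tags = [SmallRNATag(seq, dict(c)) for seq, c in tally.items()]
    tags.sort(key=lambda t: (-t.total, t.seq))
    return tags


def preprocess_fastq(fastq_paths: dict[str, str | Path], adapter: str,
                     min_overlap: int = 5, min_len: int = MIN_TAG_LEN,
                     max_len: int = MAX_TAG_LEN
                     ) -> tuple[list[SmallRNATag], dict[str, int]]:
    """Trim, filter and collapse one FASTQ file per library.

    Returns the tag set and the per-library count of retained reads (the
    RPM denominator used downstream).
    """
    trimmed: dict[str, list[str]] = {}
    for lib, path in fastq_paths.items():
        inserts = []
        with open(path) as fh:
            for _title, seq, _qual in FastqGeneralIterator(fh):
                ins, _ = trim_adapter(seq, adapter, min_overlap)
                if min_len <= len(ins) <= max_len:
                    inserts.append(ins)
        trimmed[lib] = inserts
    tags = collapse_and_filter(trimmed, min_len, max_len)
    totals = {lib: len(reads) for lib, reads in trimmed.items()}
    return tags, totals


def composition_profile(tags: list[SmallRNATag]) -> pd.DataFrame:
    """Length / 5'-nucleotide composition per library.

    For each (library, length, 5' base): the fraction of read abundance
    and the fraction of distinct tags, each normalized within its
    (library, length) cell so the four bases sum to 1.
    """
    if not tags:
        raise ValueError("composition profile of an empty tag set")
    rows = []
    for tag in tags:
        for lib, c in tag.counts.items():
            rows.append((lib, len(tag.seq), tag.seq[0], c))
    df = pd.DataFrame(rows, columns=["library_id", "length", "base", "count"])
    grouped = df.groupby(["library_id", "length", "base"]).agg(
        abundance=("count", "sum"), distinct=("count", "size")).reset_index()
    for col, frac in (("abundance", "abundance_fraction"),
                      ("distinct", "distinct_fraction")):
        totals = grouped.groupby(["library_id", "length"])[col].transform("sum")
        grouped[frac] = grouped[col] / totals
    return grouped


def tags_to_fasta(tags: list[SmallRNATag], path: str | Path) -> None:
    """Write collapsed tags as FASTA, ``>tag<N>_x<total count>``."""
    with open(path, "w") as fh:
        for i, tag in enumerate(tags, start=1):
            fh.write(f">tag{i}_x{tag.total}\n{tag.seq}\n")


def tags_to_matrix(tags: list[SmallRNATag],
                   library_ids: list[str] | None = None) -> pd.DataFrame:
    """Tag x library count matrix (rows indexed by tag sequence)."""
    if library_ids is None:
        library_ids = sorted({lib for t in tags for lib in t.counts})
    data = {lib: [t.counts.get(lib, 0) for t in tags] for lib in library_ids}
    return pd.DataFrame(data, index=[t.seq for t in tags]).rename_axis("seq")
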
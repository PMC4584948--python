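"""Synthetic small-RNA experiment generator with known ground truth.

Emulates the 12-library reciprocal-cross design (B73xMo17 and Mo17xB73;
kernels at 0/3/5 DAP, endosperm at 7/10/15 DAP): designed stem-loop
precursors releasing 21-nt miRNA/miRNA* duplexes (optionally a second,
loop-proximal tandem duplex), a 24-nt siRNA background with a 5'-A bias,
stage-dependent abundance profiles, and a diagnostic SNP inside a mature
miRNA whose alleles are drawn at the triploid 2:1 maternal:paternal
dosage in endosperm libraries.

Every planted molecule is recorded in a truth table so downstream stages
(annotation, pattern classification, allele-bias testing) can be scored
against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import revcomp
from .design import LibraryDesign, reciprocal_design
from .known import NOVEL_MIRNAS

StageKey = tuple[str, int]  # (cross, DAP)

#: Default 3' adapter (Illumina TruSeq small RNA).
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

#: Default background length distribution: dominated by 24-nt siRNAs with
#: a secondary 21-nt component, matching the length profile of maize
#: kernel/endosperm small-RNA libraries.
DEFAULT_LENGTH_DIST = {20: 0.05, 21: 0.125, 22: 0.05, 23: 0.05, 24: 0.68, 25: 0.045}

#: Average fraction of 24-nt background reads starting with 5'-A.
DEFAULT_FIVEP_A_BIAS = 0.46


class ConfigError(ValueError):
    """A simulation configuration that cannot be honoured."""


class PlacementError(ValueError):
    """A requested duplex placement that does not fit on the hairpin."""


@dataclass(frozen=True)
class SNPSpec:
    """A diagnostic SNP inside a mature miRNA.

    ``offset`` is 1-based from the mature 5' end; allele A is the base
    present in the recorded mature sequence (B73 by convention), allele B
    the alternative (Mo17).
    """

    offset: int
    allele_a: str
    allele_b: str


@dataclass
class TruthRecord:
    """One designed precursor and everything planted on it."""

    precursor_id: str
    precursor_seq: str
    mature_seq: str
    star_seq: str
    arm: str                       # arm of the mature: "5p" or "3p"
    mature_start: int              # 0-based on precursor
    star_start: int
    tandem_seq: str | None = None       # loop-proximal second duplex (".1")
    tandem_star_seq: str | None = None
    tandem_start: int | None = None
    tandem_star_start: int | None = None
    snp: SNPSpec | None = None
    #: intended mature abundance (RPM) per (cross, DAP)
    abundance_profile: dict[StageKey, float] = field(default_factory=dict)
    #: intended abundance of the tandem duplex; defaults to half the mature
    tandem_profile: dict[StageKey, float] | None = None
    #: overrides the dosage-derived allele-A fraction (genotype-effect bias)
    allele_a_fraction: float | None = None
    background: bool = False

    def __post_init__(self) -> None:
        p = self.precursor_seq
        if p[self.mature_start:self.mature_start + len(self.mature_seq)] != self.mature_seq:
            raise PlacementError("mature sequence not at recorded coordinates")
        if p[self.star_start:self.star_start + len(self.star_seq)] != self.star_seq:
            raise PlacementError("star sequence not at recorded coordinates")
        if self.snp is not None and not (1 <= self.snp.offset <= len(self.mature_seq)):
            raise PlacementError("SNP offset outside the mature sequence")
        if self.tandem_seq is not None:
            a = (self.mature_start, self.mature_start + len(self.mature_seq))
            t = (self.tandem_start, self.tandem_start + len(self.tandem_seq))
            if max(a[0], t[0]) < min(a[1], t[1]):
                raise PlacementError("tandem duplex overlaps the primary duplex")

    def mature_allele(self, which: str) -> str:
        """Mature sequence carrying allele 'A' or 'B' at the SNP."""
        if self.snp is None or which == "A":
            return self.mature_seq
        i = self.snp.offset - 1
        return self.mature_seq[:i] + self.snp.allele_b + self.mature_seq[i + 1:]


@dataclass
class SimConfig:
    """Study conditions for one simulated experiment."""

    design: LibraryDesign = field(default_factory=reciprocal_design)
    total_reads: int = 200_000
    background_fraction: float | None = None   # None: fill to intended RPM
    background_fivep_A_bias: float = DEFAULT_FIVEP_A_BIAS
    background_length_dist: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DIST))
    adapter_seq: str = DEFAULT_ADAPTER
    maternal_dosage: float = 2.0 / 3.0
    star_fraction: float = 0.1                 # star RPM as fraction of mature
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ConfigError("total_reads must be positive")
        for name in ("background_fivep_A_bias", "maternal_dosage", "star_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.background_fraction is not None and not (0.0 <= self.background_fraction <= 1.0):
            raise ConfigError("background_fraction must lie in [0, 1]")


def _random_bases(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), n)])


def _random_read_block(rng: np.random.Generator, count: int, length: int
                       ) -> list[str]:
    """``count`` uniform-ACGT reads of one length, generated in one draw."""
    codes = rng.integers(0, 4, size=(count, length), dtype=np.uint8)
    flat = np.frombuffer(b"ACGT", dtype=np.uint8)[codes]
    blob = flat.tobytes().decode("ascii")
    return [blob[i * length:(i + 1) * length] for i in range(count)]


def design_hairpin(mature: str, loop_len: int = 8, tandem: str | None = None,
                   seed: int = 0, precursor_id: str = "hp",
                   snp: SNPSpec | None = None,
                   abundance_profile: dict[StageKey, float] | None = None,
                   ) -> TruthRecord:
    """Design a stem-loop precursor releasing the given mature duplex.

    The mature sits loop-distal on the 5p arm; its star is the reverse
    complement on the 3p arm offset so the duplex carries the canonical
    2-nt 3' overhangs.  A tandem duplex, when requested, is placed
    loop-proximal to the mature on the same arm and never overlaps it.
    The terminal loop is drawn from {A, C} only, so it cannot pair with
    itself and the designed stem is the maximum-pairing structure.
    """
    mature = mature.upper()
    if not (20 <= len(mature) <= 24):
        raise PlacementError(f"mature length {len(mature)} outside 20-24")
    if loop_len < 3:
        raise ValueError(f"loop_len {loop_len} < 3 cannot close a hairpin")
    if tandem is not None:
        tandem = tandem.upper()
        if not (20 <= len(tandem) <= 24):
            raise PlacementError(f"tandem length {len(tandem)} outside 20-24")

    rng = np.random.default_rng(seed)
    pad5 = _random_bases(rng, 5)
    spacer = _random_bases(rng, 4)
    arm5 = pad5 + mature + spacer
    tandem_start = None
    if tandem is not None:
        tandem_start = len(arm5)
        arm5 = arm5 + tandem + _random_bases(rng, 2)
    loop = _random_bases(rng, loop_len, alphabet="AC")
    precursor = arm5 + loop + revcomp(arm5)
    n = len(precursor)

    def star_of(start: int, length: int) -> tuple[int, str]:
        # pairing partner of [start, start+length) shifted for the 2-nt
        # 3' overhangs on both duplex ends
        s = n - (start + length) + 2
        return s, precursor[s:s + length]

    a = len(pad5)
    star_start, star_seq = star_of(a, len(mature))
    tandem_fields: dict = {}
    if tandem is not None:
        ts_start, ts_seq = star_of(tandem_start, len(tandem))
        tandem_fields = dict(tandem_seq=tandem, tandem_star_seq=ts_seq,
                             tandem_start=tandem_start,
                             tandem_star_start=ts_start)
    return TruthRecord(
        precursor_id=precursor_id,
        precursor_seq=precursor,
        mature_seq=mature,
        star_seq=star_seq,
        arm="5p",
        mature_start=a,
        star_start=star_start,
        snp=snp,
        abundance_profile=dict(abundance_profile or {}),
        **tandem_fields,
    )


def sample_background(n: int, length_dist: dict[int, float] | None = None,
                      fivep_A_bias: float = DEFAULT_FIVEP_A_BIAS,
                      seed: int | np.random.Generator = 0) -> list[str]:
    """Draw background siRNA-like sequences.

    Lengths follow ``length_dist``; 24-nt reads start with A at the
    requested frequency (the 5'-A preference of heterochromatic siRNAs),
    all other positions are uniform over ACGT.
    """
    if n <= 0:
        return []
    dist = dict(DEFAULT_LENGTH_DIST) if length_dist is None else length_dist
    total = sum(dist.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"length distribution sums to {total}, not 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths = list(dist)
    counts = rng.multinomial(n, [dist[l] / total for l in lengths])
    reads: list[str] = []
    for length, c in zip(lengths, counts):
        if c == 0:
            continue
        block = _random_read_block(rng, int(c), length)
        if length == 24:
            biased = rng.random(int(c)) < fivep_A_bias
            other = np.array(list("CGT"))[rng.integers(0, 3, int(c))]
            block = [("A" if hit else alt) + seq[1:]
                     for seq, hit, alt in zip(block, biased, other)]
        reads.extend(block)
    return reads


@dataclass
class SimResult:
    """Paths and tables produced by :func:`simulate_experiment`."""

    fastq_paths: dict[str, Path]
    precursor_fasta: Path
    truth_table: pd.DataFrame
    truth_tsv: Path
    snp_tsv: Path
    design_tsv: Path


def _allele_a_prob(truth: TruthRecord, cross: str, tissue: str,
                   maternal_dosage: float) -> float:
    if truth.allele_a_fraction is not None:
        return truth.allele_a_fraction
    if tissue != "endosperm":
        return 0.5
    # allele A (B73) is maternal in BxM, paternal in MxB
    return maternal_dosage if cross == "BxM" else 1.0 - maternal_dosage


def simulate_experiment(truths: list[TruthRecord], cfg: SimConfig,
                        outdir: str | Path) -> SimResult:
    """Write per-library FASTQ files plus truth/SNP/design tables.

    Per library, planted reads are a multinomial draw across all planted
    species proportional to their intended RPM; the remainder of the
    library is background.  With ``background_fraction=None`` the
    background fills exactly to the library total so that intended RPM is
    unbiased.  SNP alleles are drawn per read at the dosage-appropriate
    allele-A probability.  Identical config and seed give byte-identical
    output files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = cfg.design

    # planted species: (truth, role, rpm-lookup)
    def unit_rpm(truth: TruthRecord, role: str, key: StageKey) -> float:
        if key not in truth.abundance_profile:
            raise ConfigError(
                f"{truth.precursor_id}: abundance profile missing stage {key}")
        base = truth.abundance_profile[key]
        if role == "mature":
            return base
        if role == "star":
            return base * cfg.star_fraction
        tandem = (truth.tandem_profile[key]
                  if truth.tandem_profile is not None else 0.5 * base)
        return tandem if role == "tandem" else tandem * cfg.star_fraction

    units: list[tuple[TruthRecord, str, str]] = []
    for t in truths:
        units.append((t, "mature", t.mature_seq))
        units.append((t, "star", t.star_seq))
        if t.tandem_seq is not None:
            units.append((t, "tandem", t.tandem_seq))
            units.append((t, "tandem_star", t.tandem_star_seq))

    fastq_paths: dict[str, Path] = {}
    for lib_index, lib in enumerate(design.libraries):
        rng = np.random.default_rng([cfg.seed, lib_index])
        key: StageKey = (lib.cross, lib.dap)
        rpms = np.array([unit_rpm(t, role, key) for t, role, _ in units])
        intended_planted = rpms.sum() / 1e6
        if cfg.background_fraction is None:
            bg_frac = 1.0 - intended_planted
            if bg_frac < -1e-9:
                raise ConfigError(
                    f"intended RPM in {lib.library_id} exceeds 1e6; cannot "
                    "auto-fill background")
            bg_frac = max(bg_frac, 0.0)
        else:
            bg_frac = cfg.background_fraction
        n_bg = int(round(cfg.total_reads * bg_frac))
        n_planted = cfg.total_reads - n_bg
        if rpms.sum() > 0 and n_planted > 0:
            counts = rng.multinomial(n_planted, rpms / rpms.sum())
        else:
            counts = np.zeros(len(units), dtype=int)
            n_bg = cfg.total_reads

        inserts: list[str] = []
        for (t, role, seq), c in zip(units, counts):
            if c == 0:
                continue
            if role == "mature" and t.snp is not None:
                p_a = _allele_a_prob(t, lib.cross, lib.tissue, cfg.maternal_dosage)
                n_a = rng.binomial(c, p_a)
                inserts.extend([t.mature_allele("A")] * int(n_a))
                inserts.extend([t.mature_allele("B")] * int(c - n_a))
            else:
                inserts.extend([seq] * int(c))
        inserts.extend(sample_background(
            n_bg, cfg.background_length_dist, cfg.background_fivep_A_bias, rng))

        path = outdir / f"{lib.library_id}.fastq"
        with open(path, "w") as fh:
            for i, ins in enumerate(inserts):
                read = ins + cfg.adapter_seq
                fh.write(f"@{lib.library_id}_{i}\n{read}\n+\n{'I' * len(read)}\n")
        fastq_paths[lib.library_id] = path

    precursor_fasta = outdir / "precursors.fasta"
    with open(precursor_fasta, "w") as fh:
        for t in truths:
            fh.write(f">{t.precursor_id}\n{t.precursor_seq}\n")

    rows = []
    for t in truths:
        entries = [("mature", t.mature_seq, t.mature_start, "5p"),
                   ("star", t.star_seq, t.star_start, "3p")]
        if t.tandem_seq is not None:
            entries += [("tandem", t.tandem_seq, t.tandem_start, "5p"),
                        ("tandem_star", t.tandem_star_seq, t.tandem_star_start, "3p")]
        for role, seq, start, arm in entries:
            row = {
                "precursor_id": t.precursor_id,
                "role": role,
                "seq": seq,
                "start": start + 1,      # reports are 1-based inclusive
                "end": start + len(seq),
                "arm": arm,
                "snp_offset": t.snp.offset if (t.snp and role == "mature") else "",
                "allele_a": t.snp.allele_a if (t.snp and role == "mature") else "",
                "allele_b": t.snp.allele_b if (t.snp and role == "mature") else "",
            }
            for lib in design.libraries:
                row[f"rpm_{lib.library_id}"] = unit_rpm(t, role, (lib.cross, lib.dap))
            rows.append(row)
    truth_table = pd.DataFrame(rows)
    truth_tsv = outdir / "truth.tsv"
    truth_table.to_csv(truth_tsv, sep="\t", index=False)

    snp_rows = [
        {"precursor_id": t.precursor_id,
         "position": t.mature_start + t.snp.offset,  # 1-based on precursor
         "ref": t.snp.allele_a, "alt": t.snp.allele_b}
        for t in truths if t.snp is not None
    ]
    snp_tsv = outdir / "snps.tsv"
    pd.DataFrame(snp_rows, columns=["precursor_id", "position", "ref", "alt"]
                 ).to_csv(snp_tsv, sep="\t", index=False)

    design_tsv = outdir / "design.tsv"
    design.to_tsv(design_tsv)
    return SimResult(fastq_paths, precursor_fasta, truth_table, truth_tsv,
                     snp_tsv, design_tsv)


# ---------------------------------------------------------------------------
# Canned study conditions

#: Stage-profile archetypes over (7, 10, 15)-DAP endosperm, as multiples of
#: a base RPM; kernels get a small flat level so endosperm enrichment is
#: strong (tens-fold on average).  Steps are 4-fold, comfortably past the
#: 1.5-fold classification threshold.
_PATTERN_SHAPES = {
    "one-step-down": (4.0, 1.0, 1.0),
    "one-step-up": (1.0, 1.0, 4.0),
    "two-step-up-down": (1.0, 4.0, 1.0),
    "two-step-down-up": (4.0, 1.0, 4.0),
}


def endosperm_truth_set(n_hairpins: int = 18, n_tandem: int = 2,
                        base_rpm: float = 400.0, kernel_rpm: float = 8.0,
                        seed: int = 0) -> list[TruthRecord]:
    """A study-condition truth set: endosperm-enriched 21-nt 5'-U miRNAs.

    Matures are the published novel endosperm miRNA sequences (recycled
    with substitutions when more than 18 hairpins are requested); the
    first ``n_tandem`` precursors carry a loop-proximal tandem duplex,
    mirroring the tandem miRNAs observed on single maize hairpins.
    Profiles cycle through the four temporal pattern archetypes.
    """
    rng = np.random.default_rng(seed)
    matures = list(NOVEL_MIRNAS.values())
    while len(matures) < n_hairpins:
        donor = matures[len(matures) % 18]
        i = int(rng.integers(1, len(donor)))
        alt = "ACGT"[(("ACGT".index(donor[i])) + 1 + int(rng.integers(0, 3))) % 4]
        matures.append(donor[:i] + alt + donor[i + 1:])
    shapes = list(_PATTERN_SHAPES.values())
    truths = []
    for idx in range(n_hairpins):
        shape = shapes[idx % len(shapes)]
        profile: dict[StageKey, float] = {}
        for cross in ("BxM", "MxB"):
            scale = 1.0 if cross == "BxM" else 0.8  # mild reciprocal partition
            for dap, mult in zip((7, 10, 15), shape):
                profile[(cross, dap)] = base_rpm * mult * scale
            for dap in (0, 3, 5):
                profile[(cross, dap)] = kernel_rpm * scale
        tandem = None
        if idx < n_tandem:
            donor = matures[(idx + 7) % len(matures)]
            tandem = "T" + donor[1:][::-1]  # distinct from every mature
        truths.append(design_hairpin(
            matures[idx], loop_len=8, tandem=tandem,
            seed=int(rng.integers(0, 2**31)), precursor_id=f"hp{idx + 1:03d}",
            abundance_profile=profile))
    return truths
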
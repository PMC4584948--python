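"""Allele-biased miRNA expression from a diagnostic SNP.

Endosperm is triploid (2 maternal : 1 paternal genome copies), so the
null expectation for allele counts in an endosperm library is 2:1 in
favour of whichever allele the maternal parent carries — not 1:1.  Reads
covering the SNP position of a mature miRNA are partitioned by the base
they carry; per-library goodness-of-fit chi-square tests against the
dosage null (or an optional equal null), with Benjamini-Hochberg
adjustment across tests, feed a cross-aware classification separating
genotype effects (same allele favoured in both reciprocal crosses) from
parent-of-origin effects (the favoured allele tracks the maternal
parent).  An in-silico CAPS digest mirrors the wet-lab confirmation:
alleles are distinguishable when a SNP creates or destroys a restriction
site and the fragment-length multisets differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .design import LibraryDesign
from .preprocess import SmallRNATag
from .simulate import SNPSpec

ALPHA = 0.01

BIAS_CLASSES = ("genotype-biased toward A", "genotype-biased toward B",
                "parent-of-origin maternal", "parent-of-origin paternal",
                "unbiased")


@dataclass
class AlleleCountTable:
    """Per-library allele counts for one miRNA at one SNP."""

    mirna_id: str
    snp: SNPSpec
    counts: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    # library_id -> (n_allele_A, n_allele_B, n_ambiguous)


def partition_by_allele(tags: list[SmallRNATag], reference_id: str,
                        mature_start: int, mature_end: int,
                        snp: SNPSpec, placements=None,
                        references: dict[str, str] | None = None,
                        mirna_id: str = "") -> AlleleCountTable:
    """Assign reads on a mature locus to parental alleles at the SNP.

    A tag placed on the locus whose base at the SNP offset equals
    allele A or B is counted for that allele; tags carrying a third base
    or not covering the offset are ambiguous.  Placement is by exact
    sense-strand occurrence within the mature locus when ``references``
    is given, else tags are interpreted as already locus-aligned at
    ``mature_start``.
    """
    if not (1 <= snp.offset <= mature_end - mature_start):
        raise ValueError("SNP offset outside the mature locus")
    snp_pos = mature_start + snp.offset - 1  # 0-based on the reference
    table = AlleleCountTable(mirna_id or reference_id, snp)
    for tag in tags:
        if references is not None:
            # windowed scan over the locus with the SNP position
            # wildcarded, so reads carrying either allele (or a third
            # base at the SNP) still place on the locus
            ref = references[reference_id]
            L = len(tag.seq)
            starts = []
            for s in range(max(0, mature_start - L + 1),
                           min(mature_end, len(ref) - L + 1)):
                window = ref[s:s + L]
                ok = all(a == b or s + i == snp_pos
                         for i, (a, b) in enumerate(zip(tag.seq, window)))
                if ok:
                    starts.append(s)
        else:
            starts = [mature_start]
        for start in starts:
            if not (start <= snp_pos < start + len(tag.seq)):
                kind = "ambiguous"
            else:
                base = tag.seq[snp_pos - start]
                kind = ("A" if base == snp.allele_a
                        else "B" if base == snp.allele_b else "ambiguous")
            for lib, c in tag.counts.items():
                na, nb, namb = table.counts.get(lib, (0, 0, 0))
                if kind == "A":
                    na += c
                elif kind == "B":
                    nb += c
                else:
                    namb += c
                table.counts[lib] = (na, nb, namb)
            break  # one placement per tag is enough for counting
    return table


def chi_square_bias_test(n_a: int, n_b: int, null_ratio: float = 0.5
                         ) -> tuple[float, float]:
    """1-df goodness-of-fit chi-square of (n_a, n_b) against a null fraction.

    ``null_ratio`` is the expected fraction of allele A (2/3 under the
    triploid dosage null for the maternal allele; 1/2 for the no-dosage
    model).
    """
    n = n_a + n_b
    if n < 1:
        raise ValueError("chi-square test undefined with zero informative reads")
    if not (0.0 < null_ratio < 1.0):
        raise ValueError("null_ratio must lie strictly inside (0, 1)")
    exp_a = n * null_ratio
    exp_b = n * (1.0 - null_ratio)
    chi2 = (n_a - exp_a) ** 2 / exp_a + (n_b - exp_b) ** 2 / exp_b
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def null_fraction_a(cross: str, tissue: str, maternal_dosage: float = 2 / 3,
                    dosage_null: bool = True) -> float:
    """Expected allele-A fraction under the null for one library.

    Allele A is the B73 allele, maternal in the BxM cross direction.
    Kernels (maternal sporophyte plus filial tissue mix) use 1:1.
    """
    if not dosage_null or tissue != "endosperm":
        return 0.5
    return maternal_dosage if cross == "BxM" else 1.0 - maternal_dosage


@dataclass
class BiasCall:
    """Per-library test results plus the overall bias class."""

    mirna_id: str
    table: pd.DataFrame          # library, cross, nA, nB, chi2, p, q, direction
    bias_class: str


def call_bias_class(counts: AlleleCountTable, design: LibraryDesign,
                    alpha: float = ALPHA, maternal_dosage: float = 2 / 3,
                    dosage_null: bool = True,
                    tissue: str = "endosperm") -> BiasCall:
    """Classify allelic bias across both reciprocal cross directions.

    Each tested library gets a chi-square against its dosage null and a
    BH-adjusted q-value.  Genotype bias toward an allele requires that
    allele to be significantly over-represented (q <= alpha) in both
    cross directions; a parent-of-origin call requires the significant
    excess to track the maternal (or paternal) parent in both
    directions; anything else is unbiased.
    """
    rows = []
    for lib_id, (na, nb, namb) in sorted(counts.counts.items()):
        lib = design[lib_id]
        if tissue is not None and lib.tissue != tissue:
            continue
        if na + nb == 0:
            continue
        null_a = null_fraction_a(lib.cross, lib.tissue, maternal_dosage,
                                 dosage_null)
        chi2, p = chi_square_bias_test(na, nb, null_a)
        frac_a = na / (na + nb)
        rows.append({"library_id": lib_id, "cross": lib.cross,
                     "n_a": na, "n_b": nb, "n_ambiguous": namb,
                     "null_a": null_a, "frac_a": frac_a, "chi2": chi2,
                     "p": p, "direction": "A" if frac_a > null_a else "B"})
    df = pd.DataFrame(rows)
    if df.empty:
        return BiasCall(counts.mirna_id, df, "unbiased")
    df["q"] = stats.false_discovery_control(df["p"], method="bh")

    def cross_direction(cross: str) -> str | None:
        sig = df[(df.cross == cross) & (df.q <= alpha)]
        if sig.empty:
            return None
        dirs = set(sig.direction)
        return dirs.pop() if len(dirs) == 1 else None

    d_bxm = cross_direction("BxM")
    d_mxb = cross_direction("MxB")
    if d_bxm is None or d_mxb is None:
        cls = "unbiased"
    elif d_bxm == d_mxb:
        cls = f"genotype-biased toward {d_bxm}"
    else:
        # allele A is maternal in BxM: A-excess in BxM with B-excess in MxB
        # means the maternal allele is favoured in both directions
        cls = ("parent-of-origin maternal" if d_bxm == "A"
               else "parent-of-origin paternal")
    return BiasCall(counts.mirna_id, df, cls)


def insilico_caps(amplicon: str, recognition_site: str, cut_offset: int = 1
                  ) -> list[int]:
    """Fragment lengths after digesting an amplicon at every site.

    ``cut_offset`` is the cut position within the recognition site
    (bases from the site's 5' end after which the enzyme cuts).
    Fragment lengths always sum to the amplicon length.
    """
    if not recognition_site:
        raise ValueError("recognition site must be non-empty")
    if not (0 <= cut_offset <= len(recognition_site)):
        raise ValueError("cut offset outside the recognition site")
    amplicon = amplicon.upper()
    site = recognition_site.upper()
    cuts = []
    pos = amplicon.find(site)
    while pos >= 0:
        cuts.append(pos + cut_offset)
        pos = amplicon.find(site, pos + 1)
    cuts = sorted({c for c in cuts if 0 < c < len(amplicon)})
    bounds = [0] + cuts + [len(amplicon)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def caps_distinguishable(amplicon_a: str, amplicon_b: str,
                         recognition_site: str, cut_offset: int = 1) -> bool:
    """True if the two allelic amplicons yield different fragment multisets."""
    fa = sorted(insilico_caps(amplicon_a, recognition_site, cut_offset))
    fb = sorted(insilico_caps(amplicon_b, recognition_site, cut_offset))
    return fa != fb
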
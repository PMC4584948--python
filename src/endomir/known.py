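"""Published maize endosperm miRNA sequences used as reference inputs.

The 18 novel endosperm-abundant miRNAs (Zma-miR2001..Zma-miR2018) are the
mature sequences reported for developing maize endosperm; all are 21 nt
with a 5'-terminal U (T in DNA space).  Zma-miR408-5p carries an A/G SNP
between the B73 and Mo17 inbred lines at the 11th base from the 5' end,
which makes it the one miRNA whose parental alleles can be told apart in
read data from reciprocal crosses.
"""

from __future__ import annotations

#: Mature sequences of the 18 novel endosperm-abundant miRNAs (DNA space).
NOVEL_MIRNAS: dict[str, str] = {
    "Zma-miR2001": "TCTTTTTATTAGTCGTTGGAT",
    "Zma-miR2002": "TGATATCACATGTAGAGGCTG",
    "Zma-miR2003": "TGGAGGGAATTGAAGGGGCTA",
    "Zma-miR2004": "TTGAAGGGGATTGGAGAGGAT",
    "Zma-miR2005": "TGAGGGGATTGAAGGAGCTAA",
    "Zma-miR2006": "TTCTTAGGAAAAGAGGTCGGC",
    "Zma-miR2007": "TGGAGAGGATTGTAGGGGCTA",
    "Zma-miR2008": "TTTGGATTGAATTGGTTGGTG",
    "Zma-miR2009": "TTGGATTTTGATTGGATGCAC",
    "Zma-miR2010": "TGGAGGGGATTGGAGAGGCTA",
    "Zma-miR2011": "TCTAAAATGAGTGGTGCTGAT",
    "Zma-miR2012": "TTTGGATCTAGAATCAAAGGC",
    "Zma-miR2013": "TAATTTAGGGACTAAAATGGA",
    "Zma-miR2014": "TGAAGAGAATTGAGGGGGCTA",
    "Zma-miR2015": "TGTGGATTAGGTGGGATTGGA",
    "Zma-miR2016": "TGAGGAGTCAAGTAGAACGGA",
    "Zma-miR2017": "TCGTTTTAGTTGTCGTTGGAT",
    "Zma-miR2018": "TCTCGAAGCGAGTCTGAGTGA",
}

#: 1-based offset of the B73/Mo17 SNP within mature Zma-miR408-5p.
MIR408_5P_SNP_OFFSET = 11

#: SNP alleles (B73 carries A, Mo17 carries G at the 11th base).
MIR408_5P_ALLELES = ("A", "G")
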
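"""Scan a transcript for miRNA target sites by penalty scoring.

Mismatch 1.0, G:U wobble 0.5, gap 2.0, doubled over miRNA positions
2-13; windows scoring <= 3.0 are candidate cleavage targets.
"""

import numpy as np

from endomir._seq import revcomp
from endomir.known import NOVEL_MIRNAS
from endomir.targets import scan_transcripts

mirna = NOVEL_MIRNAS["Zma-miR2001"]
rng = np.random.default_rng(4)
tx = list("".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)]))

site = list(revcomp(mirna))
site[2] = "T"                      # one G:U wobble near the miRNA 3' end
tx[800:800 + len(site)] = site
tx[1500:1500 + len(revcomp(mirna))] = list(revcomp(mirna))  # perfect site

hits = scan_transcripts(mirna, {"tx1": "".join(tx)}, cutoff=3.0,
                        mirna_id="Zma-miR2001")
for h in hits:
    print(f"{h.mirna_id} -> {h.transcript_id}:{h.position} "
          f"score {h.score:.1f} (cleavage opposite positions 10/11 "
          f"at transcript base {h.cleavage_position})")
    print("   miRNA 3'-5'", h.alignment[0])
    print("              ", h.alignment[1])
    print("  target 5'-3'", h.alignment[2])
# Score 0.0 is perfect complementarity; the planted mismatch site pays
# its positional penalty but stays under the cutoff.
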
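"""Library design: which library is which cross direction, stage and tissue.

The experiment profiled here is a 12-library reciprocal-cross time course:
B73 x Mo17 and Mo17 x B73 (maternal parent first), each sampled as whole
kernels at 0, 3 and 5 days after pollination (DAP) and dissected endosperm
at 7, 10 and 15 DAP.  Endosperm is triploid (two maternal genome copies to
one paternal), which is why cross direction matters for allele dosage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

#: Canonical cross-direction labels (maternal parent listed first).
CROSSES = ("BxM", "MxB")

#: (DAP, tissue) for the six developmental stages.
STAGES = ((0, "kernel"), (3, "kernel"), (5, "kernel"),
          (7, "endosperm"), (10, "endosperm"), (15, "endosperm"))

KERNEL_DAPS = (0, 3, 5)
ENDOSPERM_DAPS = (7, 10, 15)


@dataclass(frozen=True)
class Library:
    """One sequencing library: a (cross, stage) cell of the design."""

    library_id: str
    cross: str          # "BxM" or "MxB", maternal parent first
    dap: int            # days after pollination
    tissue: str         # "kernel" or "endosperm"

    def __post_init__(self) -> None:
        if self.cross not in CROSSES:
            raise ValueError(f"unknown cross direction {self.cross!r}")
        if self.tissue not in ("kernel", "endosperm"):
            raise ValueError(f"unknown tissue {self.tissue!r}")


@dataclass
class LibraryDesign:
    """Maps library ids to (cross, stage, tissue) and stores RPM denominators.

    ``totals`` holds the normalization denominator per library (retained
    reads after trimming and length filtering); it is filled in by the
    preprocessing stage.
    """

    libraries: list[Library]
    totals: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [lib.library_id for lib in self.libraries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate library ids in design")

    @property
    def library_ids(self) -> list[str]:
        return [lib.library_id for lib in self.libraries]

    def __getitem__(self, library_id: str) -> Library:
        for lib in self.libraries:
            if lib.library_id == library_id:
                return lib
        raise KeyError(library_id)

    def __len__(self) -> int:
        return len(self.libraries)

    def libraries_for(self, cross: str | None = None,
                      tissue: str | None = None,
                      dap: int | None = None) -> list[Library]:
        out = self.libraries
        if cross is not None:
            out = [l for l in out if l.cross == cross]
        if tissue is not None:
            out = [l for l in out if l.tissue == tissue]
        if dap is not None:
            out = [l for l in out if l.dap == dap]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "library_id": [l.library_id for l in self.libraries],
                "cross": [l.cross for l in self.libraries],
                "dap": [l.dap for l in self.libraries],
                "tissue": [l.tissue for l in self.libraries],
                "total_reads": [self.totals.get(l.library_id, 0)
                                for l in self.libraries],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LibraryDesign":
        libs = [
            Library(str(r.library_id), str(r.cross), int(r.dap), str(r.tissue))
            for r in df.itertuples()
        ]
        design = cls(libs)
        if "total_reads" in df.columns:
            design.totals = {
                str(r.library_id): int(r.total_reads)
                for r in df.itertuples() if int(r.total_reads) > 0
            }
        return design

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LibraryDesign":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def reciprocal_design() -> LibraryDesign:
    """The standard 12-library design: 2 reciprocal crosses x 6 stages."""
    libs = [
        Library(f"{cross}_{dap}DAP", cross, dap, tissue)
        for cross in CROSSES
        for dap, tissue in STAGES
    ]
    return LibraryDesign(libs)
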
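"""Gene models: minimal genomic intervals with BED6 I/O.

Coordinates are 0-based half-open internally; BED is natively 0-based
half-open so the file round-trips without shifting.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class GeneModel:
    """A gene as a genomic interval.

    ``start``/``end`` are 0-based half-open.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval for {self.gene_id}: [{self.start}, {self.end})")

    def window(self, flank: int = 20_000) -> tuple[int, int]:
        """Interval extended by ``flank`` bases on each side (clamped at 0)."""
        return max(0, self.start - flank), self.end + flank


def write_bed(genes: list[GeneModel], path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "name": [g.gene_id for g in genes],
            "score": 0,
            "strand": [g.strand for g in genes],
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> list[GeneModel]:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    return [
        GeneModel(gene_id=r.name, chrom=r.chrom, start=int(r.start), end=int(r.end), strand=r.strand)
        for r in df.itertuples(index=False)
    ]
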
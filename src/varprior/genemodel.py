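"""Gene models (transcript structures) and BED12 I/O.

Coordinate conventions are centralized here and in :mod:`varprior.variants`:
all in-memory intervals are 0-based half-open (BED convention); VCF
positions are 1-based and converted exactly once, at region
classification time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


class GeneModelError(ValueError):
    pass


@dataclass(frozen=True)
class Transcript:
    """One isoform: exon intervals plus the coding span.

    ``exons`` are 0-based half-open, sorted, non-overlapping.
    ``cds_start < cds_end`` delimit the coding region; both lie within
    the exon span.  A transcript with ``cds_start == cds_end`` is
    treated as non-coding (every exonic base is UTR-like; classified by
    position relative to the empty CDS point).
    """

    gene: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"bad strand {self.strand!r}")
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise GeneModelError(f"empty exon ({start}, {end}) in {self.gene}")
            if prev_end is not None and start < prev_end:
                raise GeneModelError(f"overlapping exons in {self.gene}")
            prev_end = end
        if self.cds_start > self.cds_end:
            raise GeneModelError("cds_start > cds_end")
        span = (self.exons[0][0], self.exons[-1][1])
        if self.cds_start < self.cds_end and not (
            span[0] <= self.cds_start and self.cds_end <= span[1]
        ):
            raise GeneModelError("coding region outside exon span")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class GeneModel:
    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self):
        self._by_chrom: dict[str, list[Transcript]] = {}
        for t in self.transcripts:
            self._by_chrom.setdefault(t.chrom, []).append(t)
        for txs in self._by_chrom.values():
            txs.sort(key=lambda t: (t.start, t.end))

    def __len__(self) -> int:
        return len(self.transcripts)

    def overlapping(self, chrom: str, pos0: int) -> list[Transcript]:
        """Transcripts whose span contains the 0-based position."""
        return [
            t
            for t in self._by_chrom.get(chrom, [])
            if t.start <= pos0 < t.end
        ]

    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.transcripts:
            seen.setdefault(t.gene)
        return list(seen)


_BED12_COLS = [
    "chrom", "start", "end", "name", "score", "strand",
    "thick_start", "thick_end", "rgb", "block_count",
    "block_sizes", "block_starts",
]


def read_bed12(path) -> GeneModel:
    """Load transcripts from a BED12 file (thickStart/thickEnd = CDS)."""
    df = pd.read_csv(path, sep="\t", header=None, names=_BED12_COLS, comment="#")
    transcripts = []
    for row in df.itertuples(index=False):
        sizes = [int(x) for x in str(row.block_sizes).rstrip(",").split(",")]
        offsets = [int(x) for x in str(row.block_starts).rstrip(",").split(",")]
        if len(sizes) != int(row.block_count) or len(offsets) != int(row.block_count):
            raise GeneModelError(f"inconsistent block columns for {row.name}")
        exons = tuple(
            (int(row.start) + off, int(row.start) + off + size)
            for off, size in zip(offsets, sizes)
        )
        transcripts.append(
            Transcript(
                gene=str(row.name),
                chrom=str(row.chrom),
                strand=str(row.strand),
                exons=exons,
                cds_start=int(row.thick_start),
                cds_end=int(row.thick_end),
            )
        )
    return GeneModel(transcripts)


def write_bed12(model: GeneModel, path) -> None:
    rows = []
    for t in model.transcripts:
        sizes = ",".join(str(e - s) for s, e in t.exons)
        offsets = ",".join(str(s - t.start) for s, e in t.exons)
        rows.append(
            (
                t.chrom, t.start, t.end, t.gene, 0, t.strand,
                t.cds_start, t.cds_end, "0,0,0", len(t.exons), sizes, offsets,
            )
        )
    pd.DataFrame(rows, columns=_BED12_COLS).to_csv(
        path, sep="\t", header=False, index=False
    )
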
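"""Genome model and allele-specific copy-number segment IO.

The scar metrics need three pieces of genomic context: chromosome lengths
(telomere positions), centromere intervals (arm boundaries), and an ordered,
non-overlapping set of allele-specific copy-number segments per sample.
Segment tables come in two institutional dialects (Broad CCLE allelic calls,
Sanger PureCN segments) plus a plain ``generic`` layout; all three use
1-based inclusive coordinates on disk and are converted to 0-based half-open
internally, so segment length is always ``end - start``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "GenomeBuild",
    "Segment",
    "SegmentProfile",
    "load_genome",
    "read_segments",
    "write_segments",
]


@dataclass(frozen=True)
class GenomeBuild:
    """Chromosome lengths and centromere intervals, in bp."""

    name: str
    chromosomes: tuple[tuple[str, int], ...]
    centromeres: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        lengths = dict(self.chromosomes)
        for chrom, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"{chrom}: non-positive length {length}")
        for chrom, (cs, ce) in self.centromeres.items():
            if chrom not in lengths:
                raise ValueError(f"centromere on unknown chromosome {chrom}")
            if not (0 < cs < ce < lengths[chrom]):
                raise ValueError(
                    f"{chrom}: centromere ({cs}, {ce}) outside chromosome "
                    f"of length {lengths[chrom]}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def centromere(self, chrom: str) -> tuple[int, int]:
        return self.centromeres[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths


@dataclass(frozen=True)
class Segment:
    """One allele-specific copy-number segment, 0-based half-open."""

    chrom: str
    start: int
    end: int
    total_cn: float
    minor_cn: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"{self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.minor_cn < 0:
            raise ValueError("minor_cn must be >= 0")
        if self.minor_cn > self.major_cn:
            raise ValueError(
                f"{self.chrom}:{self.start}-{self.end}: minor_cn "
                f"{self.minor_cn} exceeds major_cn {self.major_cn}"
            )

    @property
    def major_cn(self) -> float:
        return self.total_cn - self.minor_cn

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def state(self) -> tuple[float, float]:
        return (self.total_cn, self.minor_cn)


@dataclass
class SegmentProfile:
    """Ordered, non-overlapping segments for one sample."""

    sample_id: str
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.segments = sorted(
            self.segments, key=lambda s: (s.chrom, s.start)
        )
        prev: Segment | None = None
        for seg in self.segments:
            if prev is not None and seg.chrom == prev.chrom and seg.start < prev.end:
                raise ValueError(
                    f"sample {self.sample_id}: overlapping segments at "
                    f"{seg.chrom}:{prev.start}-{prev.end} and "
                    f"{seg.chrom}:{seg.start}-{seg.end}"
                )
            prev = seg

    def by_chrom(self) -> dict[str, list[Segment]]:
        out: dict[str, list[Segment]] = {}
        for seg in self.segments:
            out.setdefault(seg.chrom, []).append(seg)
        return out

    def merged(self) -> "SegmentProfile":
        """Merge abutting segments with identical (total_cn, minor_cn)."""
        merged: list[Segment] = []
        for seg in self.segments:
            if (
                merged
                and merged[-1].chrom == seg.chrom
                and merged[-1].end == seg.start
                and merged[-1].state == seg.state
            ):
                prev = merged.pop()
                seg = Segment(seg.chrom, prev.start, seg.end, *seg.state)
            merged.append(seg)
        return SegmentProfile(self.sample_id, merged)


# GRCh38 chromosome lengths and centromere (acen) intervals, frozen from the
# UCSC hg38 cytoband table. 22 autosomes + X; Y is excluded from scoring by
# default and is not part of this reduced build.
_GRCH38_LITE: list[tuple[str, int, int, int]] = [
    ("chr1", 248956422, 121700000, 125100000),
    ("chr2", 242193529, 91800000, 96000000),
    ("chr3", 198295559, 87800000, 94000000),
    ("chr4", 190214555, 48200000, 51800000),
    ("chr5", 181538259, 46100000, 50000000),
    ("chr6", 170805979, 58500000, 62600000),
    ("chr7", 159345973, 58100000, 62100000),
    ("chr8", 145138636, 43200000, 47200000),
    ("chr9", 138394717, 42200000, 45500000),
    ("chr10", 133797422, 38000000, 41600000),
    ("chr11", 135086622, 51000000, 55800000),
    ("chr12", 133275309, 33200000, 37800000),
    ("chr13", 114364328, 16500000, 18900000),
    ("chr14", 107043718, 16100000, 18200000),
    ("chr15", 101991189, 17500000, 20500000),
    ("chr16", 90338345, 35300000, 38400000),
    ("chr17", 83257441, 22700000, 27400000),
    ("chr18", 80373285, 15400000, 21500000),
    ("chr19", 58617616, 24200000, 28100000),
    ("chr20", 64444167, 25700000, 30400000),
    ("chr21", 46709983, 10900000, 13000000),
    ("chr22", 50818468, 13700000, 17400000),
    ("chrX", 156040895, 58100000, 63800000),
]

# Small deterministic genome for tests and examples: 3 chromosomes with
# round lengths and centromeres, big enough to host >15 Mb events on every arm.
_TOY: list[tuple[str, int, int, int]] = [
    ("chr1", 250_000_000, 120_000_000, 125_000_000),
    ("chr2", 180_000_000, 85_000_000, 90_000_000),
    ("chr3", 100_000_000, 45_000_000, 48_000_000),
]

_BUILTINS = {"GRCh38-lite": _GRCH38_LITE, "toy": _TOY}


def load_genome(source: str | Path) -> GenomeBuild:
    """Load a genome model from a builtin name or a table file.

    Builtins are ``"GRCh38-lite"`` (22 autosomes + X with frozen cytoband
    centromeres) and ``"toy"`` (3 chromosomes, used throughout the tests).
    A file must be CSV/TSV with columns
    ``chrom,length,centromere_start,centromere_end``.
    """
    if isinstance(source, str) and source in _BUILTINS:
        rows = _BUILTINS[source]
        return GenomeBuild(
            name=source,
            chromosomes=tuple((c, ln) for c, ln, _, _ in rows),
            centromeres={c: (cs, ce) for c, ln, cs, ce in rows},
        )
    path = Path(source)
    if not path.exists():
        raise ValueError(f"unknown genome builtin or missing file: {source!r}")
    sep = "\t" if path.suffix in {".tsv", ".txt", ".bed"} else ","
    df = pd.read_csv(path, sep=sep)
    required = {"chrom", "length", "centromere_start", "centromere_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"genome table missing columns: {sorted(missing)}")
    return GenomeBuild(
        name=path.stem,
        chromosomes=tuple(zip(df["chrom"].astype(str), df["length"].astype(int))),
        centromeres={
            str(r.chrom): (int(r.centromere_start), int(r.centromere_end))
            for r in df.itertuples()
        },
    )


# Column maps: dialect header -> generic header. Coordinates in all dialects
# are 1-based inclusive, the seg-file convention.
_DIALECTS: dict[str, dict[str, str]] = {
    "generic": {},
    "broad_ccle": {
        "CCLE_ID": "sample",
        "Chromosome": "chrom",
        "Start": "start",
        "End": "end",
        "Modal_Total_CN": "total_cn",
        "Modal_HSCN_1": "minor_cn",
    },
    "sanger_purecn": {
        "model_id": "sample",
        "chr": "chrom",
        "start": "start",
        "end": "end",
        "copy_number": "total_cn",
        "minor_allele_copy_number": "minor_cn",
    },
}

_GENERIC_COLUMNS = ["sample", "chrom", "start", "end", "total_cn", "minor_cn"]


def _normalize_chrom(chrom: str) -> str:
    chrom = str(chrom)
    if not chrom.lower().startswith("chr"):
        chrom = "chr" + chrom
    return chrom


def read_segments(
    path: str | Path,
    dialect: str = "generic",
    merge_adjacent: bool = True,
    include_y: bool = False,
) -> list[SegmentProfile]:
    """Read per-sample segment profiles from a CSV/TSV segment table.

    Input coordinates are 1-based inclusive; the returned profiles use
    0-based half-open coordinates. Chromosome Y is dropped unless
    ``include_y`` (copy-number calls on Y are unreliable). Adjacent segments
    with identical copy state are merged by default.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".txt", ".seg"} else ","
    df = pd.read_csv(path, sep=sep)
    rename = _DIALECTS[dialect]
    if rename:
        df = df.rename(columns=rename)
    missing = set(_GENERIC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(
            f"{path.name}: missing required columns {sorted(missing)} "
            f"for dialect {dialect!r}"
        )
    if df.empty:
        return []
    df = df.copy()
    df["chrom"] = df["chrom"].map(_normalize_chrom)
    if not include_y:
        df = df[df["chrom"] != "chrY"]
    profiles = []
    for sample, grp in df.groupby("sample", sort=True):
        segments = [
            Segment(
                chrom=r.chrom,
                start=int(r.start) - 1,
                end=int(r.end),
                total_cn=float(r.total_cn),
                minor_cn=float(r.minor_cn),
            )
            for r in grp.itertuples()
        ]
        profile = SegmentProfile(str(sample), segments)
        if merge_adjacent:
            profile = profile.merged()
        profiles.append(profile)
    return profiles


def write_segments(
    profiles: Iterable[SegmentProfile], path: str | Path
) -> None:
    """Write profiles in the generic dialect (1-based inclusive CSV)."""
    rows = [
        {
            "sample": p.sample_id,
            "chrom": s.chrom,
            "start": s.start + 1,
            "end": s.end,
            "total_cn": s.total_cn,
            "minor_cn": s.minor_cn,
        }
        for p in profiles
        for s in p.segments
    ]
    pd.DataFrame(rows, columns=_GENERIC_COLUMNS).to_csv(path, index=False)
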
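"""Genomic-scar metrics: LOH, LST, TAI, and their sum (HRDsum).

The three metrics quantify the structural damage left behind by defective
homologous recombination, each following its canonical definition:

* **LOH** — number of loss-of-heterozygosity regions (minor-allele copy
  number 0, total copy number > 0) longer than 15 Mb that do not span the
  whole chromosome.
* **LST** — number of large-scale state transitions: copy-number breakpoints
  with >= 10 Mb segments on both flanks, counted per chromosome arm after
  smoothing away segments shorter than 3 Mb; breakpoints at the centromere
  are never counted.
* **TAI** — number of allelic-imbalance regions (minor != major copy number)
  that reach a telomere but neither cross the centromere nor span the whole
  chromosome.

HRDsum = LOH + LST + TAI. All length thresholds are parameters of
:class:`ScarParams`, not constants.

Because WES-derived segments rarely extend to the literal chromosome ends,
"reaches the telomere" means within ``telomere_tolerance`` (1 kb default) of
position 0 or the chromosome length, and "whole chromosome" means covering
every *observed* segment of the chromosome rather than matching its nominal
length.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import GenomeBuild, Segment, SegmentProfile

__all__ = [
    "ScarParams",
    "ScarScores",
    "count_loh",
    "count_lst",
    "count_tai",
    "hrdsum",
]


@dataclass(frozen=True)
class ScarParams:
    """Length thresholds (bp) for the three scar metrics."""

    loh_min_len: float = 15_000_000  # LOH regions must exceed this (strict >)
    lst_min_flank: float = 10_000_000  # both LST flanks must reach this (>=)
    lst_smooth_len: float = 3_000_000  # segments below this are smoothed away
    telomere_tolerance: float = 1_000  # slack for "reaches the telomere"
    tai_min_len: float = 0  # optional minimum TAI region length

    def __post_init__(self) -> None:
        for name in ("loh_min_len", "lst_min_flank", "lst_smooth_len", "telomere_tolerance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.tai_min_len < 0:
            raise ValueError("tai_min_len must be >= 0")


@dataclass(frozen=True)
class ScarScores:
    sample_id: str
    loh: int
    lst: int
    tai: int

    @property
    def hrdsum(self) -> int:
        return self.loh + self.lst + self.tai


def _check_chroms(profile: SegmentProfile, genome: GenomeBuild) -> None:
    for seg in profile.segments:
        if seg.chrom not in genome:
            raise ValueError(
                f"sample {profile.sample_id}: chromosome {seg.chrom} "
                f"not in genome {genome.name!r}"
            )


def _runs(segments: list[Segment], predicate) -> list[list[Segment]]:
    """Maximal runs of consecutive segments satisfying ``predicate``."""
    runs: list[list[Segment]] = []
    current: list[Segment] = []
    for seg in segments:
        if predicate(seg):
            current.append(seg)
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)
    return runs


def count_loh(
    profile: SegmentProfile, genome: GenomeBuild, params: ScarParams | None = None
) -> int:
    """Count LOH regions longer than ``loh_min_len`` excluding whole-chromosome LOH.

    A region is a maximal run of consecutive segments with minor_cn = 0 and
    total_cn > 0; its length is the summed segment length (robust to
    coverage gaps). Centromere-spanning runs count as single regions.
    """
    params = params or ScarParams()
    _check_chroms(profile, genome)
    n = 0
    for chrom, segs in profile.by_chrom().items():
        for run in _runs(segs, lambda s: s.minor_cn == 0 and s.total_cn > 0):
            if len(run) == len(segs):  # whole observed chromosome
                continue
            if sum(s.length for s in run) > params.loh_min_len:
                n += 1
    return n


def _arm_segments(
    segs: list[Segment], centromere: tuple[int, int]
) -> tuple[list[Segment], list[Segment]]:
    """Clip segments at the centromere into p-arm and q-arm pieces."""
    cen_start, cen_end = centromere
    p: list[Segment] = []
    q: list[Segment] = []
    for seg in segs:
        if seg.start < cen_start:
            end = min(seg.end, cen_start)
            if end > seg.start:
                p.append(Segment(seg.chrom, seg.start, end, *seg.state))
        if seg.end > cen_end:
            start = max(seg.start, cen_end)
            if seg.end > start:
                q.append(Segment(seg.chrom, start, seg.end, *seg.state))
    return p, q


def _smooth(segs: list[Segment], smooth_len: float) -> list[Segment]:
    """Drop segments shorter than ``smooth_len`` and join equal-state flanks."""
    kept = [s for s in segs if s.length >= smooth_len]
    out: list[Segment] = []
    for seg in kept:
        if (
            out
            and out[-1].state == seg.state
            and seg.start - out[-1].end < smooth_len
        ):
            prev = out.pop()
            seg = Segment(seg.chrom, prev.start, seg.end, *seg.state)
        out.append(seg)
    return out


def count_lst(
    profile: SegmentProfile, genome: GenomeBuild, params: ScarParams | None = None
) -> int:
    """Count large-scale state transitions per chromosome arm.

    After smoothing (removal of segments < ``lst_smooth_len`` and joining of
    equal-state flanks), every junction between adjacent segments with both
    flanks >= ``lst_min_flank`` and an inter-segment gap < ``lst_smooth_len``
    counts as one transition. Arms are processed independently, so no
    breakpoint ever spans the centromere.
    """
    params = params or ScarParams()
    _check_chroms(profile, genome)
    n = 0
    # segmentation is defined only up to equal-state refinement: merge
    # abutting equal-state segments first so counts are refinement-invariant
    for chrom, segs in profile.merged().by_chrom().items():
        for arm in _arm_segments(segs, genome.centromere(chrom)):
            smoothed = _smooth(arm, params.lst_smooth_len)
            for left, right in zip(smoothed, smoothed[1:]):
                if (
                    left.length >= params.lst_min_flank
                    and right.length >= params.lst_min_flank
                    and right.start - left.end < params.lst_smooth_len
                ):
                    n += 1
    return n


def count_tai(
    profile: SegmentProfile, genome: GenomeBuild, params: ScarParams | None = None
) -> int:
    """Count telomeric allelic-imbalance regions.

    A region is a maximal run of consecutive segments with minor != major
    copy number. It counts if it reaches a chromosome end (within
    ``telomere_tolerance``), does not cross the centromere (observed bases on
    both sides), and does not span the whole observed chromosome. At most two
    regions (one per telomere) can count per chromosome.
    """
    params = params or ScarParams()
    _check_chroms(profile, genome)
    n = 0
    for chrom, segs in profile.by_chrom().items():
        cen_start, cen_end = genome.centromere(chrom)
        chrom_len = genome.lengths[chrom]
        counted = 0
        for run in _runs(segs, lambda s: s.minor_cn != s.major_cn):
            if len(run) == len(segs):  # whole observed chromosome
                continue
            start, end = run[0].start, run[-1].end
            crosses = start < cen_start and end > cen_end
            if crosses:
                continue
            reaches_p = start <= params.telomere_tolerance
            reaches_q = end >= chrom_len - params.telomere_tolerance
            if not (reaches_p or reaches_q):
                continue
            if sum(s.length for s in run) < params.tai_min_len:
                continue
            counted += 1
        n += min(counted, 2)
    return n


def hrdsum(
    profile: SegmentProfile, genome: GenomeBuild, params: ScarParams | None = None
) -> ScarScores:
    """All three scar counts and their sum for one profile."""
    params = params or ScarParams()
    return ScarScores(
        sample_id=profile.sample_id,
        loh=count_loh(profile, genome, params),
        lst=count_lst(profile, genome, params),
        tai=count_tai(profile, genome, params),
    )
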
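"""Independent oracles shared by unit and acceptance tests.

These deliberately re-derive expected values by brute force (explicit
scans, exact integer arithmetic) rather than calling the library code they
check.
"""

from fractions import Fraction
from math import comb

MB = 1_000_000


def oracle_loh(profile, genome, min_len=15 * MB):
    """LOH count by explicit run scan: minor 0, total > 0, sum length > min."""
    count = 0
    for chrom in {s.chrom for s in profile.segments}:
        segs = [s for s in profile.segments if s.chrom == chrom]
        i = 0
        while i < len(segs):
            if segs[i].minor_cn == 0 and segs[i].total_cn > 0:
                j = i
                while (
                    j + 1 < len(segs)
                    and segs[j + 1].minor_cn == 0
                    and segs[j + 1].total_cn > 0
                ):
                    j += 1
                run = segs[i : j + 1]
                whole = len(run) == len(segs)
                if not whole and sum(s.end - s.start for s in run) > min_len:
                    count += 1
                i = j + 1
            else:
                i += 1
    return count


def oracle_lst(profile, genome, min_flank=10 * MB, smooth=3 * MB):
    """LST count by per-arm enumeration of every candidate junction."""
    count = 0
    for chrom in {s.chrom for s in profile.segments}:
        cen_lo, cen_hi = genome.centromere(chrom)
        raw = sorted(
            (s for s in profile.segments if s.chrom == chrom),
            key=lambda s: s.start,
        )
        # merge abutting equal-state pieces (segmentation refinement)
        merged = []
        for s in raw:
            if (
                merged
                and merged[-1][1] == s.start
                and merged[-1][2] == (s.total_cn, s.minor_cn)
            ):
                merged[-1] = (merged[-1][0], s.end, merged[-1][2])
            else:
                merged.append((s.start, s.end, (s.total_cn, s.minor_cn)))
        for lo, hi in [(0, cen_lo), (cen_hi, genome.lengths[chrom])]:
            clipped = []
            for start, end, state in merged:
                a, b = max(start, lo), min(end, hi)
                if b > a:
                    clipped.append((a, b, state))
            big = [p for p in clipped if p[1] - p[0] >= smooth]
            joined = []
            for p in big:
                if joined and joined[-1][2] == p[2] and p[0] - joined[-1][1] < smooth:
                    joined[-1] = (joined[-1][0], p[1], p[2])
                else:
                    joined.append(list(p) if isinstance(p, tuple) else p)
                joined[-1] = tuple(joined[-1])
            for left, right in zip(joined, joined[1:]):
                if (
                    left[1] - left[0] >= min_flank
                    and right[1] - right[0] >= min_flank
                    and right[0] - left[1] < smooth
                ):
                    count += 1
    return count


def oracle_tai(profile, genome, tol=1000):
    """TAI count by explicit allelic-imbalance region scan per chromosome."""
    count = 0
    for chrom in {s.chrom for s in profile.segments}:
        cen_lo, cen_hi = genome.centromere(chrom)
        length = genome.lengths[chrom]
        segs = sorted(
            (s for s in profile.segments if s.chrom == chrom),
            key=lambda s: s.start,
        )
        per_chrom = 0
        i = 0
        while i < len(segs):
            if segs[i].minor_cn != segs[i].total_cn - segs[i].minor_cn:
                j = i
                while j + 1 < len(segs) and (
                    segs[j + 1].minor_cn
                    != segs[j + 1].total_cn - segs[j + 1].minor_cn
                ):
                    j += 1
                start, end = segs[i].start, segs[j].end
                whole = (j - i + 1) == len(segs)
                crosses = start < cen_lo and end > cen_hi
                telomeric = start <= tol or end >= length - tol
                if telomeric and not crosses and not whole:
                    per_chrom += 1
                i = j + 1
            else:
                i += 1
        count += min(per_chrom, 2)
    return count


def oracle_scars(profile, genome):
    return (
        oracle_loh(profile, genome),
        oracle_lst(profile, genome),
        oracle_tai(profile, genome),
    )


def fisher_greater_exact(a, b, c, d):
    """One-tailed (greater) Fisher p by exact hypergeometric enumeration."""
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = comb(n, r1)
    tail = Fraction(0)
    for k in range(a, min(r1, c1) + 1):
        if r1 - k <= n - c1:
            tail += Fraction(comb(c1, k) * comb(n - c1, r1 - k), denom)
    return float(tail)


def bh_stepup(pvalues):
    """Brute-force Benjamini-Hochberg step-up adjustment."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        value = min(pvalues[i] * m / rank, 1.0)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def percentile_interpolated(values, q):
    """Percentile with linear interpolation between order statistics."""
    xs = sorted(values)
    if len(xs) == 1:
        return float(xs[0])
    position = q / 100 * (len(xs) - 1)
    lo = int(position)
    frac = position - lo
    if lo + 1 < len(xs):
        return xs[lo] + frac * (xs[lo + 1] - xs[lo])
    return float(xs[lo])
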
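"""Tumor-only variant filtering, SV event annotation, and mutation contexts.

Cell lines lack matched normals, so somatic variants are approximated by a
cascade of post-calling filters: panel-of-normals and population-database
(gnomAD/dbSNP/known-indels) removal, a cohort-recurrence cutoff (variants
seen in >= 3 cell lines are treated as artifacts or germline), PASS status,
allele frequency >= 0.1, and region-aware quality cutoffs (>= 240 in
low-confidence regions, >= 170 in high-confidence regions). Structural
variants additionally require quality >= 1,000 and assembly support from
both sides of the breakpoint (AS > 0 and RAS > 0). The cascade is a pure
conjunction, so rule order never matters.

Variants are normalized first (indel left-alignment and parsimony, MNV
splitting into SNVs, multiallelic decomposition) so that recurrence keys
(chrom, pos, ref, alt) compare like with like.

Mutation contexts back the downstream HRD feature counts: the 96
trinucleotide SNV classes, the six indel classes
{del,ins} x {mh, rep, none} (microhomology-mediated deletions being the key
HR-deficiency scar), SV type x length-bin counts, and the MSI call from the
number of indels in repeat regions (>= 10,000 for cell lines).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "VariantRecord",
    "BreakendPair",
    "SVEvent",
    "ContextCounts",
    "FilterThresholds",
    "normalize_variants",
    "filter_small_variants",
    "filter_structural_variants",
    "annotate_sv_event",
    "classify_indel_context",
    "snv_trinucleotide_context",
    "count_contexts",
    "classify_msi",
    "read_vcf",
    "write_vcf",
]

SV_LENGTH_BINS: list[tuple[str, float, float]] = [
    ("0-1e3", 0, 1e3),
    ("1e3-1e4", 1e3, 1e4),
    ("1e4-1e5", 1e4, 1e5),
    ("1e5-1e6", 1e5, 1e6),
    ("1e6-1e7", 1e6, 1e7),
    (">1e7", 1e7, float("inf")),
]

INDEL_CLASSES = ["del.mh", "del.rep", "del.none", "ins.mh", "ins.rep", "ins.none"]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class VariantRecord:
    """One small variant with the fields the filter cascade reads."""

    sample_id: str
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    qual: float = 0.0
    filter_status: str = "PASS"
    allele_frequency: float = 0.0
    pon_flag: bool = False
    confidence_region: str = "NA"  # high / low / NA
    blacklist_hits: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos}: ref equals alt")
        if not 0 <= self.allele_frequency <= 1:
            raise ValueError("allele frequency outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclass(frozen=True)
class BreakendPair:
    """A paired-breakend structural variant junction."""

    sample_id: str
    chrom1: str
    pos1: int
    orient1: str  # "+" or "-"
    chrom2: str
    pos2: int
    orient2: str
    qual: float = 0.0
    filter_status: str = "PASS"
    allele_frequency: float = 0.0
    pon_flag: bool = False
    assembly_support: tuple[int, int] = (0, 0)  # (AS, RAS)

    def __post_init__(self) -> None:
        if self.orient1 not in "+-" or self.orient2 not in "+-":
            raise ValueError("orientations must be '+' or '-'")
        if min(self.assembly_support) < 0:
            raise ValueError("AS/RAS must be >= 0")

    @property
    def key(self) -> tuple:
        return (
            self.chrom1, self.pos1, self.orient1,
            self.chrom2, self.pos2, self.orient2,
        )


@dataclass(frozen=True)
class SVEvent:
    type: str  # DEL / DUP / INV / TRA
    length: int | None  # bp; None for TRA


@dataclass
class ContextCounts:
    """Counts per mutation-context category for one sample."""

    snv: dict[str, int] = field(default_factory=dict)
    indel: dict[str, int] = field(default_factory=lambda: dict.fromkeys(INDEL_CLASSES, 0))
    sv: dict[str, int] = field(default_factory=dict)

    @property
    def n_snv(self) -> int:
        return sum(self.snv.values())

    @property
    def indels_in_repeat_regions(self) -> int:
        return self.indel["del.rep"] + self.indel["ins.rep"]


@dataclass(frozen=True)
class FilterThresholds:
    """Small-variant filter cutoffs (SV cutoffs are separate arguments)."""

    min_af: float = 0.1
    max_recurrence: int = 2  # present in >= 3 cell lines -> removed
    min_qual_low_confidence: float = 240.0
    min_qual_high_confidence: float = 170.0
    min_sv_qual: float = 1000.0


# ---------------------------------------------------------------------------
# reference access: accepts a dict of chrom -> sequence or a pyfaidx.Fasta
# ---------------------------------------------------------------------------

def _fetch(reference, chrom: str, start0: int, end0: int) -> str:
    """Reference slice, 0-based half-open, uppercase; clipped at contig ends."""
    start0 = max(start0, 0)
    if end0 <= start0:
        return ""
    return str(reference[chrom][start0:end0]).upper()


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _left_align(
    reference, chrom: str, pos: int, ref: str, alt: str
) -> tuple[int, str, str]:
    """Left-align and parsimony-trim one ref/alt pair (vt-style algorithm)."""
    while True:
        # truncate shared rightmost base; re-anchor with the reference base
        # to the left when one allele would become empty
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos == 1:
                    raise ValueError(
                        f"{chrom}:{pos}: cannot left-align past contig start"
                    )
                pos -= 1
                base = _fetch(reference, chrom, pos - 1, pos)
                ref, alt = base + ref, base + alt
            continue
        break
    # trim shared leading bases, keeping one anchor base
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def normalize_variants(
    records: Iterable[VariantRecord], reference
) -> list[VariantRecord]:
    """Decompose multiallelics, split MNVs into SNVs, left-align indels.

    The reference must cover every locus; a mismatch between a record's ref
    allele and the reference sequence is an error. Normalization is
    idempotent.
    """
    out: list[VariantRecord] = []
    for rec in records:
        for alt in rec.alt.split(","):
            sub = replace(rec, alt=alt) if alt != rec.alt else rec
            observed = _fetch(
                reference, sub.chrom, sub.pos - 1, sub.pos - 1 + len(sub.ref)
            )
            if observed != sub.ref.upper():
                raise ValueError(
                    f"{sub.chrom}:{sub.pos}: ref allele {sub.ref!r} does not "
                    f"match reference {observed!r}"
                )
            if len(sub.ref) == len(sub.alt):
                if len(sub.ref) == 1:
                    out.append(sub)
                else:  # MNV -> constituent SNVs at differing positions
                    for i, (r, a) in enumerate(zip(sub.ref, sub.alt)):
                        if r != a:
                            out.append(
                                replace(sub, pos=sub.pos + i, ref=r, alt=a)
                            )
            else:
                pos, ref, alt2 = _left_align(
                    reference, sub.chrom, sub.pos, sub.ref.upper(), sub.alt.upper()
                )
                out.append(replace(sub, pos=pos, ref=ref, alt=alt2))
    return out


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_small_variants(
    records: Iterable[VariantRecord],
    cohort_recurrence: Mapping[tuple, int] | None = None,
    thresholds: FilterThresholds | None = None,
) -> list[VariantRecord]:
    """Apply the full small-variant filter conjunction; order-independent."""
    thresholds = thresholds or FilterThresholds()
    cohort_recurrence = cohort_recurrence or {}
    retained = []
    for rec in records:
        min_qual = (
            thresholds.min_qual_high_confidence
            if rec.confidence_region == "high"
            else thresholds.min_qual_low_confidence
        )
        if (
            not rec.pon_flag
            and not rec.blacklist_hits
            and cohort_recurrence.get(rec.key, 0) <= thresholds.max_recurrence
            and rec.filter_status == "PASS"
            and rec.allele_frequency >= thresholds.min_af
            and rec.qual >= min_qual
        ):
            retained.append(rec)
    return retained


def filter_structural_variants(
    pairs: Iterable[BreakendPair],
    cohort_recurrence: Mapping[tuple, int] | None = None,
    thresholds: FilterThresholds | None = None,
) -> list[BreakendPair]:
    """SV filter: qual >= 1,000, AS > 0 and RAS > 0, plus the common rules."""
    thresholds = thresholds or FilterThresholds()
    cohort_recurrence = cohort_recurrence or {}
    retained = []
    for p in pairs:
        as_, ras = p.assembly_support
        if (
            p.qual >= thresholds.min_sv_qual
            and as_ > 0
            and ras > 0
            and not p.pon_flag
            and cohort_recurrence.get(p.key, 0) <= thresholds.max_recurrence
            and p.filter_status == "PASS"
            and p.allele_frequency >= thresholds.min_af
        ):
            retained.append(p)
    return retained


# ---------------------------------------------------------------------------
# SV simple-event annotation
# ---------------------------------------------------------------------------

def annotate_sv_event(pair: BreakendPair) -> SVEvent:
    """Classify a breakend pair as DEL/DUP/INV/TRA from its orientations.

    Breakends are first put in canonical order (chrom, pos). On one
    chromosome: (+,-) = deletion, (-,+) = tandem duplication, (+,+) or (-,-)
    = inversion, with length pos2 - pos1. Different chromosomes =
    translocation (no length).
    """
    c1, p1, o1 = pair.chrom1, pair.pos1, pair.orient1
    c2, p2, o2 = pair.chrom2, pair.pos2, pair.orient2
    if (c2, p2) < (c1, p1):
        c1, p1, o1, c2, p2, o2 = c2, p2, o2, c1, p1, o1
    if c1 != c2:
        return SVEvent("TRA", None)
    if p1 == p2:
        raise ValueError(f"{c1}:{p1}: breakends at identical positions")
    if (o1, o2) == ("+", "-"):
        svtype = "DEL"
    elif (o1, o2) == ("-", "+"):
        svtype = "DUP"
    else:
        svtype = "INV"
    return SVEvent(svtype, p2 - p1)


# ---------------------------------------------------------------------------
# context classification
# ---------------------------------------------------------------------------

def _primitive_unit(seq: str) -> tuple[str, int]:
    """Smallest unit u and count k with seq == u * k."""
    n = len(seq)
    for ulen in range(1, n + 1):
        if n % ulen == 0:
            u = seq[:ulen]
            if u * (n // ulen) == seq:
                return u, n // ulen
    return seq, 1


def classify_indel_context(
    record: VariantRecord,
    reference,
    flank: int = 100,
    mh_min: int = 2,
    rep_min_units: int = 2,
) -> tuple[str, int]:
    """Classify a normalized indel as repeat, microhomology, or neither.

    * ``rep`` — the inserted/deleted sequence is k >= 1 tandem copies of a
      unit that continues for at least one more copy immediately 3' in the
      reference, for a total of >= ``rep_min_units`` copies (returned value:
      total unit count).
    * ``mh`` — otherwise, for a >= ``mh_min`` bp match between the 5' end of
      the indel sequence and the reference immediately 3' of the variant
      (returned value: homology length).
    * ``none`` — otherwise (returned value 0).
    """
    if not record.is_indel:
        raise ValueError(f"{record.chrom}:{record.pos}: not an indel")
    if len(record.ref) > len(record.alt):
        seq = record.ref[len(record.alt):].upper()
        # deleted interval is [pos + len(alt) - 1, pos + len(ref) - 1) 0-based
        flank_start0 = record.pos - 1 + len(record.ref)
    else:
        seq = record.alt[len(record.ref):].upper()
        flank_start0 = record.pos - 1 + len(record.ref)
    flank_seq = _fetch(reference, record.chrom, flank_start0, flank_start0 + flank)

    unit, k = _primitive_unit(seq)
    extra = 0
    while flank_seq[extra * len(unit):(extra + 1) * len(unit)] == unit:
        extra += 1
    if extra >= 1 and k + extra >= rep_min_units:
        return "rep", k + extra

    homology = 0
    for a, b in zip(seq, flank_seq):
        if a != b:
            break
        homology += 1
    if homology >= mh_min:
        return "mh", homology
    return "none", 0


def snv_trinucleotide_context(record: VariantRecord, reference) -> str | None:
    """Pyrimidine-strand normalized trinucleotide class, e.g. ``A[C>T]G``.

    Returns None (excluded from counts) when a flanking base is not ACGT.
    """
    if not record.is_snv:
        raise ValueError(f"{record.chrom}:{record.pos}: not an SNV")
    tri = _fetch(reference, record.chrom, record.pos - 2, record.pos + 1)
    if len(tri) != 3 or any(b not in "ACGT" for b in tri):
        return None
    ref, alt = record.ref.upper(), record.alt.upper()
    if ref in "AG":  # purine reference: reverse-complement the strand
        tri = tri.translate(_COMPLEMENT)[::-1]
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    return f"{tri[0]}[{ref}>{alt}]{tri[2]}"


def _sv_bin(length: float) -> str:
    for label, lo, hi in SV_LENGTH_BINS:
        if lo <= length < hi:
            return label
    return SV_LENGTH_BINS[-1][0]


def count_contexts(
    records: Iterable[VariantRecord],
    sv_pairs: Iterable[BreakendPair] = (),
    reference=None,
    flank: int = 100,
) -> ContextCounts:
    """Tally SNV trinucleotide, indel, and SV type/length-bin contexts."""
    counts = ContextCounts()
    for rec in records:
        if rec.is_snv:
            cls = snv_trinucleotide_context(rec, reference)
            if cls is not None:
                counts.snv[cls] = counts.snv.get(cls, 0) + 1
        elif rec.is_indel:
            kind = "del" if len(rec.ref) > len(rec.alt) else "ins"
            category, _ = classify_indel_context(rec, reference, flank=flank)
            counts.indel[f"{kind}.{category}"] += 1
    for pair in sv_pairs:
        event = annotate_sv_event(pair)
        key = event.type if event.length is None else f"{event.type}.{_sv_bin(event.length)}"
        counts.sv[key] = counts.sv.get(key, 0) + 1
    return counts


def classify_msi(
    indels_in_repeat_regions: int, threshold: int = 10_000
) -> bool:
    """MSI iff the repeat-region indel count reaches the minimum threshold."""
    if indels_in_repeat_regions < 0:
        raise ValueError("indel count must be >= 0")
    return indels_in_repeat_regions >= threshold


# ---------------------------------------------------------------------------
# VCF IO (VCF 4.2 via pysam); filter metadata travels in INFO fields
# ---------------------------------------------------------------------------

_VCF_HEADER_LINES = [
    '##INFO=<ID=AF,Number=1,Type=Float,Description="Allele frequency">',
    '##INFO=<ID=PON,Number=0,Type=Flag,Description="Panel of normals hit">',
    '##INFO=<ID=BL,Number=.,Type=String,Description="Blacklist hits (gnomad,dbsnp,known_indels)">',
    '##INFO=<ID=CONF,Number=1,Type=String,Description="Confidence region (high/low)">',
]


def read_vcf(path: str | Path, sample_id: str | None = None) -> list[VariantRecord]:
    """Read small variants from a VCF 4.2 file into VariantRecords."""
    import pysam

    path = str(path)
    sample_id = sample_id or Path(path).stem
    records = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            filters = list(rec.filter.keys())
            status = "PASS" if (not filters or filters == ["PASS"]) else filters[0]
            bl = rec.info.get("BL", ())
            if isinstance(bl, str):
                bl = (bl,)
            for alt in rec.alts or ():
                records.append(
                    VariantRecord(
                        sample_id=sample_id,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        qual=float(rec.qual) if rec.qual is not None else 0.0,
                        filter_status=status,
                        allele_frequency=float(rec.info.get("AF", 0.0)),
                        pon_flag=bool(rec.info.get("PON", False)),
                        confidence_region=str(rec.info.get("CONF", "NA")),
                        blacklist_hits=frozenset(bl),
                    )
                )
    return records


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | Path,
    contigs: Mapping[str, int],
) -> None:
    """Write VariantRecords as an uncompressed VCF 4.2 file."""
    lines = ["##fileformat=VCFv4.2"]
    for chrom, length in contigs.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.extend(_VCF_HEADER_LINES)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for rec in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
        info = [f"AF={rec.allele_frequency:g}"]
        if rec.pon_flag:
            info.append("PON")
        if rec.blacklist_hits:
            info.append("BL=" + ",".join(sorted(rec.blacklist_hits)))
        if rec.confidence_region != "NA":
            info.append(f"CONF={rec.confidence_region}")
        lines.append(
            f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t"
            f"{rec.qual:g}\t{rec.filter_status}\t{';'.join(info)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
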
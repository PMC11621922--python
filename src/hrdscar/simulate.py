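"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates one class of real input — allele-specific
copy-number profiles with planted scar events, score matrices from
distorted datasets, VCFs with planted filter outcomes and indel contexts,
feature tables with planted correlations and enrichment, and dose-response
plates — and returns the generated data together with a JSON-serializable
``truth`` dict recording exactly what was planted and under which seed.

Randomness uses the counter-based Philox generator, so regeneration with
the same seed is reproducible across platforms. Planted scar events are
non-interacting by construction: every event is separated from its
neighbours and from arm boundaries by coverage gaps larger than the LST
smoothing window, so no event creates a side effect in another metric and
the planted (LOH, LST, TAI) counts are unambiguous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeBuild, Segment, SegmentProfile
from .variants import VariantRecord, write_vcf

__all__ = [
    "rng_from_seed",
    "simulate_profile",
    "simulate_multidataset",
    "simulate_variants",
    "simulate_features",
    "simulate_dose_response",
    "SimulatedVariants",
]

MB = 1_000_000


def rng_from_seed(seed: int) -> np.random.Generator:
    """Counter-based (Philox) generator from a single integer seed."""
    return np.random.Generator(np.random.Philox(int(seed)))


# ---------------------------------------------------------------------------
# copy-number profiles with planted scar events
# ---------------------------------------------------------------------------

# planting geometry (bp): gaps around events exceed the 3 Mb LST smoothing
# window so event boundaries never count as transitions, and margins keep
# events clear of telomeres/centromeres while leaving >= 10 Mb LST flanks.
_GAP = 4 * MB
_MARGIN = 12 * MB
# largest event footprint: margin + 24 Mb event + two gaps + margin
_MIN_ARM = 2 * _MARGIN + 24 * MB + 2 * _GAP


def _arms(genome: GenomeBuild) -> list[tuple[str, int, int, str]]:
    arms = []
    for chrom, length in genome.chromosomes:
        cen_start, cen_end = genome.centromere(chrom)
        arms.append((chrom, 0, cen_start, "p"))
        arms.append((chrom, cen_end, length, "q"))
    return arms


def simulate_profile(
    genome: GenomeBuild,
    n_loh: int,
    n_lst: int,
    n_tai: int,
    seed: int,
    sample_id: str = "synthetic",
) -> tuple[SegmentProfile, dict]:
    """Diploid heterozygous baseline with planted LOH/LST/TAI events.

    Each event occupies its own chromosome arm (chosen at random), so the
    planted counts are exactly the scar counts:

    * LOH — an interior 18-28 Mb copy-neutral LOH segment (total 2,
      minor 0) isolated by >3 Mb coverage gaps;
    * LST — a 15-25 Mb segment at a different total copy number (4, 2)
      abutting the baseline on one side (the counted transition) and
      gap-isolated on the other;
    * TAI — a 16-22 Mb allelic-imbalance segment (3, 1) anchored at a
      telomere and gap-isolated inland.
    """
    rng = rng_from_seed(seed)
    arms = _arms(genome)
    n_events = n_loh + n_lst + n_tai
    usable = [a for a in arms if a[2] - a[1] >= _MIN_ARM]
    if n_events > len(usable):
        raise ValueError(
            f"genome {genome.name!r} has {len(usable)} usable arms for "
            f"{n_events} requested events"
        )
    order = rng.permutation(len(usable))
    kinds = ["loh"] * n_loh + ["lst"] * n_lst + ["tai"] * n_tai
    assignments = [(usable[order[i]], kinds[i]) for i in range(n_events)]

    # carve[chrom] = list of (start, end, total, minor or None-for-gap)
    carve: dict[str, list[tuple[int, int, tuple | None]]] = {}
    events = []
    for (chrom, arm_start, arm_end, arm_name), kind in assignments:
        if kind == "loh":
            length = int(rng.integers(16 * MB, 24 * MB + 1))
            lo = arm_start + _MARGIN
            hi = arm_end - _MARGIN - length - 2 * _GAP
            start = int(rng.integers(lo, hi + 1))
            pieces = [
                (start, start + _GAP, None),
                (start + _GAP, start + _GAP + length, (2.0, 0.0)),
                (start + _GAP + length, start + 2 * _GAP + length, None),
            ]
        elif kind == "lst":
            length = int(rng.integers(12 * MB, 20 * MB + 1))
            lo = arm_start + _MARGIN  # left baseline flank >= 10 Mb
            hi = arm_end - _MARGIN - length - _GAP
            start = int(rng.integers(lo, hi + 1))
            pieces = [
                (start, start + length, (4.0, 2.0)),
                (start + length, start + length + _GAP, None),
            ]
        else:  # tai
            length = int(rng.integers(16 * MB, 20 * MB + 1))
            if arm_name == "p":
                pieces = [
                    (arm_start, arm_start + length, (3.0, 1.0)),
                    (arm_start + length, arm_start + length + _GAP, None),
                ]
            else:
                pieces = [
                    (arm_end - length - _GAP, arm_end - length, None),
                    (arm_end - length, arm_end, (3.0, 1.0)),
                ]
        carve.setdefault(chrom, []).extend(pieces)
        events.append(
            {"kind": kind, "chrom": chrom, "arm": arm_name,
             "start": pieces[0][0], "end": pieces[-1][1]}
        )

    segments: list[Segment] = []
    for chrom, length in genome.chromosomes:
        pieces = sorted(carve.get(chrom, []))
        cursor = 0
        for start, end, state in pieces:
            if start > cursor:
                segments.append(Segment(chrom, cursor, start, 2.0, 1.0))
            if state is not None:
                segments.append(Segment(chrom, start, end, *state))
            cursor = end
        if cursor < length:
            segments.append(Segment(chrom, cursor, length, 2.0, 1.0))

    profile = SegmentProfile(sample_id, segments)
    truth = {
        "seed": int(seed),
        "sample_id": sample_id,
        "loh": n_loh,
        "lst": n_lst,
        "tai": n_tai,
        "hrdsum": n_events,
        "events": events,
    }
    return profile, truth


# ---------------------------------------------------------------------------
# multi-dataset score matrices
# ---------------------------------------------------------------------------

def _default_distortions() -> list[Callable[[np.ndarray], np.ndarray]]:
    return [
        lambda x: x,
        lambda x: 1.3 * x + 2.0,
        lambda x: 8.0 * np.sqrt(x),
    ]


def simulate_multidataset(
    truth_scores: Sequence[float] | None = None,
    distortions: Sequence[Callable] | None = None,
    noise_sd: float = 3.0,
    overlap_fraction: float = 0.35,
    seed: int = 0,
    n_samples: int = 300,
) -> tuple[pd.DataFrame, dict]:
    """Score matrix from monotone-distorted, noisy copies of truth scores.

    A core of ``overlap_fraction`` of the samples appears in every dataset
    (the consensus set); each remaining sample is assigned to one random
    dataset. Scores are ``distortion(truth) + N(0, noise_sd)``, clamped at 0.
    """
    rng = rng_from_seed(seed)
    if truth_scores is None:
        truth_scores = np.maximum(rng.gamma(shape=1.5, scale=15.0, size=n_samples), 0.0)
    truth_scores = np.asarray(truth_scores, dtype=float)
    n = truth_scores.size
    distortions = list(distortions) if distortions is not None else _default_distortions()
    if len(distortions) < 2:
        raise ValueError("need at least 2 dataset distortions")
    n_core = int(np.ceil(overlap_fraction * n))
    if n_core < 3:
        raise ValueError("overlap core must contain at least 3 samples")
    samples = [f"S{i:04d}" for i in range(n)]
    membership = {s: list(range(len(distortions))) for s in samples[:n_core]}
    for s in samples[n_core:]:
        membership[s] = [int(rng.integers(len(distortions)))]
    rows = []
    for d, fn in enumerate(distortions):
        dataset = f"ds{d}"
        for i, s in enumerate(samples):
            if d in membership[s]:
                value = float(fn(np.array([truth_scores[i]]))[0])
                value += float(rng.normal(0.0, noise_sd))
                rows.append((s, dataset, max(value, 0.0)))
    matrix = pd.DataFrame(rows, columns=["sample", "dataset", "hrdsum"])
    truth = {
        "seed": int(seed),
        "noise_sd": noise_sd,
        "n_samples": n,
        "n_common": n_core,
        "truth_scores": dict(zip(samples, truth_scores.tolist())),
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# variants: reference + VCF with planted filter outcomes and contexts
# ---------------------------------------------------------------------------

VIOLATION_CLASSES = ["pon", "blacklist", "recurrent", "not_pass", "low_af", "low_qual"]
CONTEXT_CLASSES = ["del.mh", "del.rep", "del.none", "ins.mh", "ins.rep", "ins.none"]


@dataclass
class SimulatedVariants:
    reference: dict[str, str]
    records: list[VariantRecord]
    cohort_recurrence: dict[tuple, int]
    truth: dict

    def write(self, outdir: str | Path) -> None:
        """Write ref.fa, variants.vcf, truth.json under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "ref.fa", "w") as fh:
            for name, seq in self.reference.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        write_vcf(
            self.records,
            outdir / "variants.vcf",
            contigs={c: len(s) for c, s in self.reference.items()},
        )
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=1))


def _engineer_site(seq: list[str], site0: int, kind: str) -> tuple[str, str]:
    """Overwrite reference around ``site0`` and return the (ref, alt) alleles.

    All indels are emitted in left-aligned parsimonious form: the anchor
    base is chosen so the representation cannot shift further left.
    """
    def put(offset: int, s: str) -> None:
        seq[site0 + offset : site0 + offset + len(s)] = list(s)

    if kind == "del.mh":
        # anchor C, delete GTCA, 3' flank begins GT then diverges
        put(0, "C" + "GTCA" + "GTGA")
        return "CGTCA", "C"
    if kind == "del.rep":
        # anchor G, delete AT out of an (AT)x3 run
        put(0, "G" + "ATATAT" + "CC")
        return "GAT", "G"
    if kind == "del.none":
        # anchor G, delete CAGT, flank TT: no homology, no repeat
        put(0, "G" + "CAGT" + "TTCC")
        return "GCAGT", "G"
    if kind == "ins.mh":
        put(0, "C" + "GTGA")  # insert GTCA before flank GTGA
        return "C", "CGTCA"
    if kind == "ins.rep":
        put(0, "G" + "ATAT" + "CC")  # insert AT before an (AT)x2 run
        return "G", "GAT"
    if kind == "ins.none":
        put(0, "C" + "TTGG")  # insert CAGT before flank TT
        return "C", "CCAGT"
    raise ValueError(f"unknown context class {kind!r}")


def simulate_variants(
    spec: Mapping[str, int] | None = None,
    seed: int = 0,
    sample_id: str = "synthetic",
    contig: str = "toychr1",
) -> SimulatedVariants:
    """Toy reference + VCF records with planted filter outcomes and contexts.

    ``spec`` maps class names to counts: ``"clean"`` (passing SNVs), the six
    single-violation classes (each record fails exactly one filter rule),
    and the six indel context classes (all passing). Default spec: 4 clean +
    one of each violation.
    """
    if spec is None:
        spec = {"clean": 4, **dict.fromkeys(VIOLATION_CLASSES, 1)}
    spec = dict(spec)
    unknown = set(spec) - {"clean", *VIOLATION_CLASSES, *CONTEXT_CLASSES}
    if unknown:
        raise ValueError(f"unknown spec classes {sorted(unknown)}")
    rng = rng_from_seed(seed)
    n_sites = sum(spec.values())
    spacing = 200
    ref_len = max((n_sites + 2) * spacing, 2000)
    seq = list("".join(rng.choice(list("ACGT"), size=ref_len)))

    records: list[VariantRecord] = []
    recurrence: dict[tuple, int] = {}
    truth_records = []
    site = spacing

    def clean_kwargs() -> dict:
        return dict(
            sample_id=sample_id, chrom=contig, qual=500.0,
            filter_status="PASS", allele_frequency=0.5,
            pon_flag=False, confidence_region="high",
            blacklist_hits=frozenset(),
        )

    def add_snv(kind: str, **overrides) -> VariantRecord:
        nonlocal site
        pos = site + 1  # 1-based
        ref = seq[site]
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
        kwargs = clean_kwargs() | overrides
        rec = VariantRecord(pos=pos, ref=ref, alt=alt, **kwargs)
        site += spacing
        return rec

    for kind, count in spec.items():
        for _ in range(count):
            if kind == "clean":
                rec, retain, reason = add_snv(kind), True, ""
            elif kind == "pon":
                rec, retain, reason = add_snv(kind, pon_flag=True), False, "pon"
            elif kind == "blacklist":
                rec = add_snv(kind, blacklist_hits=frozenset({"gnomad"}))
                retain, reason = False, "blacklist"
            elif kind == "recurrent":
                rec = add_snv(kind)
                recurrence[rec.key] = 3
                retain, reason = False, "recurrent"
            elif kind == "not_pass":
                rec, retain, reason = add_snv(kind, filter_status="germline"), False, "not_pass"
            elif kind == "low_af":
                rec, retain, reason = add_snv(kind, allele_frequency=0.05), False, "low_af"
            elif kind == "low_qual":
                rec, retain, reason = add_snv(kind, qual=100.0), False, "low_qual"
            else:  # planted indel context, passing all filters
                ref_a, alt_a = _engineer_site(seq, site, kind)
                rec = VariantRecord(pos=site + 1, ref=ref_a, alt=alt_a, **clean_kwargs())
                site += spacing
                retain, reason = True, ""
            records.append(rec)
            truth_records.append(
                {
                    "key": list(rec.key),
                    "retain": retain,
                    "reason": reason,
                    "context": kind if kind in CONTEXT_CLASSES else None,
                }
            )

    reference = {contig: "".join(seq)}
    truth = {
        "seed": int(seed),
        "spec": dict(spec),
        "n_retained": sum(r["retain"] for r in truth_records),
        "records": truth_records,
    }
    return SimulatedVariants(reference, records, recurrence, truth)


# ---------------------------------------------------------------------------
# feature tables with planted effects
# ---------------------------------------------------------------------------

def simulate_features(
    n_samples: int = 200,
    effects: Mapping[str, float] | None = None,
    enrichment: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame, pd.Series, dict]:
    """Scores, features with planted Pearson r, and a deficiency matrix.

    ``effects`` maps feature name -> true correlation with the score vector
    (|r| < 1). ``enrichment`` configures the boolean genes x samples
    deficiency matrix: keys ``n_genes``, ``odds_ratio``, ``baseline_rate``;
    HRD labels mark the top quartile of scores. Returns
    (scores, features, deficiency, hrd_labels, truth).
    """
    rng = rng_from_seed(seed)
    effects = dict(effects or {})
    enrichment = dict(enrichment or {})
    if any(abs(r) >= 1 for r in effects.values()):
        raise ValueError("planted |r| must be < 1")
    samples = pd.Index([f"S{i:04d}" for i in range(n_samples)], name="sample")
    z = rng.normal(size=n_samples)
    scores = pd.Series(np.maximum(20.0 + 15.0 * z, 0.0), index=samples, name="hrdsum")
    feats = {}
    for name, r in effects.items():
        feats[name] = r * z + np.sqrt(1.0 - r**2) * rng.normal(size=n_samples)
    features = pd.DataFrame(feats, index=samples)

    hrd = pd.Series(scores >= scores.quantile(0.75), index=samples, name="hrd")
    n_genes = int(enrichment.get("n_genes", 0))
    odds_ratio = float(enrichment.get("odds_ratio", 1.0))
    p0 = float(enrichment.get("baseline_rate", 0.05))
    odds1 = odds_ratio * p0 / (1.0 - p0)
    p1 = odds1 / (1.0 + odds1)
    deficiency = pd.DataFrame(
        rng.random((n_genes, n_samples))
        < np.where(hrd.to_numpy(), p1, p0),
        index=[f"gene{g}" for g in range(n_genes)],
        columns=samples,
    )
    truth = {
        "seed": int(seed),
        "n_samples": n_samples,
        "effects": effects,
        "odds_ratio": odds_ratio,
        "deficient_rates": {"hrd": p1, "non_hrd": p0},
    }
    return scores, features, deficiency, hrd, truth


# ---------------------------------------------------------------------------
# dose-response plates
# ---------------------------------------------------------------------------

def simulate_dose_response(
    a: float,
    b: float = 0.0,
    n_points: int = 10,
    dilution: float = 3.0,
    top_nmolL: float = 10_000.0,
    noise_sd: float = 0.0,
    replicates: int = 1,
    seed: int = 0,
    response_cap: float = 1.0,
    control_absorbance: float = 2.0,
    n_controls: int = 6,
) -> tuple[pd.DataFrame, dict]:
    """Replicate plates from the primary dose-response model plus noise.

    Emulates the assay design: a 10-point 1:3 dilution series from a top
    dose of 10 µmol/L. ``response_cap`` scales the curve amplitude to model
    partial-efficacy compounds. Absorbance is proportional to surviving
    fraction (1 - response); control wells sit at the untreated level.
    Returns a long-format plate table and the planted truth.
    """
    rng = rng_from_seed(seed)
    conc = top_nmolL / dilution ** np.arange(n_points)
    x = np.log10(conc)
    y_true = response_cap * (1.0 - 1.0 / (1.0 + 10.0 ** (10.0**b * (x - a))))
    rows = []
    for rep in range(replicates):
        for c in range(n_controls):
            rows.append(
                {
                    "replicate": rep,
                    "well": f"ctrl{c}",
                    "concentration_nmolL": 0.0,
                    "absorbance": control_absorbance
                    * (1.0 + rng.normal(0.0, noise_sd)),
                    "is_control": True,
                }
            )
        for i, (ci, yi) in enumerate(zip(conc, y_true)):
            rows.append(
                {
                    "replicate": rep,
                    "well": f"d{i}",
                    "concentration_nmolL": ci,
                    "absorbance": control_absorbance
                    * (1.0 - yi + rng.normal(0.0, noise_sd)),
                    "is_control": False,
                }
            )
    plate = pd.DataFrame(rows)
    truth = {
        "seed": int(seed),
        "a": a,
        "b": b,
        "ic50_nmolL": 10.0**a,
        "noise_sd": noise_sd,
        "response_cap": response_cap,
        "replicates": replicates,
    }
    return plate, truth
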
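"""HRD classification from HRDsum scores and CHORD probabilities.

The HRDsum cutoff is derived as the 5th percentile of summary scores among
cell lines with known BRCA1/2 deficiencies (linear interpolation between
order statistics, rounded to the nearest integer — the cutoff is reported as
an integer, e.g. 47 for cell lines). Samples at or above the cutoff are
HRDsum-high (the boundary is inclusive). CHORD-based classification is
HRD iff the probability strictly exceeds 0.4, with MSI samples excluded
before classification (CHORD is not applicable to MSI genomes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "CutoffResult",
    "HRDCall",
    "derive_cutoff",
    "classify_hrdsum",
    "classify_chord",
]

CHORD_THRESHOLD = 0.4


@dataclass(frozen=True)
class CutoffResult:
    """Integer cutoff plus the unrounded percentile it was derived from."""

    cutoff: int
    percentile_value: float
    percentile: float
    n_deficient: int

    def __float__(self) -> float:
        return float(self.cutoff)


@dataclass(frozen=True)
class HRDCall:
    sample_id: str
    hrdsum: float | None = None
    chord_p: float | None = None
    hrdsum_class: str = "NA"  # high / low / NA
    chord_class: str = "NA"  # HRD / HRP / MSI-excluded / NA


def derive_cutoff(
    scores: Mapping[str, float], deficient_ids: Iterable[str], percentile: float = 5
) -> CutoffResult:
    """Cutoff = ``percentile``-th percentile of scores of deficient samples.

    Linear interpolation between order statistics; the integer cutoff is the
    nearest-integer rounding of the interpolated value, which is retained
    unrounded in the result.
    """
    deficient = [scores[s] for s in set(deficient_ids) if s in scores]
    if not deficient:
        raise ValueError("no deficient samples with scores")
    value = float(np.percentile(deficient, percentile))
    return CutoffResult(
        cutoff=int(round(value)),
        percentile_value=value,
        percentile=percentile,
        n_deficient=len(deficient),
    )


def classify_hrdsum(score: float, cutoff: float) -> str:
    """'high' iff score >= cutoff (inclusive boundary)."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    return "high" if score >= float(cutoff) else "low"


def classify_chord(p: float, msi: bool = False) -> str:
    """'MSI-excluded' if MSI, else 'HRD' iff p > 0.4 (strict)."""
    if not 0 <= p <= 1:
        raise ValueError(f"probability {p} outside [0, 1]")
    if msi:
        return "MSI-excluded"
    return "HRD" if p > CHORD_THRESHOLD else "HRP"
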
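"""Gene deficiency / proficiency / likely-silencing labels per cell line.

A gene in a cell line is **deficient** if it carries a homozygous
(allele frequency > 0.85) mutation annotated pathogenic by ClinVar or
predicted HIGH impact, or if it has a deep (homozygous) deletion. It is
**proficient** if it has no mutations at all, no deep deletion, and
expression above the gene's lower quartile (log2(TPM+1); 3.8 for BRCA1,
2.07 for BRCA2 in the reference cohort). A gene is **likely silenced**
epigenetically when expression is below the lower quartile and promoter
methylation fraction exceeds 0.3. All boundaries are strict as printed.

Manual literature overrides (e.g. known revertants, methylation reported
outside the input tables) are supplied as an explicit mapping, never
hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "MutationRecord",
    "GeneState",
    "is_pathogenic_clinvar",
    "label_deficient",
    "label_proficient",
    "label_silenced",
    "expression_lower_quartile",
    "label_gene",
]

HOMOZYGOUS_AF = 0.85
METHYLATION_THRESHOLD = 0.3


@dataclass(frozen=True)
class MutationRecord:
    sample_id: str
    gene: str
    allele_frequency: float
    clinvar_significance: str = ""
    impact: str = "NA"  # HIGH / MODERATE / LOW / MODIFIER / NA

    def __post_init__(self) -> None:
        if not 0 <= self.allele_frequency <= 1:
            raise ValueError(
                f"allele frequency {self.allele_frequency} outside [0, 1]"
            )


@dataclass(frozen=True)
class GeneState:
    sample_id: str
    gene: str
    label: str  # deficient / proficient / silenced-likely / indeterminate
    deep_deletion: bool = False
    expression: float | None = None
    promoter_methylation: float | None = None


def is_pathogenic_clinvar(significance: str) -> bool:
    """Case-insensitive 'pathogenic' (incl. likely), excluding conflicting/benign."""
    s = (significance or "").lower()
    return "pathogenic" in s and "conflicting" not in s and "benign" not in s


def label_deficient(
    mutations: Iterable[MutationRecord], deep_deletion: bool
) -> bool:
    """Deficient iff a homozygous damaging mutation exists or a deep deletion."""
    if deep_deletion:
        return True
    return any(
        m.allele_frequency > HOMOZYGOUS_AF
        and (is_pathogenic_clinvar(m.clinvar_significance) or m.impact == "HIGH")
        for m in mutations
    )


def label_proficient(
    mutations: Iterable[MutationRecord],
    deep_deletion: bool,
    expression: float,
    expr_lower_quartile: float,
) -> bool:
    """Proficient iff no mutations of any kind, no deletion, expression above quartile."""
    if deep_deletion or any(True for _ in mutations):
        return False
    return expression > expr_lower_quartile


def label_silenced(
    expression: float, expr_lower_quartile: float, methylation: float | None
) -> bool:
    """Likely silenced iff low expression and promoter methylation > 0.3."""
    if methylation is None:
        return False
    return expression < expr_lower_quartile and methylation > METHYLATION_THRESHOLD


def expression_lower_quartile(expression: Iterable[float]) -> float:
    """25th percentile, linear interpolation between order statistics."""
    values = np.asarray(list(expression), dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 expression values for a quartile")
    return float(np.percentile(values, 25))


def label_gene(
    sample_id: str,
    gene: str,
    mutations: Iterable[MutationRecord],
    deep_deletion: bool,
    expression: float | None,
    expr_lower_quartile: float | None,
    methylation: float | None = None,
    overrides: Mapping[tuple[str, str], str] | None = None,
) -> GeneState:
    """Combine the three criteria into one mutually exclusive label.

    Deficiency takes precedence, then likely silencing, then proficiency;
    anything else is indeterminate. ``overrides[(sample, gene)]`` replaces
    the computed label (literature knowledge such as reversion events).
    """
    mutations = list(mutations)
    if overrides and (sample_id, gene) in overrides:
        label = overrides[(sample_id, gene)]
    elif label_deficient(mutations, deep_deletion):
        label = "deficient"
    elif (
        expression is not None
        and expr_lower_quartile is not None
        and label_silenced(expression, expr_lower_quartile, methylation)
    ):
        label = "silenced-likely"
    elif (
        expression is not None
        and expr_lower_quartile is not None
        and label_proficient(mutations, deep_deletion, expression, expr_lower_quartile)
    ):
        label = "proficient"
    else:
        label = "indeterminate"
    return GeneState(
        sample_id=sample_id,
        gene=gene,
        label=label,
        deep_deletion=deep_deletion,
        expression=expression,
        promoter_methylation=methylation,
    )
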
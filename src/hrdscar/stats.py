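"""Association and enrichment statistics for cell-line feature matrices.

Covers four analyses over a samples x features table with per-sample
metadata flags (noncancerous, MSI, tissue):

* one-tailed Fisher exact enrichment of gene deficiencies among HRD lines,
  restricted to genes deficient in at least one HRD line, with
  Benjamini-Hochberg adjustment;
* per-feature Pearson correlation scans against a score vector
  (pairwise-complete observations, constant features reported as NA);
* Kruskal-Wallis tests of a response across score-quartile bins;
* CRISPR screen guide-level log2 fold changes (pseudocount 1,
  median-centered per replicate, averaged across replicates) with gene
  scores as the median over guides.

Noncancerous and MSI samples are excluded centrally by the FeatureTable
mask, so every scan applies the same exclusion rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FeatureTable",
    "EnrichmentResult",
    "fisher_greater_p",
    "fisher_enrichment",
    "bh_adjust",
    "correlate_scan",
    "quartile_kruskal",
    "crispr_gene_scores",
]


@dataclass
class FeatureTable:
    """Samples x features matrix with exclusion metadata.

    ``features`` is a DataFrame indexed by sample; ``noncancerous`` and
    ``msi`` are boolean Series over the same index.
    """

    features: pd.DataFrame
    noncancerous: pd.Series | None = None
    msi: pd.Series | None = None
    tissue: pd.Series | None = None

    def __post_init__(self) -> None:
        idx = self.features.index
        for name in ("noncancerous", "msi", "tissue"):
            s = getattr(self, name)
            if s is not None and not s.index.equals(idx):
                raise ValueError(f"{name} index does not match features index")

    def included_samples(self) -> pd.Index:
        """Samples after the central noncancerous/MSI exclusion."""
        mask = pd.Series(True, index=self.features.index)
        if self.noncancerous is not None:
            mask &= ~self.noncancerous.astype(bool)
        if self.msi is not None:
            mask &= ~self.msi.astype(bool)
        return self.features.index[mask]


@dataclass(frozen=True)
class EnrichmentResult:
    gene: str
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_one_tailed: float
    q_bh: float = field(default=float("nan"), compare=False)


def fisher_greater_p(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Odds ratio and one-tailed (greater) Fisher exact p for a 2x2 table."""
    odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(odds), float(p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrichment(
    deficiency: pd.DataFrame, hrd_labels: pd.Series
) -> list[EnrichmentResult]:
    """One-tailed Fisher enrichment of deficiency among HRD samples per gene.

    ``deficiency`` is genes x samples boolean; ``hrd_labels`` boolean over
    the same samples. Genes with no deficient HRD sample are excluded before
    testing; BH adjustment runs across the included genes only.
    """
    hrd = hrd_labels.reindex(deficiency.columns)
    if hrd.isna().any():
        raise ValueError("HRD labels missing for some samples")
    hrd = hrd.astype(bool).to_numpy()
    results = []
    for gene, row in deficiency.iterrows():
        d = row.astype(bool).to_numpy()
        a = int(np.sum(d & hrd))
        if a == 0:  # inclusion rule: deficient in >= 1 HRD sample
            continue
        b = int(np.sum(d & ~hrd))
        c = int(np.sum(~d & hrd))
        dd = int(np.sum(~d & ~hrd))
        odds, p = fisher_greater_p(a, b, c, dd)
        results.append(EnrichmentResult(str(gene), ((a, b), (c, dd)), odds, p))
    if not results:
        raise ValueError("no genes deficient in any HRD sample")
    q = bh_adjust([r.p_one_tailed for r in results])
    return [
        EnrichmentResult(r.gene, r.table, r.odds_ratio, r.p_one_tailed, float(qi))
        for r, qi in zip(results, q)
    ]


def correlate_scan(
    scores: pd.Series, table: FeatureTable, min_n: int = 3
) -> pd.DataFrame:
    """Pearson r and two-sided p per feature, BH-adjusted across features.

    Pairwise-complete samples per feature, after the table's central
    exclusions. Constant features (or < ``min_n`` pairs) yield NA and are
    left out of the BH adjustment. P-values use the exact t-form with
    n - 2 degrees of freedom.
    """
    samples = table.included_samples().intersection(scores.dropna().index)
    out = pd.DataFrame(
        index=table.features.columns,
        columns=["r", "p", "q_bh", "n_used"],
        dtype=float,
    )
    for feat in table.features.columns:
        y = table.features.loc[samples, feat]
        paired = pd.concat([scores.loc[samples], y], axis=1).dropna()
        n = len(paired)
        out.loc[feat, "n_used"] = n
        if n < min_n or paired.iloc[:, 0].nunique() < 2 or paired.iloc[:, 1].nunique() < 2:
            continue
        r, p = sps.pearsonr(paired.iloc[:, 0], paired.iloc[:, 1])
        out.loc[feat, ["r", "p"]] = [r, p]
    tested = out["p"].notna()
    if tested.any():
        out.loc[tested, "q_bh"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    return out


def _quartile_bins(scores: np.ndarray) -> np.ndarray:
    """Bin by interpolated quartile breaks; values at a break go to the lower bin."""
    breaks = np.percentile(scores, [25, 50, 75])
    return np.searchsorted(breaks, scores, side="left")


def quartile_kruskal(scores: pd.Series, response: pd.Series):
    """Kruskal-Wallis H across score-quartile bins of the response.

    Requires >= 4 distinct score values and responses in >= 2 non-empty
    bins. Returns (H, p, groups). Ties are rank-corrected; degenerate
    quartile breaks collapse bins, reducing the degrees of freedom.
    """
    paired = pd.concat([scores, response], axis=1).dropna()
    s = paired.iloc[:, 0].to_numpy(dtype=float)
    y = paired.iloc[:, 1].to_numpy(dtype=float)
    if len(np.unique(s)) < 4:
        raise ValueError("need >= 4 distinct score values for quartile binning")
    bins = _quartile_bins(s)
    groups = [y[bins == b] for b in np.unique(bins)]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("responses present in fewer than 2 bins")
    if np.unique(y).size == 1:  # all tied: no rank variation, H = 0
        return 0.0, 1.0, groups
    h, p = sps.kruskal(*groups)
    return float(h), float(p), groups


def crispr_gene_scores(
    counts_initial: pd.DataFrame,
    counts_endpoint: pd.DataFrame,
    guide_to_gene: pd.Series,
) -> pd.Series:
    """Gene fitness scores from a CRISPR screen count matrix pair.

    Per replicate (column): lfc = log2((end + 1) / (init + 1)), centered by
    the replicate's median lfc. Guide scores average the centered lfcs
    across replicates; gene scores take the median over the gene's guides.
    """
    if not counts_initial.index.equals(counts_endpoint.index):
        raise ValueError("guide indices differ between timepoints")
    missing = counts_initial.index.difference(guide_to_gene.index)
    if len(missing):
        raise ValueError(f"guides missing from mapping: {list(missing)[:5]}")
    lfc = np.log2((counts_endpoint + 1) / (counts_initial + 1))
    centered = lfc - lfc.median(axis=0)
    guide_scores = centered.mean(axis=1)
    return guide_scores.groupby(guide_to_gene.reindex(guide_scores.index)).median()
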
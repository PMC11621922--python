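"""Cross-dataset harmonization of HRDsum scores via natural-spline regression.

Allele-specific copy-number calls from different institutes produce HRDsum
scores on shifted scales. Harmonization proceeds in three steps:

1. for the samples present in *every* dataset, take the per-sample median of
   their raw scores ("consensus medians");
2. for each dataset, regress the consensus medians on that dataset's raw
   scores using a natural cubic spline basis (default 4 degrees of freedom,
   knots at quantiles of the raw scores; linear extrapolation beyond the
   boundary knots, which is definitional for natural splines);
3. map every dataset's scores through its fitted spline, clamp at 0
   (HRDsum is a count), and average per sample across datasets.

The score matrix is a long-format :class:`pandas.DataFrame` with columns
``sample``, ``dataset``, ``hrdsum``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy

__all__ = [
    "SplineMap",
    "SplineHarmonizer",
    "consensus_medians",
    "fit_spline_map",
    "apply_and_merge",
]

MATRIX_COLUMNS = ["sample", "dataset", "hrdsum"]


def _validate_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    missing = set(MATRIX_COLUMNS) - set(matrix.columns)
    if missing:
        raise ValueError(f"score matrix missing columns {sorted(missing)}")
    if matrix.duplicated(["sample", "dataset"]).any():
        raise ValueError("score matrix has duplicate (sample, dataset) entries")
    if (matrix["hrdsum"] < 0).any():
        raise ValueError("raw HRDsum scores must be >= 0")
    return matrix


@dataclass
class SplineMap:
    """A fitted raw-score -> consensus-score natural-spline map."""

    dataset_id: str
    degrees_of_freedom: int
    design_info: object = field(repr=False)
    coefficients: np.ndarray = field(repr=False)
    fitted_range: tuple[float, float] = (0.0, 0.0)

    def __call__(self, raw: np.ndarray) -> np.ndarray:
        raw = np.asarray(raw, dtype=float)
        basis = patsy.build_design_matrices([self.design_info], {"x": raw})[0]
        return np.asarray(basis) @ self.coefficients


def consensus_medians(matrix: pd.DataFrame) -> pd.Series:
    """Median raw score per sample, over the samples present in all datasets."""
    matrix = _validate_matrix(matrix)
    datasets = matrix["dataset"].unique()
    if len(datasets) < 2:
        raise ValueError("need scores from at least 2 datasets")
    per_sample = matrix.groupby("sample")["dataset"].nunique()
    common = per_sample.index[per_sample == len(datasets)]
    if len(common) == 0:
        raise ValueError("no samples shared by all datasets")
    sub = matrix[matrix["sample"].isin(common)]
    return sub.groupby("sample")["hrdsum"].median()


def fit_spline_map(
    dataset_scores: pd.Series, medians: pd.Series, df: int = 4, dataset_id: str = ""
) -> SplineMap:
    """Least-squares natural-spline fit predicting consensus medians from raw scores."""
    if df < 3:
        raise ValueError("natural cubic spline basis requires df >= 3")
    shared = dataset_scores.index.intersection(medians.index)
    if len(shared) < df + 2:
        raise ValueError(
            f"dataset {dataset_id!r}: {len(shared)} common samples, "
            f"need at least {df + 2} for df={df}"
        )
    x = dataset_scores.loc[shared].to_numpy(dtype=float)
    y = medians.loc[shared].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"dataset {dataset_id!r}: degenerate (constant) raw scores")
    design = patsy.dmatrix(f"cr(x, df={int(df)})", {"x": x})
    coef, *_ = np.linalg.lstsq(np.asarray(design), y, rcond=None)
    return SplineMap(
        dataset_id=dataset_id,
        degrees_of_freedom=int(df),
        design_info=design.design_info,
        coefficients=coef,
        fitted_range=(float(x.min()), float(x.max())),
    )


def apply_and_merge(
    matrix: pd.DataFrame, maps: dict[str, SplineMap]
) -> pd.Series:
    """Transform each dataset through its map, clamp at 0, average per sample.

    Returns a summary score for every sample present in >= 1 dataset.
    """
    matrix = _validate_matrix(matrix)
    missing = set(matrix["dataset"].unique()) - set(maps)
    if missing:
        raise ValueError(f"no spline map for datasets {sorted(missing)}")
    parts = []
    for dataset, grp in matrix.groupby("dataset"):
        transformed = np.maximum(maps[dataset](grp["hrdsum"].to_numpy()), 0.0)
        parts.append(pd.Series(transformed, index=grp["sample"]))
    return pd.concat(parts).groupby(level=0).mean().rename("summary_hrdsum")


class SplineHarmonizer:
    """Fit/transform interface over the three harmonization steps.

    Parameters
    ----------
    df : int
        Degrees of freedom of the natural cubic spline basis.

    Attributes (after :meth:`fit`)
    ------------------------------
    medians_ : pd.Series
        Consensus medians over the common samples.
    maps_ : dict[str, SplineMap]
        Fitted per-dataset spline maps.
    """

    def __init__(self, df: int = 4):
        self.df = df

    def get_params(self, deep: bool = True) -> dict:
        return {"df": self.df}

    def set_params(self, **params) -> "SplineHarmonizer":
        for k, v in params.items():
            if k not in {"df"}:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, matrix: pd.DataFrame) -> "SplineHarmonizer":
        matrix = _validate_matrix(matrix)
        self.medians_ = consensus_medians(matrix)
        self.maps_ = {
            dataset: fit_spline_map(
                grp.set_index("sample")["hrdsum"],
                self.medians_,
                df=self.df,
                dataset_id=str(dataset),
            )
            for dataset, grp in matrix.groupby("dataset")
        }
        return self

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "maps_"):
            raise ValueError("SplineHarmonizer is not fitted")
        summary = apply_and_merge(matrix, self.maps_)
        n = matrix.groupby("sample")["dataset"].nunique().rename("n_datasets")
        return pd.concat([summary, n], axis=1).rename_axis("sample")

    def fit_transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        return self.fit(matrix).transform(matrix)
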
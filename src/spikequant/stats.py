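"""Downstream ecological and genomic statistics.

Covers the small battery of analyses that sit on top of the quantitative
pipeline: the f-ratio (fraction of production fueled by nitrate),
completeness-corrected genome sizes, basic assembly statistics,
copy-number-versus-N:Fe ordinary least squares, Welch's t test for group
comparison, a standardized PCA over nitrogen gene copy numbers and N:Fe,
and estimate-versus-reference agreement (slope against the 1:1 line).

Regression uses statsmodels OLS; PCA uses scikit-learn with z-scored
columns and deterministic component signs (the largest-magnitude loading of
each component is made positive).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .io import read_fasta

__all__ = [
    "UptakeProfile",
    "StationEnvironment",
    "GenomeStats",
    "f_ratio",
    "estimated_complete_size",
    "genome_stats",
    "copy_vs_nfe_regression",
    "group_compare",
    "nitrogen_pca",
    "agreement",
    "RegressionSummary",
]


@dataclass(frozen=True)
class UptakeProfile:
    """Paired nitrate and ammonium uptake rates for one size fraction."""

    size_fraction: str
    nitrate_uptake: float
    ammonium_uptake: float

    def __post_init__(self) -> None:
        if self.nitrate_uptake < 0 or self.ammonium_uptake < 0:
            raise ValueError("uptake rates must be >= 0")


@dataclass(frozen=True)
class StationEnvironment:
    """Surface nitrate and dissolved iron at a station, both nanomolar."""

    station_id: str
    nitrate_nM: float
    dissolved_iron_nM: float

    @property
    def n_fe_ratio(self) -> float:
        if self.dissolved_iron_nM <= 0:
            return float("nan")
        return self.nitrate_nM / self.dissolved_iron_nM


@dataclass
class GenomeStats:
    genome_id: str
    assembled_size_bp: int
    contig_count: int
    gc_percent: float
    completeness_percent: float = float("nan")
    contamination_percent: float = float("nan")
    estimated_complete_size_bp: float = float("nan")


@dataclass
class RegressionSummary:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    conf_int: tuple[float, float]
    mean_ratio: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "n": self.n,
            "conf_int": list(self.conf_int),
            "mean_ratio": self.mean_ratio,
        }


def f_ratio(profile: UptakeProfile) -> float:
    """Fraction of production fueled by nitrate: NO3 / (NO3 + NH4) uptake."""
    total = profile.nitrate_uptake + profile.ammonium_uptake
    if total <= 0:
        raise ValueError(
            f"size fraction {profile.size_fraction!r}: both uptake rates are "
            "zero; f-ratio undefined"
        )
    return profile.nitrate_uptake / total


def estimated_complete_size(
    assembled_size_bp: float, completeness_percent: float
) -> float:
    """Completeness-corrected genome size: assembled / (completeness/100).

    Input and output in bp (pass Mbp to get Mbp); display convention in the
    pipeline's tables is Mb to two decimals.
    """
    if not 0 < completeness_percent <= 100:
        raise ValueError("completeness_percent must be in (0, 100]")
    return assembled_size_bp / (completeness_percent / 100.0)


def genome_stats(fasta_path: str | Path, genome_id: str | None = None) -> GenomeStats:
    """Assembly statistics: total size, contig count, GC percent.

    Size counts non-gap bases; GC is 100*(G+C)/(A+C+G+T) with ambiguity
    codes excluded from numerator and denominator, case-insensitive.
    """
    records = read_fasta(fasta_path)
    if not records:
        raise ValueError(f"{fasta_path}: empty FASTA, no genome statistics")
    size = 0
    gc = at = 0
    for rec in records:
        seq = str(rec.seq).upper()
        size += sum(1 for c in seq if c != "-")
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError(f"{fasta_path}: no unambiguous A/C/G/T bases")
    return GenomeStats(
        genome_id=genome_id or Path(fasta_path).stem,
        assembled_size_bp=size,
        contig_count=len(records),
        gc_percent=100.0 * gc / (gc + at),
    )


def copy_vs_nfe_regression(
    stations: list[StationEnvironment],
    copy_numbers: dict[str, float],
) -> RegressionSummary:
    """OLS of a gene's copy number on log10(N:Fe) across stations.

    ``copy_numbers`` maps station_id to the gene's copies per genome
    equivalent. Stations with nonpositive iron (N:Fe undefined) or without a
    copy number are excluded with a warning via the returned n.
    """
    xs, ys = [], []
    for st in stations:
        ratio = st.n_fe_ratio
        y = copy_numbers.get(st.station_id)
        if y is None or not np.isfinite(y) or not np.isfinite(ratio) or ratio <= 0:
            continue
        xs.append(np.log10(ratio))
        ys.append(y)
    if len(xs) < 3:
        raise ValueError(
            f"need >=3 stations with finite log10(N:Fe) and copy numbers, got {len(xs)}"
        )
    return _ols(np.asarray(xs), np.asarray(ys))


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionSummary:
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int()  # rows: const, slope
    return RegressionSummary(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        n=int(model.nobs),
        conf_int=(float(ci[1][0]), float(ci[1][1])),
    )


def group_compare(values_a, values_b) -> tuple[float, float]:
    """Welch's unequal-variance two-sided t test: (statistic, p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def nitrogen_pca(
    matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Standardized PCA over a complete station x variable matrix.

    Columns are z-scored (copy numbers and N:Fe live on different scales).
    Component signs are fixed by making the largest-magnitude loading of
    each component positive, so repeated runs and duplicated rows give
    identical scores. Returns (scores, loadings, variance_explained), with
    variance_explained summing to 1 over the returned components.
    """
    from sklearn.decomposition import PCA

    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values; resolve exclusions first")
    if len(matrix) < 2:
        raise ValueError("PCA needs at least 2 rows")
    x = matrix.to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    pca = PCA(n_components=min(z.shape), svd_solver="full")
    scores = pca.fit_transform(z)
    loadings = pca.components_
    for k in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] *= -1
            scores[:, k] *= -1
    comp_names = [f"PC{i + 1}" for i in range(loadings.shape[0])]
    scores_df = pd.DataFrame(scores, index=matrix.index, columns=comp_names)
    loadings_df = pd.DataFrame(loadings, index=comp_names, columns=matrix.columns)
    var = pca.explained_variance_ratio_
    return scores_df, loadings_df, var / var.sum()


def agreement(estimates, references) -> RegressionSummary:
    """Estimate-versus-reference agreement: OLS slope plus mean ratio.

    A slope near 1 with intercept near 0 indicates the estimator tracks the
    reference (the 1:1 line); ``mean_ratio`` is the mean of estimate over
    reference, a direct bias measure.
    """
    e = np.asarray(estimates, dtype=float)
    r = np.asarray(references, dtype=float)
    if e.shape != r.shape or e.ndim != 1:
        raise ValueError("estimates and references must be paired 1-D arrays")
    if len(e) < 2:
        raise ValueError("need at least 2 pairs")
    if (r <= 0).any() or (e < 0).any():
        raise ValueError("agreement expects positive references")
    summary = _ols(r, e)
    summary.mean_ratio = float(np.mean(e / r))
    return summary
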
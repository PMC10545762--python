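"""Absolute volumetric abundances (genomes per liter) from spiked libraries.

Two estimators of the same physical quantity:

* ``marker_abundance`` counts single-copy marker-gene (recA-type) reads for a
  taxon. Dividing the read count by (marker gene length x r_read), where
  r_read is the standards' reads-per-base-per-molecule recovery, converts the
  counts to genome equivalents in the extracted sample; dividing by the
  volume filtered yields genomes L^-1.

* ``mag_abundance`` uses the mean depth of coverage of a reference genome
  (a MAG) and the coverage-based recovery ratio: M_a = M_cov / R_cov, then
  per-liter = M_a / volume.

``population_accounting`` expresses MAG-based estimates as percentages of
the marker-derived (and optionally an externally counted, e.g. flow
cytometry) population total; percentages above 100 are legitimate sampling
outcomes and are reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genecopy import consensus_filter
from .standards import RecoveryRatio, StandardSpec, mean_depth, _depth_lookup

__all__ = [
    "SampleMetadata",
    "AbundanceEstimate",
    "AccountingReport",
    "marker_abundance",
    "mag_abundance",
    "population_accounting",
    "abundance_table",
]


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    volume_filtered: float  # liters
    depth_m: float = float("nan")
    station: str = ""

    def __post_init__(self) -> None:
        if self.volume_filtered <= 0:
            raise ValueError(f"sample {self.sample_id}: volume_filtered must be > 0")


@dataclass
class AbundanceEstimate:
    """Genomes L^-1 for one taxon or MAG, with its derivation components."""

    entity_id: str
    sample_id: str
    molecules_in_sample: float
    per_liter: float
    method: str  # "marker_reads" or "mag_coverage"
    components: dict = field(default_factory=dict)
    flag: str = ""


@dataclass
class AccountingReport:
    """Each MAG's share of the marker-derived (and external) population total."""

    sample_id: str
    marker_total_per_liter: float
    mag_percent_of_marker: dict[str, float]
    mag_sum_percent_of_marker: float | None
    mag_percent_of_external: dict[str, float] | None = None
    mag_sum_percent_of_external: float | None = None
    flag: str = ""


def marker_abundance(
    assignments: pd.DataFrame,
    marker_length: int,
    ratio: RecoveryRatio,
    meta: SampleMetadata,
    taxon: str | None = None,
    marker_role: str = "marker",
) -> AbundanceEstimate:
    """Taxon abundance from single-copy marker reads.

    genome equivalents in sample = marker_reads / (marker_length * r_read);
    per-liter divides by the volume filtered. When ``taxon`` is given, only
    reads passing the dual-taxonomy consensus filter for that taxon count.
    """
    if marker_length <= 0:
        raise ValueError("marker_length must be > 0")
    if ratio.r_read is None or ratio.r_read <= 0:
        raise ValueError("recovery ratio r_read must be computed and positive")
    hits = assignments.loc[assignments["role"] == marker_role]
    if taxon is not None:
        hits = consensus_filter(hits, taxon)
    n_reads = len(hits)
    molecules = n_reads / (marker_length * ratio.r_read)
    return AbundanceEstimate(
        entity_id=taxon if taxon is not None else "all",
        sample_id=meta.sample_id,
        molecules_in_sample=molecules,
        per_liter=molecules / meta.volume_filtered,
        method="marker_reads",
        components={
            "marker_reads": n_reads,
            "marker_length": marker_length,
            "r_read": ratio.r_read,
            "volume_filtered": meta.volume_filtered,
        },
        flag="zero marker reads" if n_reads == 0 else "",
    )


def mag_abundance(
    depths: pd.DataFrame,
    mag_id: str,
    ratio: RecoveryRatio,
    meta: SampleMetadata,
    completeness_percent: float | None = None,
) -> AbundanceEstimate:
    """MAG population abundance from mean coverage: M_a = M_cov / R_cov.

    The default divides total mapped bases by the assembled MAG size, exactly
    as the recovery-ratio calibration does for the standards. When
    ``completeness_percent`` is given, coverage is instead averaged over the
    completeness-corrected genome size (assembled size / completeness), an
    explicit opt-in for users who want reads-per-complete-genome semantics;
    it assumes the unassembled fraction recruits no reads and therefore
    scales the estimate by completeness/100.
    """
    if ratio.r_cov is None or ratio.r_cov <= 0:
        raise ValueError("recovery ratio r_cov must be computed and positive")
    length, bases = _depth_lookup(depths, mag_id)
    if completeness_percent is not None:
        if not 0 < completeness_percent <= 100:
            raise ValueError("completeness_percent must be in (0, 100]")
        length = length / (completeness_percent / 100.0)
    m_cov = mean_depth(length, bases)
    molecules = m_cov / ratio.r_cov
    return AbundanceEstimate(
        entity_id=mag_id,
        sample_id=meta.sample_id,
        molecules_in_sample=molecules,
        per_liter=molecules / meta.volume_filtered,
        method="mag_coverage",
        components={
            "m_cov": m_cov,
            "r_cov": ratio.r_cov,
            "reference_length_bp": length,
            "volume_filtered": meta.volume_filtered,
            "completeness_percent": completeness_percent,
        },
        flag="zero coverage" if bases == 0 else "",
    )


def population_accounting(
    mag_estimates: list[AbundanceEstimate],
    marker_estimate: AbundanceEstimate,
    external_counts_per_liter: float | None = None,
) -> AccountingReport:
    """Percent of the taxon population captured by each MAG.

    Percentages may exceed 100 (independent estimators of the same
    population). A zero marker total with nonzero MAG estimates leaves the
    percentages undefined and flags the report.
    """
    ids = {e.sample_id for e in mag_estimates} | {marker_estimate.sample_id}
    if len(ids) != 1:
        raise ValueError(f"estimates span multiple samples: {sorted(ids)}")
    total = marker_estimate.per_liter
    mag_sum = sum(e.per_liter for e in mag_estimates)
    if total <= 0:
        defined = mag_sum == 0
        report = AccountingReport(
            sample_id=marker_estimate.sample_id,
            marker_total_per_liter=total,
            mag_percent_of_marker={e.entity_id: float("nan") for e in mag_estimates},
            mag_sum_percent_of_marker=None,
            flag="" if defined else "marker total is zero; percentages undefined",
        )
    else:
        report = AccountingReport(
            sample_id=marker_estimate.sample_id,
            marker_total_per_liter=total,
            mag_percent_of_marker={
                e.entity_id: 100.0 * e.per_liter / total for e in mag_estimates
            },
            mag_sum_percent_of_marker=100.0 * mag_sum / total,
        )
    if external_counts_per_liter is not None and external_counts_per_liter > 0:
        report.mag_percent_of_external = {
            e.entity_id: 100.0 * e.per_liter / external_counts_per_liter
            for e in mag_estimates
        }
        report.mag_sum_percent_of_external = (
            100.0 * mag_sum / external_counts_per_liter
        )
    return report


def abundance_table(estimates: list[AbundanceEstimate]) -> pd.DataFrame:
    """Long-format per-sample abundance table for TSV emission."""
    return pd.DataFrame(
        [
            {
                "sample_id": e.sample_id,
                "entity_id": e.entity_id,
                "method": e.method,
                "genomes_per_liter": e.per_liter,
                "molecules_in_sample": e.molecules_in_sample,
                "flag": e.flag,
                **{f"component_{k}": v for k, v in e.components.items()},
            }
            for e in estimates
        ]
    )
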
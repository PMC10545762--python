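"""Taxon-restricted gene copy numbers per genome equivalent.

The statistic: within a taxon's reads (retained only when BOTH taxonomy
systems agree on the taxon — the dual-consensus filter that suppresses
misannotation), the ratio of a nitrogen gene's read abundance to the
single-copy marker's read abundance estimates the gene's mean copies per
genome in that population. With length normalisation on (the default), each
read contributes 1/gene_length so genes of different lengths are directly
comparable:

    copies = (sum over gene reads of 1/l_gene) / (sum over marker reads of 1/l_marker)

which for uniform gene lengths reduces to
(gene_reads / gene_length) / (marker_reads / marker_length). Log2-scaled
values are reported alongside; a sample with zero gene reads keeps
copies = 0 but is excluded from log-space outputs with a recorded reason
(log2(0) is undefined — no pseudocounts). Zero marker reads leave the whole
ratio undefined, a distinct exclusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CopyNumberResult",
    "consensus_filter",
    "copy_number",
    "copy_number_matrix",
    "copy_number_table",
]


@dataclass
class CopyNumberResult:
    sample_id: str
    taxon: str
    gene_role: str
    copies_per_genome: float
    log2_copies: float  # NaN when undefined
    gene_reads: int
    marker_reads: int
    excluded: bool
    reason: str = ""
    length_normalized: bool = True


def consensus_filter(assignments: pd.DataFrame, taxon: str) -> pd.DataFrame:
    """Retain reads whose labels in BOTH taxonomy systems match ``taxon``.

    Matching is exact after case-folding; no rank-aware logic. An empty
    result is valid.
    """
    t = taxon.casefold()
    mask = (assignments["taxon_a"].str.casefold() == t) & (
        assignments["taxon_b"].str.casefold() == t
    )
    return assignments.loc[mask]


def _role_density(hits: pd.DataFrame, length_normalize: bool) -> float:
    """Read abundance of a role: plain count or length-normalised density."""
    if not length_normalize:
        return float(len(hits))
    lengths = hits["subject_gene_length"].to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise ValueError("subject_gene_length must be positive for normalization")
    return float(np.sum(1.0 / lengths))


def copy_number(
    assignments: pd.DataFrame,
    taxon: str,
    gene_role: str,
    marker_role: str = "marker",
    length_normalize: bool = True,
    sample_id: str = "",
    apply_filter: bool = True,
) -> CopyNumberResult:
    """Copies of ``gene_role`` per genome equivalent of ``taxon``.

    Set ``apply_filter=False`` if the consensus filter was already applied.
    """
    hits = consensus_filter(assignments, taxon) if apply_filter else assignments
    gene_hits = hits.loc[hits["role"] == gene_role]
    marker_hits = hits.loc[hits["role"] == marker_role]
    n_gene, n_marker = len(gene_hits), len(marker_hits)
    if n_marker == 0:
        return CopyNumberResult(
            sample_id=sample_id,
            taxon=taxon,
            gene_role=gene_role,
            copies_per_genome=float("nan"),
            log2_copies=float("nan"),
            gene_reads=n_gene,
            marker_reads=0,
            excluded=True,
            reason="no marker reads; ratio undefined",
            length_normalized=length_normalize,
        )
    copies = _role_density(gene_hits, length_normalize) / _role_density(
        marker_hits, length_normalize
    )
    if n_gene == 0:
        return CopyNumberResult(
            sample_id=sample_id,
            taxon=taxon,
            gene_role=gene_role,
            copies_per_genome=0.0,
            log2_copies=float("nan"),
            gene_reads=0,
            marker_reads=n_marker,
            excluded=True,
            reason=f"no {gene_role} reads; excluded from log2 output",
            length_normalized=length_normalize,
        )
    return CopyNumberResult(
        sample_id=sample_id,
        taxon=taxon,
        gene_role=gene_role,
        copies_per_genome=copies,
        log2_copies=math.log2(copies),
        gene_reads=n_gene,
        marker_reads=n_marker,
        excluded=False,
        length_normalized=length_normalize,
    )


def copy_number_matrix(
    results: list[CopyNumberResult],
    roles: list[str] | None = None,
    log_space: bool = False,
) -> pd.DataFrame:
    """Wide sample x role matrix for regression/PCA.

    Linear output puts 0 where a sample had no gene reads; log-space output
    leaves those cells missing (NaN) per the exclusion contract. Undefined
    entries (no marker reads) are NaN in both. Duplicate (sample, role)
    pairs are rejected.
    """
    rows = [
        (r.sample_id, r.gene_role, r.log2_copies if log_space else r.copies_per_genome)
        for r in results
        if roles is None or r.gene_role in roles
    ]
    df = pd.DataFrame(rows, columns=["sample_id", "gene_role", "value"])
    dup = df.duplicated(subset=["sample_id", "gene_role"])
    if dup.any():
        pairs = df.loc[dup, ["sample_id", "gene_role"]].to_records(index=False)
        raise ValueError(f"duplicate (sample, role) entries: {list(pairs)[:5]}")
    wide = df.pivot(index="sample_id", columns="gene_role", values="value")
    if roles is not None:
        wide = wide.reindex(columns=roles)
    return wide


def copy_number_table(results: list[CopyNumberResult]) -> pd.DataFrame:
    """Long-format results table for TSV emission."""
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "taxon": r.taxon,
                "gene_role": r.gene_role,
                "copies": r.copies_per_genome,
                "log2_copies": r.log2_copies,
                "gene_reads": r.gene_reads,
                "marker_reads": r.marker_reads,
                "excluded": r.excluded,
                "reason": r.reason,
            }
            for r in results
        ]
    )
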
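"""Internal-standard recovery ratios.

Internal genomic standards — foreign genomes spiked into a sample at a known
molecule count S_a before DNA extraction — calibrate absolute quantification.
After sequencing, the standard's recovered signal is measured either as its
mean depth of coverage S_cov (total bases mapped divided by genome length) or
as a per-base read density, and the recovery ratio is

    R_cov = S_cov / S_a        (genome-coverage units per molecule added)
    r_read = reads / (genome_length * S_a)   (reads per base per molecule)

For a library of constant read length ``rl`` the two are algebraically
locked: ``R_cov = r_read * rl``. Each spiked standard yields its own ratio;
the sample-level ratio is the arithmetic mean across standards, with the
per-standard values retained for QC. A standard that recovered zero reads is
excluded from the mean with a warning rather than aborting the run.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StandardSpec",
    "RecoveryRatio",
    "mean_depth",
    "coverage_recovery_ratio",
    "read_recovery_ratio",
    "recovery_ratios",
    "standards_from_truth",
]


@dataclass(frozen=True)
class StandardSpec:
    """An internal-standard genome with its known spiked molecule count."""

    genome_id: str
    genome_length: int
    molecules_added: float
    sequence: str = ""

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError(f"standard {self.genome_id}: genome_length must be > 0")
        if self.molecules_added <= 0:
            raise ValueError(f"standard {self.genome_id}: molecules_added must be > 0")


@dataclass
class RecoveryRatio:
    """Recovery of the spiked standards from one sequencing library.

    ``r_cov`` is mean coverage per molecule added (Eq.-1 sense); ``r_read``
    is reads per base per molecule. Whichever form was not computed is None.
    ``usable`` is False when no standard recovered any signal.
    """

    r_cov: float | None = None
    r_read: float | None = None
    per_standard: dict[str, float] = field(default_factory=dict)
    aggregation: str = "arithmetic_mean"
    usable: bool = True

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "r_cov": self.r_cov,
                "r_read": self.r_read,
                "per_standard": self.per_standard,
                "aggregation": self.aggregation,
                "usable": self.usable,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def mean_depth(reference_length_bp: float, total_bases_mapped: float) -> float:
    """Mean depth of coverage: total bases mapped / reference length."""
    if reference_length_bp <= 0:
        raise ValueError("reference length must be > 0")
    if total_bases_mapped < 0:
        raise ValueError("total bases mapped must be >= 0")
    return total_bases_mapped / reference_length_bp


def _depth_lookup(depths: pd.DataFrame, reference_id: str) -> tuple[float, float]:
    row = depths.loc[depths["reference_id"] == reference_id]
    if row.empty:
        raise ValueError(f"reference {reference_id!r} absent from depth table")
    if len(row) > 1:
        raise ValueError(f"reference {reference_id!r} duplicated in depth table")
    return float(row["reference_length_bp"].iloc[0]), float(
        row["total_bases_mapped"].iloc[0]
    )


def _aggregate(per_standard: dict[str, float]) -> tuple[float, bool]:
    """Arithmetic mean over standards with nonzero recovery.

    Zero-recovery standards are excluded with a warning; an all-zero set
    yields ratio 0 flagged unusable.
    """
    nonzero = {k: v for k, v in per_standard.items() if v > 0}
    dropped = sorted(set(per_standard) - set(nonzero))
    if dropped:
        warnings.warn(
            f"standards with zero recovery excluded from the mean: {dropped}",
            stacklevel=3,
        )
    if not nonzero:
        return 0.0, False
    return float(np.mean(list(nonzero.values()))), True


def coverage_recovery_ratio(
    depths: pd.DataFrame, standards: list[StandardSpec]
) -> RecoveryRatio:
    """Coverage-based recovery ratio R_cov = S_cov / S_a per standard.

    ``depths`` is a table with columns reference_id, reference_length_bp,
    total_bases_mapped. Every standard must appear in it. The aggregate is
    the arithmetic mean of per-standard ratios.
    """
    if not standards:
        raise ValueError("no standards supplied")
    per: dict[str, float] = {}
    for std in standards:
        length, bases = _depth_lookup(depths, std.genome_id)
        s_cov = mean_depth(length, bases)
        per[std.genome_id] = s_cov / std.molecules_added
    r_cov, usable = _aggregate(per)
    return RecoveryRatio(r_cov=r_cov, per_standard=per, usable=usable)


def read_recovery_ratio(
    assignments: pd.DataFrame, standards: list[StandardSpec]
) -> RecoveryRatio:
    """Read-based recovery: reads per base per molecule, per standard.

    Counts every read assigned to each standard genome (any role) from the
    assignment table and normalises by genome length and molecules added.
    """
    if not standards:
        raise ValueError("no standards supplied")
    counts = assignments.groupby("subject_genome_id").size()
    per: dict[str, float] = {}
    for std in standards:
        n_reads = int(counts.get(std.genome_id, 0))
        per[std.genome_id] = n_reads / (std.genome_length * std.molecules_added)
    r_read, usable = _aggregate(per)
    return RecoveryRatio(r_read=r_read, per_standard=per, usable=usable)


def standards_from_truth(truth_df: pd.DataFrame) -> list[StandardSpec]:
    """Build StandardSpec entries from a community truth table.

    Uses the rows with kind == "standard" (columns genome_id, length_bp,
    molecules), matching the truth TSV the simulator writes.
    """
    rows = truth_df.loc[truth_df["kind"] == "standard"]
    if rows.empty:
        raise ValueError("truth table lists no internal standards")
    return [
        StandardSpec(
            genome_id=str(r["genome_id"]),
            genome_length=int(r["length_bp"]),
            molecules_added=float(r["molecules"]),
        )
        for _, r in rows.iterrows()
    ]


def recovery_ratios(
    depths: pd.DataFrame,
    assignments: pd.DataFrame,
    standards: list[StandardSpec],
) -> RecoveryRatio:
    """Both recovery flavours on the same library, in one object."""
    cov = coverage_recovery_ratio(depths, standards)
    rd = read_recovery_ratio(assignments, standards)
    return RecoveryRatio(
        r_cov=cov.r_cov,
        r_read=rd.r_read,
        per_standard={
            f"{k}:cov": v for k, v in cov.per_standard.items()
        }
        | {f"{k}:read": v for k, v in rd.per_standard.items()},
        usable=cov.usable and rd.usable,
    )
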
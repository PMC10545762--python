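"""File I/O: FASTA, TSV tables with declared schemas, and output headers.

All tabular interchange is tab-separated with a single header line; lines
beginning with ``#`` are comments. Every file written by the pipeline starts
with a comment header carrying the tool version, a hash of the run
configuration, and the random seed, so outputs are traceable to their run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__

logger = logging.getLogger("spikequant")

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_table",
    "write_table",
    "write_json",
    "output_header",
    "config_hash",
]


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a nucleotide FASTA file into a list of ``SeqRecord``.

    Tolerates multi-line records, mixed case and CRLF endings. An empty file
    yields an empty list with a warning. A file whose first non-blank line is
    not a header is rejected with the offending line number.
    """
    path = Path(path)
    with open(path, "r", newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ValueError(
                    f"{path}: malformed FASTA, line {lineno} is not a header: "
                    f"{stripped[:40]!r}"
                )
            break
        else:
            warnings.warn(f"{path}: empty FASTA file", stacklevel=2)
            return []
    return list(SeqIO.parse(str(path), "fasta"))


def write_fasta(records: Iterable[SeqRecord | tuple[str, str]], path: str | Path) -> None:
    """Write records to FASTA. Accepts ``SeqRecord`` or ``(id, sequence)`` pairs."""
    out = []
    for rec in records:
        if isinstance(rec, SeqRecord):
            out.append(rec)
        else:
            rec_id, seq = rec
            out.append(SeqRecord(Seq(seq), id=rec_id, description=""))
    SeqIO.write(out, str(path), "fasta")


def config_hash(config: Mapping) -> str:
    """Short stable hash of a configuration mapping (order-insensitive)."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def output_header(seed: int | None = None, config: Mapping | None = None) -> str:
    """Comment header stamped onto every output file."""
    chash = config_hash(config) if config is not None else "none"
    return f"# spikequant v{__version__} config={chash} seed={seed}\n"


def write_json(obj: Mapping, path: str | Path, seed: int | None = None,
               config: Mapping | None = None) -> None:
    """Write a JSON summary with provenance keys (version, config hash, seed)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "_tool": f"spikequant v{__version__}",
        "_config": config_hash(config) if config is not None else "none",
        "_seed": seed,
        **obj,
    }
    path.write_text(json.dumps(payload, indent=2, default=float) + "\n")


def read_table(
    path: str | Path,
    required: Sequence[str] = (),
    dtypes: Mapping[str, type] | None = None,
) -> pd.DataFrame:
    """Read a TSV table, checking required columns and coercing types.

    Unknown columns are preserved. A missing required column is rejected by
    name; a value that cannot be coerced is rejected with its row number
    (1-based, excluding header and comment lines).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    if dtypes:
        for col, typ in dtypes.items():
            if col not in df.columns:
                continue
            try:
                df[col] = df[col].astype(typ)
            except (ValueError, TypeError):
                coerced = pd.to_numeric(df[col], errors="coerce")
                bad = coerced.isna() & df[col].notna()
                row = int(bad.idxmax()) + 1 if bad.any() else -1
                raise ValueError(
                    f"{path}: column '{col}' row {row}: cannot coerce "
                    f"{df[col][bad].iloc[0]!r} to {typ.__name__}"
                ) from None
    return df


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config: Mapping | None = None,
) -> None:
    """Write a TSV table prefixed with the standard provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(output_header(seed=seed, config=config))
        df.to_csv(fh, sep="\t", index=False)
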
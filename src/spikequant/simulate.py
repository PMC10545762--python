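"""Synthetic spiked-metagenome communities with full ground truth.

The generator emulates the sampled system behind internal-standard
quantitative metagenomics: a multi-genome community at known cell
concentrations (cells L^-1), a measured volume of water filtered, and a small
number of foreign internal-standard genomes added at known molecule counts
before extraction. Sequencing is modelled as uniform read sampling: a source
molecule contributes reads in proportion to (molecules x genome length), and
read start positions are uniform along the source. Gene-level read assignment
uses the midpoint rule — a read counts toward a gene exactly when the read's
midpoint lies inside the annotated gene interval — so the expected number of
reads assigned to a gene of length ``l`` on a genome of length ``L`` with
read length ``rl`` is exactly ``n_genome * l / (L - rl + 1)``: proportional
to plain gene length, which makes length-normalised downstream estimators
unbiased by construction.

Taxonomy-annotation error is configurable: with probability
``annotation_error_rate`` a read's label in exactly one of the two taxonomy
systems (chosen uniformly) is replaced by a different taxon, which is what a
dual-taxonomy consensus filter is designed to reject.

Reads never span reference ends (no circularity) and are always full length,
so the depth table conserves total bases exactly: ``sum(total_bases_mapped)
= total_reads x read_length``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .standards import StandardSpec
from . import io as sqio

__all__ = [
    "GENE_ROLES",
    "GeneLocus",
    "MockGenome",
    "GeneDesign",
    "GenomeDesign",
    "StandardDesign",
    "CommunityDesign",
    "CommunityTruth",
    "build_community",
    "simulate_sample",
    "subsample_assignments",
    "default_design",
    "write_community",
    "write_sample",
    "ASSIGNMENT_COLUMNS",
    "DEPTH_COLUMNS",
]

#: Controlled vocabulary for gene roles. ``marker`` is the single-copy
#: recA analogue; the three nitrogen roles mirror narB / focA / amt.
GENE_ROLES = (
    "marker",
    "nitrate_reductase",
    "nitrite_transporter",
    "ammonium_transporter",
    "other",
)

ASSIGNMENT_COLUMNS = [
    "read_id",
    "subject_gene_id",
    "subject_genome_id",
    "role",
    "taxon_a",
    "taxon_b",
    "subject_gene_length",
]

DEPTH_COLUMNS = ["reference_id", "reference_length_bp", "total_bases_mapped"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class GeneLocus:
    """One annotated gene on a mock genome (1-based, inclusive coordinates)."""

    gene_id: str
    role: str
    start: int
    end: int
    copy_index: int = 1

    def __post_init__(self) -> None:
        if self.role not in GENE_ROLES:
            raise ValueError(f"unknown gene role {self.role!r}")
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: end < start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class MockGenome:
    """A community member: sequence, dual taxonomy labels, gene annotation."""

    genome_id: str
    taxon_label_a: str
    taxon_label_b: str
    length: int
    genes: tuple[GeneLocus, ...]
    sequence: str = ""

    def __post_init__(self) -> None:
        markers = [g for g in self.genes if g.role == "marker"]
        if len(markers) != 1:
            raise ValueError(
                f"genome {self.genome_id}: expected exactly one marker gene, "
                f"found {len(markers)}"
            )
        ordered = sorted(self.genes, key=lambda g: g.start)
        for prev, cur in zip(ordered, ordered[1:]):
            if cur.start <= prev.end:
                raise ValueError(
                    f"genome {self.genome_id}: genes {prev.gene_id} and "
                    f"{cur.gene_id} overlap"
                )
        for g in self.genes:
            if g.start < 1 or g.end > self.length:
                raise ValueError(
                    f"genome {self.genome_id}: gene {g.gene_id} outside [1, length]"
                )

    @property
    def marker(self) -> GeneLocus:
        return next(g for g in self.genes if g.role == "marker")

    def copy_count(self, role: str) -> int:
        return sum(1 for g in self.genes if g.role == role)


@dataclass(frozen=True)
class GeneDesign:
    """Requested gene complement entry: ``copies`` loci of ``length`` bp."""

    role: str
    length: int
    copies: int = 1


@dataclass(frozen=True)
class GenomeDesign:
    genome_id: str
    taxon_a: str
    taxon_b: str
    length: int
    cells_per_liter: float
    marker_length: int = 1000
    genes: tuple[GeneDesign, ...] = ()


@dataclass(frozen=True)
class StandardDesign:
    genome_id: str
    length: int
    molecules_added: float


@dataclass(frozen=True)
class CommunityDesign:
    """Full specification of a spiked sample; the seed fixes every draw."""

    genomes: tuple[GenomeDesign, ...]
    standards: tuple[StandardDesign, ...]
    volume_filtered: float = 2.0
    read_length: int = 150
    total_reads: int = 300_000
    annotation_error_rate: float = 0.0
    edge_margin: int = 200
    seed: int = 0


@dataclass
class CommunityTruth:
    """Ground truth for a built community, keyed by genome id."""

    cells_per_liter: dict[str, float]
    molecules_in_sample: dict[str, float]
    molecules_added: dict[str, float]
    gene_copies: dict[str, dict[str, int]]
    marker_lengths: dict[str, int]
    taxon_a: dict[str, str]
    taxon_b: dict[str, str]
    lengths: dict[str, int]
    volume_filtered: float
    read_length: int
    total_reads: int
    annotation_error_rate: float
    seed: int


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _place_genes(
    rng: np.random.Generator, design: GenomeDesign, margin: int
) -> tuple[GeneLocus, ...]:
    """Place non-overlapping gene loci with an edge margin.

    The margin keeps every gene at least ``margin`` bp from both genome ends
    so the feasible read-midpoint range covers each gene completely (exact
    midpoint-rule expectations). Random gaps between genes come from a
    multinomial split of the leftover length.
    """
    wanted: list[tuple[str, int]] = [("marker", design.marker_length)]
    for gd in design.genes:
        if gd.role == "marker":
            raise ValueError(
                f"genome {design.genome_id}: marker is implicit, do not list it"
            )
        wanted.extend((gd.role, gd.length) for _ in range(gd.copies))
    total = sum(length for _, length in wanted)
    slack = design.length - 2 * margin - total
    if slack < 0:
        raise ValueError(
            f"genome {design.genome_id}: requested genes ({total} bp plus "
            f"2x{margin} bp margins) exceed genome length {design.length} bp"
        )
    order = rng.permutation(len(wanted))
    n_gaps = len(wanted) + 1
    gaps = rng.multinomial(slack, np.full(n_gaps, 1.0 / n_gaps))
    loci: list[GeneLocus] = []
    copy_counter: dict[str, int] = {}
    pos = margin + 1
    for slot, gidx in enumerate(order):
        role, length = wanted[gidx]
        pos += int(gaps[slot])
        copy_counter[role] = copy_counter.get(role, 0) + 1
        loci.append(
            GeneLocus(
                gene_id=f"{design.genome_id}:{role}_{copy_counter[role]}",
                role=role,
                start=pos,
                end=pos + length - 1,
                copy_index=copy_counter[role],
            )
        )
        pos += length
    return tuple(loci)


def build_community(
    design: CommunityDesign,
) -> tuple[list[MockGenome], list[StandardSpec], CommunityTruth]:
    """Materialise a community design into genomes, standards and truth.

    Sequences are uniform random nucleotides (assignment tables, not
    alignments, are the pipeline's contract). Standards carry their known
    molecule counts; community members' molecules in the sample are
    cells_per_liter x volume_filtered, one genome copy per cell.
    """
    if not design.genomes and not design.standards:
        raise ValueError("community design lists no genomes and no standards")
    rng = np.random.default_rng(design.seed)
    genomes: list[MockGenome] = []
    for gd in design.genomes:
        loci = _place_genes(rng, gd, design.edge_margin)
        genomes.append(
            MockGenome(
                genome_id=gd.genome_id,
                taxon_label_a=gd.taxon_a,
                taxon_label_b=gd.taxon_b,
                length=gd.length,
                genes=loci,
                sequence=_random_sequence(rng, gd.length),
            )
        )
    standards: list[StandardSpec] = []
    for sd in design.standards:
        standards.append(
            StandardSpec(
                genome_id=sd.genome_id,
                genome_length=sd.length,
                molecules_added=sd.molecules_added,
                sequence=_random_sequence(rng, sd.length),
            )
        )
    truth = CommunityTruth(
        cells_per_liter={gd.genome_id: gd.cells_per_liter for gd in design.genomes},
        molecules_in_sample={
            gd.genome_id: gd.cells_per_liter * design.volume_filtered
            for gd in design.genomes
        },
        molecules_added={sd.genome_id: sd.molecules_added for sd in design.standards},
        gene_copies={
            g.genome_id: {role: g.copy_count(role) for role in GENE_ROLES if role != "other"}
            for g in genomes
        },
        marker_lengths={g.genome_id: g.marker.length for g in genomes},
        taxon_a={g.genome_id: g.taxon_label_a for g in genomes}
        | {s.genome_id: s.genome_id for s in standards},
        taxon_b={g.genome_id: g.taxon_label_b for g in genomes}
        | {s.genome_id: s.genome_id for s in standards},
        lengths={g.genome_id: g.length for g in genomes}
        | {s.genome_id: s.genome_length for s in standards},
        volume_filtered=design.volume_filtered,
        read_length=design.read_length,
        total_reads=design.total_reads,
        annotation_error_rate=design.annotation_error_rate,
        seed=design.seed,
    )
    return genomes, standards, truth


def _corrupt_labels(
    rng: np.random.Generator,
    taxon_a: np.ndarray,
    taxon_b: np.ndarray,
    error_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Corrupt exactly one taxonomy system per selected read.

    The wrong label is the cyclically-next distinct label in that system's
    pool (deterministic given the draw); with a single-label pool a sentinel
    suffix is used so the corrupted label still disagrees.
    """
    n = len(taxon_a)
    hit = rng.random(n) < error_rate
    which_b = rng.random(n) < 0.5  # True: corrupt system B, else system A
    for labels, mask in ((taxon_a, hit & ~which_b), (taxon_b, hit & which_b)):
        if not mask.any():
            continue
        pool = np.unique(labels)
        if len(pool) == 1:
            labels[mask] = pool[0] + "__mis"
            continue
        idx = np.searchsorted(pool, labels[mask])
        labels[mask] = pool[(idx + 1) % len(pool)]
    return taxon_a, taxon_b


def simulate_sample(
    genomes: Sequence[MockGenome],
    standards: Sequence[StandardSpec],
    truth: CommunityTruth,
    with_sequences: bool = True,
) -> tuple[list, pd.DataFrame, pd.DataFrame]:
    """Draw a sequencing library and derive assignment and depth tables.

    Returns ``(reads, assignments, depths)``. ``reads`` is a list of
    Biopython ``SeqRecord`` (empty when ``with_sequences`` is False — the
    tables alone carry everything downstream estimators consume).
    ``assignments`` has one row per read (columns ``ASSIGNMENT_COLUMNS``);
    reads whose midpoint falls in no annotated gene carry role ``other`` and
    gene id ``intergenic``. ``depths`` has one row per reference with total
    bases mapped.
    """
    if truth.total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if not genomes and not standards:
        raise ValueError("cannot simulate: no community genomes and no standards")
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 1]))
    rl = truth.read_length

    sources: list[tuple[str, int, str, object]] = []
    for g in genomes:
        sources.append((g.genome_id, g.length, g.sequence, g))
    for s in standards:
        sources.append((s.genome_id, s.genome_length, s.sequence, None))
    weights = np.array(
        [
            (
                truth.molecules_in_sample.get(sid, 0.0)
                + truth.molecules_added.get(sid, 0.0)
            )
            * length
            for sid, length, _, _ in sources
        ],
        dtype=float,
    )
    if weights.sum() <= 0:
        raise ValueError("no source has positive molecules x length weight")
    for _, length, _, _ in sources:
        if length < rl:
            raise ValueError("read length exceeds a reference length")
    counts = rng.multinomial(truth.total_reads, weights / weights.sum())

    frames: list[pd.DataFrame] = []
    reads: list = []
    depth_rows: list[tuple[str, int, int]] = []
    for (sid, length, sequence, genome), n_i in zip(sources, counts):
        depth_rows.append((sid, length, int(n_i) * rl))
        if n_i == 0:
            continue
        starts0 = rng.integers(0, length - rl + 1, size=n_i)  # 0-based
        mid1 = starts0 + rl // 2 + 1  # 1-based midpoint
        gene_id = np.full(n_i, "intergenic", dtype=object)
        role = np.full(n_i, "other", dtype=object)
        gene_len = np.zeros(n_i, dtype=int)
        if genome is not None and genome.genes:
            ordered = sorted(genome.genes, key=lambda g: g.start)
            gstarts = np.array([g.start for g in ordered])
            gends = np.array([g.end for g in ordered])
            gids = np.array([g.gene_id for g in ordered], dtype=object)
            groles = np.array([g.role for g in ordered], dtype=object)
            glens = gends - gstarts + 1
            idx = np.searchsorted(gstarts, mid1, side="right") - 1
            inside = (idx >= 0) & (mid1 <= gends[idx.clip(0)])
            hit_idx = idx[inside]
            gene_id[inside] = gids[hit_idx]
            role[inside] = groles[hit_idx]
            gene_len[inside] = glens[hit_idx]
            intergenic_len = length - int(glens.sum())
        else:
            intergenic_len = length
        gene_len[gene_len == 0] = intergenic_len
        read_ids = np.array([f"{sid}_r{k}" for k in range(n_i)], dtype=object)
        frames.append(
            pd.DataFrame(
                {
                    "read_id": read_ids,
                    "subject_gene_id": gene_id,
                    "subject_genome_id": sid,
                    "role": role,
                    "taxon_a": truth.taxon_a.get(sid, sid),
                    "taxon_b": truth.taxon_b.get(sid, sid),
                    "subject_gene_length": gene_len,
                }
            )
        )
        if with_sequences:
            from Bio.Seq import Seq
            from Bio.SeqRecord import SeqRecord

            arr = np.frombuffer(sequence.encode(), dtype="S1")
            window = arr[starts0[:, None] + np.arange(rl)[None, :]]
            for rid, row in zip(read_ids, window):
                reads.append(SeqRecord(Seq(row.tobytes().decode()), id=rid, description=""))

    assignments = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=ASSIGNMENT_COLUMNS)
    )
    if truth.annotation_error_rate > 0 and len(assignments):
        ta = assignments["taxon_a"].to_numpy(dtype=object, copy=True)
        tb = assignments["taxon_b"].to_numpy(dtype=object, copy=True)
        ta, tb = _corrupt_labels(rng, ta, tb, truth.annotation_error_rate)
        assignments["taxon_a"] = ta
        assignments["taxon_b"] = tb
    depths = pd.DataFrame(depth_rows, columns=DEPTH_COLUMNS)
    return reads, assignments[ASSIGNMENT_COLUMNS], depths


def subsample_assignments(
    assignments: pd.DataFrame,
    depths: pd.DataFrame,
    read_length: int,
    fraction: float,
    rng: np.random.Generator | int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Randomly retain a fraction of reads and rebuild the depth table.

    Emulates sequencing the same extract to a shallower depth; used to check
    that abundance estimates are invariant to library depth. Reference
    lengths are carried over from the full-depth ``depths`` table.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    keep = rng.random(len(assignments)) < fraction
    sub = assignments.loc[keep].reset_index(drop=True)
    counts = sub.groupby("subject_genome_id", sort=False).size()
    sub_depths = depths.copy()
    sub_depths["total_bases_mapped"] = [
        int(counts.get(ref, 0)) * read_length
        for ref in sub_depths["reference_id"]
    ]
    return sub, sub_depths


def default_design(
    seed: int = 0,
    total_reads: int = 300_000,
    annotation_error_rate: float = 0.0,
) -> CommunityDesign:
    """Study-condition community: a subarctic HNLC surface sample in miniature.

    Five community genomes and three spiked standards. The focal genus
    ("Synechococcus" in both taxonomy systems) totals 5 x 10^7 cells L^-1 —
    the deep-chlorophyll-maximum peak density scale — dominated by two
    populations (clade IV / clade I analogues) that both carry two ammonium
    transporters and no nitrate-assimilation genes, plus a minor
    nitrate/nitrite-capable ecotype. Two non-focal background genomes carry
    the full nitrogen gene set so the consensus filter has something to
    reject. Genome sizes are scaled down (50 kb community members, 20 kb
    standards) to keep simulation fast; all estimators are scale-free in
    genome length.
    """
    nitrogen = lambda narb, foca, amt: tuple(
        GeneDesign(role, length, copies)
        for role, length, copies in (
            ("nitrate_reductase", 2100, narb),
            ("nitrite_transporter", 850, foca),
            ("ammonium_transporter", 1200, amt),
        )
        if copies > 0
    )
    genomes = (
        GenomeDesign(
            "syn_sp1", "Synechococcus", "Synechococcus", 50_000,
            cells_per_liter=2.8e7, genes=nitrogen(0, 0, 2),
        ),
        GenomeDesign(
            "syn_sp2", "Synechococcus", "Synechococcus", 50_000,
            cells_per_liter=1.9e7, genes=nitrogen(0, 0, 2),
        ),
        GenomeDesign(
            "syn_eco", "Synechococcus", "Synechococcus", 50_000,
            cells_per_liter=0.3e7, genes=nitrogen(1, 1, 2),
        ),
        GenomeDesign(
            "pelagibacter", "Pelagibacter", "Pelagibacteraceae", 50_000,
            cells_per_liter=1.0e8, genes=nitrogen(1, 1, 1),
        ),
        GenomeDesign(
            "flavobacter", "Flavobacterium", "Flavobacteriaceae", 50_000,
            cells_per_liter=5.0e7, genes=nitrogen(1, 1, 1),
        ),
    )
    standards = (
        StandardDesign("std_thermus", 20_000, 2.0e7),
        StandardDesign("std_deinococcus", 20_000, 2.5e7),
        StandardDesign("std_halophile", 20_000, 1.5e7),
    )
    return CommunityDesign(
        genomes=genomes,
        standards=standards,
        volume_filtered=2.0,
        read_length=150,
        total_reads=total_reads,
        annotation_error_rate=annotation_error_rate,
        seed=seed,
    )


def truth_table(truth: CommunityTruth) -> pd.DataFrame:
    """Ground truth as a flat table (one row per reference)."""
    rows = []
    for gid in truth.lengths:
        is_standard = gid in truth.molecules_added
        copies = truth.gene_copies.get(gid, {})
        rows.append(
            {
                "genome_id": gid,
                "kind": "standard" if is_standard else "community",
                "taxon_a": truth.taxon_a[gid],
                "taxon_b": truth.taxon_b[gid],
                "length_bp": truth.lengths[gid],
                "cells_per_liter": truth.cells_per_liter.get(gid, 0.0),
                "molecules": truth.molecules_added.get(
                    gid, truth.molecules_in_sample.get(gid, 0.0)
                ),
                "marker_copies": copies.get("marker", 0),
                "marker_length_bp": truth.marker_lengths.get(gid, 0),
                "nitrate_reductase_copies": copies.get("nitrate_reductase", 0),
                "nitrite_transporter_copies": copies.get("nitrite_transporter", 0),
                "ammonium_transporter_copies": copies.get("ammonium_transporter", 0),
            }
        )
    return pd.DataFrame(rows)


def write_community(
    genomes: Sequence[MockGenome],
    standards: Sequence[StandardSpec],
    truth: CommunityTruth,
    outdir: str | Path,
) -> None:
    """Write genome/standard FASTA and the truth TSV into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sqio.write_fasta(
        [(g.genome_id, g.sequence) for g in genomes], outdir / "genomes.fasta"
    )
    sqio.write_fasta(
        [(s.genome_id, s.sequence) for s in standards], outdir / "standards.fasta"
    )
    sqio.write_table(truth_table(truth), outdir / "truth.tsv", seed=truth.seed)


def write_sample(
    reads: Sequence,
    assignments: pd.DataFrame,
    depths: pd.DataFrame,
    truth: CommunityTruth,
    outdir: str | Path,
) -> None:
    """Write reads FASTA (if any), assignment TSV and depth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if reads:
        sqio.write_fasta(reads, outdir / "reads.fasta")
    sqio.write_table(assignments, outdir / "assignments.tsv", seed=truth.seed)
    sqio.write_table(depths, outdir / "depths.tsv", seed=truth.seed)

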
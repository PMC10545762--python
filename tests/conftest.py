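"""Shared fixtures: simulated communities with known ground truth."""

from __future__ import annotations

from types import SimpleNamespace

import pytest

import spikequant as sq
from spikequant.simulate import CommunityDesign, GeneDesign, GenomeDesign, StandardDesign

FOCAL = "Synechococcus"


def simulate_design(design: CommunityDesign) -> SimpleNamespace:
    genomes, standards, truth = sq.build_community(design)
    reads, assignments, depths = sq.simulate_sample(
        genomes, standards, truth, with_sequences=False
    )
    return SimpleNamespace(
        design=design,
        genomes=genomes,
        standards=standards,
        truth=truth,
        assignments=assignments,
        depths=depths,
    )


def two_mag_design(
    seed: int = 0, total_reads: int = 200_000, error_rate: float = 0.0
) -> CommunityDesign:
    """Two focal populations (the MAG analogues) as the ONLY members of the
    focal taxon, plus one background genome and three standards."""
    return CommunityDesign(
        genomes=(
            GenomeDesign("mag_1", FOCAL, FOCAL, 50_000, cells_per_liter=3.0e7,
                         genes=(GeneDesign("ammonium_transporter", 1200, 2),)),
            GenomeDesign("mag_2", FOCAL, FOCAL, 50_000, cells_per_liter=2.0e7,
                         genes=(GeneDesign("ammonium_transporter", 1200, 2),)),
            GenomeDesign("bg", "Pelagibacter", "Pelagibacteraceae", 50_000,
                         cells_per_liter=8.0e7,
                         genes=(GeneDesign("nitrate_reductase", 2100, 1),)),
        ),
        standards=(
            StandardDesign("std_a", 20_000, 2.0e7),
            StandardDesign("std_b", 20_000, 2.5e7),
            StandardDesign("std_c", 20_000, 1.5e7),
        ),
        volume_filtered=2.0,
        read_length=150,
        total_reads=total_reads,
        annotation_error_rate=error_rate,
        seed=seed,
    )


def carrier_design(
    f: float, k: int, role: str = "nitrate_reductase",
    seed: int = 0, total_reads: int = 200_000, gene_length: int = 1500,
) -> CommunityDesign:
    """Focal population in which a fraction ``f`` of genomes carries ``k``
    copies of ``role`` (expected copies per genome equivalent = f x k)."""
    total_cells = 5.0e7
    genomes = []
    if f > 0:
        genomes.append(
            GenomeDesign("carrier", FOCAL, FOCAL, 50_000,
                         cells_per_liter=f * total_cells,
                         genes=(GeneDesign(role, gene_length, k),))
        )
    if f < 1:
        genomes.append(
            GenomeDesign("noncarrier", FOCAL, FOCAL, 50_000,
                         cells_per_liter=(1 - f) * total_cells)
        )
    return CommunityDesign(
        genomes=tuple(genomes),
        standards=(StandardDesign("std_a", 20_000, 2.0e7),),
        total_reads=total_reads,
        seed=seed,
    )


@pytest.fixture(scope="session")
def community() -> SimpleNamespace:
    """The default study-condition community at 3x10^5 reads."""
    return simulate_design(sq.default_design(seed=11, total_reads=300_000))


@pytest.fixture(scope="session")
def two_mag() -> SimpleNamespace:
    return simulate_design(two_mag_design(seed=7, total_reads=200_000))
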
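"""Seeded generation of every input the pipeline consumes.

Re-exports the genome and expression simulators and provides
:func:`make_fixture_suite`, which writes a complete small on-disk fixture set
(genomes, annotations, count matrices, labels, truth tables) deterministically
from one seed.
"""

from __future__ import annotations

from pathlib import Path

from .matrix_io import write_matrix
from .sim_counts import (  # noqa: F401
    DEFAULT_STAGES,
    ExpressionSimConfig,
    ExpressionTruth,
    simulate_counts,
)
from .sim_genomes import (  # noqa: F401
    GenomeSimConfig,
    SimulatedGenomes,
    generate_genomes,
    write_genome_fixture,
)


def make_fixture_suite(out_dir, seed: int = 0) -> dict:
    """Write genomes + annotations + count matrices + truth tables.

    Regeneration with the same seed is byte-identical. Returns the path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sim = generate_genomes(GenomeSimConfig(seed=seed))
    paths = write_genome_fixture(sim, out / "genomes")

    matrices, truth = simulate_counts(ExpressionSimConfig(seed=seed))
    for species, matrix in matrices.items():
        write_matrix(matrix, out / f"counts_{species}", fmt="mtx")
        paths[f"counts_{species}"] = out / f"counts_{species}"
    truth.markers.to_csv(out / "expression_markers.tsv", sep="\t", index=False)
    paths["expression_markers"] = out / "expression_markers.tsv"
    with open(out / "stage_labels.tsv", "w") as fh:
        fh.write("cell_id\tstage\n")
        for cid, stage in truth.stage_of_cell.items():
            fh.write(f"{cid}\t{stage}\n")
    paths["stage_labels"] = out / "stage_labels.tsv"
    return paths
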
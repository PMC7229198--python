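"""Toy two-species genome simulator with planted orthology truth.

Species B carries a mutated copy of every species-A exon (orthologs), with a
fixed per-exon substitution count of ``round(divergence * exon_length)`` at
distinct random positions — so a divergence of 0.02 yields identity 0.98 for
every planted ortholog, exactly, rather than on average. Decoy exons are
exact duplicate copies planted in intergenic space (alternating between the
two genomes), which the second-hit filter must remove. A configurable number
of genes receive one intron lengthened in species B by more than the
intron-difference threshold, which the gene-level intron filter must remove.

The truth table records, per annotated species-A exon, the category and the
reason code the filter chain is expected to assign. Output is byte-identical
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ExonRecord

_BASES = np.array(list("ACGT"))


@dataclass
class GenomeSimConfig:
    n_genes: int = 50
    exons_per_gene: tuple = (2, 4)        # inclusive range
    exon_len: tuple = (120, 180)          # bp, inclusive range
    intron_len: tuple = (200, 800)        # bp, inclusive range
    intergenic_len: tuple = (300, 600)    # bp between genes
    ortholog_divergence: float = 0.02     # substitutions per base, applied exactly
    intron_jitter: int = 100              # max +/- bp change of B introns
    n_decoy_duplicates: int = 10
    n_intron_shift_genes: int = 5
    intron_shift_bp: int = 12_000         # added to one B intron of shifted genes
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.ortholog_divergence <= 1.0:
            raise ValueError("divergence must be in [0, 1]")
        for name in ("exons_per_gene", "exon_len", "intron_len", "intergenic_len"):
            lo, hi = getattr(self, name)
            if lo <= 0 or lo > hi:
                raise ValueError(f"infeasible range for {name}: ({lo}, {hi})")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_decoy_duplicates + self.n_intron_shift_genes > self.n_genes:
            raise ValueError(
                "decoy and intron-shift gene sets must fit disjointly in n_genes"
            )
        if self.intron_jitter >= self.intron_shift_bp:
            raise ValueError("intron_jitter must be well below intron_shift_bp")


@dataclass
class SimulatedGenomes:
    genome_a: dict
    genome_b: dict
    exons_a: list
    exons_b: list
    truth: pd.DataFrame
    config: GenomeSimConfig = field(repr=False, default=None)


def _random_seq(rng, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _mutate(rng, seq: str, n_sub: int) -> str:
    """Substitute exactly n_sub distinct positions, each to a different base."""
    if n_sub == 0:
        return seq
    arr = np.array(list(seq))
    pos = rng.choice(len(seq), size=min(n_sub, len(seq)), replace=False)
    for p in pos:
        options = [b for b in "ACGT" if b != arr[p]]
        arr[p] = options[rng.integers(0, 3)]
    return "".join(arr)


def generate_genomes(config: GenomeSimConfig) -> SimulatedGenomes:
    rng = np.random.default_rng(config.seed)
    lo_e, hi_e = config.exons_per_gene

    # Per-gene structure, shared between the species.
    genes = []
    for g in range(config.n_genes):
        n_ex = int(rng.integers(lo_e, hi_e + 1))
        exon_seqs = [_random_seq(rng, int(rng.integers(*config.exon_len, endpoint=True)))
                     for _ in range(n_ex)]
        introns_a = [int(rng.integers(*config.intron_len, endpoint=True))
                     for _ in range(n_ex - 1)]
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            {"gene_id": f"G{g:03d}", "exon_seqs": exon_seqs,
             "introns_a": introns_a, "strand": strand}
        )

    # Disjoint gene sets for intron shifts (need >= 2 exons) and decoy parents.
    multi = [i for i, g in enumerate(genes) if len(g["exon_seqs"]) >= 2]
    if len(multi) < config.n_intron_shift_genes:
        raise ValueError("not enough multi-exon genes for the requested intron shifts")
    shift_gene_idx = set(multi[: config.n_intron_shift_genes])
    decoy_pool = [i for i in range(config.n_genes) if i not in shift_gene_idx]
    decoy_parents = []  # (gene_idx, exon_idx, target_species)
    for d in range(config.n_decoy_duplicates):
        gi = decoy_pool[d % len(decoy_pool)]
        ei = int(rng.integers(0, len(genes[gi]["exon_seqs"])))
        decoy_parents.append((gi, ei, "A" if d % 2 == 0 else "B"))
    decoy_of = {}
    for gi, ei, sp in decoy_parents:
        decoy_of.setdefault((gi, ei), sp)

    # Species-B exon sequences and intron lengths.
    shifted_intron = {}
    for gi in shift_gene_idx:
        n_intr = len(genes[gi]["introns_a"])
        shifted_intron[gi] = int(rng.integers(0, n_intr))
    for g_idx, gene in enumerate(genes):
        gene["exon_seqs_b"] = []
        for seq in gene["exon_seqs"]:
            n_sub = round(config.ortholog_divergence * len(seq))
            gene["exon_seqs_b"].append(_mutate(rng, seq, n_sub))
        introns_b = []
        for j, ia in enumerate(gene["introns_a"]):
            jitter = int(rng.integers(-config.intron_jitter, config.intron_jitter + 1))
            ib = max(20, ia + jitter)
            if shifted_intron.get(g_idx) == j:
                ib += config.intron_shift_bp
            introns_b.append(ib)
        gene["introns_b"] = introns_b

    # Assemble the two chromosomes.
    def assemble(species: str) -> tuple:
        chrom = f"chr{species}1"
        parts, exons, pos = [], [], 0
        seq_key = "exon_seqs" if species == "A" else "exon_seqs_b"
        intr_key = "introns_a" if species == "A" else "introns_b"
        for g_idx, gene in enumerate(genes):
            gap = int(rng.integers(*config.intergenic_len, endpoint=True))
            parts.append(_random_seq(rng, gap))
            pos += gap
            for e_idx, eseq in enumerate(gene[seq_key]):
                exons.append(
                    ExonRecord(
                        exon_id=f"{gene['gene_id']}e{e_idx}{'' if species == 'A' else 'b'}",
                        gene_id=gene["gene_id"],
                        chrom=chrom, start=pos, end=pos + len(eseq),
                        strand=gene["strand"], species=species,
                    )
                )
                parts.append(eseq)
                pos += len(eseq)
                if e_idx < len(gene[seq_key]) - 1:
                    ilen = gene[intr_key][e_idx]
                    parts.append(_random_seq(rng, ilen))
                    pos += ilen
        # Decoy blocks at the chromosome tail, spaced by intergenic sequence.
        for gi, ei, sp in decoy_parents:
            if sp != species:
                continue
            gap = int(rng.integers(*config.intergenic_len, endpoint=True))
            parts.append(_random_seq(rng, gap))
            pos += gap
            dseq = genes[gi]["exon_seqs"][ei]
            parts.append(dseq)
            pos += len(dseq)
        parts.append(_random_seq(rng, int(rng.integers(*config.intergenic_len, endpoint=True))))
        return {chrom: "".join(parts)}, exons

    genome_a, exons_a = assemble("A")
    genome_b, exons_b = assemble("B")

    # Truth table for species-A exons.
    rows = []
    for g_idx, gene in enumerate(genes):
        n_ex = len(gene["exon_seqs"])
        flanks = set()
        if g_idx in shifted_intron:
            j = shifted_intron[g_idx]
            flanks = {j, j + 1}  # both metaexons adjacent to the shifted intron
        for e_idx, seq in enumerate(gene["exon_seqs"]):
            n_sub = round(config.ortholog_divergence * len(seq))
            identity = 1.0 - n_sub / len(seq)
            if identity < 0.92:
                reason = "low_identity"
            elif (g_idx, e_idx) in decoy_of:
                reason = "second_hit"
            elif e_idx in flanks:
                reason = "intron_diff"
            else:
                reason = ""
            rows.append(
                {
                    "exon_id": f"{gene['gene_id']}e{e_idx}",
                    "gene_id": gene["gene_id"],
                    "category": (
                        "decoy_parent" if (g_idx, e_idx) in decoy_of
                        else "intron_shift_flank" if e_idx in flanks
                        else "clean"
                    ),
                    "planted_identity": identity,
                    "expected_retained": reason == "",
                    "expected_reason": reason,
                }
            )
    truth = pd.DataFrame(rows)
    return SimulatedGenomes(genome_a, genome_b, exons_a, exons_b, truth, config)


def write_genome_fixture(sim: SimulatedGenomes, out_dir) -> dict:
    """Write FASTA + GTF per species and the truth table; deterministic bytes."""
    from .gtf import write_exons_gtf, write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta_a": out / "speciesA.fa", "fasta_b": out / "speciesB.fa",
        "gtf_a": out / "speciesA.gtf", "gtf_b": out / "speciesB.gtf",
        "truth": out / "genome_truth.tsv",
    }
    write_fasta(sim.genome_a, paths["fasta_a"])
    write_fasta(sim.genome_b, paths["fasta_b"])
    write_exons_gtf(sim.exons_a, paths["gtf_a"])
    write_exons_gtf(sim.exons_b, paths["gtf_b"])
    sim.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
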
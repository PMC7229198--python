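"""A small k-mer-seeded, ungapped exon-to-genome aligner.

Sized for toy genomes (tens to hundreds of kilobases): every exact k-mer shared
between a query exon and the genome anchors a full-length ungapped alignment of
the exon at that diagonal, and identity is counted as matching bases over
aligned columns. Gaps are not modeled at this scale; external PSL hit tables
(e.g. from BLAT) can be ingested instead via :func:`orthostage.gtf.read_psl`.
"""

from __future__ import annotations

import warnings
from collections import defaultdict

import numpy as np

from .types import AlignmentHit

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def build_kmer_index(genome: dict, k: int) -> dict:
    """Map every k-mer of every chromosome to its (chrom, position) list."""
    index: dict = defaultdict(list)
    for chrom, seq in genome.items():
        for pos in range(len(seq) - k + 1):
            index[seq[pos : pos + k]].append((chrom, pos))
    return index


def _genome_arrays(genome: dict) -> dict:
    return {c: np.frombuffer(s.encode("ascii"), dtype=np.uint8) for c, s in genome.items()}


def rank_hits(hits: list) -> list:
    """Order hits best-first and assign ranks.

    Sort key: identity descending, then aligned length descending, then
    (chrom, leftmost target start) — a total, deterministic order.
    """
    ordered = sorted(
        hits,
        key=lambda h: (-h.identity, -h.aligned_length, h.target_chrom, h.target_start, h.target_strand),
    )
    return [
        AlignmentHit(
            h.query_exon_id, h.target_species, h.target_chrom, h.target_start,
            h.target_end, h.target_strand, h.identity, h.aligned_length, rank=i + 1,
        )
        for i, h in enumerate(ordered)
    ]


def compute_exon_hits(
    exon_sequences: dict,
    target_genome: dict,
    target_species: str,
    min_report_identity: float = 0.5,
    k: int = 11,
) -> dict:
    """Align every exon sequence against a genome; return hits per exon.

    Parameters
    ----------
    exon_sequences
        Mapping exon_id -> sequence (the exon in its transcribed orientation).
    target_genome
        Mapping chromosome -> sequence.
    target_species
        Label recorded on each hit.
    min_report_identity
        Hits below this identity are not reported.
    k
        Seed length. An exon shorter than ``k`` gets zero hits and a warning.

    Returns
    -------
    dict mapping exon_id -> list of :class:`AlignmentHit`, rank-ordered
    (rank 1 = best). Exons with no hit map to an empty list.
    """
    if not target_genome or all(len(s) == 0 for s in target_genome.values()):
        raise ValueError("target genome is empty")
    if not exon_sequences:
        raise ValueError("no exon sequences supplied")

    index = build_kmer_index(target_genome, k)
    arrays = _genome_arrays(target_genome)
    results: dict = {}

    for exon_id, seq in exon_sequences.items():
        seq = seq.upper()
        if len(seq) < k:
            warnings.warn(
                f"exon {exon_id} (length {len(seq)}) is shorter than seed k={k}; "
                "reported with zero hits",
                stacklevel=2,
            )
            results[exon_id] = []
            continue

        hits = []
        for strand, query in (("+", seq), ("-", reverse_complement(seq))):
            qarr = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
            qlen = len(query)
            # Candidate diagonals: genome offset at which query position 0 aligns.
            anchors = set()
            for i in range(qlen - k + 1):
                for chrom, pos in index.get(query[i : i + k], ()):
                    anchors.add((chrom, pos - i))
            for chrom, g0 in anchors:
                garr = arrays[chrom]
                lo = max(g0, 0)
                hi = min(g0 + qlen, len(garr))
                if hi - lo < k:
                    continue
                qseg = qarr[lo - g0 : hi - g0]
                gseg = garr[lo:hi]
                matches = int((qseg == gseg).sum())
                aligned = hi - lo
                identity = matches / aligned
                if identity >= min_report_identity:
                    hits.append(
                        AlignmentHit(
                            exon_id, target_species, chrom, lo, hi, strand,
                            identity, aligned,
                        )
                    )
        results[exon_id] = rank_hits(hits)
    return results


def extract_exon_sequences(exons, genome: dict) -> dict:
    """Pull each exon's sequence (transcribed orientation) from its genome."""
    out = {}
    for ex in exons:
        seq = genome[ex.chrom][ex.start : ex.end]
        if ex.strand == "-":
            seq = reverse_complement(seq)
        out[ex.exon_id] = seq
    return out
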
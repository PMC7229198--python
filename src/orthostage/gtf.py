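"""Annotation and alignment-table IO: GTF/GFF, FASTA, PSL, BED.

GTF/GFF coordinates (1-based, closed) are converted to the package's internal
0-based half-open convention on read, and back on write.
"""

from __future__ import annotations

from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import rank_hits
from .types import AlignmentHit, ExonRecord


def read_exons_gtf(path, species: str):
    """Read exon features from a GTF/GFF file into ExonRecords."""
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons = []
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("gene_id", [None])[0]
        exon_id = feat.attributes.get("exon_id", [feat.id])[0]
        if gene_id is None:
            raise ValueError(f"exon {exon_id} in {path} lacks a gene_id attribute")
        exons.append(
            ExonRecord(
                exon_id=exon_id, gene_id=gene_id, chrom=feat.seqid,
                start=feat.start - 1, end=feat.end, strand=feat.strand,
                species=species,
            )
        )
    return exons


def write_exons_gtf(exons, path, source: str = "orthostage") -> None:
    with open(path, "w") as fh:
        for ex in sorted(exons, key=lambda e: (e.chrom, e.start, e.end, e.exon_id)):
            attrs = f'gene_id "{ex.gene_id}"; exon_id "{ex.exon_id}";'
            fh.write(
                f"{ex.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                f"{ex.strand}\t.\t{attrs}\n"
            )


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in sorted(genome.items())
    ]
    SeqIO.write(records, str(path), "fasta")


#: Standard 21-column PSL layout (no header lines assumed).
PSL_COLUMNS = [
    "matches", "misMatches", "repMatches", "nCount", "qNumInsert", "qBaseInsert",
    "tNumInsert", "tBaseInsert", "strand", "qName", "qSize", "qStart", "qEnd",
    "tName", "tSize", "tStart", "tEnd", "blockCount", "blockSizes", "qStarts",
    "tStarts",
]


def read_psl(path, target_species: str) -> dict:
    """Ingest a PSL alignment table into ranked per-query hit lists.

    Identity is matches / (matches + misMatches + qNumInsert + tNumInsert),
    so externally produced BLAT output is directly usable.
    """
    frame = pd.read_csv(str(path), sep="\t", names=PSL_COLUMNS, comment="#")
    hits: dict = {}
    for _, row in frame.iterrows():
        denom = row.matches + row.misMatches + row.qNumInsert + row.tNumInsert
        identity = float(row.matches) / denom if denom else 0.0
        hit = AlignmentHit(
            query_exon_id=row.qName,
            target_species=target_species,
            target_chrom=row.tName,
            target_start=int(row.tStart),
            target_end=int(row.tEnd),
            target_strand=str(row.strand)[-1],
            identity=min(identity, 1.0),
            aligned_length=int(row.tEnd) - int(row.tStart),
        )
        hits.setdefault(row.qName, []).append(hit)
    return {q: rank_hits(hs) for q, hs in hits.items()}


def read_bed_intervals(path) -> pd.DataFrame:
    """Read a BED file (>= 4 columns: chrom, start, end, name[, score, strand])."""
    frame = pd.read_csv(
        str(path), sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    return frame


def write_bed_intervals(frame: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    out = frame.copy()
    if "score" not in out:
        out["score"] = 0
    if "strand" not in out:
        out["strand"] = "."
    out[cols].to_csv(str(path), sep="\t", header=False, index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
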
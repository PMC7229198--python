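"""Build the high-confidence orthologous metaexon table between two species.

The filter chain mirrors the cross-species mappability criteria used for
human/macaque expression comparison:

1. identity — the exon's best hit in the other species' genome must reach at
   least 92% sequence identity (inclusive);
2. second hit — no secondary (rank >= 2) hit with identity above 90%
   (exclusive) in either genome, guarding against paralogs and duplications;
3. reciprocity — the exon's best same-species hit must map back to its own
   annotated location (>= 1 bp overlap, same strand, configurable);
4. collapse — overlapping or bookended same-gene exons merge into metaexons;
5. gene-level — metaexons overlapping a second gene, genes annotated on two
   or more chromosomes in either species, and metaexons flanking an intron
   whose length differs by >= 10,000 bp between the species are discarded.

Reason-code precedence when several filters would remove an exon:
low_identity, then second_hit, then no_reciprocal. An exact duplicate copy of
an exon elsewhere in its own genome yields two identity-1.0 self hits; the
second-hit rule is the cause of removal, so it is checked before reciprocity.
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path

import pandas as pd

from .types import (
    INTRON_DIFF,
    LOW_IDENTITY,
    MULTI_CHROM,
    MULTI_GENE,
    NO_RECIPROCAL,
    SECOND_HIT,
    UNANNOTATED,
    FilterReport,
    GenomicInterval,
    Metaexon,
)


def filter_orthologous_exons(
    exons,
    hits_cross: dict,
    hits_self: dict,
    min_identity: float = 0.92,
    second_hit_identity: float = 0.90,
    min_overlap_bp: int = 1,
    report: FilterReport | None = None,
):
    """Apply the identity, second-hit and reciprocal-mapping filters.

    Parameters
    ----------
    exons
        The query species' annotated exons (list of :class:`ExonRecord`).
    hits_cross
        exon_id -> ranked hits of this exon against the *other* species'
        genome.
    hits_self
        exon_id -> ranked hits against the exon's *own* genome. Every exon
        must have an entry (an empty list is allowed; a missing key is an
        input-contract error).
    min_identity
        Best cross-species hit must reach this identity (inclusive).
    second_hit_identity
        Any rank >= 2 hit above this identity (exclusive), in either genome,
        removes the exon.
    min_overlap_bp
        Overlap required between the best self hit and the annotated locus.

    Returns
    -------
    (retained_exons, best_cross_hit, report)
        ``best_cross_hit`` maps retained exon_id -> its rank-1 cross-species
        hit, used downstream to pair metaexon coordinates in species B.
    """
    missing = [ex.exon_id for ex in exons if ex.exon_id not in hits_self]
    if missing:
        raise KeyError(
            f"{len(missing)} exon(s) have no same-species hit list "
            f"(e.g. {missing[0]}); every exon requires one (may be empty)"
        )

    removed: dict = defaultdict(list)
    retained = []
    best_cross = {}
    for ex in exons:
        cross = hits_cross.get(ex.exon_id, [])
        own = hits_self[ex.exon_id]

        if not cross or cross[0].identity < min_identity:
            removed[LOW_IDENTITY].append(ex.exon_id)
            continue

        second = [h for h in cross[1:] if h.identity > second_hit_identity]
        second += [h for h in own[1:] if h.identity > second_hit_identity]
        if second:
            removed[SECOND_HIT].append(ex.exon_id)
            continue

        maps_back = bool(own) and own[0].target_chrom == ex.chrom and (
            own[0].target_strand == ex.strand
            and min(own[0].target_end, ex.end) - max(own[0].target_start, ex.start)
            >= min_overlap_bp
        )
        if not maps_back:
            removed[NO_RECIPROCAL].append(ex.exon_id)
            continue

        retained.append(ex)
        best_cross[ex.exon_id] = cross[0]

    if report is None:
        report = FilterReport()
    report.add_stage("ortholog_filters", len(exons), len(retained), removed)
    return retained, best_cross, report


def merge_intervals(intervals):
    """Merge overlapping or bookended intervals on one chromosome/strand.

    Returns a sorted list of merged :class:`GenomicInterval`.
    """
    if not intervals:
        return []
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.chrom == last.chrom and iv.start <= last.end:
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.strand)
        else:
            merged.append(iv)
    return merged


def collapse_metaexons(retained_exons, best_cross_hit: dict | None = None):
    """Collapse overlapping same-gene exons into metaexons.

    Within each gene, overlapping or bookended exon intervals are merged;
    disjoint intervals yield distinct metaexons. When ``best_cross_hit`` is
    given, each metaexon carries the merged target intervals of its
    constituents' best cross-species hits as its species-B coordinates.
    Output order is deterministic: (chrom, start) within gene, genes sorted.
    """
    by_gene: dict = defaultdict(list)
    for ex in retained_exons:
        by_gene[ex.gene_id].append(ex)

    metaexons = []
    for gene_id in sorted(by_gene):
        exons = sorted(by_gene[gene_id], key=lambda e: (e.chrom, e.start, e.end))
        clusters: list = []
        for ex in exons:
            if (
                clusters
                and ex.chrom == clusters[-1]["chrom"]
                and ex.start <= clusters[-1]["end"]
            ):
                clusters[-1]["end"] = max(clusters[-1]["end"], ex.end)
                clusters[-1]["exons"].append(ex)
            else:
                clusters.append(
                    {"chrom": ex.chrom, "start": ex.start, "end": ex.end, "exons": [ex]}
                )
        for i, cl in enumerate(clusters, start=1):
            members = cl["exons"]
            iv_a = GenomicInterval(cl["chrom"], cl["start"], cl["end"], members[0].strand)
            ivs_b = []
            if best_cross_hit:
                targets = [
                    best_cross_hit[ex.exon_id].interval
                    for ex in members
                    if ex.exon_id in best_cross_hit
                ]
                ivs_b = merge_intervals(targets)
            metaexons.append(
                Metaexon(
                    metaexon_id=f"{gene_id}:ME{i:03d}",
                    gene_id=gene_id,
                    intervals_a=[iv_a],
                    intervals_b=ivs_b,
                    constituent_exons=[ex.exon_id for ex in members],
                )
            )
    return metaexons


def _gene_chrom_map(exons) -> dict:
    out: dict = defaultdict(set)
    for ex in exons:
        out[ex.gene_id].add(ex.chrom)
    return out


def _b_span(me: Metaexon):
    """(chrom, start, end) covering all species-B intervals, or None."""
    if not me.intervals_b:
        return None
    chroms = {iv.chrom for iv in me.intervals_b}
    if len(chroms) > 1:
        return None
    start = min(iv.start for iv in me.intervals_b)
    end = max(iv.end for iv in me.intervals_b)
    return (next(iter(chroms)), start, end)


def apply_gene_level_filters(
    metaexons,
    annotation_exons_a,
    annotation_exons_b=None,
    max_intron_diff: int = 10_000,
    intron_side: str = "either",
    report: FilterReport | None = None,
):
    """Gene-level cleanup of the collapsed metaexon table.

    Removes, in order: (i) metaexons whose species-A interval overlaps an
    annotated exon of a different gene (``multi_gene``); (ii) every metaexon
    of a gene annotated on two or more chromosomes in either species
    (``multi_chrom``), or absent from the species-B annotation
    (``unannotated``); (iii) metaexons flanking an intron whose length
    differs between species by at least ``max_intron_diff`` bp
    (``intron_diff``). Introns are measured between adjacent retained
    metaexons of the same gene, in species A from the merged intervals and in
    species B from the paired coordinates; ``intron_side`` selects whether an
    exon is removed when its upstream, downstream, or either flanking intron
    is discordant. Flagging is simultaneous over the current adjacency
    (single pass, 5'->3').
    """
    if intron_side not in ("either", "upstream", "downstream"):
        raise ValueError(f"bad intron_side {intron_side!r}")
    if report is None:
        report = FilterReport()

    n_input = len(metaexons)
    removed: dict = defaultdict(list)

    # (i) overlap with a second gene's annotated exons, species A.
    by_chrom: dict = defaultdict(list)
    for ex in annotation_exons_a:
        by_chrom[ex.chrom].append(ex)
    survivors = []
    for me in metaexons:
        iv = me.span_a
        foreign = any(
            ex.gene_id != me.gene_id
            and min(ex.end, iv.end) - max(ex.start, iv.start) >= 1
            for ex in by_chrom.get(iv.chrom, ())
        )
        if foreign:
            removed[MULTI_GENE].append(me.metaexon_id)
        else:
            survivors.append(me)

    # (ii) genes on >= 2 chromosomes in either species; genes missing from B.
    chroms_a = _gene_chrom_map(annotation_exons_a)
    chroms_b = _gene_chrom_map(annotation_exons_b) if annotation_exons_b is not None else None
    kept = []
    for me in survivors:
        if len(chroms_a.get(me.gene_id, set())) >= 2:
            removed[MULTI_CHROM].append(me.metaexon_id)
        elif chroms_b is not None and me.gene_id not in chroms_b:
            removed[UNANNOTATED].append(me.metaexon_id)
        elif chroms_b is not None and len(chroms_b[me.gene_id]) >= 2:
            removed[MULTI_CHROM].append(me.metaexon_id)
        else:
            kept.append(me)

    # (iii) intron-size discordance between adjacent same-gene metaexons.
    by_gene: dict = defaultdict(list)
    for me in kept:
        by_gene[me.gene_id].append(me)
    flagged = set()
    for gene_id, mes in by_gene.items():
        mes = sorted(mes, key=lambda m: (m.span_a.chrom, m.span_a.start))
        for prev, nxt in zip(mes, mes[1:]):
            intron_a = nxt.span_a.start - prev.span_a.end
            span_prev, span_nxt = _b_span(prev), _b_span(nxt)
            if span_prev is None or span_nxt is None:
                continue  # no paired coordinates: intron rule not evaluable
            if span_prev[0] != span_nxt[0]:
                discordant = True  # adjacent metaexons on different B chromosomes
            else:
                lo, hi = sorted([span_prev, span_nxt], key=lambda s: s[1])
                intron_b = max(0, hi[1] - lo[2])
                discordant = abs(intron_a - intron_b) >= max_intron_diff
            if discordant:
                if intron_side in ("either", "downstream"):
                    flagged.add(prev.metaexon_id)
                if intron_side in ("either", "upstream"):
                    flagged.add(nxt.metaexon_id)
    final = []
    for me in kept:
        if me.metaexon_id in flagged:
            removed[INTRON_DIFF].append(me.metaexon_id)
        else:
            final.append(me)

    report.add_stage("gene_level_filters", n_input, len(final), removed)
    return final, report


# --------------------------------------------------------------------------
# Table IO


def metaexons_to_frame(metaexons) -> pd.DataFrame:
    rows = []
    for me in metaexons:
        a = me.span_a
        rows.append(
            {
                "metaexon_id": me.metaexon_id,
                "gene_id": me.gene_id,
                "chrom_a": a.chrom,
                "start_a": a.start,
                "end_a": a.end,
                "strand_a": a.strand,
                "intervals_b": ";".join(
                    f"{iv.chrom}:{iv.start}-{iv.end}({iv.strand})" for iv in me.intervals_b
                ),
                "n_constituents": len(me.constituent_exons),
                "constituent_exons": ",".join(me.constituent_exons),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "metaexon_id", "gene_id", "chrom_a", "start_a", "end_a", "strand_a",
            "intervals_b", "n_constituents", "constituent_exons",
        ],
    )


def _parse_intervals_b(text: str):
    if not isinstance(text, str) or not text:
        return []
    out = []
    for block in text.split(";"):
        loc, strand = block[:-1].rsplit("(", 1)
        chrom, span = loc.rsplit(":", 1)
        start, end = span.split("-")
        out.append(GenomicInterval(chrom, int(start), int(end), strand))
    return out


def write_metaexon_table(metaexons, out_dir) -> dict:
    """Write the TSV mapping table plus one BED file per species.

    Round-trips losslessly through :func:`read_metaexon_table`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = metaexons_to_frame(metaexons)
    tsv = out_dir / "metaexons.tsv"
    frame.to_csv(tsv, sep="\t", index=False)

    bed_a = out_dir / "metaexons_speciesA.bed"
    with open(bed_a, "w") as fh:
        for me in metaexons:
            a = me.span_a
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{me.metaexon_id}\t0\t{a.strand}\n")
    bed_b = out_dir / "metaexons_speciesB.bed"
    with open(bed_b, "w") as fh:
        for me in metaexons:
            for iv in me.intervals_b:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{me.metaexon_id}\t0\t{iv.strand}\n")
    return {"tsv": tsv, "bed_a": bed_a, "bed_b": bed_b}


def read_metaexon_table(path):
    """Read the TSV written by :func:`write_metaexon_table`."""
    frame = pd.read_csv(path, sep="\t", dtype={"constituent_exons": str})
    metaexons = []
    for _, row in frame.iterrows():
        metaexons.append(
            Metaexon(
                metaexon_id=row["metaexon_id"],
                gene_id=row["gene_id"],
                intervals_a=[
                    GenomicInterval(
                        row["chrom_a"], int(row["start_a"]), int(row["end_a"]), row["strand_a"]
                    )
                ],
                intervals_b=_parse_intervals_b(row["intervals_b"]),
                constituent_exons=str(row["constituent_exons"]).split(","),
            )
        )
    return metaexons


def build_metaexon_table(
    exons_a,
    exons_b,
    genome_a: dict,
    genome_b: dict,
    min_identity: float = 0.92,
    second_hit_identity: float = 0.90,
    max_intron_diff: int = 10_000,
    seed_k: int = 11,
    hits_cross: dict | None = None,
    hits_self: dict | None = None,
):
    """End-to-end metaexon construction for one query species (A vs B).

    Computes hits with the built-in aligner unless pre-made hit tables are
    supplied (e.g. ingested from PSL). Returns (metaexons, report).
    """
    from .align import compute_exon_hits, extract_exon_sequences

    if hits_cross is None or hits_self is None:
        seqs = extract_exon_sequences(exons_a, genome_a)
        if hits_cross is None:
            hits_cross = compute_exon_hits(seqs, genome_b, "B", k=seed_k)
        if hits_self is None:
            hits_self = compute_exon_hits(seqs, genome_a, "A", k=seed_k)

    report = FilterReport()
    retained, best_cross, report = filter_orthologous_exons(
        exons_a, hits_cross, hits_self,
        min_identity=min_identity, second_hit_identity=second_hit_identity,
        report=report,
    )
    metaexons = collapse_metaexons(retained, best_cross)
    final, report = apply_gene_level_filters(
        metaexons, exons_a, exons_b, max_intron_diff=max_intron_diff, report=report
    )
    return final, report
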
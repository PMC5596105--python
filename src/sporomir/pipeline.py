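"""End-to-end pipeline: preprocess -> annotate -> discover -> quantify ->
DE -> targets -> integrate.

The pipeline runs from a directory of inputs (FASTQ libraries, gene-model
FASTA, reference mature set, mRNA condition-mean table, regulator
annotation, library metadata) — exactly what the simulator writes — and
returns a :class:`PipelineResult` with every intermediate product plus a
JSON-ready run report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from sporomir import annotate, discovery, expression, integrate, preprocess, targets
from sporomir.sequences import normalize


@dataclass
class PipelineParams:
    min_len: int = 19
    max_len: int = 27
    min_total: int = 2
    min_locus_reads: float = 100.0
    max_star_shift: int = 6
    min_mean_count: float = 10.0
    de_method: str = "kal"
    alpha: float = 0.05
    min_abs_log2: float = 1.0
    target_cutoff: float = 3.0
    max_gaps: int = 1
    corr_threshold: float = -0.6


@dataclass
class PipelineResult:
    tags: pd.DataFrame
    profile: preprocess.LengthProfile
    stats: preprocess.PreprocessStats
    conserved_hits: pd.DataFrame
    family_counts: pd.Series
    discovery: discovery.DiscoveryResult
    catalog: pd.Series  # member name -> mature sequence
    expr: expression.ExpressionSet
    de: pd.DataFrame
    dems: list[str]
    clusters: pd.DataFrame
    degs: set
    target_table: pd.DataFrame
    census: dict
    pairs: pd.DataFrame
    summary: dict
    report: dict = field(default_factory=dict)


def _read_fasta_dict(path: Path) -> dict[str, str]:
    return {rec.id: normalize(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def build_catalog(
    tags: pd.DataFrame,
    hits: pd.DataFrame,
    novel: list,
    conserved_cands: list,
) -> pd.Series:
    """Assemble the miRNA catalog: conserved members (every tag hitting the
    reference set, i.e. canonical matures and their isomiRs), novel guides,
    and observed star sequences.

    Member expression is simply the tag's own count row, so each member is
    one distinct sequence; names are deterministic.
    """
    totals = tags.sum(axis=1)
    members: dict[str, str] = {}
    taken: set[str] = set()

    def add(name: str, seq: str) -> None:
        if seq not in taken:
            members[name] = seq
            taken.add(seq)

    if len(hits):
        h = hits.copy()
        h["total"] = h["tag"].map(totals).fillna(0)
        h["canonical"] = (
            (h["n_substitutions"] == 0) & (h["offset_5p"] == 0) & (h["offset_3p"] == 0)
        )
        for ref_id, grp in h.groupby("ref_id", sort=True):
            grp = grp.sort_values(
                ["canonical", "total", "tag"], ascending=[False, False, True],
                kind="stable",
            )
            serial = 0
            for row in grp.itertuples(index=False):
                if row.canonical:
                    add(ref_id, row.tag)
                else:
                    serial += 1
                    add(f"{ref_id}.iso{serial}", row.tag)
    for cand in novel:
        add(cand.name, cand.guide_seq)
        if cand.star_observed:
            star_arm = "3p" if cand.guide_arm == "5p" else "5p"
            add(cand.name.rsplit("_", 1)[0] + f"_{star_arm}", cand.star_seq)
    for cand, hit in conserved_cands:
        if cand.star_observed:
            add(f"{hit.ref_id}-star", cand.star_seq)
    return pd.Series(members, name="sequence")


def run_pipeline(indir: str | Path, params: PipelineParams | None = None) -> PipelineResult:
    """Run every stage from a simulator-style input directory."""
    params = params or PipelineParams()
    indir = Path(indir)

    meta = pd.read_csv(indir / "library_metadata.tsv", sep="\t").set_index("library")
    fastqs = [indir / "libraries" / f"{lib}.fastq" for lib in meta.index]
    tags, profile, stats = preprocess.run(
        fastqs, params.min_len, params.max_len, params.min_total
    )

    refs = annotate.load_references(
        indir / "reference_matures.fa",
        indir / "reference_families.tsv",
        (indir / "reference_flanks.tsv")
        if (indir / "reference_flanks.tsv").exists()
        else None,
    )
    hits = annotate.match_tags(list(tags.index), refs)
    fam_counts = annotate.family_census(hits)

    gene_models = _read_fasta_dict(indir / "transcripts.fa")
    disc = discovery.discover(
        tags,
        gene_models,
        refs,
        min_locus_reads=params.min_locus_reads,
        max_star_shift=params.max_star_shift,
    )

    catalog = build_catalog(tags, hits, disc.novel, disc.conserved)
    counts = tags.loc[catalog.values]
    counts.index = catalog.index
    lengths = pd.Series([len(s) for s in catalog.values], index=catalog.index)
    lib_sizes = tags.sum(axis=0)
    temps = meta["temperature"].astype(str)
    expr = expression.quantify(counts, lengths, lib_sizes, temps)
    expr = expression.filter_expressed(expr, params.min_mean_count)
    de = expression.de_all_contrasts(
        expr, method=params.de_method, alpha=params.alpha,
        min_abs_log2=params.min_abs_log2,
    )
    dems = expression.call_dems(de)
    clusters = expression.cluster_profiles(de, expr.condition_mean_rpkm())

    mrna = pd.read_csv(indir / "mrna_expression.tsv", sep="\t").set_index("transcript")
    mrna.columns = [str(c) for c in mrna.columns]
    degs = integrate.call_degs(mrna, min_abs_log2=params.min_abs_log2)

    dem_seqs = {m: catalog[m] for m in dems}
    deg_models = {t: gene_models[t] for t in sorted(degs) if t in gene_models}
    table, census = targets.target_table(
        dem_seqs, deg_models, cutoff=params.target_cutoff, max_gaps=params.max_gaps
    )

    mirna_means = expression.ExpressionSet(
        expr.counts, expr.rpkm, expr.lengths, expr.library_sizes, expr.temperatures
    ).condition_mean_rpkm()
    pairs = integrate.correlate_pairs(
        table, mirna_means, mrna, dems=set(dems), degs=degs,
        threshold=params.corr_threshold,
    )
    ann = pd.read_csv(indir / "regulator_annotation.tsv", sep="\t")
    pairs = integrate.classify_regulators(pairs, ann)

    stage_counts = {
        **stats.as_dict(),
        "n_tags": int(len(tags)),
        "n_conserved_tags": int(len(hits)),
        "n_accepted_loci": len(disc.accepted_loci),
        "n_candidates": len(disc.candidates),
        "n_novel_mirnas": len(disc.novel),
        "n_catalog_members": int(len(catalog)),
        "n_expressed": int(len(expr.counts)),
        "n_dems": len(dems),
        "n_degs": len(degs),
    }
    summary = integrate.summarize(pairs, set(dems), degs, stage_counts)
    result = PipelineResult(
        tags=tags,
        profile=profile,
        stats=stats,
        conserved_hits=hits,
        family_counts=fam_counts,
        discovery=disc,
        catalog=catalog,
        expr=expr,
        de=de,
        dems=dems,
        clusters=clusters,
        degs=degs,
        target_table=table,
        census=census,
        pairs=pairs,
        summary=summary,
        report=summary["report"],
    )
    return result


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Write the pipeline's tabular outputs and the JSON run report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    preprocess.write_collapsed_fasta(result.tags, outdir / "tags.fa")
    result.tags.rename_axis("sequence").to_csv(outdir / "tag_counts.tsv", sep="\t")
    result.conserved_hits.to_csv(outdir / "conserved_hits.tsv", sep="\t", index=False)
    result.catalog.rename_axis("mirna").to_csv(outdir / "catalog.tsv", sep="\t")
    result.de.to_csv(outdir / "de_calls.tsv", sep="\t", index=False)
    result.clusters.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    result.target_table.to_csv(outdir / "target_sites.tsv", sep="\t", index=False)
    result.pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
    result.pairs[result.pairs["retained"]].to_csv(
        outdir / "pairs_retained.tsv", sep="\t", index=False
    )
    result.summary["category_table"].to_csv(outdir / "table3_like.tsv", sep="\t")
    fam = pd.DataFrame({"n_isomirs": result.family_counts})
    fam.to_csv(outdir / "family_census.tsv", sep="\t")
    with open(outdir / "novel_mirnas.fa", "w") as fh:
        for cand in result.discovery.novel:
            fh.write(f">{cand.name} count={cand.guide_count:.0f}\n{cand.guide_seq}\n")
    with open(outdir / "precursors.fa", "w") as fh:
        for cand in result.discovery.novel:
            fh.write(f">{cand.name}_precursor\n{cand.precursor}\n")
    with open(outdir / "precursor_structures.tsv", "w") as fh:
        fh.write("name\tstructure\n")
        for cand in result.discovery.novel:
            fh.write(f"{cand.name}\t{cand.structure}\n")
    with open(outdir / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
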
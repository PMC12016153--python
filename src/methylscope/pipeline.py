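"""End-to-end orchestration: calling, motifs, context, ambiguity, reporting.

Runs the analysis stages in order on a (genome, annotation, pileup,
optional strand-counts) bundle and writes the stage TSVs plus the summary
artifacts: a motif table with asterisk notation for complementary-strand
methylation, a per-meth-site methylation-fraction matrix, density/window/
histogram/region tables, and — when strand counts are provided — the
ambiguous-site table, masked genome and context PFM.  Also provides
replicate agreement statistics over shared coordinates.

Outputs are pure functions of inputs + config: two runs with identical
inputs and seed produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .ambiguity import (
    associate,
    context_pfm,
    detect_ambiguous,
    mask_genome,
    sites_table,
)
from .context import (
    define_regions,
    density_table,
    flag_top,
    gene_density,
    genome_region_fraction,
    motif_region_proportions,
    pm_histogram,
    read_gff3,
    window_density,
    window_table,
)
from .motifs import (
    Motif,
    find_motifs_denovo,
    fraction_explained,
    index_calls,
    read_motif_table,
    scan,
    summarize_motif,
    summary_table,
)
from .pileup import (
    DEFAULT_CALL_THRESHOLD,
    DEFAULT_MIN_TOTAL_READS,
    call_methylation,
    read_bedmethyl,
    write_calls,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    fasta: str
    bedmethyl: str
    gff3: str | None = None
    strand_counts: str | None = None
    motif_table: str | None = None
    discover_motifs: bool = True
    discover_mod_types: tuple[str, ...] = ("6mA",)
    call_threshold: float = DEFAULT_CALL_THRESHOLD
    min_total_reads: int = DEFAULT_MIN_TOTAL_READS
    region_flank: int = 40
    window_size: int = 1000
    top_fraction: float = 0.05
    ambiguity_min_cov: int = 10
    ambiguity_min_minor_frac: float = 0.2
    pfm_halfwidth: int = 5
    outdir: str = "methylscope_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.call_threshold < 1:
            raise ValueError("call_threshold must lie in (0, 1)")
        if not 0 < self.top_fraction < 1:
            raise ValueError("top_fraction must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "discover_mod_types" in data:
            data["discover_mod_types"] = tuple(data["discover_mod_types"])
        return cls(**data)


def _require(path: str | None, what: str) -> Path:
    if path is None:
        raise PipelineError(f"{what} input not configured")
    p = Path(path)
    if not p.exists():
        raise PipelineError(f"{what} file not found: {p}")
    return p


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute call -> motifs -> genomic context -> ambiguity and write the
    report bundle into ``config.outdir``.  Returns the artifact paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fasta = _require(config.fasta, "genome FASTA")
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
    if not contigs:
        raise PipelineError(f"stage load: no sequences in {fasta}")
    contig, genome = next(iter(contigs.items()))

    # --- stage: methylation calling -------------------------------------
    try:
        records = read_bedmethyl(_require(config.bedmethyl, "bedMethyl pileup"))
        calls = call_methylation(
            records,
            threshold=config.call_threshold,
            min_total_reads=config.min_total_reads,
        )
    except Exception as exc:
        raise PipelineError(f"stage call: {exc}") from exc
    paths["calls"] = outdir / "calls.tsv"
    write_calls(calls, paths["calls"])
    call_index = index_calls(calls)

    # --- stage: motifs ----------------------------------------------------
    try:
        motifs: list[Motif] = []
        if config.motif_table:
            motifs.extend(read_motif_table(_require(config.motif_table, "motif table")))
        elif config.discover_motifs:
            for mod_type in config.discover_mod_types:
                motifs.extend(find_motifs_denovo(genome, calls, mod_type))
        pairs = [(m, scan(genome, m, contig=contig)) for m in motifs]
        summaries = [
            summarize_motif(occ, call_index, threshold=config.call_threshold)
            for _, occ in pairs
            if occ
        ]
    except Exception as exc:
        raise PipelineError(f"stage motifs: {exc}") from exc
    motif_df = summary_table(summaries)
    paths["motif_summary"] = outdir / "motif_summary.tsv"
    motif_df.to_csv(paths["motif_summary"], sep="\t", index=False,
                    float_format="%.6f")
    table1 = pd.DataFrame(
        [
            {
                "motif": m.render(),
                "mod_types": ",".join(
                    sorted({s.mod_type for s in m.meth_sites})
                ),
            }
            for m in motifs
        ],
        columns=["motif", "mod_types"],
    )
    paths["motif_table"] = outdir / "motif_table.tsv"
    table1.to_csv(paths["motif_table"], sep="\t", index=False)

    explained = {}
    for mod_type in config.discover_mod_types:
        fr = fraction_explained(calls, [occ for _, occ in pairs], mod_type)
        explained[mod_type] = fr

    # --- stage: genomic context ------------------------------------------
    region_fraction = None
    if config.gff3:
        try:
            genes = read_gff3(_require(config.gff3, "GFF3 annotation"))
            for mod_type in config.discover_mod_types:
                dens = flag_top(
                    gene_density(calls, genes, mod_type,
                                 threshold=config.call_threshold),
                    fraction=config.top_fraction,
                )
                p = outdir / f"gene_density_{mod_type}.tsv"
                density_table(dens).to_csv(p, sep="\t", index=False,
                                           float_format="%.6f")
                paths[f"gene_density_{mod_type}"] = p
                pm_pairs = [
                    (c.position, c.percent_modified)
                    for c in calls
                    if c.mod_type == mod_type and c.percent_modified is not None
                ]
                wins = window_density(
                    pm_pairs, len(genome), window=config.window_size,
                    contig=contig, mod_type=mod_type,
                )
                p = outdir / f"window_density_{mod_type}.tsv"
                window_table(wins).to_csv(p, sep="\t", index=False)
                paths[f"window_density_{mod_type}"] = p
                hist, _ = pm_histogram(pm_pairs, genes)
                p = outdir / f"pm_histogram_{mod_type}.tsv"
                hist.to_csv(p, sep="\t", float_format="%.6f")
                paths[f"pm_histogram_{mod_type}"] = p
            regions = define_regions(
                genes, flank=config.region_flank,
                contig_lengths={contig: len(genome)},
            )
            region_fraction = genome_region_fraction(regions, len(genome))
            props = motif_region_proportions(
                pairs, calls, regions, threshold=config.call_threshold
            )
            paths["region_proportions"] = outdir / "region_proportions.tsv"
            props.to_csv(paths["region_proportions"], sep="\t", index=False,
                         float_format="%.6f")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage genomic_context: {exc}") from exc

    # --- stage: ambiguity -------------------------------------------------
    if config.strand_counts:
        try:
            from .simulate import read_strand_counts

            counts = read_strand_counts(
                _require(config.strand_counts, "strand counts")
            )
            sites = detect_ambiguous(
                counts,
                reference=genome,
                min_cov=config.ambiguity_min_cov,
                min_minor_frac=config.ambiguity_min_minor_frac,
            )
            sites = associate(sites, calls)
            paths["ambiguous_sites"] = outdir / "ambiguous_sites.tsv"
            sites_table(sites).to_csv(paths["ambiguous_sites"], sep="\t",
                                      index=False)
            masked = mask_genome(genome, sites)
            paths["masked_fasta"] = outdir / "genome.masked.fasta"
            from .simulate import write_fasta

            write_fasta(masked, paths["masked_fasta"], name=contig)
            pfm = context_pfm(sites, genome, k=config.pfm_halfwidth)
            paths["context_pfm"] = outdir / "context_pfm.tsv"
            pfm.to_frame().to_csv(paths["context_pfm"], sep="\t",
                                  float_format="%.6f")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage ambiguity: {exc}") from exc

    # --- run log ----------------------------------------------------------
    paths["run_log"] = outdir / "run_log.txt"
    with open(paths["run_log"], "w") as fh:
        fh.write(f"methylscope {__version__}\n")
        fh.write(f"seed\t{config.seed}\n")
        fh.write(f"call_threshold\t{config.call_threshold}\n")
        fh.write(f"min_total_reads\t{config.min_total_reads}\n")
        fh.write(f"region_flank\t{config.region_flank}\n")
        fh.write(f"window_size\t{config.window_size}\n")
        fh.write(f"top_fraction\t{config.top_fraction}\n")
        fh.write(f"ambiguity_min_cov\t{config.ambiguity_min_cov}\n")
        fh.write(f"ambiguity_min_minor_frac\t{config.ambiguity_min_minor_frac}\n")
        for mod_type, fr in explained.items():
            fh.write(
                f"fraction_explained_{mod_type}\t"
                f"{'' if fr is None else f'{fr:.6f}'}\n"
            )
        if region_fraction is not None:
            fh.write(f"genome_region_fraction\t{region_fraction:.6f}\n")
    return paths


# ---------------------------------------------------------------------------
# replicate comparison
# ---------------------------------------------------------------------------

def compare_replicates(
    call_sets: Sequence[Iterable], labels: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pairwise agreement of methylated positions across replicates.

    All call sets must live on the same reference coordinates.  Per
    modification type and pair: intersection, union, Jaccard index and
    per-set exclusive counts.
    """
    if len(call_sets) < 2:
        raise ValueError("need at least two call sets")
    labels = list(labels) if labels else [f"set_{i + 1}" for i in range(len(call_sets))]
    sets: list[dict[str, set]] = []
    contigs_seen = []
    for calls in call_sets:
        by_type: dict[str, set] = {}
        ctgs = set()
        for c in calls:
            ctgs.add(c.contig)
            if c.is_methylated:
                by_type.setdefault(c.mod_type, set()).add(
                    (c.contig, c.position, c.strand)
                )
        sets.append(by_type)
        contigs_seen.append(ctgs)
    shared = set.union(*contigs_seen) if contigs_seen else set()
    for ctgs in contigs_seen:
        if ctgs and shared and not (ctgs & shared):
            raise ValueError("call sets share no contigs (mismatched references)")

    mod_types = sorted({t for s in sets for t in s})
    rows = []
    for mod_type in mod_types:
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                a = sets[i].get(mod_type, set())
                b = sets[j].get(mod_type, set())
                inter, union = len(a & b), len(a | b)
                rows.append(
                    {
                        "mod_type": mod_type,
                        "set_a": labels[i], "set_b": labels[j],
                        "n_a": len(a), "n_b": len(b),
                        "intersection": inter, "union": union,
                        "jaccard": inter / union if union else 1.0,
                        "exclusive_a": len(a - b), "exclusive_b": len(b - a),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["mod_type", "set_a", "set_b", "n_a", "n_b",
                 "intersection", "union", "jaccard",
                 "exclusive_a", "exclusive_b"],
    )
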
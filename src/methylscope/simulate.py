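"""Synthetic bacterial methylome data with known ground truth.

Generates a random genome with planted methylation motifs, a Bakta-style
annotation, a Modkit-style modified-base pileup, and a strand-split
basecall count table, together with a manifest of the planted truth.  The
statistical structure mirrors the assumptions of the downstream analysis:

* motif occurrences are planted non-overlapping at uniform-random eligible
  positions on a random strand; each methylatable site of each occurrence
  is methylated with probability ``p_site``;
* at a methylated site, each of the ``coverage`` reads per strand is called
  modified with probability ``p_read``; reads independently fail the
  confidence filter with probability ``p_fail`` or carry a non-canonical
  base with probability ``p_diff``;
* off-motif positions acquire a spurious methylation signal with per-base
  probability ``background_call_rate`` (and then the same per-read signal);
* on the strand carrying a 6mA, the G immediately 5' of the methylated
  adenine is miscalled A with per-read probability ``ambiguity_error_rate``
  — the strand-specific basecalling-error pattern the ambiguity module
  detects.

Depth is constant per position; identical config + seed gives
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import (
    IUPAC_EXPANSION,
    MOD_TYPE_BASE,
    MOD_TYPE_TO_CODE,
    Motif,
    reverse_complement,
)
from .pileup import PileupRecord, write_bedmethyl

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class SimulationError(ValueError):
    """Raised for infeasible or inconsistent simulation configurations."""


@dataclass
class MotifSpec:
    """One motif to plant (or to leave as background only).

    ``p_site`` is the per-site methylation probability (drawn independently
    for every methylatable base of every planted occurrence); ``p_read`` the
    per-read modified-call probability at a methylated site.
    """

    motif: Motif
    planted_count: int = 0
    background_only: bool = False
    p_site: float = 1.0
    p_read: float = 0.9

    def __post_init__(self) -> None:
        if not 0 <= self.p_site <= 1 or not 0 <= self.p_read <= 1:
            raise SimulationError("p_site and p_read must lie in [0, 1]")
        if self.planted_count < 0:
            raise SimulationError("planted_count must be >= 0")


@dataclass
class SimulationConfig:
    genome_length: int = 200_000
    gc_content: float = 0.5
    seed: int = 0
    motif_specs: list[MotifSpec] = field(default_factory=list)
    #: reads per strand per position; the emulated study design targets 100X
    coverage: int = 100
    p_fail: float = 0.05
    p_diff: float = 0.01
    background_call_rate: float = 0.0
    background_p_read: float = 0.9
    ambiguity_error_rate: float = 0.0
    #: uniform per-read miscall floor in the strand-count table
    base_error_rate: float = 0.0
    gene_count: int = 0
    gene_length_mean: int = 1000
    gene_length_sd: float | None = None
    cog_alphabet: str = "CDEFGHIJKLMNOPQSTUV"
    rrna_fraction: float = 0.01
    trna_fraction: float = 0.03
    include_ori: bool = True
    contig_name: str = "contig_1"

    def __post_init__(self) -> None:
        probs = (
            self.gc_content, self.p_fail, self.p_diff, self.background_call_rate,
            self.background_p_read, self.ambiguity_error_rate, self.base_error_rate,
            self.rrna_fraction, self.trna_fraction,
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise SimulationError("all probabilities must lie in [0, 1]")
        if self.genome_length <= 0:
            raise SimulationError("genome_length must be positive")
        if self.coverage <= 0:
            raise SimulationError("coverage must be positive")
        if self.gene_count < 0:
            raise SimulationError("gene_count must be >= 0")


@dataclass(frozen=True)
class PlantedOccurrence:
    motif: Motif
    contig: str
    start: int
    strand: str


@dataclass(frozen=True)
class AmbiguityTruthSite:
    """A planted strand-discordance candidate: a G 5' of a methylated 6mA."""

    contig: str
    position: int          # plus-strand coordinate of the miscalled G
    discordant_strand: str
    meth_position: int     # plus-strand coordinate of the associated 6mA
    meth_strand: str


@dataclass
class GroundTruth:
    planted_occurrences: list[PlantedOccurrence] = field(default_factory=list)
    #: unique (contig, position, strand, mod_type)
    methylated_sites: set[tuple[str, int, str, str]] = field(default_factory=set)
    #: per methylated site, the per-read signal probability of its motif
    read_probabilities: dict[tuple[str, int, str, str], float] = field(
        default_factory=dict
    )
    ambiguous_sites_truth: list[AmbiguityTruthSite] = field(default_factory=list)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per simulation stage
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


def _instantiate(pattern: str, rng: np.random.Generator) -> str:
    return "".join(
        ch if ch in "ACGT" else rng.choice(sorted(IUPAC_EXPANSION[ch]))
        for ch in pattern
    )


def generate_genome(config: SimulationConfig) -> tuple[str, GroundTruth]:
    """Random genome with planted, non-overlapping motif occurrences.

    Background bases are i.i.d. at the configured GC content.  The truth
    manifest records planted occurrences and the methylated sites drawn at
    ``p_site`` per site; accidental background matches of a motif are
    permitted but never enter the manifest.
    """
    planted = [
        (spec, spec.planted_count)
        for spec in config.motif_specs
        if spec.planted_count > 0 and not spec.background_only
    ]
    footprint = sum(len(spec.motif.pattern) * n for spec, n in planted)
    if footprint > config.genome_length / 2:
        raise SimulationError(
            f"planted motif footprint {footprint} exceeds half the genome "
            f"({config.genome_length / 2:.0f} bases)"
        )

    rng = _rng(config, 0)
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.frombuffer(b"ACGT", dtype="S1")
    genome = rng.choice(bases, size=config.genome_length, p=p).copy()

    occupied = np.zeros(config.genome_length, dtype=bool)
    truth = GroundTruth()
    contig = config.contig_name
    for spec, count in planted:
        L = len(spec.motif.pattern)
        max_attempts = 200 * count + 1000
        placed = 0
        attempts = 0
        while placed < count:
            attempts += 1
            if attempts > max_attempts:
                raise SimulationError(
                    f"could not place {count} occurrences of "
                    f"{spec.motif.pattern} (planting density infeasible)"
                )
            start = int(rng.integers(0, config.genome_length - L + 1))
            if occupied[start:start + L].any():
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            word = _instantiate(spec.motif.pattern, rng)
            if strand == "-":
                word = reverse_complement(word)
            genome[start:start + L] = np.frombuffer(word.encode(), dtype="S1")
            occupied[start:start + L] = True
            truth.planted_occurrences.append(
                PlantedOccurrence(spec.motif, contig, start, strand)
            )
            placed += 1

    genome_str = genome.tobytes().decode()

    # Methylation acts genome-wide: every occurrence of a configured motif
    # (planted or accidental) is methylated per-site at p_site, as a
    # methyltransferase recognising the motif would do.  The manifest of
    # planted occurrences above still records only deliberate plantings.
    from .motifs import scan as _scan

    decided: set[tuple[str, int, str, str]] = set()
    for spec in config.motif_specs:
        for occ in _scan(genome_str, spec.motif, contig=contig):
            for so in occ.sites:
                key = (contig, so.position, so.strand, so.site.mod_type)
                if key in decided:
                    continue
                decided.add(key)
                if rng.random() < spec.p_site:
                    truth.methylated_sites.add(key)
                    truth.read_probabilities[key] = spec.p_read

    # geometric candidates for strand-discordant miscalls (G 5' of 6mA)
    if config.ambiguity_error_rate > 0:
        for (ctg, pos, strand, mod_type) in sorted(truth.methylated_sites):
            if mod_type != "6mA":
                continue
            if strand == "+" and pos > 0 and genome_str[pos - 1] == "G":
                truth.ambiguous_sites_truth.append(
                    AmbiguityTruthSite(ctg, pos - 1, "+", pos, "+")
                )
            elif strand == "-" and pos + 1 < len(genome_str) \
                    and genome_str[pos + 1] == "C":
                truth.ambiguous_sites_truth.append(
                    AmbiguityTruthSite(ctg, pos + 1, "-", pos, "-")
                )
    return genome_str, truth


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimGene:
    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    feature_class: str
    cog_category: str | None


def generate_annotation(config: SimulationConfig, genome: str) -> list[SimGene]:
    """Non-overlapping genes packed with random gaps over the genome.

    Gene lengths are drawn around ``gene_length_mean``; strands, COG
    categories and rRNA/tRNA labels are random; one strandless ``ori``
    feature is included when configured.  Raises when the drawn genes
    cannot fit in the genome.
    """
    n = config.gene_count
    if n == 0:
        return []
    rng = _rng(config, 1)
    sd = config.gene_length_sd
    if sd is None:
        sd = config.gene_length_mean / 5
    lengths = np.maximum(
        100, np.round(rng.normal(config.gene_length_mean, sd, size=n))
    ).astype(int)
    intervals = [("gene", int(l)) for l in lengths]
    if config.include_ori:
        intervals.append(("ori", 250))
    total = sum(l for _, l in intervals)
    slack = len(genome) - total
    if slack < 0:
        raise SimulationError(
            f"{len(intervals)} features of total length {total} cannot fit "
            f"in a {len(genome)}-base genome"
        )
    k = len(intervals)
    gaps = rng.multinomial(slack, np.full(k + 1, 1.0 / (k + 1)))
    order = rng.permutation(k)

    classes = rng.choice(
        ["rRNA", "tRNA", "CDS"],
        size=n,
        p=[config.rrna_fraction, config.trna_fraction,
           1 - config.rrna_fraction - config.trna_fraction],
    )
    cogs = rng.choice(list(config.cog_alphabet), size=n)
    strands = rng.choice(["+", "-"], size=n)

    genes: list[SimGene] = []
    cursor = 0
    gene_i = 0
    for slot, idx in enumerate(order):
        cursor += int(gaps[slot])
        kind, length = intervals[idx]
        start, end = cursor, cursor + length
        if kind == "ori":
            genes.append(
                SimGene("ori_1", config.contig_name, start, end, ".", "ori", None)
            )
        else:
            genes.append(
                SimGene(
                    f"gene_{gene_i + 1:05d}", config.contig_name, start, end,
                    str(strands[gene_i]), str(classes[gene_i]),
                    str(cogs[gene_i]),
                )
            )
            gene_i += 1
        cursor = end
    genes.sort(key=lambda g: g.start)
    return genes


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

def _methylatable_positions(genome_arr: np.ndarray, mod_type: str):
    """(positions, strand) pairs where the canonical base can carry mod_type."""
    base = MOD_TYPE_BASE[mod_type]
    comp = _COMP[base]
    plus = np.flatnonzero(genome_arr == base.encode())
    minus = np.flatnonzero(genome_arr == comp.encode())
    return plus, minus


def simulate_pileup(
    genome: str, truth: GroundTruth, config: SimulationConfig
) -> list[PileupRecord]:
    """Modkit-style pileup records for every methylatable base.

    Per record: ``n_fail ~ Binom(coverage, p_fail)``, then
    ``n_diff ~ Binom(coverage - n_fail, p_diff)``; the remaining reads are
    valid coverage, of which ``n_mod ~ Binom(n_valid, p_read)`` at
    methylated (or spurious-background) sites and 0 elsewhere.  ``n_delete``
    and ``n_nocall`` are emitted as 0.
    """
    rng = _rng(config, 2)
    genome_arr = np.frombuffer(genome.encode(), dtype="S1")
    mod_types = sorted(
        {s.mod_type for spec in config.motif_specs for s in spec.motif.meth_sites}
    ) or ["6mA"]
    contig = config.contig_name
    records: list[PileupRecord] = []
    for mod_type in mod_types:
        plus, minus = _methylatable_positions(genome_arr, mod_type)
        for strand, positions in (("+", plus), ("-", minus)):
            npos = len(positions)
            if npos == 0:
                continue
            cov = config.coverage
            n_fail = rng.binomial(cov, config.p_fail, size=npos)
            n_diff = rng.binomial(cov - n_fail, config.p_diff)
            n_valid = cov - n_fail - n_diff
            p_read = np.zeros(npos)
            meth_mask = np.zeros(npos, dtype=bool)
            for i, pos in enumerate(positions):
                key = (contig, int(pos), strand, mod_type)
                if key in truth.methylated_sites:
                    meth_mask[i] = True
                    p_read[i] = truth.read_probabilities[key]
            if config.background_call_rate > 0:
                spurious = (~meth_mask) & (
                    rng.random(npos) < config.background_call_rate
                )
                p_read[spurious] = config.background_p_read
            n_mod = rng.binomial(n_valid, p_read)
            mod_code = MOD_TYPE_TO_CODE[mod_type]
            for i, pos in enumerate(positions):
                records.append(
                    PileupRecord(
                        contig=contig,
                        start=int(pos),
                        mod_code=mod_code,
                        strand=strand,
                        n_valid_cov=int(n_valid[i]),
                        n_mod=int(n_mod[i]),
                        n_canonical=int(n_valid[i] - n_mod[i]),
                        n_fail=int(n_fail[i]),
                        n_diff=int(n_diff[i]),
                    )
                )
    records.sort(key=lambda r: (r.contig, r.start, r.strand, r.mod_code))
    return records


# ---------------------------------------------------------------------------
# strand-split base counts
# ---------------------------------------------------------------------------

STRAND_COUNT_COLUMNS = ["chrom", "pos0", "strand", "nA", "nC", "nG", "nT"]


def simulate_strand_counts(
    genome: str, truth: GroundTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Per-position, per-strand basecall counts in plus-strand base space.

    Basecalls of minus-strand reads are complemented onto the reference
    strand before counting, so a minus-strand G→A miscall (5' of a
    minus-strand 6mA) surfaces as a C/T mixture in the minus-strand row.
    All positions are error-free apart from the planted discordance sites
    and the optional uniform ``base_error_rate`` floor.
    """
    rng = _rng(config, 3)
    L = len(genome)
    cov = config.coverage
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    ref = np.frombuffer(genome.encode(), dtype="S1")
    ref_col = np.select(
        [ref == b"A", ref == b"C", ref == b"G", ref == b"T"], [0, 1, 2, 3], 3
    )

    counts = {
        strand: np.zeros((L, 4), dtype=int) for strand in "+-"
    }
    for strand in "+-":
        counts[strand][np.arange(L), ref_col] = cov

    if config.base_error_rate > 0:
        for strand in "+-":
            n_err = rng.binomial(cov, config.base_error_rate, size=L)
            split = rng.multinomial(n_err, [1 / 3] * 3)
            c = counts[strand]
            c[np.arange(L), ref_col] -= n_err
            others = np.array(
                [[b for b in range(4) if b != r] for r in ref_col]
            )
            for j in range(3):
                np.add.at(c, (np.arange(L), others[:, j]), split[:, j])

    e = config.ambiguity_error_rate
    if e > 0:
        for site in truth.ambiguous_sites_truth:
            c = counts[site.discordant_strand]
            if site.discordant_strand == "+":
                # G miscalled as A on the plus strand
                src, dst = base_idx["G"], base_idx["A"]
            else:
                # minus-strand G→A, complemented to plus space: C→T
                src, dst = base_idx["C"], base_idx["T"]
            n_err = int(rng.binomial(c[site.position, src], e))
            c[site.position, src] -= n_err
            c[site.position, dst] += n_err

    frames = []
    for strand in "+-":
        c = counts[strand]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": config.contig_name,
                    "pos0": np.arange(L),
                    "strand": strand,
                    "nA": c[:, 0], "nC": c[:, 1], "nG": c[:, 2], "nT": c[:, 3],
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["chrom", "pos0", "strand"], ignore_index=True)


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_fasta(genome: str, path, name: str = "contig_1") -> None:
    SeqIO.write([SeqRecord(Seq(genome), id=name, description="")], path, "fasta")


def write_gff3(genes: Sequence[SimGene], path, contig_lengths=None) -> None:
    type_map = {"CDS": "CDS", "rRNA": "rRNA", "tRNA": "tRNA", "ori": "rep_origin"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if contig_lengths:
            for ctg, length in contig_lengths.items():
                fh.write(f"##sequence-region {ctg} 1 {length}\n")
        for g in genes:
            attrs = [f"ID={g.gene_id}", "product=hypothetical protein",
                     f"feature_class={g.feature_class}"]
            if g.cog_category:
                attrs.append(f"cog={g.cog_category}")
            fh.write(
                "\t".join(
                    [
                        g.contig, "methylscope_sim",
                        type_map.get(g.feature_class, "gene"),
                        str(g.start + 1), str(g.end), ".", g.strand, ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def write_strand_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_strand_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})


def write_truth(truth: GroundTruth, path) -> None:
    """Ground-truth manifest TSV (one row per planted item, typed)."""
    rows = []
    for occ in truth.planted_occurrences:
        rows.append(
            {
                "kind": "occurrence", "contig": occ.contig, "position": occ.start,
                "strand": occ.strand, "detail": occ.motif.pattern,
            }
        )
    for (contig, pos, strand, mod_type) in sorted(truth.methylated_sites):
        rows.append(
            {
                "kind": "methylated_site", "contig": contig, "position": pos,
                "strand": strand, "detail": mod_type,
            }
        )
    for site in truth.ambiguous_sites_truth:
        rows.append(
            {
                "kind": "ambiguous_site", "contig": site.contig,
                "position": site.position, "strand": site.discordant_strand,
                "detail": f"6mA@{site.meth_position}{site.meth_strand}",
            }
        )
    pd.DataFrame(
        rows, columns=["kind", "contig", "position", "strand", "detail"]
    ).to_csv(path, sep="\t", index=False)


def simulate_bundle(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Run the full generator and write all artifacts into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, truth = generate_genome(config)
    genes = generate_annotation(config, genome)
    pileup = simulate_pileup(genome, truth, config)
    counts = simulate_strand_counts(genome, truth, config)
    paths = {
        "fasta": outdir / "genome.fasta",
        "gff3": outdir / "annotation.gff3",
        "bedmethyl": outdir / "pileup.bedmethyl",
        "strand_counts": outdir / "strand_counts.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(genome, paths["fasta"], name=config.contig_name)
    write_gff3(genes, paths["gff3"], {config.contig_name: len(genome)})
    write_bedmethyl(pileup, paths["bedmethyl"])
    write_strand_counts(counts, paths["strand_counts"])
    write_truth(truth, paths["truth"])
    return paths
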
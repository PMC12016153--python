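"""Methylation in its genomic context: genes, windows, and regulatory regions.

Quantifies where methylated bases fall relative to the annotation:

* per-gene methylation density (methylated bases per gene length), with the
  globally top fraction of genes flagged as hypermethylated;
* windowed density: the mean of raw Percent Modified values in fixed-size
  tiling windows, usable alongside the annotation to spot enriched regions
  such as rRNA/tRNA clusters;
* Percent Modified histograms per feature class over a stated value range;
* the 40-base promoter / gene-start / gene-end region geometry used to ask
  whether motifs concentrate in regulatory regions (40 bases captures the
  bacterial core promoter with its -10 and -35 elements).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_REGION_FLANK = 40
DEFAULT_WINDOW = 1000
DEFAULT_TOP_FRACTION = 0.05

FEATURE_CLASSES = ("CDS", "rRNA", "tRNA", "ori", "other")


@dataclass(frozen=True)
class GeneFeature:
    """Annotated interval; coordinates 0-based half-open."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    feature_class: str = "CDS"
    cog_category: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_gff3(path) -> list[GeneFeature]:
    """Read a Bakta-style GFF3 into :class:`GeneFeature` records.

    Feature class comes from the ``feature_class`` attribute when present,
    else from the GFF type (CDS/rRNA/tRNA/rep_origin); the COG category is
    read from a ``cog`` (or Bakta ``COG``) attribute, keeping the first
    letter when several are annotated.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    type_map = {"CDS": "CDS", "rRNA": "rRNA", "tRNA": "tRNA",
                "rep_origin": "ori", "oriC": "ori"}
    genes = []
    for i, feat in enumerate(db.all_features(order_by=("seqid", "start"))):
        fclass = feat.attributes.get("feature_class", [None])[0]
        if fclass is None:
            fclass = type_map.get(feat.featuretype, "other")
        cog = (feat.attributes.get("cog") or feat.attributes.get("COG") or [None])[0]
        if cog:
            cog = cog[0]
        gene_id = feat.attributes.get("ID", [f"feature_{i + 1}"])[0]
        genes.append(
            GeneFeature(
                gene_id=gene_id,
                contig=feat.seqid,
                start=feat.start - 1,  # GFF3 is 1-based inclusive
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else ".",
                feature_class=fclass,
                cog_category=cog,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# per-gene density
# ---------------------------------------------------------------------------

@dataclass
class DensityRecord:
    gene_id: str
    mod_type: str
    n_methylated: int
    gene_length: int
    density: float
    is_top: bool = False
    feature_class: str = "CDS"
    cog_category: str | None = None


def _methylated_positions(calls: Iterable, mod_type: str, threshold: float):
    """Sorted plus-coordinates of methylated bases (one entry per strand)."""
    pos = [
        c.position
        for c in calls
        if c.mod_type == mod_type
        and c.percent_modified is not None
        and c.percent_modified > threshold
        and not c.low_coverage
    ]
    return np.sort(np.asarray(pos, dtype=int))


def gene_density(
    calls: Iterable,
    genes: Sequence[GeneFeature],
    mod_type: str,
    threshold: float = 0.5,
) -> list[DensityRecord]:
    """Methylated bases per gene length, both strands counted.

    A methylated base is a call with Percent Modified strictly above
    ``threshold``; each (position, strand) counts once, and density is
    n_methylated / (end - start).
    """
    calls = list(calls)
    positions = _methylated_positions(calls, mod_type, threshold)
    records = []
    for g in genes:
        if g.length == 0:
            raise ValueError(f"zero-length gene {g.gene_id}")
        n = int(
            np.searchsorted(positions, g.end, side="left")
            - np.searchsorted(positions, g.start, side="left")
        )
        records.append(
            DensityRecord(
                gene_id=g.gene_id,
                mod_type=mod_type,
                n_methylated=n,
                gene_length=g.length,
                density=n / g.length,
                feature_class=g.feature_class,
                cog_category=g.cog_category,
            )
        )
    return records


def flag_top(
    records: Sequence[DensityRecord], fraction: float = DEFAULT_TOP_FRACTION
) -> list[DensityRecord]:
    """Flag exactly ``ceil(fraction * N)`` densest genes as hypermethylated.

    Ties at the cutoff are broken by gene_id lexicographic order so the
    flagged set is deterministic.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    records = list(records)
    if not records:
        return []
    k = math.ceil(fraction * len(records))
    order = sorted(records, key=lambda r: (-r.density, r.gene_id))
    top_ids = {r.gene_id for r in order[:k]}
    return [replace(r, is_top=r.gene_id in top_ids) for r in records]


# ---------------------------------------------------------------------------
# windowed density
# ---------------------------------------------------------------------------

@dataclass
class WindowDensity:
    contig: str
    window_start: int
    mod_type: str
    mean_raw_pm: float | None
    n_positions: int


def window_density(
    pm_values: Iterable[tuple[int, float]],
    genome_length: int,
    window: int = DEFAULT_WINDOW,
    contig: str = "contig_1",
    mod_type: str = "6mA",
) -> list[WindowDensity]:
    """Mean raw Percent Modified per tiling window of ``window`` bases.

    ``pm_values`` are (position, percent_modified) pairs, both strands
    pooled; the mean is taken over positions that have a value (windows
    without any are emitted with ``mean_raw_pm=None``).  The final partial
    window is included.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    pairs = list(pm_values)
    n_windows = max(1, math.ceil(genome_length / window))
    sums = np.zeros(n_windows)
    counts = np.zeros(n_windows, dtype=int)
    for pos, pm in pairs:
        w = pos // window
        if 0 <= w < n_windows:
            sums[w] += pm
            counts[w] += 1
    return [
        WindowDensity(
            contig, w * window, mod_type,
            (sums[w] / counts[w]) if counts[w] else None, int(counts[w]),
        )
        for w in range(n_windows)
    ]


# ---------------------------------------------------------------------------
# PM histograms per feature class
# ---------------------------------------------------------------------------

def pm_histogram(
    pm_values: Iterable[tuple[int, float]],
    genes: Sequence[GeneFeature],
    bins: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Normalised Percent Modified distribution per feature class.

    ``bins`` must monotonically cover [0.1, 1.0] (default: nine 0.1-wide
    bins); values below 0.1 are excluded.  Returns (proportions frame
    indexed by feature class, bin edges).
    """
    edges = np.asarray(bins if bins is not None else np.linspace(0.1, 1.0, 10))
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    pairs = [(p, v) for p, v in pm_values if v >= edges[0]]
    positions = np.array([p for p, _ in pairs], dtype=int)
    values = np.array([v for _, v in pairs], dtype=float)

    rows = {}
    classes = sorted({g.feature_class for g in genes})
    for fclass in classes:
        mask = np.zeros(len(positions), dtype=bool)
        for g in genes:
            if g.feature_class == fclass:
                mask |= (positions >= g.start) & (positions < g.end)
        vals = values[mask]
        hist, _ = np.histogram(vals, bins=edges)
        total = hist.sum()
        rows[fclass] = hist / total if total else np.zeros(len(edges) - 1)
    labels = [f"[{edges[i]:.2f},{edges[i + 1]:.2f})" for i in range(len(edges) - 1)]
    return pd.DataFrame.from_dict(rows, orient="index", columns=labels), edges


# ---------------------------------------------------------------------------
# promoter / gene-start / gene-end regions
# ---------------------------------------------------------------------------

Interval = tuple[int, int]


@dataclass(frozen=True)
class GeneRegions:
    gene_id: str
    promoter: Interval
    start_region: Interval
    end_region: Interval


@dataclass
class RegionSet:
    """Strand-aware promoter/start/end intervals for a gene set."""

    per_gene: list[GeneRegions]
    flank: int

    def category_intervals(self, category: str) -> list[Interval]:
        attr = {"promoter": "promoter", "start": "start_region",
                "end": "end_region"}[category]
        return [
            getattr(g, attr) for g in self.per_gene
            if getattr(g, attr)[1] > getattr(g, attr)[0]
        ]

    def all_intervals(self) -> list[Interval]:
        out = []
        for cat in ("promoter", "start", "end"):
            out.extend(self.category_intervals(cat))
        return out


def _merge(intervals: Iterable[Interval]) -> list[Interval]:
    ivs = sorted(i for i in intervals if i[1] > i[0])
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _union_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in _merge(intervals))


def define_regions(
    genes: Sequence[GeneFeature],
    flank: int = DEFAULT_REGION_FLANK,
    contig_lengths: Mapping[str, int] | None = None,
) -> RegionSet:
    """Promoter, gene-start and gene-end intervals for each stranded gene.

    For a plus-strand gene [s, e): promoter [s-flank, s), start [s, s+flank),
    end [e-flank, e); mirrored for minus-strand genes.  Intervals are
    clipped to the contig, and start/end regions never extend beyond the
    gene itself (they may overlap for genes shorter than 2*flank).
    Strandless features (e.g. ori) carry no regions.
    """
    per_gene = []
    for g in genes:
        if g.strand not in "+-":
            continue
        L = None
        if contig_lengths is not None:
            L = contig_lengths.get(g.contig)

        def clip(a: int, b: int) -> Interval:
            a = max(0, a)
            if L is not None:
                b = min(b, L)
            return (a, max(a, b))

        if g.strand == "+":
            promoter = clip(g.start - flank, g.start)
            start_region = clip(g.start, min(g.start + flank, g.end))
            end_region = clip(max(g.end - flank, g.start), g.end)
        else:
            promoter = clip(g.end, g.end + flank)
            start_region = clip(max(g.end - flank, g.start), g.end)
            end_region = clip(g.start, min(g.start + flank, g.end))
        per_gene.append(GeneRegions(g.gene_id, promoter, start_region, end_region))
    return RegionSet(per_gene, flank)


def genome_region_fraction(regions: RegionSet, genome_length: int) -> float:
    """Fraction of the genome inside any promoter/start/end interval (union)."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    return _union_length(regions.all_intervals()) / genome_length


def positions_in_intervals(positions: Sequence[int], intervals: Iterable[Interval]):
    """Boolean mask: which positions fall in the merged interval union."""
    merged = _merge(intervals)
    pos = np.asarray(positions, dtype=int)
    mask = np.zeros(len(pos), dtype=bool)
    if not merged:
        return mask
    starts = np.array([s for s, _ in merged])
    ends = np.array([e for _, e in merged])
    idx = np.searchsorted(starts, pos, side="right") - 1
    valid = idx >= 0
    mask[valid] = pos[valid] < ends[idx[valid]]
    return mask


def region_membership_fractions(
    positions: Sequence[int], regions: RegionSet
) -> dict[str, float]:
    """Per-category fraction of positions inside promoter/start/end regions.

    A position in several categories counts once in each; fractions are
    therefore reported separately and need not sum to <= 1.  Empty input
    yields zero fractions.
    """
    n = len(positions)
    out = {}
    for cat in ("promoter", "start", "end"):
        if n == 0:
            out[cat] = 0.0
        else:
            mask = positions_in_intervals(positions, regions.category_intervals(cat))
            out[cat] = float(mask.sum()) / n
    return out


def motif_region_proportions(
    motif_occurrence_pairs: Sequence[tuple[object, Sequence]],
    calls: Iterable,
    regions: RegionSet,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Per motif meth site, the proportion of its methylated bases that fall
    in promoter / gene-start / gene-end regions.

    ``motif_occurrence_pairs`` is a list of (Motif, occurrences); membership
    is judged by the methylated base's position, not the motif span.
    """
    from .motifs import index_calls

    call_index = index_calls(calls)
    rows = []
    for motif, occurrences in motif_occurrence_pairs:
        for site in motif.meth_sites:
            positions = []
            for occ in occurrences:
                so = next(s for s in occ.sites if s.site == site)
                call = call_index.get((so.position, so.strand, site.mod_type))
                if (
                    call is not None
                    and call.percent_modified is not None
                    and call.percent_modified > threshold
                ):
                    positions.append(so.position)
            fr = region_membership_fractions(positions, regions)
            rows.append(
                {
                    "motif": motif.render(),
                    "offset": site.offset,
                    "mod_type": site.mod_type,
                    "n_methylated": len(positions),
                    "promoter": fr["promoter"],
                    "start": fr["start"],
                    "end": fr["end"],
                }
            )
    return pd.DataFrame(
        rows,
        columns=["motif", "offset", "mod_type", "n_methylated",
                 "promoter", "start", "end"],
    )


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def density_table(records: Sequence[DensityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id, "cog": r.cog_category or "",
                "feature_class": r.feature_class, "mod_type": r.mod_type,
                "n_methylated": r.n_methylated, "gene_length": r.gene_length,
                "density": r.density, "is_top": int(r.is_top),
            }
            for r in records
        ],
        columns=["gene_id", "cog", "feature_class", "mod_type",
                 "n_methylated", "gene_length", "density", "is_top"],
    )


def window_table(windows: Sequence[WindowDensity]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig": w.contig, "window_start": w.window_start,
                "mod_type": w.mod_type,
                "mean_raw_pm": "" if w.mean_raw_pm is None
                else f"{w.mean_raw_pm:.6f}",
                "n_positions": w.n_positions,
            }
            for w in windows
        ],
        columns=["contig", "window_start", "mod_type", "mean_raw_pm",
                 "n_positions"],
    )
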
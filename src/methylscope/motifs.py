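"""Methylation motif representation, scanning, and summarisation.

Bacterial DNA methylation is motif-driven: a methyltransferase recognises a
short (possibly degenerate, possibly bipartite) sequence and modifies a
specific base within it, on one or both strands.  This module provides the
:class:`Motif` container with explicit per-site bookkeeping (offset,
modification type, strand), an IUPAC-aware genome scanner that reports
occurrences on both strands, summaries of how often each methylatable site
is actually called methylated, and a simple greedy de novo motif finder.

Conventions
-----------
* Coordinates are 0-based; occurrence ``start`` is always a plus-strand
  coordinate, also for minus-strand occurrences.
* A meth site with ``on_reverse=True`` sits on the strand opposite the
  pattern's orientation.  In reports such a base is rendered with a trailing
  ``*`` (e.g. ``GAT*C`` for the Dam palindrome, where the adenine opposite
  the T is methylated on the complementary strand).
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MOD_TYPES = ("6mA", "5mC", "4mC")

#: Modkit-style single-letter / ChEBI codes used in bedMethyl column 4.
MOD_TYPE_TO_CODE = {"6mA": "a", "5mC": "m", "4mC": "21839"}
MOD_CODE_TO_TYPE = {v: k for k, v in MOD_TYPE_TO_CODE.items()}

#: Canonical (unmodified) base carrying each modification.
MOD_TYPE_BASE = {"6mA": "A", "5mC": "C", "4mC": "C"}

IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
IUPAC_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_EXPANSION.items()}

IUPAC_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_DNA_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC letters allowed)."""
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def iupac_match(pattern_char: str, base: str) -> bool:
    """True iff ``base`` belongs to the IUPAC expansion of ``pattern_char``.

    Genome-side ambiguity letters other than the exact pattern character
    only match ``N`` (conservative behaviour on masked assemblies): a masked
    ``R`` in the genome matches pattern ``N`` but not pattern ``R`` or ``A``.
    """
    try:
        expansion = IUPAC_EXPANSION[pattern_char]
    except KeyError:
        raise ValueError(f"unknown IUPAC character {pattern_char!r}") from None
    if base not in IUPAC_EXPANSION:
        raise ValueError(f"unknown base {base!r}")
    if base in "ACGT":
        return base in expansion
    return expansion == IUPAC_EXPANSION["N"]


@dataclass(frozen=True)
class MethSite:
    """One methylatable base within a motif pattern."""

    offset: int
    mod_type: str
    on_reverse: bool = False

    def __post_init__(self) -> None:
        if self.mod_type not in MOD_TYPES:
            raise ValueError(f"unknown modification type {self.mod_type!r}")


@dataclass(frozen=True)
class Motif:
    """IUPAC motif plus the positions/types/strands of its methylated bases."""

    pattern: str
    meth_sites: tuple[MethSite, ...] = ()

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        for ch in self.pattern:
            if ch not in IUPAC_EXPANSION:
                raise ValueError(f"invalid IUPAC character {ch!r} in {self.pattern!r}")
        object.__setattr__(self, "meth_sites", tuple(self.meth_sites))
        for site in self.meth_sites:
            if not 0 <= site.offset < len(self.pattern):
                raise ValueError(
                    f"meth site offset {site.offset} outside pattern {self.pattern!r}"
                )
            ch = self.pattern[site.offset]
            if site.on_reverse:
                ch = IUPAC_COMPLEMENT[ch]
            needed = MOD_TYPE_BASE[site.mod_type]
            if needed not in IUPAC_EXPANSION[ch]:
                raise ValueError(
                    f"{site.mod_type} at offset {site.offset} of {self.pattern!r} "
                    f"(strand-adjusted base {ch!r}) cannot carry base {needed}"
                )

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def is_palindromic(self) -> bool:
        return self.pattern == reverse_complement(self.pattern)

    def reverse_complement(self) -> "Motif":
        """Motif as seen on the opposite strand; an involution."""
        L = len(self.pattern)
        sites = tuple(
            MethSite(L - 1 - s.offset, s.mod_type, not s.on_reverse)
            for s in self.meth_sites
        )
        return Motif(reverse_complement(self.pattern), sites)

    def render(self, mark_palindromic_partner: bool = True) -> str:
        """Pattern string with ``*`` after bases methylated on the complement.

        For palindromic motifs the mirrored position implicitly carries the
        same modification on the opposite strand; with
        ``mark_palindromic_partner`` that implied base is starred as well, so
        ``GATC`` (6mA at offset 1) renders as ``GAT*C`` and ``CCWGG`` (5mC at
        offset 1) as ``CCWG*G``.
        """
        starred = {s.offset for s in self.meth_sites if s.on_reverse}
        if mark_palindromic_partner and self.is_palindromic:
            L = len(self.pattern)
            for s in self.meth_sites:
                if not s.on_reverse:
                    starred.add(L - 1 - s.offset)
        out = []
        for i, ch in enumerate(self.pattern):
            out.append(ch)
            if i in starred:
                out.append("*")
        return "".join(out)

    def site_label(self, site: MethSite) -> str:
        strand = "-" if site.on_reverse else "+"
        return f"{self.pattern}:{site.offset}{strand}:{site.mod_type}"


@dataclass(frozen=True)
class SiteOccurrence:
    """Genomic location of one methylatable base of one motif occurrence."""

    site: MethSite
    position: int
    strand: str


@dataclass(frozen=True)
class MotifOccurrence:
    """A single match of a motif on the genome.

    ``strand`` is the orientation in which the pattern matches; ``start`` is
    the plus-strand coordinate of the leftmost matched base either way.
    """

    contig: str
    start: int
    strand: str
    motif: Motif
    sites: tuple[SiteOccurrence, ...] = ()


def _pattern_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern:
        exp = sorted(IUPAC_EXPANSION[ch])
        # genome-side non-ACGT letters only match pattern N
        if ch == "N":
            exp = sorted(IUPAC_EXPANSION.keys())
        parts.append("[" + "".join(exp) + "]" if len(exp) > 1 else exp[0])
    return re.compile("(?=" + "".join(parts) + ")")


def _site_occurrences(motif: Motif, start: int, strand: str) -> tuple[SiteOccurrence, ...]:
    L = len(motif.pattern)
    out = []
    for s in motif.meth_sites:
        if strand == "+":
            pos = start + s.offset
            st = "-" if s.on_reverse else "+"
        else:
            pos = start + (L - 1 - s.offset)
            st = "+" if s.on_reverse else "-"
        out.append(SiteOccurrence(s, pos, st))
    return tuple(out)


def scan(genome: str, motif: Motif, contig: str = "contig_1") -> list[MotifOccurrence]:
    """All occurrences of ``motif`` on both strands of ``genome``.

    Plus-strand matches of the pattern are reported with strand ``+``;
    plus-strand matches of its reverse complement with strand ``-``.
    Palindromic motifs therefore yield two occurrences per start, carrying
    the meth sites of each strand.  Overlapping occurrences are all
    reported.
    """
    genome = genome.upper()
    occurrences: list[MotifOccurrence] = []
    for strand, m in (("+", motif), ("-", motif.reverse_complement())):
        rx = _pattern_regex(m.pattern)
        for hit in rx.finditer(genome):
            start = hit.start()
            occurrences.append(
                MotifOccurrence(
                    contig, start, strand, motif,
                    _site_occurrences(motif, start, strand),
                )
            )
    occurrences.sort(key=lambda o: (o.start, o.strand))
    return occurrences


@dataclass
class SiteSummary:
    """Methylation summary for one meth site of a motif across occurrences."""

    motif: Motif
    site: MethSite
    n_occurrences: int
    n_methylated: int
    n_no_data: int
    mean_percent_modified: float | None

    @property
    def fraction_methylated(self) -> float | None:
        """Methylated occurrences over all occurrences (no-data counted unmethylated)."""
        if self.n_occurrences == 0:
            return None
        return self.n_methylated / self.n_occurrences

    @property
    def fraction_methylated_with_data(self) -> float | None:
        n = self.n_occurrences - self.n_no_data
        return self.n_methylated / n if n else None


@dataclass
class MotifSummary:
    motif: Motif
    n_occurrences: int
    site_summaries: list[SiteSummary]
    threshold: float


CallIndex = Mapping[tuple[int, str, str], "object"]


def index_calls(calls: Iterable) -> dict[tuple[int, str, str], object]:
    """Index methylation calls by (position, strand, mod_type)."""
    return {(c.position, c.strand, c.mod_type): c for c in calls}


def summarize_motif(
    occurrences: Sequence[MotifOccurrence],
    calls: CallIndex | Iterable,
    threshold: float = 0.5,
) -> MotifSummary:
    """Per-meth-site methylation fractions over a motif's occurrences.

    A site counts as methylated when its position has a call with
    ``percent_modified`` strictly above ``threshold``; occurrences whose
    base has no pileup call count as unmethylated and are additionally
    flagged as no-data.
    """
    if not isinstance(calls, Mapping):
        calls = index_calls(calls)
    if not occurrences:
        return MotifSummary(None, 0, [], threshold)  # type: ignore[arg-type]
    motif = occurrences[0].motif
    summaries = []
    for site in motif.meth_sites:
        n_meth = n_nodata = 0
        pms: list[float] = []
        for occ in occurrences:
            so = next(s for s in occ.sites if s.site == site)
            call = calls.get((so.position, so.strand, site.mod_type))
            if call is None or call.percent_modified is None:
                n_nodata += 1
                continue
            pms.append(call.percent_modified)
            if call.percent_modified > threshold:
                n_meth += 1
        summaries.append(
            SiteSummary(
                motif, site, len(occurrences), n_meth, n_nodata,
                float(np.mean(pms)) if pms else None,
            )
        )
    return MotifSummary(motif, len(occurrences), summaries, threshold)


def evaluate_motif(
    genome: str,
    calls: CallIndex | Iterable,
    motif: Motif,
    threshold: float = 0.5,
    contig: str = "contig_1",
) -> MotifSummary:
    """Scan ``motif`` and summarise its methylation state in one step.

    The user-facing verb for assessing a candidate motif (e.g. ``TGGCCA`` or
    ``TCGA``) against an existing call set.
    """
    occ = scan(genome, motif, contig=contig)
    summary = summarize_motif(occ, calls, threshold=threshold)
    if not occ:
        summary = MotifSummary(motif, 0, [], threshold)
    return summary


def fraction_explained(
    calls: Iterable,
    occurrence_lists: Sequence[Sequence[MotifOccurrence]],
    mod_type: str,
) -> float | None:
    """Fraction of methylated bases of ``mod_type`` that lie inside a motif.

    Measures how much of the genome-wide methylation signal the supplied
    motif set accounts for; 1.0 means every methylated base coincides with
    some motif's methylatable position.  Returns None when no base of the
    type is methylated.
    """
    meth = {
        (c.position, c.strand)
        for c in calls
        if c.mod_type == mod_type and c.is_methylated
    }
    if not meth:
        return None
    in_motif = set()
    for occs in occurrence_lists:
        for occ in occs:
            for so in occ.sites:
                if so.site.mod_type == mod_type:
                    in_motif.add((so.position, so.strand))
    return len(meth & in_motif) / len(meth)


# ---------------------------------------------------------------------------
# de novo motif discovery
# ---------------------------------------------------------------------------

def _merge_one_column(patterns: dict[str, set[int]]) -> dict[str, set[int]]:
    """Merge patterns differing at exactly one column into IUPAC codes."""
    merged = dict(patterns)
    changed = True
    while changed:
        changed = False
        items = sorted(merged)
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                if a not in merged or b not in merged or len(a) != len(b):
                    continue
                diff = [k for k in range(len(a)) if a[k] != b[k]]
                if len(diff) != 1:
                    continue
                k = diff[0]
                union = IUPAC_EXPANSION[a[k]] | IUPAC_EXPANSION[b[k]]
                new = a[:k] + IUPAC_CODE[frozenset(union)] + a[k + 1:]
                sites = merged.pop(a) | merged.pop(b)
                merged[new] = merged.get(new, set()) | sites
                changed = True
                break
            if changed:
                break
    return merged


def find_motifs_denovo(
    genome: str,
    calls: Iterable,
    mod_type: str,
    context_k: int = 10,
    min_sites: int = 50,
    min_fold: float = 4.0,
) -> list[Motif]:
    """Greedy discovery of enriched motifs around methylated bases.

    Extracts the +/-``context_k`` reference context of every methylated base
    (reverse-complemented for minus-strand calls so the modified base is
    centred in canonical orientation), counts exact w-mers anchored on the
    modified base for widths 4..``context_k``, keeps words with
    fold-enrichment >= ``min_fold`` over the genome-composition expectation
    and support >= ``min_sites``, merges words differing in a single column
    into IUPAC degenerate codes, and returns maximal non-redundant motifs
    with the methylated offset recorded.
    """
    genome = genome.upper()
    meth = [c for c in calls if c.mod_type == mod_type and c.is_methylated]
    if len(meth) < min_sites:
        logger.warning(
            "only %d methylated %s sites (< min_sites=%d); no motifs reported",
            len(meth), mod_type, min_sites,
        )
        return []

    L = len(genome)
    contexts: list[str] = []
    for c in meth:
        lo, hi = c.position - context_k, c.position + context_k + 1
        if lo < 0 or hi > L:
            continue
        window = genome[lo:hi]
        if c.strand == "-":
            window = reverse_complement(window)
        contexts.append(window)
    n_sites = len(contexts)
    if n_sites < min_sites:
        return []

    base_freq = Counter(genome)
    total = sum(base_freq[b] for b in "ACGT")
    p = {b: base_freq[b] / total for b in "ACGT"}

    # candidate words per (start offset rel. centre, width)
    candidates: dict[tuple[str, int], set[int]] = {}
    for w in range(4, context_k + 1):
        for start_off in range(-w + 1, 1):
            words: dict[str, set[int]] = {}
            a = context_k + start_off
            for idx, ctx in enumerate(contexts):
                word = ctx[a:a + w]
                if any(ch not in "ACGT" for ch in word):
                    continue
                words.setdefault(word, set()).add(idx)
            centre = -start_off  # index of modified base inside the word
            kept = {}
            for word, idxs in words.items():
                if len(idxs) < min_sites:
                    continue
                # expectation conditions on the (fixed) modified base
                exp = n_sites * float(
                    np.prod([p[ch] for i, ch in enumerate(word) if i != centre])
                )
                if exp > 0 and len(idxs) / exp >= min_fold:
                    kept[word] = idxs
            for word, idxs in _merge_one_column(kept).items():
                # trim uninformative N columns at the edges
                lo_t, hi_t = 0, len(word)
                while lo_t < hi_t and word[lo_t] == "N" and lo_t != centre:
                    lo_t += 1
                while hi_t > lo_t and word[hi_t - 1] == "N" and hi_t - 1 != centre:
                    hi_t -= 1
                trimmed = word[lo_t:hi_t]
                off = centre - lo_t
                if len(trimmed) < 4:
                    continue
                key = (trimmed, off)
                candidates[key] = candidates.get(key, set()) | idxs

    # maximal non-redundant selection, deterministic ordering
    def specificity(pat: str) -> float:
        return sum(2.0 - np.log2(len(IUPAC_EXPANSION[ch])) for ch in pat)

    ranked = sorted(
        candidates.items(),
        key=lambda kv: (-len(kv[1]), -specificity(kv[0][0]), -len(kv[0][0]), kv[0]),
    )
    covered: set[int] = set()
    motifs: list[Motif] = []
    for (pat, off), idxs in ranked:
        if len(idxs - covered) < min_sites:
            continue
        motifs.append(Motif(pat, (MethSite(off, mod_type, False),)))
        covered |= idxs
    return motifs


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

MOTIF_TABLE_COLUMNS = ["pattern", "offset", "mod_type", "on_reverse"]


def read_motif_table(path) -> list[Motif]:
    """Read a motif spec TSV (pattern, offset, mod_type, on_reverse)."""
    df = pd.read_csv(path, sep="\t", dtype={"pattern": str})
    motifs = []
    for pattern, grp in df.groupby("pattern", sort=False):
        sites = tuple(
            MethSite(int(r.offset), str(r.mod_type), bool(r.on_reverse))
            for r in grp.itertuples()
        )
        motifs.append(Motif(str(pattern), sites))
    return motifs


def write_motif_table(motifs: Sequence[Motif], path) -> None:
    rows = [
        {"pattern": m.pattern, "offset": s.offset, "mod_type": s.mod_type,
         "on_reverse": s.on_reverse}
        for m in motifs for s in m.meth_sites
    ]
    pd.DataFrame(rows, columns=MOTIF_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def occurrences_to_bed(occurrences: Sequence[MotifOccurrence]) -> pd.DataFrame:
    """Occurrence list as a 0-based BED-like frame (name = motif pattern)."""
    rows = [
        {
            "chrom": o.contig,
            "start": o.start,
            "end": o.start + len(o.motif.pattern),
            "name": o.motif.pattern,
            "score": 0,
            "strand": o.strand,
        }
        for o in occurrences
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )


def summary_table(summaries: Sequence[MotifSummary]) -> pd.DataFrame:
    """Flat per-meth-site summary table (one row per site, heatmap-style)."""
    rows = []
    for ms in summaries:
        for ss in ms.site_summaries:
            rows.append(
                {
                    "motif": ms.motif.render(),
                    "pattern": ms.motif.pattern,
                    "offset": ss.site.offset,
                    "mod_type": ss.site.mod_type,
                    "on_reverse": ss.site.on_reverse,
                    "n_occurrences": ss.n_occurrences,
                    "n_methylated": ss.n_methylated,
                    "n_no_data": ss.n_no_data,
                    "fraction_methylated": ss.fraction_methylated,
                    "fraction_methylated_with_data": ss.fraction_methylated_with_data,
                    "mean_percent_modified": ss.mean_percent_modified,
                }
            )
    return pd.DataFrame(rows)
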
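"""bedMethyl pileup records and per-position methylation statistics.

A modified-base pileup summarises, per (position, strand, modification
code), how many aligned reads were called modified, canonical, filtered out
by the basecaller's confidence threshold, or mismatching the canonical
base.  Two statistics are computed from those counts:

* ``Fraction Modified``  = N_mod / N_valid_cov
* ``Percent Modified``   = N_mod / (N_valid_cov + N_fail + N_diff)

Fraction Modified only looks at confidently classified reads and is prone
to false positives at positions where few reads pass the confidence filter;
Percent Modified counts filtered-out and mismatching reads in the
denominator and therefore measures agreement among *all* reads covering the
position.  A position is called methylated when Percent Modified is
strictly above the call threshold (default 0.5; 0.3 is a useful lower
setting for partially modified motifs).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .motifs import MOD_CODE_TO_TYPE

#: Default Modkit-style confidence filter threshold; the pileups consumed
#: here were produced upstream with this setting, so it is provenance
#: metadata rather than a parameter of any computation in this module.
FILTER_THRESHOLD = 0.75

DEFAULT_CALL_THRESHOLD = 0.5
LOW_CALL_THRESHOLD = 0.3
DEFAULT_MIN_TOTAL_READS = 5

BEDMETHYL_COLUMNS = [
    "chrom", "start", "end", "mod_code", "score", "strand",
    "thick_start", "thick_end", "color",
    "n_valid_cov", "fraction_pct", "n_mod", "n_canonical", "n_other_mod",
    "n_delete", "n_fail", "n_diff", "n_nocall",
]

_KNOWN_MOD_CODES = set(MOD_CODE_TO_TYPE)


class BedMethylParseError(ValueError):
    """Raised for malformed bedMethyl input; message names the line."""


@dataclass
class PileupRecord:
    """One strand-specific genomic position's modification counts.

    Coordinates are 0-based half-open (``end == start + 1``).  ``mod_code``
    is ``a`` (6mA), ``m`` (5mC) or ``21839`` (4mC); other codes are carried
    through but flagged by the reader.  ``n_valid_cov`` is the number of
    reads classified modified or canonical after the upstream confidence
    filter.
    """

    contig: str
    start: int
    mod_code: str
    strand: str
    n_valid_cov: int
    n_mod: int
    n_canonical: int
    n_other_mod: int = 0
    n_delete: int = 0
    n_fail: int = 0
    n_diff: int = 0
    n_nocall: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_valid_cov, self.n_mod, self.n_canonical, self.n_other_mod,
            self.n_delete, self.n_fail, self.n_diff, self.n_nocall,
        )
        if any(c < 0 for c in counts):
            raise ValueError(f"negative count in record at {self.contig}:{self.start}")
        if self.n_valid_cov != self.n_mod + self.n_canonical + self.n_other_mod:
            raise ValueError(
                f"n_valid_cov != n_mod + n_canonical + n_other_mod at "
                f"{self.contig}:{self.start}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def end(self) -> int:
        return self.start + 1

    @property
    def mod_type(self) -> str | None:
        return MOD_CODE_TO_TYPE.get(self.mod_code)

    @property
    def total_depth(self) -> int:
        return (
            self.n_valid_cov + self.n_delete + self.n_fail
            + self.n_diff + self.n_nocall
        )


@dataclass
class MethylationCall:
    """Fraction/Percent Modified values and binary status for one position."""

    contig: str
    position: int
    strand: str
    mod_type: str
    fraction_modified: float | None
    percent_modified: float | None
    is_methylated: bool | None
    n_valid_cov: int
    low_coverage: bool = False
    threshold: float = DEFAULT_CALL_THRESHOLD


def fraction_modified(rec: PileupRecord) -> float | None:
    """N_mod / N_valid_cov; None when no read passed the confidence filter."""
    if rec.n_valid_cov == 0:
        return None
    return rec.n_mod / rec.n_valid_cov


def percent_modified(rec: PileupRecord) -> float | None:
    """N_mod / (N_valid_cov + N_fail + N_diff); None on a zero denominator.

    Filtered (``n_fail``) and mismatching (``n_diff``) reads enter the
    denominator only; deletions and no-calls do not (and ``n_other_mod`` is
    already inside ``n_valid_cov``, so it is not added again).
    """
    denom = rec.n_valid_cov + rec.n_fail + rec.n_diff
    if denom == 0:
        return None
    return rec.n_mod / denom


def call_methylation(
    records: Iterable[PileupRecord],
    threshold: float = DEFAULT_CALL_THRESHOLD,
    min_total_reads: int = DEFAULT_MIN_TOTAL_READS,
) -> list[MethylationCall]:
    """Call per-position methylation status from pileup records.

    ``is_methylated`` is True iff Percent Modified is *strictly* above
    ``threshold``.  Records with total depth below ``min_total_reads`` are
    emitted with ``is_methylated=None`` and ``low_coverage=True``; records
    whose Percent Modified is undefined (zero denominator) are skipped.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    calls = []
    for rec in records:
        pm = percent_modified(rec)
        if pm is None:
            continue
        fm = fraction_modified(rec)
        mod_type = rec.mod_type
        if mod_type is None:
            continue
        low = rec.total_depth < min_total_reads
        calls.append(
            MethylationCall(
                contig=rec.contig,
                position=rec.start,
                strand=rec.strand,
                mod_type=mod_type,
                fraction_modified=fm,
                percent_modified=pm,
                is_methylated=None if low else pm > threshold,
                n_valid_cov=rec.n_valid_cov,
                low_coverage=low,
                threshold=threshold,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# I/O — 18-column Modkit-dialect bedMethyl and a flat calls TSV
# ---------------------------------------------------------------------------

def read_bedmethyl(path) -> list[PileupRecord]:
    """Read an 18-column tab-separated bedMethyl file.

    Raises :class:`BedMethylParseError` naming the offending line for
    column-count mismatches or negative counts.  Rows with an unknown
    modification code are kept but reported via a flag on the record's
    ``mod_type`` (None) and a summary warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=BEDMETHYL_COLUMNS,
            dtype={"chrom": str, "mod_code": str, "strand": str},
            comment="#",
        )
    except pd.errors.ParserError as exc:
        raise BedMethylParseError(f"{path}: {exc}") from exc
    if df.empty:
        return []
    if df[BEDMETHYL_COLUMNS[-1]].isna().any():
        line = int(df[df[BEDMETHYL_COLUMNS[-1]].isna()].index[0]) + 1
        raise BedMethylParseError(
            f"{path} line {line}: expected 18 tab-separated columns"
        )
    count_cols = BEDMETHYL_COLUMNS[9:10] + BEDMETHYL_COLUMNS[11:]
    for col in count_cols:
        bad = df.index[df[col] < 0]
        if len(bad):
            raise BedMethylParseError(
                f"{path} line {int(bad[0]) + 1}: negative count in column {col}"
            )
    records = []
    for row in df.itertuples(index=True):
        try:
            records.append(
                PileupRecord(
                    contig=row.chrom,
                    start=int(row.start),
                    mod_code=str(row.mod_code),
                    strand=str(row.strand),
                    n_valid_cov=int(row.n_valid_cov),
                    n_mod=int(row.n_mod),
                    n_canonical=int(row.n_canonical),
                    n_other_mod=int(row.n_other_mod),
                    n_delete=int(row.n_delete),
                    n_fail=int(row.n_fail),
                    n_diff=int(row.n_diff),
                    n_nocall=int(row.n_nocall),
                )
            )
        except ValueError as exc:
            raise BedMethylParseError(f"{path} line {row.Index + 1}: {exc}") from exc
    unknown = {r.mod_code for r in records} - _KNOWN_MOD_CODES
    if unknown:
        import logging
        logging.getLogger(__name__).warning(
            "%s: unknown modification codes %s preserved but not analysed",
            path, sorted(unknown),
        )
    return records


def write_bedmethyl(records: Sequence[PileupRecord], path) -> None:
    """Write records in the 18-column dialect (tab-separated, no header)."""
    rows = []
    for r in records:
        fm = fraction_modified(r)
        rows.append(
            (
                r.contig, r.start, r.end, r.mod_code,
                min(r.n_valid_cov, 1000), r.strand,
                r.start, r.end, "255,0,0",
                r.n_valid_cov, f"{(fm or 0.0) * 100:.2f}",
                r.n_mod, r.n_canonical, r.n_other_mod,
                r.n_delete, r.n_fail, r.n_diff, r.n_nocall,
            )
        )
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


CALLS_COLUMNS = [
    "contig", "position", "strand", "mod_type",
    "fraction_modified", "percent_modified", "is_methylated",
    "n_valid_cov", "low_coverage",
]


def write_calls(calls: Sequence[MethylationCall], path) -> None:
    rows = [
        {
            "contig": c.contig,
            "position": c.position,
            "strand": c.strand,
            "mod_type": c.mod_type,
            "fraction_modified": "" if c.fraction_modified is None
            else f"{c.fraction_modified:.6f}",
            "percent_modified": "" if c.percent_modified is None
            else f"{c.percent_modified:.6f}",
            "is_methylated": "" if c.is_methylated is None else int(c.is_methylated),
            "n_valid_cov": c.n_valid_cov,
            "low_coverage": int(c.low_coverage),
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=CALLS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_calls(path) -> list[MethylationCall]:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "strand": str})
    calls = []
    for row in df.itertuples():
        is_meth = row.is_methylated
        calls.append(
            MethylationCall(
                contig=row.contig,
                position=int(row.position),
                strand=row.strand,
                mod_type=row.mod_type,
                fraction_modified=None if pd.isna(row.fraction_modified)
                else float(row.fraction_modified),
                percent_modified=None if pd.isna(row.percent_modified)
                else float(row.percent_modified),
                is_methylated=None if pd.isna(is_meth) else bool(int(is_meth)),
                n_valid_cov=int(row.n_valid_cov),
                low_coverage=bool(int(row.low_coverage)),
            )
        )
    return calls
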
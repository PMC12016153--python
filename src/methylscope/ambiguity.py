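"""Strand-specific basecalling ambiguities induced by 6mA methylation.

Nanopore basecalls near a methylated adenine are error-prone on the strand
carrying the modification: the G immediately 5' of a 6mA is often miscalled
as A, producing positions where reads disagree — an R (A/G mixture) on the
plus strand, or, when the modification sits on the minus strand, a Y (C/T
mixture) as seen from the plus reference.  This module detects such mixed
positions from strand-split basecall counts, classifies them R/Y, links
them to the adjacent methylated adenine, masks them in the genome with
their IUPAC code, and extracts the surrounding sequence context as a
position frequency matrix for DNA-logo display.

The count table convention follows the simulator: basecalls of minus-strand
reads are complemented to plus (reference) base space, one row per
(position, strand).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .motifs import reverse_complement

DEFAULT_MIN_COV = 10
DEFAULT_MIN_MINOR_FRAC = 0.2

_BASES = ("A", "C", "G", "T")
_CODE_PAIRS = {frozenset("AG"): "R", frozenset("CT"): "Y"}


@dataclass(frozen=True)
class StrandBaseCount:
    """Basecall counts for one (position, strand), in plus base space."""

    contig: str
    position: int
    strand: str
    nA: int
    nC: int
    nG: int
    nT: int

    def __post_init__(self) -> None:
        if min(self.nA, self.nC, self.nG, self.nT) < 0:
            raise ValueError("negative basecall count")

    @property
    def depth(self) -> int:
        return self.nA + self.nC + self.nG + self.nT

    def counts(self) -> dict[str, int]:
        return {"A": self.nA, "C": self.nC, "G": self.nG, "T": self.nT}


@dataclass
class AmbiguousSite:
    """A position with strand-specific mixed basecalls, classified R or Y."""

    contig: str
    position: int
    code: str                      # R = A/G mixture, Y = C/T mixture
    minor_fraction: float
    discordant_strand: str
    associated_meth: tuple[int, str] | None = None
    association_kind: str = "none"  # R_before_plus_6mA | Y_opposite_minus_6mA | none


def _as_frame(counts) -> pd.DataFrame:
    if isinstance(counts, pd.DataFrame):
        return counts
    return pd.DataFrame(
        [
            {
                "chrom": c.contig, "pos0": c.position, "strand": c.strand,
                "nA": c.nA, "nC": c.nC, "nG": c.nG, "nT": c.nT,
            }
            for c in counts
        ]
    )


def detect_ambiguous(
    counts,
    reference: str | None = None,
    min_cov: int = DEFAULT_MIN_COV,
    min_minor_frac: float = DEFAULT_MIN_MINOR_FRAC,
) -> list[AmbiguousSite]:
    """Positions whose two most frequent basecalls on one strand are an
    A/G (R) or C/T (Y) pair with minor fraction >= ``min_minor_frac``.

    Strands are evaluated independently at depth >= ``min_cov``; codes are
    expressed in plus-strand base space (counts are already stored that
    way, so a minus-strand A/G read mixture surfaces here as C/T = Y).
    ``counts`` may be a list of :class:`StrandBaseCount` or the simulator's
    count frame.
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    if not 0 < min_minor_frac <= 0.5:
        raise ValueError("min_minor_frac must lie in (0, 0.5]")
    df = _as_frame(counts)
    mat = df[["nA", "nC", "nG", "nT"]].to_numpy(dtype=int)
    depth = mat.sum(axis=1)
    order = np.argsort(mat, axis=1)
    top, second = order[:, -1], order[:, -2]
    top_n = mat[np.arange(len(mat)), top]
    second_n = mat[np.arange(len(mat)), second]
    with np.errstate(invalid="ignore", divide="ignore"):
        minor_frac = np.where(depth > 0, second_n / np.maximum(depth, 1), 0.0)
    eligible = (depth >= min_cov) & (second_n > 0) & (minor_frac >= min_minor_frac)

    sites: list[AmbiguousSite] = []
    for i in np.flatnonzero(eligible):
        pair = frozenset((_BASES[top[i]], _BASES[second[i]]))
        code = _CODE_PAIRS.get(pair)
        if code is None:
            continue  # other mixtures are not methylation signatures
        sites.append(
            AmbiguousSite(
                contig=str(df.iat[i, df.columns.get_loc("chrom")]),
                position=int(df.iat[i, df.columns.get_loc("pos0")]),
                code=code,
                minor_fraction=float(minor_frac[i]),
                discordant_strand=str(df.iat[i, df.columns.get_loc("strand")]),
            )
        )
    sites.sort(key=lambda s: (s.contig, s.position, s.discordant_strand))
    return sites


def associate(sites: Sequence[AmbiguousSite], calls: Iterable) -> list[AmbiguousSite]:
    """Link each ambiguous site to an adjacent methylated adenine, if any.

    An R at plus position p is linked iff a methylated 6mA call exists at
    p+1 on the plus strand; a Y at plus position q iff a methylated 6mA
    exists on the minus strand at q-1 (the minus-strand G at q has its
    5'-neighbouring adenine at plus coordinate q-1).  Only immediate
    adjacency is considered.
    """
    meth_6ma = {
        (c.position, c.strand)
        for c in calls
        if c.mod_type == "6mA" and c.is_methylated
    }
    out = []
    for s in sites:
        if s.code == "R" and (s.position + 1, "+") in meth_6ma:
            out.append(
                replace(
                    s,
                    associated_meth=(s.position + 1, "+"),
                    association_kind="R_before_plus_6mA",
                )
            )
        elif s.code == "Y" and (s.position - 1, "-") in meth_6ma:
            out.append(
                replace(
                    s,
                    associated_meth=(s.position - 1, "-"),
                    association_kind="Y_opposite_minus_6mA",
                )
            )
        else:
            out.append(replace(s, associated_meth=None, association_kind="none"))
    return out


def count_discordant(
    counts,
    reference: str | None = None,
    min_frac: float = DEFAULT_MIN_MINOR_FRAC,
    min_cov: int = DEFAULT_MIN_COV,
) -> tuple[int, list[int]]:
    """Count positions where the two strands' basecalls disagree.

    The FASTQ-only analogue of :func:`detect_ambiguous`: a position is
    discordant when, on some strand with depth >= ``min_cov``, at least
    ``min_frac`` of the reads disagree with the consensus (majority) base
    of the opposite strand, both expressed in plus base space.  Returns the
    total and the sorted positions.
    """
    df = _as_frame(counts)
    mat = df[["nA", "nC", "nG", "nT"]].to_numpy(dtype=int)
    pos = df["pos0"].to_numpy(dtype=int)
    plus = (df["strand"].to_numpy() == "+")

    pos_p, idx_p = pos[plus], np.flatnonzero(plus)
    pos_m, idx_m = pos[~plus], np.flatnonzero(~plus)
    common, ip, im = np.intersect1d(pos_p, pos_m, return_indices=True)
    a = mat[idx_p[ip]]  # plus-strand counts per shared position
    b = mat[idx_m[im]]  # minus-strand counts (plus base space)
    da, db = a.sum(axis=1), b.sum(axis=1)
    covered = (da >= min_cov) & (db >= min_cov)

    def disagreement(x, y, dx):
        consensus = y.argmax(axis=1)
        agreeing = x[np.arange(len(x)), consensus]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(dx > 0, (dx - agreeing) / np.maximum(dx, 1), 0.0)

    hit = covered & (
        (disagreement(a, b, da) >= min_frac) | (disagreement(b, a, db) >= min_frac)
    )
    discordant = sorted(int(p) for p in common[hit])
    return len(discordant), discordant


def mask_genome(genome: str, sites: Sequence[AmbiguousSite]) -> str:
    """Replace each ambiguous position's base by its IUPAC code (R/Y).

    Raises when a site's code is incompatible with the reference base pair
    (an R position must be A or G on the plus strand; Y must be C or T).
    """
    arr = list(genome)
    compatible = {"R": set("AG"), "Y": set("CT")}
    for s in sites:
        ref = arr[s.position].upper()
        if ref not in compatible[s.code]:
            raise ValueError(
                f"site at {s.position} has code {s.code} but reference base {ref}"
            )
        arr[s.position] = s.code
    return "".join(arr)


@dataclass
class ContextPFM:
    """Base-frequency matrix of the reference context around ambiguous sites."""

    k: int
    matrix: np.ndarray  # (2k+1, 4), columns A, C, G, T
    n_sites: int

    def consensus(self) -> str:
        if self.n_sites == 0:
            return ""
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix,
            index=pd.Index(range(-self.k, self.k + 1), name="offset"),
            columns=list(_BASES),
        )


def context_pfm(
    sites: Sequence[AmbiguousSite], genome: str, k: int = 5
) -> ContextPFM:
    """Reference-context position frequency matrix centred on the sites.

    Each site contributes its window [p-k, p+k], reverse-complemented when
    the discordant strand is minus so every context reads 5'->3' on the
    erroneous strand.  Rows sum to 1 when any site contributes; an empty
    site list yields a flagged all-zero matrix.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = np.zeros((2 * k + 1, 4))
    n = 0
    base_idx = {b: i for i, b in enumerate(_BASES)}
    L = len(genome)
    for s in sites:
        lo, hi = s.position - k, s.position + k + 1
        if lo < 0 or hi > L:
            continue
        window = genome[lo:hi].upper()
        if s.discordant_strand == "-":
            window = reverse_complement(window)
        if any(b not in base_idx for b in window):
            continue
        for j, b in enumerate(window):
            counts[j, base_idx[b]] += 1
        n += 1
    matrix = counts / n if n else counts
    return ContextPFM(k, matrix, n)


SITES_COLUMNS = ["contig", "pos0", "code", "minor_frac", "strand",
                 "assoc_kind", "assoc_pos"]


def sites_table(sites: Sequence[AmbiguousSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig": s.contig, "pos0": s.position, "code": s.code,
                "minor_frac": f"{s.minor_fraction:.4f}",
                "strand": s.discordant_strand,
                "assoc_kind": s.association_kind,
                "assoc_pos": "" if s.associated_meth is None
                else s.associated_meth[0],
            }
            for s in sites
        ],
        columns=SITES_COLUMNS,
    )
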
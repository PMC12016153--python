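"""IUPAC semantics, both-strand motif scanning against an independent
oracle, summaries, signal conservation, and de novo discovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylscope.motifs import (
    MethSite,
    Motif,
    evaluate_motif,
    find_motifs_denovo,
    fraction_explained,
    index_calls,
    iupac_match,
    read_motif_table,
    reverse_complement,
    scan,
    summarize_motif,
    write_motif_table,
)
from methylscope.pileup import MethylationCall, call_methylation
from methylscope.simulate import (
    MotifSpec,
    SimulationConfig,
    generate_genome,
    simulate_pileup,
)

GATC = Motif("GATC", (MethSite(1, "6mA"),))

# Recognition motifs of the restriction-modification systems detected in the
# four emulated species (asterisks stripped; spans Type I bipartite, Type II
# palindromic and Type III non-palindromic patterns).
KNOWN_PATTERNS = [
    "GATC", "CCWGG", "GACNNNNNNGTC", "AGCNNNNNCTTC", "GAAANNNNNNGGG",
    "GAAGAC", "TGGCCA", "GAAYNNNNNGTCT", "TCGA", "CAGDAC",
    "CYAANNNNNNGRTY", "GWAGNNNNNGAT", "CGANNNNNNNTCC", "GAAGNNNNNTAC",
    "CCAYNNNNNNRTC", "CCAYNNNNNNTTYG", "CCAYNNNNNNTGT", "AGGNNNNNGAT",
]

# independent IUPAC table for the oracle (typed from the standard code)
ORACLE_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
ORACLE_COMP = dict(zip("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN"))


def oracle_positions(seq: str, pattern: str) -> np.ndarray:
    """Character-by-character match at every start, vectorised over starts."""
    n, m = len(seq), len(pattern)
    if n < m:
        return np.array([], dtype=int)
    arr = np.frombuffer(seq.encode(), dtype="S1")
    ok = np.ones(n - m + 1, dtype=bool)
    for j, ch in enumerate(pattern):
        allowed = np.frombuffer(ORACLE_SETS[ch].encode(), dtype="S1")
        ok &= np.isin(arr[j:j + n - m + 1], allowed)
    return np.flatnonzero(ok)


def oracle_scan(seq: str, pattern: str) -> set[tuple[int, str]]:
    rc = "".join(ORACLE_COMP[c] for c in reversed(pattern))
    hits = {(int(p), "+") for p in oracle_positions(seq, pattern)}
    hits |= {(int(p), "-") for p in oracle_positions(seq, rc)}
    return hits


# ---------------------------------------------------------------------------
# IUPAC primitives
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "pat,base,expected",
    [("N", "G", True), ("D", "C", False), ("W", "A", True), ("R", "A", True),
     ("R", "C", False), ("Y", "T", True), ("B", "A", False), ("A", "A", True)],
)
def test_iupac_match(pat, base, expected):
    assert iupac_match(pat, base) is expected


def test_iupac_match_rejects_unknown_characters():
    with pytest.raises(ValueError):
        iupac_match("Z", "A")


def test_masked_genome_bases_match_only_n():
    # ambiguity codes in the genome (from masking) never match R/Y patterns
    assert iupac_match("N", "R")
    assert not iupac_match("R", "R")
    assert not iupac_match("A", "R")


@pytest.mark.parametrize(
    "pattern,expected",
    [("GATC", "GATC"), ("CCWGG", "CCWGG"), ("GAAGAC", "GTCTTC"),
     ("CAGDAC", "GTHCTG"), ("GAAANNNNNNGGG", "CCCNNNNNNTTTC")],
)
def test_reverse_complement_patterns(pattern, expected):
    assert reverse_complement(pattern) == expected


def test_reverse_complement_motif_remaps_sites():
    m = Motif("GAAGAC", (MethSite(4, "6mA"), MethSite(3, "4mC", True)))
    rc = m.reverse_complement()
    assert rc.pattern == "GTCTTC"
    assert {(s.offset, s.mod_type, s.on_reverse) for s in rc.meth_sites} == {
        (1, "6mA", True), (2, "4mC", False),
    }


@settings(max_examples=100, derandomize=True)
@given(st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=15),
       st.integers(0, 14))
def test_reverse_complement_is_involution(pattern, off):
    sites = ()
    if off < len(pattern) and "A" in ORACLE_SETS[pattern[off]]:
        sites = (MethSite(off, "6mA"),)
    m = Motif(pattern, sites)
    assert m.reverse_complement().reverse_complement() == m


def test_palindromy_iff_self_reverse_complement():
    assert Motif("GATC").is_palindromic
    assert Motif("CCWGG").is_palindromic
    assert not Motif("GAAGAC").is_palindromic


# ---------------------------------------------------------------------------
# Table-style asterisk rendering
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "motif,rendered",
    [
        (GATC, "GAT*C"),
        (Motif("CCWGG", (MethSite(1, "5mC"),)), "CCWG*G"),
        (Motif("GAAANNNNNNGGG", (MethSite(3, "6mA"), MethSite(11, "4mC", True))),
         "GAAANNNNNNGG*G"),
        (Motif("GAAGAC", (MethSite(4, "6mA"), MethSite(3, "4mC", True))),
         "GAAG*AC"),
        (Motif("CAGDAC", (MethSite(4, "6mA"),)), "CAGDAC"),
    ],
)
def test_complementary_strand_asterisk_rendering(motif, rendered):
    assert motif.render() == rendered


def test_meth_site_base_compatibility_enforced():
    with pytest.raises(ValueError):
        Motif("GATC", (MethSite(2, "6mA"),))  # T cannot carry 6mA on +
    # but the complement of that T can
    Motif("GATC", (MethSite(2, "6mA", on_reverse=True),))


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def test_palindrome_reported_once_per_strand_with_site_geometry():
    occs = scan("AAGATCAA", GATC)
    assert [(o.start, o.strand) for o in occs] == [(2, "+"), (2, "-")]
    plus, minus = occs
    assert (plus.sites[0].position, plus.sites[0].strand) == (3, "+")
    assert (minus.sites[0].position, minus.sites[0].strand) == (4, "-")


def test_degenerate_match():
    occs = scan("TCCAGGT", Motif("CCWGG", (MethSite(1, "5mC"),)))
    assert [(o.start, o.strand) for o in occs] == [(1, "+"), (1, "-")]


def test_bipartite_both_strand_site_coordinates():
    bip = Motif("GAAANNNNNNGGG", (MethSite(3, "6mA"), MethSite(11, "4mC", True)))
    genome = "T" + "GAAACGTACG" + "GGG" + "TT"  # GAAA + 6 spacer bases + GGG
    occs = [o for o in scan(genome, bip) if o.strand == "+"]
    assert len(occs) == 1
    sites = {(s.site.mod_type, s.position, s.strand) for s in occs[0].sites}
    # 6mA on the plus strand at offset 3; 4mC on the minus strand under the
    # guanine at offset 11 — two separate methylated positions
    assert sites == {("6mA", 4, "+"), ("4mC", 12, "-")}


def test_overlapping_occurrences_all_reported():
    # AA is not palindromic (revcomp TT), so only plus-strand matches here
    occs = scan("AAAA", Motif("AA"))
    assert [(o.start, o.strand) for o in occs] == [(0, "+"), (1, "+"), (2, "+")]
    # overlapping palindrome occurrences are likewise all kept
    occs = scan("GATCGATC", GATC)
    assert [(o.start, o.strand) for o in occs] == [
        (0, "+"), (0, "-"), (4, "+"), (4, "-"),
    ]


def test_scanner_matches_oracle_on_random_sequences(rng):
    for _ in range(40):
        L = int(rng.integers(1000, 2001))
        seq = "".join(rng.choice(list("ACGT"), size=L))
        for pattern in KNOWN_PATTERNS:
            got = {(o.start, o.strand) for o in scan(seq, Motif(pattern))}
            assert got == oracle_scan(seq, pattern), pattern


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _call(pos, strand, pm, mod_type="6mA"):
    return MethylationCall("contig_1", pos, strand, mod_type, pm, pm,
                           pm > 0.5, 100)


def test_summary_all_and_none_methylated():
    genome = "TTGATCTT" * 10
    occs = scan(genome, GATC)
    full = [_call(s.position, s.strand, 0.9) for o in occs for s in o.sites]
    s = summarize_motif(occs, full).site_summaries[0]
    assert s.fraction_methylated == 1.0 and s.n_no_data == 0

    s = summarize_motif(occs, []).site_summaries[0]
    assert s.fraction_methylated == 0.0
    assert s.n_no_data == s.n_occurrences


def test_summary_fraction_monotone_in_threshold():
    genome = "TTGATCTT" * 30
    occs = scan(genome, GATC)
    rng = np.random.default_rng(0)
    calls = [_call(s.position, s.strand, float(rng.uniform(0.2, 0.9)))
             for o in occs for s in o.sites]
    fracs = [
        summarize_motif(occs, calls, threshold=t).site_summaries[0].fraction_methylated
        for t in (0.3, 0.5, 0.7)
    ]
    assert fracs[0] >= fracs[1] >= fracs[2]


def test_evaluate_absent_motif_is_empty(gatc_sim):
    summary = evaluate_motif("ACGT" * 100, [], Motif("GGGGGGGGGG"))
    assert summary.n_occurrences == 0 and summary.site_summaries == []


def test_evaluate_equals_scan_plus_summarize(gatc_sim):
    genome, calls = gatc_sim["genome"], gatc_sim["calls"]
    idx = index_calls(calls)
    via_eval = evaluate_motif(genome, idx, GATC)
    via_compose = summarize_motif(scan(genome, GATC), idx)
    a, b = via_eval.site_summaries[0], via_compose.site_summaries[0]
    assert (a.n_occurrences, a.n_methylated) == (b.n_occurrences, b.n_methylated)


def test_rarely_methylated_candidate_motif():
    # candidate motifs with p_site ~ 0.05 show only a few methylated
    # occurrences when evaluated
    tcga = Motif("TCGA", (MethSite(1, "5mC"),))
    config = SimulationConfig(
        genome_length=60_000, seed=9,
        motif_specs=[MotifSpec(tcga, planted_count=150, p_site=0.05, p_read=0.9)],
    )
    genome, truth = generate_genome(config)
    calls = call_methylation(simulate_pileup(genome, truth, config))
    summary = evaluate_motif(genome, calls, tcga)
    frac = summary.site_summaries[0].fraction_methylated
    assert frac < 0.15
    n = summary.n_occurrences
    lo, hi = 0.05 - 3 * np.sqrt(0.05 * 0.95 / n), 0.05 + 3 * np.sqrt(0.05 * 0.95 / n)
    assert lo <= frac <= hi


def test_fraction_explained_trivial_cases(gatc_sim):
    calls = gatc_sim["calls"]
    occs = scan(gatc_sim["genome"], GATC)
    assert fraction_explained(calls, [occs], "6mA") == 1.0
    assert fraction_explained(calls, [], "6mA") == 0.0
    assert fraction_explained([], [occs], "6mA") is None


# ---------------------------------------------------------------------------
# de novo discovery
# ---------------------------------------------------------------------------

def test_denovo_recovers_planted_palindrome(gatc_sim):
    found = find_motifs_denovo(gatc_sim["genome"], gatc_sim["calls"], "6mA")
    assert [(m.pattern, m.meth_sites[0].offset) for m in found] == [("GATC", 1)]


def test_denovo_degenerate_not_widened_to_n():
    # planted CAGDAC must come back as D (A/G/T), not N: the C variant has
    # no methylated support in the genome
    cag = Motif("CAGDAC", (MethSite(4, "6mA"),))
    config = SimulationConfig(
        genome_length=120_000, seed=11,
        motif_specs=[MotifSpec(cag, planted_count=400, p_site=0.98, p_read=0.9)],
    )
    genome, truth = generate_genome(config)
    calls = call_methylation(simulate_pileup(genome, truth, config))
    found = find_motifs_denovo(genome, calls, "6mA")
    assert [(m.pattern, m.meth_sites[0].offset) for m in found] == [("CAGDAC", 4)]


def test_denovo_low_frequency_motif_below_min_sites_not_reported():
    config = SimulationConfig(
        genome_length=100_000, seed=13,
        motif_specs=[
            MotifSpec(Motif("GAAGAC", (MethSite(4, "6mA"),)),
                      planted_count=200, p_site=0.98, p_read=0.9)
        ],
    )
    genome, truth = generate_genome(config)
    calls = call_methylation(simulate_pileup(genome, truth, config))
    assert find_motifs_denovo(genome, calls, "6mA", min_sites=250) == []
    assert find_motifs_denovo(genome, calls, "6mA", min_sites=50) != []


def test_denovo_too_few_sites_warns_and_returns_empty(caplog):
    import logging

    with caplog.at_level(logging.WARNING):
        out = find_motifs_denovo("ACGT" * 1000, [], "6mA")
    assert out == []
    assert any("min_sites" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def test_motif_table_roundtrip(tmp_path):
    motifs = [
        GATC,
        Motif("GAAANNNNNNGGG", (MethSite(3, "6mA"), MethSite(11, "4mC", True))),
    ]
    path = tmp_path / "motifs.tsv"
    write_motif_table(motifs, path)
    assert read_motif_table(path) == motifs
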
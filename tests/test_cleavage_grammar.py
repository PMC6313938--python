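"""Motif-grammar tests against exhaustive brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chlamysec.cleavage_grammar import (
    MotifConfig,
    find_amidation_sites,
    find_furin_sites,
    find_known_motif_sites,
    find_pc_sites,
    find_terminal_amidation,
)
from conftest import AA20, random_protein

BASIC = set("KR")


# --- independent brute-force oracles (index-pair enumeration) ---------------

def brute_pc(seq, spacings):
    out = set()
    for i in range(len(seq)):
        for j in range(i + 1, len(seq)):
            if seq[i] in BASIC and seq[j] in BASIC and (j - i - 1) in spacings:
                out.add((i + 1, j + 1))
    return out


def brute_furin(seq):
    return {(i + 1, i + 4) for i in range(len(seq) - 3)
            if seq[i] == "R" and seq[i + 2] in BASIC and seq[i + 3] == "R"}


def brute_amidation(seq, spacings):
    out = set()
    for g in range(len(seq)):
        if seq[g] != "G":
            continue
        if g + 2 < len(seq) and seq[g + 1] in BASIC and seq[g + 2] in BASIC:
            out.add(("G_KR_KR", g + 1))
        for n in spacings:
            i = g - n - 1
            if i >= 0 and g + 1 < len(seq) and seq[i] in BASIC \
                    and seq[g + 1] in BASIC:
                out.add(("KR_XnG_KR", g + 1))
        if 0 < g < len(seq) - 2 and seq[g - 1] == "R" \
                and seq[g + 1] in BASIC and seq[g + 2] == "R":
            out.add(("RG_KR_R", g + 1))
    return out


def fits(text, pattern):
    return len(text) == len(pattern) and all(
        p in ("X", c) for p, c in zip(pattern, text))


def brute_known(seq, motifs, excluded):
    out = set()
    for pat in motifs:
        for i in range(len(seq) - len(pat) + 1):
            text = seq[i:i + len(pat)]
            if fits(text, pat) and not any(fits(text, e) for e in excluded):
                out.add((i + 1, i + len(pat)))
    return out


# --- oracle equivalence on seeded random sequences ---------------------------

@pytest.mark.parametrize("finder,oracle", [
    ("pc", brute_pc),
    ("furin", brute_furin),
    ("amidation", brute_amidation),
    ("known", brute_known),
])
def test_finders_match_brute_force(finder, oracle, config, rng):
    """Each finder returns exactly the site set of an exhaustive
    position-by-position enumeration, on 300 random sequences per finder."""
    for _ in range(300):
        length = int(rng.integers(10, 501))
        seq = random_protein(rng, length)
        if finder == "pc":
            got = {(s.start, s.end) for s in find_pc_sites(seq, config)}
            want = oracle(seq, config.pc_spacings)
        elif finder == "furin":
            got = {(s.start, s.end) for s in find_furin_sites(seq)}
            want = oracle(seq)
        elif finder == "amidation":
            got = {(s.site_class, s.gly_position)
                   for s in find_amidation_sites(seq, config)}
            want = oracle(seq, config.amidation_spacings)
        else:
            got = {(s.start, s.end) for s in find_known_motif_sites(seq, config)}
            want = oracle(seq, config.known_motifs, config.excluded_motifs)
        assert got == want


def test_pc_mean_matches_analytic_expectation(rng):
    """For i.i.d. sequences with per-residue basic probability p, the mean
    number of spacing-n PC sites in length-L sequences is (L-n-1)p^2,
    checked within 3 Monte-Carlo standard errors on 10,000 sequences."""
    L, n, p = 60, 2, 2 / 20
    cfg = MotifConfig(pc_spacings=frozenset({n}))
    counts = np.empty(10_000)
    seqs = rng.choice(list(AA20), size=(10_000, L))
    for i in range(10_000):
        counts[i] = len(find_pc_sites("".join(seqs[i]), cfg))
    expected = (L - n - 1) * p * p
    se = counts.std(ddof=1) / np.sqrt(len(counts))
    assert abs(counts.mean() - expected) < 3 * se


# --- pinned examples ---------------------------------------------------------

def test_pc_examples(config):
    sites = find_pc_sites("AKRSA", MotifConfig(pc_spacings=frozenset({0})))
    assert [(s.start, s.end, s.cleavage_after) for s in sites] == [(2, 3, 3)]

    # paired-basic run RKR: two spacing-0 sites; spacing 1 is not in the set
    seq = "A" * 135 + "RKR" + "A" * 20
    spans = {(s.start, s.end) for s in find_pc_sites(seq, config)}
    assert (136, 137) in spans and (137, 138) in spans
    assert (136, 138) not in spans

    assert find_pc_sites("ACDEFG", config) == []
    assert find_pc_sites("", config) == []


def test_pc_sites_sorted_by_end_then_start(config, rng):
    seq = random_protein(rng, 300)
    sites = find_pc_sites(seq, config)
    assert [(s.end, s.start) for s in sites] == sorted(
        (s.end, s.start) for s in sites)


def test_furin_examples():
    sites = find_furin_sites("ARQKRA")
    assert [(s.start, s.end, s.cleavage_after) for s in sites] == [(2, 5, 5)]
    assert find_furin_sites("KQKR") == []
    # RGRR is both a furin site and an RG(K/R)R amidation motif
    assert len(find_furin_sites("RGRR")) == 1
    amid = find_amidation_sites("RGRR")
    assert any(a.site_class == "RG_KR_R" for a in amid)


def test_amidation_examples(config):
    a = find_amidation_sites("AGKRA", config)
    assert ("G_KR_KR", 2) in {(s.site_class, s.gly_position) for s in a}
    a = find_amidation_sites("KAGRD", config)
    assert ("KR_XnG_KR", 3) in {(s.site_class, s.gly_position) for s in a}
    a = find_amidation_sites("ARGKRD", config)
    assert ("RG_KR_R", 3) in {(s.site_class, s.gly_position) for s in a}


def test_amidation_gly_invariant(config, rng):
    seq = random_protein(rng, 400)
    for s in find_amidation_sites(seq, config):
        assert seq[s.gly_position - 1] == "G"


def test_terminal_amidation(config):
    assert find_terminal_amidation("MADG", config).site_class == "terminal_G"
    site = find_terminal_amidation("MADGKR", config)
    assert site.site_class == "terminal_G_basic_tail"
    assert site.gly_position == 4
    assert find_terminal_amidation("MADK", config) is None
    # tail longer than max_basic_tail is not a PAM substrate route
    assert find_terminal_amidation("MADGKRKR", config) is None


def test_known_motif_exclusions():
    cfg = MotifConfig(known_motifs=("KK",), excluded_motifs=())
    sites = find_known_motif_sites("AKKA", cfg)
    assert [(s.start, s.end, s.cleavage_after) for s in sites] == [(2, 3, 3)]

    cfg = MotifConfig(known_motifs=("RK", "KR"), excluded_motifs=("RK",))
    assert find_known_motif_sites("ARKA", cfg) == []

    cfg = MotifConfig(known_motifs=("KXXK",), excluded_motifs=("KXXK",))
    assert find_known_motif_sites("AKAAK", cfg) == []


def test_bad_motif_pattern_rejected():
    with pytest.raises(ValueError):
        MotifConfig(known_motifs=("KZR",))


@given(st.text(alphabet=AA20.replace("K", "").replace("R", ""),
               min_size=1, max_size=120))
@settings(max_examples=60, deadline=None)
def test_no_basics_no_sites(seq):
    """Sequences with no K and no R yield zero PC, furin and known-motif
    sites."""
    cfg = MotifConfig()
    assert find_pc_sites(seq, cfg) == []
    assert find_furin_sites(seq) == []
    assert find_known_motif_sites(seq, cfg) == []


@given(st.text(alphabet=AA20, min_size=5, max_size=150),
       st.sets(st.sampled_from([0, 1, 2, 3, 4, 5, 6]), min_size=1))
@settings(max_examples=80, deadline=None)
def test_enlarging_spacings_is_monotone(seq, spacings):
    """Enlarging pc_spacings never removes a reported site."""
    small = MotifConfig(pc_spacings=frozenset(spacings))
    large = MotifConfig(pc_spacings=frozenset(spacings | {0, 2, 4, 6}))
    got_small = {(s.start, s.end) for s in find_pc_sites(seq, small)}
    got_large = {(s.start, s.end) for s in find_pc_sites(seq, large)}
    assert got_small <= got_large


def test_config_yaml_roundtrip(tmp_path, config):
    path = tmp_path / "motifs.yaml"
    config.to_yaml(path)
    assert MotifConfig.from_yaml(path) == config
    assert MotifConfig.default_file() == MotifConfig()


def test_presets_differ_only_in_spacings():
    full = MotifConfig.preset("methods-spacings")
    restricted = MotifConfig.preset("results-spacings")
    assert full.pc_spacings == frozenset({0, 2, 4, 6})
    assert restricted.pc_spacings == frozenset({0, 2})
    assert full.known_motifs == restricted.known_motifs
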
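"""Cleavage-product enumeration, trimming/amidation and summary tests."""

import pytest

from chlamysec.cleavage_grammar import CleavageSite, MotifConfig, find_pc_sites
from chlamysec.peptide_products import (
    PredictedPeptide,
    amide_histogram,
    cleave,
    enumerate_products,
    summarize_proteome,
    summary_to_tsv,
    trim_and_amidate,
)
from chlamysec.proteome_io import ProteinRecord, SignalAnnotation
from chlamysec.synthetic_data import generate_proteome


def site(after, pid="p1"):
    return CleavageSite(pid, "PC", "KR", after - 1, after, after)


def pep(seq):
    return PredictedPeptide("p1", 1, len(seq), 1, len(seq), seq)


def test_cleave_single_cut():
    rec = ProteinRecord("p1", "MKWVSAEGKRSFLD")
    out = cleave(rec, [site(10)], signal_end=4)
    assert [p.sequence for p in out] == ["SAEGKR", "SFLD"]
    assert [(p.start, p.end) for p in out] == [(5, 10), (11, 14)]
    assert [(p.mature_start, p.mature_end) for p in out] == [(1, 6), (7, 10)]


def test_cleave_no_sites_and_tiling():
    rec = ProteinRecord("p1", "MKWVSAEGKRSFLD")
    assert [p.sequence for p in cleave(rec, [], 4)] == ["SAEGKRSFLD"]
    out = cleave(rec, [site(7), site(10)], 4)
    assert len(out) == 3
    assert sum(len(p.sequence) for p in out) == rec.length - 4
    assert "".join(p.sequence for p in out) == rec.sequence[4:]


def test_cleave_collapses_duplicates_and_skips_outside():
    rec = ProteinRecord("p1", "MKWVSAEGKRSFLD")
    out = cleave(rec, [site(10), site(10), site(2), site(14)], 4)
    # position 2 is inside the signal, 14 is the C-terminus: no extra cuts
    assert [p.sequence for p in out] == ["SAEGKR", "SFLD"]


def test_trim_and_amidate_stepwise():
    p = trim_and_amidate(pep("SAEGKR"))
    assert (p.trimmed_basics, p.amidated, p.amide_residue, p.length_final) == \
           (2, True, "E", 3)
    p = trim_and_amidate(pep("SFLD"))
    assert (p.trimmed_basics, p.amidated) == (0, False)
    # trimming to a bare G would amidate nothing: degenerate boundary
    p = trim_and_amidate(pep("GKR"))
    assert not p.amidated and not p.degenerate
    p = trim_and_amidate(pep("KRKR"))
    assert p.degenerate and not p.amidated


def test_amide_histogram():
    peptides = [trim_and_amidate(pep(s)) for s in ("SAEGKR", "QGK", "SFLD")]
    hist = amide_histogram(peptides)
    assert hist == {"E": 1, "Q": 1}
    assert sum(hist.values()) == sum(1 for p in peptides if p.amidated)
    assert amide_histogram([trim_and_amidate(pep("SFLD"))]) == {}


def test_tiling_conservation_on_random_precursors(rng):
    """Pre-trim peptide lengths always sum to the mature-chain length."""
    from conftest import random_protein
    cfg = MotifConfig()
    for _ in range(50):
        seq = "M" + random_protein(rng, int(rng.integers(20, 200)))
        rec = ProteinRecord("p", seq)
        sites = find_pc_sites(seq, cfg, "p")
        out = cleave(rec, sites, signal_end=1)
        assert sum(len(p.sequence) for p in out) == rec.length - 1


def test_planted_sites_recovered_exactly():
    """Every planted amidatable site yields exactly one amidated peptide
    with the planted amide residue; motif-free spacers yield none."""
    records, signal_map, _, truth = generate_proteome(
        8, sites_per_protein=3, site_classes=["G_KR_KR"], seed=7)
    cfg = MotifConfig()
    for rec in records:
        products = enumerate_products(
            rec, signal_map[rec.protein_id].signal_end, cfg)
        amidated = [p for p in products if p.amidated]
        planted = truth.planted_amidated[rec.protein_id]
        assert len(amidated) == len(planted) == 3
        assert [p.amide_residue for p in amidated] == \
               [t["amide_residue"] for t in planted]
        assert [p.end for p in amidated] == \
               [t["cleavage_after"] for t in planted]


def test_no_false_amidation_without_planted_sites():
    records, signal_map, _, truth = generate_proteome(
        5, sites_per_protein=0, seed=3)
    summary = summarize_proteome(records, signal_map)
    assert summary.n_amidated_peptides == 0
    assert summary.n_proteins_with_pc_sites == 0
    assert summary.n_with_furin == 0


def test_summarize_counts_planted_truth():
    records, signal_map, _, truth = generate_proteome(
        6, sites_per_protein=2, site_classes=["G_KR_KR"], seed=11)
    summary = summarize_proteome(records, signal_map)
    assert summary.n_amidated_peptides == 2 * len(records)
    assert summary.n_with_G_KR_KR == len(records)
    assert sum(summary.amide_residue_histogram.values()) == \
           summary.n_amidated_peptides
    assert sum(summary.length_distribution.values()) == \
           summary.n_amidated_peptides


def test_terminal_g_counted():
    rec = ProteinRecord("p1", "MSTAAAQFG")
    summary = summarize_proteome([rec], {"p1": SignalAnnotation("p1", False)})
    assert summary.n_terminal_G == 1
    assert summary.n_amidated_peptides >= 1


def test_summary_export_deterministic(tmp_path):
    """Identical inputs and config produce byte-identical exports."""
    records, signal_map, _, _ = generate_proteome(4, seed=5)
    paths = []
    for name in ("a.tsv", "b.tsv"):
        summary = summarize_proteome(records, signal_map)
        path = tmp_path / name
        summary_to_tsv(summary, path)
        paths.append(path.read_bytes())
    assert paths[0] == paths[1]


def test_known_motifs_mode_counts_g_terminated_products():
    # KK cut after a G-ending stretch: amidatable in known-motifs mode
    rec = ProteinRecord("p1", "MSTAGKKAAAF")
    cfg = MotifConfig(known_motifs=("KK",), excluded_motifs=())
    summary = summarize_proteome(
        [rec], {"p1": SignalAnnotation("p1", False)}, cfg,
        mode="known_motifs")
    assert summary.n_proteins_neuropred == 1
    assert summary.n_amidated_peptides == 1
    assert summary.amide_residue_histogram == {"A": 1}
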
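"""Peptide-product enumeration and proteome-wide processing statistics.

Models the canonical secretory-granule processing cascade: signal-peptide
removal, simultaneous endoproteolytic cleavage at every predicted site,
carboxypeptidase-B-like removal of C-terminal Lys/Arg, and PAM amidation
of products left ending in glycine (the glycine is consumed, leaving the
penultimate residue alpha-amidated).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from chlamysec.cleavage_grammar import (
    AmidationSite,
    CleavageSite,
    MotifConfig,
    find_amidation_sites,
    find_furin_sites,
    find_known_motif_sites,
    find_pc_sites,
    find_terminal_amidation,
)
from chlamysec.proteome_io import ProteinRecord, SignalAnnotation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PredictedPeptide:
    """A product of cleavage, optional CPB trimming and optional amidation.

    ``start``/``end`` are 1-based in the precursor; ``mature_start``/
    ``mature_end`` the same span in post-signal-peptide coordinates.
    ``sequence`` is the pre-trim cleavage product; ``trimmed_basics``
    counts C-terminal K/R removed; when ``amidated``, ``amide_residue``
    is the residue left C-terminal after glycine removal and
    ``length_final`` the mature-product length.
    """

    precursor_id: str
    start: int
    end: int
    mature_start: int
    mature_end: int
    sequence: str
    trimmed_basics: int = 0
    amidated: bool = False
    amide_residue: str | None = None
    length_final: int | None = None
    degenerate: bool = False


@dataclass
class ProteomeSummary:
    """Per-proteome counts of cleavage/amidation potential."""

    n_proteins: int = 0
    n_proteins_with_pc_sites: int = 0
    n_with_G_KR_KR: int = 0
    n_with_KR_XnG_KR: int = 0
    n_with_furin: int = 0
    n_furin_amidatable: int = 0
    n_terminal_G: int = 0
    n_terminal_G_tail: int = 0
    n_proteins_neuropred: int = 0
    n_amidated_peptides: int = 0
    length_distribution: Counter = None
    amide_residue_histogram: Counter = None
    amidated_per_protein: Counter = None

    def __post_init__(self) -> None:
        self.length_distribution = self.length_distribution or Counter()
        self.amide_residue_histogram = self.amide_residue_histogram or Counter()
        self.amidated_per_protein = self.amidated_per_protein or Counter()


def cleave(
    record: ProteinRecord,
    sites: Sequence[CleavageSite],
    signal_end: int = 0,
) -> list[PredictedPeptide]:
    """Cut the mature chain after every distinct cleavage point.

    The mature chain is residues ``signal_end + 1 .. length``. Sites
    sharing a cleavage point collapse to one cut; sites outside the
    mature chain are skipped with a log entry. The returned peptides
    tile the mature chain exactly.
    """
    L = record.length
    cuts: set[int] = set()
    for s in sites:
        if s.cleavage_after <= signal_end or s.cleavage_after >= L:
            logger.debug("%s: site at %d outside mature chain, skipped",
                         record.protein_id, s.cleavage_after)
            continue
        cuts.add(s.cleavage_after)
    bounds = [signal_end] + sorted(cuts) + [L]
    peptides = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        peptides.append(PredictedPeptide(
            precursor_id=record.protein_id,
            start=lo + 1, end=hi,
            mature_start=lo + 1 - signal_end, mature_end=hi - signal_end,
            sequence=record.sequence[lo:hi],
        ))
    return peptides


def trim_and_amidate(peptide: PredictedPeptide) -> PredictedPeptide:
    """Apply CPB-like trimming then PAM amidation to one peptide.

    C-terminal K/R are removed iteratively; if the remainder ends in
    glycine and keeps at least one residue after its removal, the
    product is amidated (an amide of nothing is meaningless). A peptide
    trimmed away entirely is flagged degenerate.
    """
    seq = peptide.sequence
    if not seq:
        raise ValueError("empty peptide")
    trimmed = 0
    while seq and seq[-1] in "KR":
        seq = seq[:-1]
        trimmed += 1
    if not seq:
        return replace(peptide, trimmed_basics=trimmed, degenerate=True)
    if seq.endswith("G") and len(seq) >= 2:
        core = seq[:-1]
        return replace(
            peptide, trimmed_basics=trimmed, amidated=True,
            amide_residue=core[-1], length_final=len(core))
    return replace(peptide, trimmed_basics=trimmed, amidated=False,
                   length_final=len(seq))


def amide_histogram(peptides: Iterable[PredictedPeptide]) -> Counter:
    """Counts of the amide-bearing C-terminal residue over amidated peptides."""
    return Counter(p.amide_residue for p in peptides if p.amidated)


def enumerate_products(
    record: ProteinRecord,
    signal_end: int,
    config: MotifConfig,
    mode: str = "grammar",
) -> list[PredictedPeptide]:
    """Cleave one precursor under the chosen site model and process products.

    ``grammar`` mode cuts at PC plus furin sites; ``known_motifs`` mode
    cuts at the NeuroPred-style known-motif sites. Sites overlapping the
    signal peptide never produce cuts (the signal is removed upstream of
    granule processing).
    """
    seq = record.sequence
    if mode == "grammar":
        sites = find_pc_sites(seq, config, record.protein_id)
        sites += find_furin_sites(seq, record.protein_id)
    elif mode == "known_motifs":
        sites = find_known_motif_sites(seq, config, record.protein_id)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    sites = [s for s in sites if s.start > signal_end]
    return [trim_and_amidate(p) for p in cleave(record, sites, signal_end)]


def summarize_proteome(
    records: Iterable[ProteinRecord],
    signal_map: dict[str, SignalAnnotation],
    config: MotifConfig | None = None,
    mode: str = "grammar",
) -> ProteomeSummary:
    """Run the site finders on every record and tally proteome-wide counts.

    Motif presence counts (PC, amidation classes, furin, terminal
    glycines) are evaluated on the mature chain. ``n_amidated_peptides``
    counts per (precursor, span); identical sequences from different
    precursors count separately. Deterministic given inputs and config.
    """
    config = config or MotifConfig()
    summary = ProteomeSummary()
    for rec in records:
        summary.n_proteins += 1
        sig = signal_map.get(rec.protein_id)
        signal_end = sig.signal_end if (sig and sig.has_signal) else 0
        mature = rec.sequence[signal_end:]
        if not mature:
            continue

        pc = find_pc_sites(mature, config, rec.protein_id)
        if pc:
            summary.n_proteins_with_pc_sites += 1
        amid = find_amidation_sites(mature, config, rec.protein_id)
        classes = {a.site_class for a in amid}
        if "G_KR_KR" in classes:
            summary.n_with_G_KR_KR += 1
        if "KR_XnG_KR" in classes:
            summary.n_with_KR_XnG_KR += 1

        furin = find_furin_sites(mature, rec.protein_id)
        if furin:
            summary.n_with_furin += 1
            # a furin cut is amidatable when the upstream product, after
            # CPB trimming, ends in glycine
            for site in furin:
                up = mature[:site.cleavage_after].rstrip("KR")
                if len(up) >= 2 and up.endswith("G"):
                    summary.n_furin_amidatable += 1
                    break

        term = find_terminal_amidation(mature, config, rec.protein_id)
        if term is not None:
            if term.site_class == "terminal_G":
                summary.n_terminal_G += 1
            else:
                summary.n_terminal_G_tail += 1

        products = enumerate_products(rec, signal_end, config, mode=mode)
        amidated = [p for p in products if p.amidated]
        if mode == "known_motifs" and amidated:
            summary.n_proteins_neuropred += 1
        summary.n_amidated_peptides += len(amidated)
        if amidated:
            summary.amidated_per_protein[rec.protein_id] = len(amidated)
        for p in amidated:
            summary.length_distribution[p.length_final] += 1
            summary.amide_residue_histogram[p.amide_residue] += 1
    return summary


def peptides_to_tsv(peptides: Iterable[PredictedPeptide], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("precursor_id\tstart\tend\tsequence\ttrimmed_basics\t"
                 "amidated\tamide_residue\tlength_final\n")
        for p in peptides:
            fh.write(f"{p.precursor_id}\t{p.start}\t{p.end}\t{p.sequence}\t"
                     f"{p.trimmed_basics}\t{'Y' if p.amidated else 'N'}\t"
                     f"{p.amide_residue or '-'}\t{p.length_final or '-'}\n")


def summary_to_tsv(summary: ProteomeSummary, path: str | Path) -> None:
    """Key-value export; histogram keys are sorted for byte-identical reruns."""
    with open(path, "w") as fh:
        fh.write("key\tvalue\n")
        for key in ("n_proteins", "n_proteins_with_pc_sites", "n_with_G_KR_KR",
                    "n_with_KR_XnG_KR", "n_with_furin", "n_furin_amidatable",
                    "n_terminal_G", "n_terminal_G_tail", "n_proteins_neuropred",
                    "n_amidated_peptides"):
            fh.write(f"{key}\t{getattr(summary, key)}\n")
        for res, cnt in sorted(summary.amide_residue_histogram.items()):
            fh.write(f"amide_{res}\t{cnt}\n")
        for length, cnt in sorted(summary.length_distribution.items()):
            fh.write(f"len_{length}\t{cnt}\n")
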
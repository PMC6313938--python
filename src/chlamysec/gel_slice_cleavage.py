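"""Intact-versus-cleaved inference from gel-slice-resolved peptides.

An SDS-PAGE lane is cut into fixed molecular-weight slices before in-gel
digestion, so each identified tryptic peptide carries the mass range of
the species it came from. A secreted protein whose peptides appear only
in slices at or above its intact mass was recovered intact; peptides
concentrated in clearly lower-mass slices evidence stable proteolytic
fragments, and the residue span of those peptides locates the fragment
(N-terminal, C-terminal or internal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: average amino-acid residue mass, kDa — for the approximate sequence-mass
#: fallback only
AVG_RESIDUE_KDA = 0.110


@dataclass(frozen=True)
class GelSlice:
    """One molecular-weight interval of the gel; bounds in kDa, half-open
    [mass_low, mass_high)."""

    slice_index: int
    mass_low: float
    mass_high: float

    def __post_init__(self) -> None:
        if not 0 < self.mass_low < self.mass_high:
            raise ValueError(f"bad slice bounds {self.mass_low}-{self.mass_high}")


@dataclass(frozen=True)
class SliceEvidence:
    """Tryptic peptides of one protein observed in one slice."""

    protein_id: str
    slice_index: int
    peptide_start: int
    peptide_end: int
    spectral_count: int

    def __post_init__(self) -> None:
        if self.spectral_count < 1:
            raise ValueError("spectral_count must be >= 1")
        if not 1 <= self.peptide_start <= self.peptide_end:
            raise ValueError("bad peptide span")


@dataclass(frozen=True)
class FragmentRegion:
    location: str              # N_terminal, C_terminal or internal
    span_start: int
    span_end: int
    domains: tuple[str, ...] = ()


@dataclass(frozen=True)
class CleavageCall:
    protein_id: str
    status: str                # intact, cleaved or ambiguous
    fragment_regions: tuple[FragmentRegion, ...]
    evidence_slices: tuple[int, ...]


def _check_slices(slices: Sequence[GelSlice]) -> list[GelSlice]:
    if not slices:
        raise ValueError("empty slice list")
    ordered = sorted(slices, key=lambda s: s.mass_low)
    for a, b in zip(ordered[:-1], ordered[1:]):
        if b.mass_low < a.mass_high:
            raise ValueError(f"slices {a.slice_index} and {b.slice_index} overlap")
    return ordered


def locate_intact_slice(intact_mass_kda: float, slices: Sequence[GelSlice]) -> int:
    """Index of the slice whose [mass_low, mass_high) contains the intact mass.

    A mass exactly on a boundary falls in the higher slice (half-open
    convention); a mass outside the union is assigned the nearest
    boundary slice and logged.
    """
    ordered = _check_slices(slices)
    for s in ordered:
        if s.mass_low <= intact_mass_kda < s.mass_high:
            return s.slice_index
    if intact_mass_kda >= ordered[-1].mass_high:
        logger.warning("mass %.1f kDa above all slices; using top slice",
                       intact_mass_kda)
        return ordered[-1].slice_index
    logger.warning("mass %.1f kDa below all slices; using bottom slice",
                   intact_mass_kda)
    return ordered[0].slice_index


def approximate_mass_kda(sequence: str) -> float:
    """Approximate protein mass from length (average residue masses)."""
    return len(sequence) * AVG_RESIDUE_KDA


def _merge_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of residue spans, merging overlapping or adjacent intervals."""
    merged: list[tuple[int, int]] = []
    for lo, hi in sorted(spans):
        if merged and lo <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def call_cleavage(
    protein_id: str,
    protein_length: int,
    evidence: Sequence[SliceEvidence],
    slices: Sequence[GelSlice],
    intact_mass_kda: float,
    tolerance_fraction: float = 0.2,
    min_counts: int = 2,
    terminal_fraction: float = 0.4,
) -> CleavageCall:
    """Call a protein intact, cleaved or ambiguous from its slice evidence.

    Slices with ``mass_high < (1 - tolerance_fraction) * intact_mass`` are
    "sub-intact" (gel migration is imprecise, hence the tolerance). When
    sub-intact slices carry at least ``min_counts`` summed spectral counts
    the protein is called cleaved, and fragment regions are the merged
    peptide-span unions in those slices, labelled N_terminal when the
    union lies within the first ``terminal_fraction`` of the protein,
    C_terminal within the last, else internal. When all evidence sits in
    slices at or above the intact-mass slice the protein is intact;
    anything in between is ambiguous.
    """
    my_evidence = [e for e in evidence if e.protein_id == protein_id]
    if not my_evidence:
        raise ValueError(f"no slice evidence for {protein_id}")
    ordered = _check_slices(slices)
    by_index = {s.slice_index: s for s in ordered}
    for e in my_evidence:
        if e.slice_index not in by_index:
            raise ValueError(f"unknown slice index {e.slice_index} in evidence")
        if e.peptide_end > protein_length:
            raise ValueError(
                f"{protein_id}: peptide span {e.peptide_start}-{e.peptide_end} "
                f"exceeds length {protein_length}")

    intact_index = locate_intact_slice(intact_mass_kda, slices)
    threshold = (1.0 - tolerance_fraction) * intact_mass_kda
    sub_intact = {s.slice_index for s in ordered if s.mass_high < threshold}

    sub_evidence = [e for e in my_evidence if e.slice_index in sub_intact]
    used = tuple(sorted({e.slice_index for e in my_evidence}))

    if sum(e.spectral_count for e in sub_evidence) >= min_counts:
        spans = _merge_spans(
            [(e.peptide_start, e.peptide_end) for e in sub_evidence])
        n_cut = terminal_fraction * protein_length
        c_cut = (1.0 - terminal_fraction) * protein_length
        regions = []
        for lo, hi in spans:
            if hi <= n_cut:
                loc = "N_terminal"
            elif lo >= c_cut:
                loc = "C_terminal"
            else:
                loc = "internal"
            regions.append(FragmentRegion(loc, lo, hi))
        return CleavageCall(protein_id, "cleaved", tuple(regions), used)

    intact_low = by_index[intact_index].mass_low
    if all(by_index[e.slice_index].mass_low >= intact_low for e in my_evidence):
        return CleavageCall(protein_id, "intact", (), used)
    return CleavageCall(protein_id, "ambiguous", (), used)


def annotate_fragments_with_domains(
    call: CleavageCall,
    domain_table: Sequence[tuple[str, str, int, int]],
    min_overlap_fraction: float = 0.5,
) -> CleavageCall:
    """Label fragment regions with domains they cover.

    ``domain_table`` rows are (protein_id, domain_name, start, end); a
    region is labelled with every domain whose span it overlaps by at
    least ``min_overlap_fraction`` of the domain length.
    """
    regions = []
    for reg in call.fragment_regions:
        labels = []
        for pid, name, dlo, dhi in domain_table:
            if pid != call.protein_id:
                continue
            overlap = min(reg.span_end, dhi) - max(reg.span_start, dlo) + 1
            if overlap >= min_overlap_fraction * (dhi - dlo + 1):
                labels.append(name)
        regions.append(FragmentRegion(reg.location, reg.span_start,
                                      reg.span_end, tuple(labels)))
    return CleavageCall(call.protein_id, call.status, tuple(regions),
                        call.evidence_slices)


# --- TSV plumbing ------------------------------------------------------------

def read_slices_tsv(path: str | Path) -> list[GelSlice]:
    """Slices TSV: index <TAB> low_kda <TAB> high_kda."""
    slices = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.split("\t")
            if f[0] in {"index", "slice_index"}:
                continue
            slices.append(GelSlice(int(f[0]), float(f[1]), float(f[2])))
    return slices


def read_evidence_tsv(path: str | Path) -> list[SliceEvidence]:
    """Evidence TSV: protein_id, slice_index, pep_start, pep_end, count."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if f[0] == "protein_id":
                continue
            out.append(SliceEvidence(f[0], int(f[1]), int(f[2]), int(f[3]),
                                     int(f[4])))
    return out


def read_domains_tsv(path: str | Path) -> list[tuple[str, str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if f[0] == "protein_id":
                continue
            out.append((f[0], f[1], int(f[2]), int(f[3])))
    return out


def calls_to_tsv(calls: Iterable[CleavageCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tstatus\tfragments\tevidence_slices\n")
        for c in calls:
            frags = ";".join(
                f"{r.location}:{r.span_start}-{r.span_end}"
                + (f"[{','.join(r.domains)}]" if r.domains else "")
                for r in c.fragment_regions) or "-"
            fh.write(f"{c.protein_id}\t{c.status}\t{frags}\t"
                     f"{','.join(map(str, c.evidence_slices))}\n")
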
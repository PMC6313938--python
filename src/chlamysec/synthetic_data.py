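"""Ground-truthed synthetic inputs for every pipeline stage.

Three generators emulate the study's data shapes: precursor proteins
with a planted signal peptide and planted cleavage/amidation motifs,
six-sample secretome spectral-count tables (two datasets of three) with
controlled presence patterns and overdispersed counts, and gel-slice
peptide evidence for intact and cleaved proteins with known fragment
boundaries. Every generator is a pure function of (parameters, seed) and
returns a truth record alongside the data.

Spacer regions use an alphabet without K, R or G, so no motif can arise
by accident and false-positive expectations are exactly zero. Planted
motifs are separated by 9-residue spacers: cross-motif basic-residue
gaps are then >= 9, outside both the PC spacing set {0,2,4,6} and the
amidation spacings {1,3}, so each planted site yields exactly one cut.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from chlamysec.gel_slice_cleavage import GelSlice, SliceEvidence
from chlamysec.proteome_io import (
    ProteinRecord,
    SignalAnnotation,
    TopologyAnnotation,
)
from chlamysec.secretome_merge import SampleRun

#: spacer alphabet — no K/R/G so spacers can never complete a motif
SPACER_ALPHABET = "ASTVLEDQNPF"
#: hydrophobic core alphabet for planted signal peptides
SIGNAL_ALPHABET = "LAVFIW"

SPACER_LEN = 9
SAMPLE_IDS = ("A", "B", "C", "D", "E", "F")

#: motif templates planted between spacers; G_KR_KR yields one amidated
#: peptide per site (the G survives CPB trimming), PC and furin do not
#: (their products end in the spacer / Q residue after trimming).
SITE_TEMPLATES = {
    "PC": "KR",
    "furin": "RQKR",
    "G_KR_KR": "GKR",
}


@dataclass
class SyntheticTruth:
    """Planted ground truth; serializes to/from JSON exactly."""

    planted_sites: dict = field(default_factory=dict)
    planted_amidated: dict = field(default_factory=dict)
    signal_ends: dict = field(default_factory=dict)
    presence: dict = field(default_factory=dict)
    retained: list = field(default_factory=list)
    gel_status: dict = field(default_factory=dict)
    fragment_spans: dict = field(default_factory=dict)
    intact_mass_kda: dict = field(default_factory=dict)
    protein_lengths: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _spacer(rng: np.random.Generator, n: int = SPACER_LEN) -> str:
    return "".join(rng.choice(list(SPACER_ALPHABET), size=n))


def generate_precursor(
    n_sites: int,
    site_classes: Sequence[str] | None = None,
    spacer_composition: str = SPACER_ALPHABET,
    seed: int = 0,
    protein_id: str = "syn1",
    signal_len: int = 20,
) -> tuple[ProteinRecord, SyntheticTruth]:
    """One precursor: signal peptide, then alternating spacers and motifs.

    ``site_classes`` cycles over the requested classes (default all of
    ``SITE_TEMPLATES``). The truth records every planted site position
    (1-based position of the residue the cleavage follows), the expected
    amidated products for G_KR_KR sites, and the signal end.
    """
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    if set(spacer_composition) & set("KRG"):
        raise ValueError("spacer_composition must exclude K, R and G")
    classes = list(site_classes or SITE_TEMPLATES)
    for c in classes:
        if c not in SITE_TEMPLATES:
            raise ValueError(f"unknown site class {c!r}")
    rng = np.random.default_rng(seed)

    signal = "M" + "".join(rng.choice(list(SIGNAL_ALPHABET), size=signal_len - 1))
    parts = [signal]
    pos = signal_len
    truth = SyntheticTruth()
    truth.signal_ends[protein_id] = signal_len
    sites = []
    amidated = []
    for i in range(n_sites):
        spacer = "".join(rng.choice(list(spacer_composition), size=SPACER_LEN))
        cls = classes[i % len(classes)]
        motif = SITE_TEMPLATES[cls]
        parts.append(spacer)
        parts.append(motif)
        pos += SPACER_LEN + len(motif)
        sites.append({"site_class": cls, "cleavage_after": pos})
        if cls == "G_KR_KR":
            # product ends ...<spacer>GKR; CPB trims KR, PAM consumes G
            amidated.append({"cleavage_after": pos,
                             "amide_residue": spacer[-1]})
    parts.append("".join(rng.choice(list(spacer_composition), size=SPACER_LEN)))
    sequence = "".join(parts)
    truth.planted_sites[protein_id] = sites
    truth.planted_amidated[protein_id] = amidated
    truth.protein_lengths[protein_id] = len(sequence)
    return ProteinRecord(protein_id, sequence), truth


def generate_proteome(
    n_proteins: int,
    sites_per_protein: int = 3,
    site_classes: Sequence[str] | None = None,
    seed: int = 0,
) -> tuple[list[ProteinRecord], dict[str, SignalAnnotation],
           dict[str, TopologyAnnotation], SyntheticTruth]:
    """A proteome of planted precursors plus matching annotation maps."""
    rng = np.random.default_rng(seed)
    records, truth = [], SyntheticTruth()
    signal_map, topo_map = {}, {}
    for i in range(n_proteins):
        pid = f"syn{i + 1:04d}"
        rec, t = generate_precursor(
            sites_per_protein, site_classes,
            seed=int(rng.integers(0, 2**31 - 1)), protein_id=pid)
        records.append(rec)
        truth.planted_sites.update(t.planted_sites)
        truth.planted_amidated.update(t.planted_amidated)
        truth.signal_ends.update(t.signal_ends)
        truth.protein_lengths.update(t.protein_lengths)
        signal_map[pid] = SignalAnnotation(pid, True, t.signal_ends[pid])
        topo_map[pid] = TopologyAnnotation(pid)
    return records, signal_map, topo_map, truth


def generate_secretome(
    n_proteins: int = 100,
    presence_distribution: dict[int, float] | None = None,
    count_mean: float = 20.0,
    count_dispersion: float = 2.0,
    seed: int = 0,
) -> tuple[list[SampleRun], SyntheticTruth]:
    """Six-sample secretome count tables with a known presence pattern.

    Each protein draws a presence count from ``presence_distribution``
    (a probability map over 1..6; default uniform) and that many of the
    six samples uniformly at random. Counts are 1 + NegBin(mean,
    dispersion) — shifted so counts are strictly positive, overdispersed
    like real spectral counts. Samples A-C form dataset 1, D-F dataset 2.
    The truth records each protein's presence and the set a >= 4-of-6
    filter must retain.
    """
    presence_distribution = presence_distribution or {
        k: 1 / 6 for k in range(1, 7)}
    levels = sorted(presence_distribution)
    probs = np.array([presence_distribution[k] for k in levels], dtype=float)
    if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
        raise ValueError("presence_distribution must be a probability map")
    if set(levels) - set(range(1, 7)):
        raise ValueError("presence levels must lie in 1..6")
    if count_mean <= 1 or count_dispersion <= 0:
        raise ValueError("count_mean must exceed 1, dispersion be positive")

    rng = np.random.default_rng(seed)
    m, k = count_mean - 1.0, count_dispersion
    truth = SyntheticTruth()
    counts: dict[str, dict[str, int]] = {s: {} for s in SAMPLE_IDS}
    for i in range(n_proteins):
        pid = f"sec{i + 1:04d}"
        presence = int(rng.choice(levels, p=probs))
        members = rng.choice(len(SAMPLE_IDS), size=presence, replace=False)
        for j in members:
            c = 1 + int(rng.negative_binomial(k, k / (k + m)))
            counts[SAMPLE_IDS[j]][pid] = c
        truth.presence[pid] = presence
        if presence >= 4:
            truth.retained.append(pid)
    truth.retained.sort()
    samples = [
        SampleRun(s, 1 if s in "ABC" else 2, counts[s]) for s in SAMPLE_IDS
    ]
    return samples, truth


DEFAULT_SLICES = (
    GelSlice(1, 10, 18),
    GelSlice(2, 18, 25),
    GelSlice(3, 25, 40),
    GelSlice(4, 40, 60),
    GelSlice(5, 60, 100),
    GelSlice(6, 100, 250),
)


def generate_gel_dataset(
    n_intact: int = 5,
    n_cleaved: int = 5,
    slices: Sequence[GelSlice] = DEFAULT_SLICES,
    seed: int = 0,
) -> tuple[list[SliceEvidence], SyntheticTruth]:
    """Gel-slice evidence for intact and cleaved proteins.

    Intact proteins (~50 kDa) get peptides only in their intact-mass
    slice; cleaved proteins get peptides confined to a planted terminal
    fragment (N- or C-terminal quarter, ~12 kDa) observed in the lowest
    slice. The truth records status, fragment spans, intact masses and
    lengths, so downstream calls can be checked exactly.
    """
    rng = np.random.default_rng(seed)
    slices = sorted(slices, key=lambda s: s.mass_low)
    truth = SyntheticTruth()
    evidence: list[SliceEvidence] = []

    def peptides_in(pid: str, slice_index: int, lo: int, hi: int, n_pep: int):
        for _ in range(n_pep):
            a = int(rng.integers(lo, hi - 8))
            b = a + int(rng.integers(8, 15))
            b = min(b, hi)
            evidence.append(SliceEvidence(pid, slice_index, a, b,
                                          int(rng.integers(1, 5))))

    for i in range(n_intact):
        pid = f"gel_intact{i + 1:02d}"
        length = int(rng.integers(400, 520))          # ~44-57 kDa
        mass = round(length * 0.110, 1)
        intact_slice = next(s for s in slices
                            if s.mass_low <= mass < s.mass_high)
        peptides_in(pid, intact_slice.slice_index, 1, length, 4)
        truth.gel_status[pid] = "intact"
        truth.intact_mass_kda[pid] = mass
        truth.protein_lengths[pid] = length

    for i in range(n_cleaved):
        pid = f"gel_cleaved{i + 1:02d}"
        length = int(rng.integers(400, 520))
        mass = round(length * 0.110, 1)
        terminal = "N_terminal" if i % 2 == 0 else "C_terminal"
        frag_len = length // 4                        # ~11-14 kDa fragment
        if terminal == "N_terminal":
            lo, hi = 1, frag_len
        else:
            lo, hi = length - frag_len + 1, length
        frag_mass = frag_len * 0.110
        frag_slice = next(s for s in slices
                          if s.mass_low <= frag_mass < s.mass_high)
        peptides_in(pid, frag_slice.slice_index, lo, hi, 4)
        truth.gel_status[pid] = "cleaved"
        truth.fragment_spans[pid] = [[terminal, lo, hi]]
        truth.intact_mass_kda[pid] = mass
        truth.protein_lengths[pid] = length
    return evidence, truth


def write_fixture_directory(out_dir: str | Path, seed: int = 0) -> dict:
    """Write a complete fixture set (FASTA, annotation TSVs, sample TSVs,
    slices, evidence, truth manifests) and return the paths written."""
    from chlamysec.proteome_io import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=3)]

    records, signal_map, topo_map, truth_p = generate_proteome(
        20, seed=seeds[0])
    write_fasta(records, out / "proteome.fasta")
    with open(out / "signal.tsv", "w") as fh:
        for pid, ann in signal_map.items():
            fh.write(f"{pid}\tY\t{ann.signal_end}\n")
    with open(out / "topology.tsv", "w") as fh:
        for pid in signal_map:
            fh.write(f"{pid}\t-\n")
    with open(out / "localization.tsv", "w") as fh:
        for pid in signal_map:
            fh.write(f"{pid}\tSP\n")
    truth_p.to_json(out / "truth_precursors.json")

    samples, truth_s = generate_secretome(seed=seeds[1])
    for s in samples:
        with open(out / f"sample_{s.sample_id}.tsv", "w") as fh:
            for pid, c in sorted(s.counts.items()):
                fh.write(f"{pid}\t{c}\n")
    truth_s.to_json(out / "truth_secretome.json")

    evidence, truth_g = generate_gel_dataset(seed=seeds[2])
    with open(out / "slices.tsv", "w") as fh:
        for s in DEFAULT_SLICES:
            fh.write(f"{s.slice_index}\t{s.mass_low}\t{s.mass_high}\n")
    with open(out / "evidence.tsv", "w") as fh:
        for e in evidence:
            fh.write(f"{e.protein_id}\t{e.slice_index}\t{e.peptide_start}\t"
                     f"{e.peptide_end}\t{e.spectral_count}\n")
    with open(out / "intact_masses.tsv", "w") as fh:
        for pid, m in sorted(truth_g.intact_mass_kda.items()):
            fh.write(f"{pid}\t{m}\t{truth_g.protein_lengths[pid]}\n")
    truth_g.to_json(out / "truth_gel.json")
    return {"dir": str(out)}
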
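"""Membrane-topology classification from signal-peptide and TM-helix calls.

Single-pass topology follows from two binary facts: a cleavable signal
peptide routes the N-terminus into the ER lumen, and a transmembrane
helix anchors the chain. Signal + no helix = secreted; signal + helix =
Type I (N-terminus luminal); helix without a cleavable signal = Type II
(the helix is an internal signal anchor, N-terminus cytosolic); neither
= not membrane/secretory ("other"). Helix position is deliberately not
used: a C-terminal anchor without a signal peptide is still Type II.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

from chlamysec.proteome_io import (
    SignalAnnotation,
    TopologyAnnotation,
    read_annotation_table,
)

CALLS = ("secreted", "type_I", "type_II", "other")


@dataclass(frozen=True)
class TopologyCall:
    protein_id: str
    call: str
    rationale: str


def classify_topology(
    signal_ann: SignalAnnotation, topology_ann: TopologyAnnotation,
) -> TopologyCall:
    """Assign secreted / type_I / type_II / other; rules are exhaustive
    and mutually exclusive over the (signal, helix) truth table."""
    if signal_ann.protein_id != topology_ann.protein_id:
        raise ValueError("annotation protein_id mismatch")
    has_signal = signal_ann.has_signal
    has_tm = bool(topology_ann.tm_helices)
    if has_signal and not has_tm:
        return TopologyCall(signal_ann.protein_id, "secreted",
                            "signal peptide, no TM helix")
    if has_signal and has_tm:
        return TopologyCall(signal_ann.protein_id, "type_I",
                            "signal peptide plus TM helix")
    if has_tm:
        return TopologyCall(signal_ann.protein_id, "type_II",
                            "TM helix without cleavable signal")
    return TopologyCall(signal_ann.protein_id, "other",
                        "no signal peptide, no TM helix")


def topology_census(calls: Iterable[TopologyCall]) -> dict[str, int]:
    """Counts per call class; values sum to the number of inputs."""
    counts = Counter(c.call for c in calls)
    return {k: counts.get(k, 0) for k in CALLS}


def classify_maps(
    signal_map: dict[str, SignalAnnotation],
    topology_map: dict[str, TopologyAnnotation],
) -> list[TopologyCall]:
    """Classify every protein present in either map; missing annotations
    default to no signal / no helix."""
    ids = sorted(set(signal_map) | set(topology_map))
    calls = []
    for pid in ids:
        sig = signal_map.get(pid, SignalAnnotation(pid, False))
        topo = topology_map.get(pid, TopologyAnnotation(pid))
        calls.append(classify_topology(sig, topo))
    return calls


def load_s8_reference_annotations() -> tuple[
    dict[str, SignalAnnotation], dict[str, TopologyAnnotation]
]:
    """Load the packaged annotation table for the 21 S8 (subtilisin-domain)
    proteins of the *C. reinhardtii* genome (signal and TM-helix columns).

    Returns (signal_map, topology_map) ready for :func:`classify_maps`.
    """
    data = resources.files("chlamysec").joinpath("data/s8_subtilisins.tsv")
    signal_map: dict[str, SignalAnnotation] = {}
    topology_map: dict[str, TopologyAnnotation] = {}
    with resources.as_file(data) as path:
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                pid, length, signal, tm = line.rstrip("\n").split("\t")
                if pid == "protein_id":
                    continue
                if signal == "no":
                    signal_map[pid] = SignalAnnotation(pid, False)
                else:
                    end = int(signal.replace("–", "-").split("-")[1])
                    signal_map[pid] = SignalAnnotation(pid, True, end)
                if tm == "no":
                    topology_map[pid] = TopologyAnnotation(pid)
                else:
                    lo, hi = tm.replace("–", "-").split("-")
                    topology_map[pid] = TopologyAnnotation(
                        pid, ((int(lo), int(hi)),))
    return signal_map, topology_map


def calls_to_tsv(calls: Iterable[TopologyCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tcall\trationale\n")
        for c in calls:
            fh.write(f"{c.protein_id}\t{c.call}\t{c.rationale}\n")
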
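"""Protein FASTA and annotation-table input, and secretome pre-filtering.

The analysis input set is the subset of a proteome carrying a predicted
N-terminal signal peptide (SignalP-style call) and no transmembrane
helix (TMHMM-style spans) — soluble proteins routed into the secretory
pathway. Predictions are consumed as annotation tables, never computed
here.

Conventions: positions are 1-based inclusive throughout; sequences are
upper-cased and trailing stop symbols ``*`` stripped at read time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

LOCALIZATION_CATEGORIES = frozenset({"C", "M", "SP", "O", "NA"})


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry.

    Attributes
    ----------
    protein_id : unique identifier (first whitespace-delimited header token,
        e.g. ``Cre01.g049950``).
    description : remainder of the FASTA header.
    sequence : amino-acid string over the 20-letter alphabet (X allowed).
    """

    protein_id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.protein_id!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SignalAnnotation:
    """Signal-peptide call; ``signal_end`` is the last signal residue (1-based)."""

    protein_id: str
    has_signal: bool
    signal_end: int | None = None

    def __post_init__(self) -> None:
        if self.has_signal and (self.signal_end is None or self.signal_end < 1):
            raise ValueError(
                f"{self.protein_id}: has_signal requires signal_end >= 1"
            )


@dataclass(frozen=True)
class TopologyAnnotation:
    """Transmembrane-helix spans, 1-based inclusive, ordered, non-overlapping."""

    protein_id: str
    tm_helices: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.tm_helices:
            if start < 1 or end < start:
                raise ValueError(f"{self.protein_id}: bad TM span {start}-{end}")
            if start <= prev_end:
                raise ValueError(
                    f"{self.protein_id}: TM spans overlap or are unordered"
                )
            prev_end = end


@dataclass(frozen=True)
class LocalizationAnnotation:
    """Subcellular localization category.

    One of C (chloroplast), M (mitochondrion), SP (secretory pathway),
    O (other), NA (not assigned) — the PredAlgo class set.
    """

    protein_id: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in LOCALIZATION_CATEGORIES:
            raise ValueError(
                f"{self.protein_id}: unknown localization {self.category!r}"
            )


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into a list of :class:`ProteinRecord`.

    Sequences are upper-cased and trailing ``*`` stop symbols stripped.
    Order is preserved. Duplicate ids and empty sequences raise ``ValueError``.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        pid = entry.id
        if pid in seen:
            raise ValueError(f"duplicate protein id in FASTA: {pid!r}")
        seen.add(pid)
        seq = str(entry.seq).upper().rstrip("*")
        if not seq:
            raise ValueError(f"empty sequence in FASTA for {pid!r}")
        desc = entry.description
        if desc.startswith(pid):
            desc = desc[len(pid):].strip()
        records.append(ProteinRecord(pid, seq, desc))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA; round-trips ids and sequences exactly."""
    entries = [
        SeqRecord(Seq(r.sequence), id=r.protein_id, description=r.description)
        for r in records
    ]
    SeqIO.write(entries, str(path), "fasta")


def _parse_spans(text: str) -> tuple[tuple[int, int], ...]:
    """Parse ``37-59;100-120`` style span lists; ``-`` or ``no`` mean none."""
    text = text.strip()
    if text in {"-", "", "no", "none"}:
        return ()
    spans = []
    for token in text.split(";"):
        token = token.strip().replace("–", "-")  # en-dash tolerated
        lo, hi = token.split("-")
        spans.append((int(lo), int(hi)))
    return tuple(spans)


def read_annotation_table(path: str | Path, kind: str) -> dict:
    """Read a tab-separated annotation table keyed by protein_id.

    Layouts (no header row required; a header starting with ``protein_id``
    or ``#`` is skipped):

    * ``signal``:       protein_id <TAB> Y/N <TAB> signal_end (``-`` when N)
    * ``topology``:     protein_id <TAB> semicolon-separated start-end spans or ``-``
    * ``localization``: protein_id <TAB> one of C/M/SP/O/NA

    Unparseable rows raise ``ValueError`` naming the row number.
    """
    if kind not in {"signal", "topology", "localization"}:
        raise ValueError(f"unknown annotation kind {kind!r}")
    out: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] in {"protein_id", "id"}:
                continue
            try:
                pid = fields[0].strip()
                if kind == "signal":
                    flag = fields[1].strip().upper()
                    if flag not in {"Y", "N"}:
                        raise ValueError(f"signal flag must be Y/N, got {flag!r}")
                    if flag == "Y":
                        out[pid] = SignalAnnotation(pid, True, int(fields[2]))
                    else:
                        out[pid] = SignalAnnotation(pid, False)
                elif kind == "topology":
                    out[pid] = TopologyAnnotation(pid, _parse_spans(fields[1]))
                else:
                    out[pid] = LocalizationAnnotation(pid, fields[1].strip().upper())
            except (IndexError, ValueError) as exc:
                raise ValueError(
                    f"{path}: cannot parse {kind} row {lineno}: {line!r} ({exc})"
                ) from exc
    return out


def select_secreted_soluble(
    records: Iterable[ProteinRecord],
    signal_map: dict[str, SignalAnnotation],
    topology_map: dict[str, TopologyAnnotation],
) -> list[ProteinRecord]:
    """Keep proteins with a signal peptide and no transmembrane helix.

    Records lacking an annotation row default to no-signal / no-helix
    (prediction tools routinely omit negatives); every defaulted id is
    logged. Idempotent on its own output; result is a subset of the input.
    """
    records = list(records)
    kept: list[ProteinRecord] = []
    for rec in records:
        sig = signal_map.get(rec.protein_id)
        if sig is None:
            logger.info("no signal annotation for %s; treated as no signal",
                        rec.protein_id)
            sig = SignalAnnotation(rec.protein_id, False)
        topo = topology_map.get(rec.protein_id)
        if topo is None:
            logger.info("no topology annotation for %s; treated as zero helices",
                        rec.protein_id)
            topo = TopologyAnnotation(rec.protein_id)
        if sig.has_signal and not topo.tm_helices:
            kept.append(rec)
    logger.info("select_secreted_soluble: kept %d of %d proteins",
                len(kept), len(records))
    return kept


# --- convenience converters from raw predictor outputs -----------------------

def signalp_short_to_tsv(path_in: str | Path, path_out: str | Path) -> int:
    """Convert SignalP 4.1 short-format output to the signal TSV layout.

    Columns used: name (1), D-score decision ``?`` column ``Y``/``N`` (10th,
    header ``D``-cutoff decision) and Ymax position for the cleavage site.
    Returns the number of rows written.
    """
    n = 0
    with open(path_in) as fh, open(path_out, "w") as out:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.split()
            # name Cmax pos Ymax pos Smax pos Smean D ? Dmaxcut net
            pid, ymax_pos, decision = f[0], int(f[4]), f[9]
            if decision == "Y":
                out.write(f"{pid}\tY\t{ymax_pos - 1}\n")
            else:
                out.write(f"{pid}\tN\t-\n")
            n += 1
    return n


def tmhmm_long_to_tsv(path_in: str | Path, path_out: str | Path) -> int:
    """Convert TMHMM 2.0 long-format output to the topology TSV layout."""
    helices: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path_in) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.split()
            pid = f[0]
            if pid not in helices:
                helices[pid] = []
                order.append(pid)
            if len(f) >= 5 and f[2] == "TMhelix":
                helices[pid].append((int(f[3]), int(f[4])))
    with open(path_out, "w") as out:
        for pid in order:
            spans = helices[pid]
            text = ";".join(f"{a}-{b}" for a, b in spans) if spans else "-"
            out.write(f"{pid}\t{text}\n")
    return len(order)
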
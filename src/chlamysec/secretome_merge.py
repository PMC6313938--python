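"""Merge six per-sample spectral-count tables into a filtered secretome.

Label-free spectral counts from replicate secretome preparations (two
datasets of three samples each, A-C and D-F) are scaled to a common
total (Scaffold-style "normalized spectral counts"), merged by protein,
filtered by a minimum-presence rule (seen in at least four of the six
samples), summarized as mean +/- SEM with absent samples contributing
zero, and ranked by abundance. A localization triage then flags the
signal-peptide-containing ("soluble secretome") subset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from chlamysec.proteome_io import LocalizationAnnotation, SignalAnnotation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SampleRun:
    """One sample's protein -> spectral-count table; absence is omission."""

    sample_id: str
    dataset_id: int
    counts: dict[str, float]

    def __post_init__(self) -> None:
        bad = [p for p, c in self.counts.items() if c <= 0]
        if bad:
            raise ValueError(
                f"sample {self.sample_id}: non-positive counts for {bad[:3]}")

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))


@dataclass
class MergedProtein:
    """Per-protein presence and normalized spectral-count statistics."""

    protein_id: str
    presence: int
    normalized_counts: dict[str, float]
    avg_total: float
    sem: float
    rank: int | None = None
    is_signal_peptide: bool | None = None


def read_sample_tsv(path: str | Path, sample_id: str, dataset_id: int) -> SampleRun:
    """Read a per-sample TSV (protein_id, spectral_count)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["protein_id", "count"])
    df = df[df["protein_id"] != "protein_id"]
    return SampleRun(sample_id, dataset_id,
                     dict(zip(df["protein_id"], df["count"].astype(float))))


def normalize_counts(samples: Sequence[SampleRun]) -> list[SampleRun]:
    """Scale each sample so all per-sample totals equal the mean total.

    A sample's counts are multiplied by (mean total over samples) /
    (that sample's total); with one sample this is the identity.
    """
    if not samples:
        raise ValueError("need at least one sample")
    totals = [s.total for s in samples]
    if any(t == 0 for t in totals):
        raise ValueError("sample with zero total spectral counts")
    mean_total = float(np.mean(totals))
    out = []
    for s, t in zip(samples, totals):
        factor = mean_total / t
        out.append(replace(s, counts={p: c * factor for p, c in s.counts.items()}))
    return out


def merge_and_filter(
    samples: Sequence[SampleRun], min_presence: int = 4,
) -> list[MergedProtein]:
    """Union the samples, drop proteins seen in fewer than ``min_presence``.

    ``avg_total`` is the mean normalized count over all samples with
    absent samples contributing 0; ``sem`` is the sample standard
    deviation (n-1 denominator) divided by sqrt(n), n = number of
    samples. Sample order does not affect the result.
    """
    if min_presence > len(samples):
        raise ValueError(
            f"min_presence={min_presence} exceeds {len(samples)} samples")
    n = len(samples)
    all_ids = sorted(set().union(*(s.counts.keys() for s in samples)))
    merged = []
    for pid in all_ids:
        values = {s.sample_id: s.counts.get(pid, 0.0) for s in samples}
        presence = sum(1 for v in values.values() if v > 0)
        if presence < min_presence:
            continue
        vec = np.array(sorted(values.values()))  # order-free statistics
        avg = float(vec.mean())
        sem = float(vec.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        merged.append(MergedProtein(pid, presence, values, avg, sem))
    return merged


def dataset_census(samples: Sequence[SampleRun]) -> dict[str, int]:
    """Protein counts per dataset, their union and intersection."""
    per: dict[int, set[str]] = {}
    for s in samples:
        per.setdefault(s.dataset_id, set()).update(s.counts)
    sets = list(per.values())
    union = set().union(*sets) if sets else set()
    inter = set.intersection(*sets) if sets else set()
    out = {f"dataset_{d}": len(ids) for d, ids in sorted(per.items())}
    out["union"] = len(union)
    out["intersection"] = len(inter)
    return out


def triage_signal_peptide(
    merged: Iterable[MergedProtein],
    localization_map: dict[str, LocalizationAnnotation],
    signal_map: dict[str, SignalAnnotation],
) -> list[MergedProtein]:
    """Flag the soluble-secretome subset.

    A protein is signal-peptide-positive when its localization category
    is SP, or when it is O/NA but carries a signal-peptide call. C and M
    proteins are excluded even with a signal call (organellar transit
    peptides confound the predictor). Missing annotations default to
    NA / no signal and are logged.
    """
    out = []
    for m in merged:
        loc = localization_map.get(m.protein_id)
        if loc is None:
            logger.info("no localization for %s; treated as NA", m.protein_id)
            category = "NA"
        else:
            category = loc.category
        sig = signal_map.get(m.protein_id)
        has_signal = bool(sig and sig.has_signal)
        flag = category == "SP" or (category in {"O", "NA"} and has_signal)
        out.append(replace_flag(m, flag))
    return out


def replace_flag(m: MergedProtein, flag: bool) -> MergedProtein:
    return MergedProtein(m.protein_id, m.presence, m.normalized_counts,
                         m.avg_total, m.sem, m.rank, flag)


def rank_and_share(
    merged: Sequence[MergedProtein], n: int,
) -> tuple[list[MergedProtein], float]:
    """Rank by descending ``avg_total`` and report the top-n count share.

    Ties break lexicographically by protein_id for determinism. The
    share is the top-n sum of ``avg_total`` over the total sum, in
    [0, 1], non-decreasing in n, and 1 at n = N.
    """
    if not 1 <= n <= len(merged):
        raise ValueError(f"n must be in 1..{len(merged)}")
    ordered = sorted(merged, key=lambda m: (-m.avg_total, m.protein_id))
    ranked = [
        MergedProtein(m.protein_id, m.presence, m.normalized_counts,
                      m.avg_total, m.sem, i + 1, m.is_signal_peptide)
        for i, m in enumerate(ordered)
    ]
    total = sum(m.avg_total for m in ranked)
    share = sum(m.avg_total for m in ranked[:n]) / total if total > 0 else 0.0
    return ranked[:n], share


def merged_to_tsv(merged: Sequence[MergedProtein], path: str | Path) -> None:
    """Export ranked merged proteins (rank, accession, avg, sem/avg, presence)."""
    ordered = sorted(merged, key=lambda m: (-m.avg_total, m.protein_id))
    with open(path, "w") as fh:
        fh.write("rank\taccession\tavg_total_spectral_counts\tsem_over_avg\t"
                 "presence\tis_signal_peptide\n")
        for i, m in enumerate(ordered, start=1):
            rel = m.sem / m.avg_total if m.avg_total > 0 else 0.0
            flag = {True: "Y", False: "N", None: "-"}[m.is_signal_peptide]
            fh.write(f"{i}\t{m.protein_id}\t{m.avg_total:.1f}\t{rel:.2f}\t"
                     f"{m.presence}\t{flag}\n")
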
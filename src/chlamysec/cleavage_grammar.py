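"""Motif grammar for prohormone-convertase, furin and amidation sites.

Prohormone convertases (PCs) cleave precursor proteins C-terminal to
single or paired basic residues, here modelled as (K/R)X_n(K/R) with a
configurable spacing set; furin recognizes RX(K/R)R. Carboxypeptidase
B-like trimming then exposes C-terminal glycines that peptidylglycine
alpha-amidating monooxygenase (PAM) converts into C-terminal amides,
so amidation potential is screened as glycine-containing basic motifs
(G(K/R)(K/R); (K/R)X_nG(K/R), n in {1,3}; RG(K/R)R) plus terminal
-Gly / -Gly-(K/R)_n endings that need no endoprotease.

All matchers report every match, including overlapping and nested ones;
deduplication is a downstream concern. Positions are 1-based inclusive
and the cleavage point is "after residue i".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

BASIC = frozenset("KR")

#: NeuroPred-style "known motifs": mono-/dibasic plus spaced patterns.
#: The exact published table is user-replaceable via MotifConfig files.
DEFAULT_KNOWN_MOTIFS = ("KR", "RR", "KK", "RK", "KXXK", "KXXR", "RXXK", "RXXR")
DEFAULT_EXCLUDED_MOTIFS = ("RK", "KXXK", "KXXR")


@dataclass(frozen=True)
class CleavageSite:
    """A matched endoproteolytic motif; scissile bond after ``cleavage_after``."""

    protein_id: str
    site_class: str            # "PC", "furin" or "known_motif"
    motif_text: str
    start: int                 # 1-based inclusive span of the match
    end: int
    cleavage_after: int


@dataclass(frozen=True)
class AmidationSite:
    """An amidation motif; ``gly_position`` is the amide-donating glycine."""

    protein_id: str
    site_class: str            # G_KR_KR, KR_XnG_KR, RG_KR_R,
                               # terminal_G, terminal_G_basic_tail
    gly_position: int
    start: int
    end: int


@dataclass(frozen=True)
class MotifConfig:
    """Tunable motif-grammar parameters.

    ``pc_spacings`` is the set of allowed X_n spacer lengths between the two
    basic residues of a PC site ({0,2,4,6} by default; {0,2} is the common
    restricted variant, available as the ``results-spacings`` preset).
    ``known_motifs`` patterns are strings over {K, R, X} with X = any
    residue; matches whose text also fits an ``excluded_motifs`` pattern
    are removed after matching.
    """

    pc_spacings: frozenset[int] = frozenset({0, 2, 4, 6})
    amidation_spacings: frozenset[int] = frozenset({1, 3})
    known_motifs: tuple[str, ...] = DEFAULT_KNOWN_MOTIFS
    excluded_motifs: tuple[str, ...] = DEFAULT_EXCLUDED_MOTIFS
    max_basic_tail: int = 3

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.pc_spacings | self.amidation_spacings):
            raise ValueError("spacings must be non-negative")
        if self.max_basic_tail < 1:
            raise ValueError("max_basic_tail must be >= 1")
        for pat in tuple(self.known_motifs) + tuple(self.excluded_motifs):
            if not pat or set(pat) - set("KRX"):
                raise ValueError(
                    f"motif pattern {pat!r} must be non-empty over {{K,R,X}}"
                )

    @classmethod
    def default_file(cls) -> "MotifConfig":
        """Load the packaged default configuration file
        (``data/known_motifs.yaml``); equal to ``MotifConfig()``."""
        from importlib import resources
        data = resources.files("chlamysec").joinpath("data/known_motifs.yaml")
        with resources.as_file(data) as path:
            return cls.from_yaml(path)

    @classmethod
    def preset(cls, name: str) -> "MotifConfig":
        """Named presets: ``methods-spacings`` ({0,2,4,6}) and
        ``results-spacings`` ({0,2})."""
        if name == "methods-spacings":
            return cls()
        if name == "results-spacings":
            return cls(pc_spacings=frozenset({0, 2}))
        raise ValueError(f"unknown preset {name!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MotifConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "pc_spacings" in raw:
            kwargs["pc_spacings"] = frozenset(int(n) for n in raw["pc_spacings"])
        if "amidation_spacings" in raw:
            kwargs["amidation_spacings"] = frozenset(
                int(n) for n in raw["amidation_spacings"])
        if "known_motifs" in raw:
            kwargs["known_motifs"] = tuple(raw["known_motifs"])
        if "excluded_motifs" in raw:
            kwargs["excluded_motifs"] = tuple(raw["excluded_motifs"])
        if "max_basic_tail" in raw:
            kwargs["max_basic_tail"] = int(raw["max_basic_tail"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "pc_spacings": sorted(self.pc_spacings),
            "amidation_spacings": sorted(self.amidation_spacings),
            "known_motifs": list(self.known_motifs),
            "excluded_motifs": list(self.excluded_motifs),
            "max_basic_tail": self.max_basic_tail,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def find_pc_sites(
    sequence: str, config: MotifConfig | None = None, protein_id: str = "",
) -> list[CleavageSite]:
    """All (K/R)X_n(K/R) matches with n in ``config.pc_spacings``.

    The intervening X residues are unconstrained (they may themselves be
    basic), so overlapping and nested sites are all reported, sorted by
    (end, start). Cleavage is after the second basic residue.
    """
    config = config or MotifConfig()
    L = len(sequence)
    sites = []
    for end in range(1, L + 1):                     # 1-based
        if sequence[end - 1] not in BASIC:
            continue
        for n in config.pc_spacings:
            start = end - n - 1
            if start >= 1 and sequence[start - 1] in BASIC:
                sites.append(CleavageSite(
                    protein_id, "PC", sequence[start - 1:end], start, end, end))
    sites.sort(key=lambda s: (s.end, s.start))
    return sites


def find_furin_sites(sequence: str, protein_id: str = "") -> list[CleavageSite]:
    """All RX(K/R)R matches; cleavage after the final arginine."""
    sites = []
    for start in range(1, len(sequence) - 2):
        s = sequence[start - 1:start + 3]
        if s[0] == "R" and s[2] in BASIC and s[3] == "R":
            sites.append(CleavageSite(
                protein_id, "furin", s, start, start + 3, start + 3))
    return sites


def find_amidation_sites(
    sequence: str, config: MotifConfig | None = None, protein_id: str = "",
) -> list[AmidationSite]:
    """Internal amidation motifs: G(K/R)(K/R), (K/R)X_nG(K/R), RG(K/R)R.

    ``gly_position`` marks the glycine that would be left C-terminal after
    endoproteolytic cleavage and carboxypeptidase trimming, i.e. the PAM
    substrate glycine. One record per (class, position); a glycine may
    satisfy several classes.
    """
    config = config or MotifConfig()
    L = len(sequence)
    sites = []
    for g in range(1, L + 1):
        if sequence[g - 1] != "G":
            continue
        # G(K/R)(K/R)
        if g + 2 <= L and sequence[g] in BASIC and sequence[g + 1] in BASIC:
            sites.append(AmidationSite(protein_id, "G_KR_KR", g, g, g + 2))
        # (K/R)X_nG(K/R)
        for n in config.amidation_spacings:
            start = g - n - 1
            if (start >= 1 and g + 1 <= L
                    and sequence[start - 1] in BASIC
                    and sequence[g] in BASIC):
                sites.append(AmidationSite(
                    protein_id, "KR_XnG_KR", g, start, g + 1))
        # RG(K/R)R
        if (g >= 2 and g + 2 <= L and sequence[g - 2] == "R"
                and sequence[g] in BASIC and sequence[g + 1] == "R"):
            sites.append(AmidationSite(protein_id, "RG_KR_R", g, g - 1, g + 2))
    sites.sort(key=lambda s: (s.gly_position, s.start, s.site_class))
    return sites


def find_terminal_amidation(
    sequence: str, config: MotifConfig | None = None, protein_id: str = "",
) -> AmidationSite | None:
    """C-terminal -Gly or -Gly-(K/R)_n ending (no endoprotease required).

    Returns ``terminal_G`` when the final residue is glycine,
    ``terminal_G_basic_tail`` when a glycine is followed only by 1 to
    ``max_basic_tail`` basic residues, else ``None``.
    """
    if not sequence:
        raise ValueError("empty sequence")
    config = config or MotifConfig()
    L = len(sequence)
    if sequence[-1] == "G":
        return AmidationSite(protein_id, "terminal_G", L, L, L)
    tail = 0
    i = L
    while i >= 1 and sequence[i - 1] in BASIC and tail < config.max_basic_tail:
        tail += 1
        i -= 1
    if tail >= 1 and i >= 1 and sequence[i - 1] == "G":
        return AmidationSite(protein_id, "terminal_G_basic_tail", i, i, L)
    return None


def _pattern_matches(text: str, pattern: str) -> bool:
    """True when ``text`` fits a {K,R,X}-pattern of the same length."""
    return len(text) == len(pattern) and all(
        p == "X" or p == c for p, c in zip(pattern, text))


def find_known_motif_sites(
    sequence: str, config: MotifConfig | None = None, protein_id: str = "",
) -> list[CleavageSite]:
    """Match every ``known_motifs`` pattern, then drop excluded matches.

    A match is removed when its matched text fits any ``excluded_motifs``
    pattern (exclusion is applied to the text, after matching). Cleavage
    is after the final residue of the motif.
    """
    config = config or MotifConfig()
    if not config.known_motifs:
        raise ValueError("known_motifs must be non-empty")
    L = len(sequence)
    sites = []
    seen: set[tuple[int, int]] = set()
    for pattern in config.known_motifs:
        w = len(pattern)
        for start in range(1, L - w + 2):
            text = sequence[start - 1:start - 1 + w]
            if not _pattern_matches(text, pattern):
                continue
            if any(_pattern_matches(text, ex) for ex in config.excluded_motifs):
                continue
            span = (start, start + w - 1)
            if span in seen:        # same text matched by two patterns
                continue
            seen.add(span)
            sites.append(CleavageSite(
                protein_id, "known_motif", text, span[0], span[1], span[1]))
    sites.sort(key=lambda s: (s.end, s.start))
    return sites


def sites_to_tsv(sites, path: str | Path) -> None:
    """Export a site list as TSV (protein_id, class, motif, start, end, cleavage_after)."""
    with open(path, "w") as fh:
        fh.write("protein_id\tclass\tmotif\tstart\tend\tcleavage_after\n")
        for s in sites:
            if isinstance(s, CleavageSite):
                fh.write(f"{s.protein_id}\t{s.site_class}\t{s.motif_text}\t"
                         f"{s.start}\t{s.end}\t{s.cleavage_after}\n")
            else:
                fh.write(f"{s.protein_id}\t{s.site_class}\tG@{s.gly_position}\t"
                         f"{s.start}\t{s.end}\t-\n")
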
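"""Activation-loop motif catalog, classification and census summaries.

The canonical MAPK activation-loop motifs are T-E-Y, T-G-Y, T-D-Y and T-P-Y;
nine additional variants (T-T-Y, T-I-Y, T-N-Y, T-H-Y, T-S-Y, K-G-Y, T-Q-Y,
S-E-Y, S-D-Y) have been described in fungi. Motifs are stored undelimited
("TEY") and rendered dashed ("T-E-Y") only in reports. The group map assigns
motifs to the four major phylogenetic groups A-D of fungal MAPKs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .scan import KinaseAnnotation

CANONICAL_MOTIFS: tuple[str, ...] = ("TEY", "TGY", "TDY", "TPY")
NOVEL_MOTIFS: tuple[str, ...] = (
    "TTY", "TIY", "TNY", "THY", "TSY", "KGY", "TQY", "SEY", "SDY",
)
#: Motif -> phylogenetic groups; T-D-Y itself has not been observed in
#: fungal MAPKs, so it carries no fungal group.
DEFAULT_GROUP_MAP: dict[str, frozenset[str]] = {
    "TEY": frozenset("ABCD"),
    "TGY": frozenset("ABCD"),
    "TNY": frozenset("AC"),
    "KGY": frozenset("AC"),
    "THY": frozenset("AB"),
    "TSY": frozenset("A"),
    "TQY": frozenset("B"),
    "TIY": frozenset("D"),
    "TTY": frozenset("D"),
    "SEY": frozenset("D"),
    "SDY": frozenset("D"),
}

GROUP_LABELS = frozenset("ABCD")


def dashed(motif: str) -> str:
    """Render 'TEY' as 'T-E-Y' for reports."""
    return "-".join(motif)


@dataclass(frozen=True)
class MotifCatalog:
    canonical: tuple[str, ...] = CANONICAL_MOTIFS
    novel: tuple[str, ...] = NOVEL_MOTIFS
    group_map: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_MAP)
    )

    def __post_init__(self) -> None:
        overlap = set(self.canonical) & set(self.novel)
        if overlap:
            raise ValueError(f"motifs both canonical and novel: {sorted(overlap)}")
        known = set(self.canonical) | set(self.novel)
        for motif, groups in self.group_map.items():
            if motif not in known:
                raise ValueError(f"group_map motif {motif!r} not in catalog")
            if not set(groups) <= GROUP_LABELS:
                raise ValueError(f"bad group labels for {motif!r}: {sorted(groups)}")

    @property
    def order(self) -> tuple[str, ...]:
        """Catalog display order: canonical motifs first, then novel."""
        return self.canonical + self.novel

    def sort_motifs(self, motifs: Iterable[str]) -> list[str]:
        """De-duplicate and order motifs by catalog order; unknown motifs
        trail in first-appearance order."""
        rank = {m: i for i, m in enumerate(self.order)}
        seen: list[str] = []
        for m in motifs:
            if m not in seen:
                seen.append(m)
        return sorted(seen, key=lambda m: (rank.get(m, len(rank)), seen.index(m)))

    @classmethod
    def default(cls) -> "MotifCatalog":
        return cls()

    @classmethod
    def from_config(cls, path: str | Path) -> "MotifCatalog":
        """Load from YAML with keys canonical, novel, group_map."""
        with open(path, encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh) or {}
        kwargs = {}
        if "canonical" in cfg:
            kwargs["canonical"] = tuple(str(m).upper() for m in cfg["canonical"])
        if "novel" in cfg:
            kwargs["novel"] = tuple(str(m).upper() for m in cfg["novel"])
        if "group_map" in cfg:
            kwargs["group_map"] = {
                str(m).upper(): frozenset(str(g).upper() for g in groups)
                for m, groups in cfg["group_map"].items()
            }
        return cls(**kwargs)


@dataclass(frozen=True)
class MotifClass:
    """Classification of one triplet: status canonical/novel/unknown."""

    motif: str
    status: str
    groups: frozenset[str] = frozenset()
    note: str = ""


def classify_motif(triplet: str, catalog: MotifCatalog | None = None) -> MotifClass:
    """Exact-match lookup of a 3-residue triplet against the catalog.

    Case-insensitive; anything outside the catalog is 'unknown'. T-D-Y is
    flagged as unobserved among fungal MAPKs.
    """
    catalog = catalog or MotifCatalog.default()
    if len(triplet) != 3:
        raise ValueError(f"triplet must have length 3, got {triplet!r}")
    motif = triplet.upper()
    note = "not observed in fungal MAPKs" if motif == "TDY" else ""
    groups = frozenset(catalog.group_map.get(motif, frozenset()))
    if motif in catalog.canonical:
        return MotifClass(motif, "canonical", groups, note)
    if motif in catalog.novel:
        return MotifClass(motif, "novel", groups, note)
    return MotifClass(motif, "unknown", frozenset(), note)


@dataclass(frozen=True)
class SpeciesSummary:
    """One census row: species, division, MAPK count, motif repertoire."""

    genus: str
    species_epithet: str
    division: str
    n_mapks: int
    motif_set: tuple[str, ...]

    @property
    def species(self) -> str:
        return f"{self.genus} {self.species_epithet}".strip()


def summarize_by_species(
    annotations: Sequence[KinaseAnnotation],
    catalog: MotifCatalog | None = None,
) -> list[SpeciesSummary]:
    """Per-species census: MAPK count and de-duplicated motif repertoire.

    Rows appear in order of first appearance; motif sets follow catalog
    order (canonical first).
    """
    catalog = catalog or MotifCatalog.default()
    order: list[tuple[str, str]] = []
    per_species: dict[tuple[str, str], list[KinaseAnnotation]] = {}
    for ann in annotations:
        key = (ann.genus, ann.species_epithet)
        if key not in per_species:
            per_species[key] = []
            order.append(key)
        per_species[key].append(ann)
    rows = []
    for key in order:
        anns = per_species[key]
        rows.append(
            SpeciesSummary(
                genus=key[0],
                species_epithet=key[1],
                division=anns[0].division,
                n_mapks=len(anns),
                motif_set=tuple(catalog.sort_motifs(a.triplet for a in anns)),
            )
        )
    return rows


def summarize_by_group(
    annotations: Sequence[KinaseAnnotation],
    groups: Mapping[str, str],
    catalog: MotifCatalog | None = None,
) -> dict[str, tuple[str, ...]]:
    """Union of motif labels per phylogenetic group, in catalog order.

    ``groups`` maps record ids to group labels (A-D); labels outside A-D
    raise, annotations without a group assignment are skipped, and groups
    with no annotations are omitted.
    """
    catalog = catalog or MotifCatalog.default()
    per_group: dict[str, list[str]] = {}
    for ann in annotations:
        label = groups.get(ann.record_id)
        if label is None:
            continue
        if label not in GROUP_LABELS:
            raise ValueError(f"unknown group label {label!r} for {ann.record_id!r}")
        per_group.setdefault(label, []).append(ann.triplet)
    return {
        g: tuple(catalog.sort_motifs(motifs))
        for g, motifs in sorted(per_group.items())
    }


def make_gene_name(genus: str, species_epithet: str) -> str:
    """Two-letter gene-symbol prefix + 'MPK': uppercase genus initial,
    lowercase species-epithet initial (e.g. AkMPK)."""
    if not genus or not genus.isalpha():
        raise ValueError(f"genus must be non-empty alphabetic, got {genus!r}")
    if not species_epithet or not species_epithet.isalpha():
        raise ValueError(
            f"species epithet must be non-empty alphabetic, got {species_epithet!r}"
        )
    return genus[0].upper() + species_epithet[0].lower() + "MPK"


def paralog_names(genus: str, species_epithet: str, count: int) -> list[str]:
    """Gene names for ``count`` paralogs: a bare name for a single gene,
    -A/-B/... suffixes in first-appearance order otherwise."""
    base = make_gene_name(genus, species_epithet)
    if count < 1:
        raise ValueError("count must be >= 1")
    if count == 1:
        return [base]
    if count > 26:
        raise ValueError("more than 26 paralogs not supported")
    return [f"{base}-{chr(ord('A') + i)}" for i in range(count)]
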
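"""Kinase-domain anchoring and activation-loop triplet extraction.

MAPK catalytic domains carry two short conserved anchors flanking the
activation loop: the catalytic-loop H-R-D-L-K-P-N on the N-terminal side and
T-R-W-Y-R-A-P (the APE-region tryptophan block) on the C-terminal side. The
dual-phosphorylation T-x-Y triplet sits between them. The scanner locates
both anchors (tolerating a small mismatch budget), pairs each N-anchor hit
with the nearest downstream C-anchor hit, and extracts the triplet whose
third residue is the phospho-acceptor tyrosine.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .prosite import PrositePattern, match_pattern, parse_prosite
from .seqio import ProteinRecord

N_ANCHOR_DEFAULT = "H-R-D-L-K-P-N"
C_ANCHOR_DEFAULT = "T-R-W-Y-R-A-P"


@dataclass(frozen=True)
class AnchorCatalog:
    """Anchors and selection thresholds for activation-loop scanning.

    ``offset_window`` bounds the number of residues between the triplet's
    last position and the C-anchor start; ``first_residues`` constrains the
    triplet's phospho-acceptor first position (T/S/K covers every reported
    fungal activation-loop motif).
    """

    n_anchor: PrositePattern
    c_anchor: PrositePattern
    max_mismatches: int = 2
    first_residues: frozenset[str] = frozenset("TSK")
    offset_window: tuple[int, int] = (4, 14)

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        lo, hi = self.offset_window
        if lo > hi:
            raise ValueError("offset_window min must be <= max")

    @classmethod
    def default(cls, **overrides) -> "AnchorCatalog":
        return cls(
            n_anchor=parse_prosite(N_ANCHOR_DEFAULT),
            c_anchor=parse_prosite(C_ANCHOR_DEFAULT),
            **overrides,
        )

    @classmethod
    def from_config(cls, path: str | Path) -> "AnchorCatalog":
        """Load from a YAML config with keys n_anchor, c_anchor,
        max_mismatches, first_residues, offset_window."""
        with open(path, encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh) or {}
        kwargs = {}
        if "n_anchor" in cfg:
            kwargs["n_anchor"] = parse_prosite(cfg["n_anchor"])
        else:
            kwargs["n_anchor"] = parse_prosite(N_ANCHOR_DEFAULT)
        if "c_anchor" in cfg:
            kwargs["c_anchor"] = parse_prosite(cfg["c_anchor"])
        else:
            kwargs["c_anchor"] = parse_prosite(C_ANCHOR_DEFAULT)
        if "max_mismatches" in cfg:
            kwargs["max_mismatches"] = int(cfg["max_mismatches"])
        if "first_residues" in cfg:
            kwargs["first_residues"] = frozenset(str(cfg["first_residues"]).upper())
        if "offset_window" in cfg:
            lo, hi = cfg["offset_window"]
            kwargs["offset_window"] = (int(lo), int(hi))
        return cls(**kwargs)


@dataclass(frozen=True)
class KinaseAnnotation:
    """One located kinase domain: anchor spans and the extracted triplet.

    All spans are 1-based inclusive ``(start, end)`` intervals on the
    unaligned protein sequence; ``loop_span`` is the region strictly between
    the anchors. ``anchor_mismatches`` is (n_anchor, c_anchor) mismatch
    counts.
    """

    record_id: str
    n_anchor_span: tuple[int, int]
    c_anchor_span: tuple[int, int]
    loop_span: tuple[int, int]
    triplet: str
    triplet_span: tuple[int, int]
    anchor_mismatches: tuple[int, int]
    genus: str = ""
    species_epithet: str = ""
    division: str = ""

    def __post_init__(self) -> None:
        if len(self.triplet) != 3:
            raise ValueError("triplet must have length 3")
        if self.triplet[2] != "Y":
            raise ValueError("triplet third residue must be Y")
        if not (
            self.n_anchor_span[1]
            < self.triplet_span[0]
            <= self.triplet_span[1]
            < self.c_anchor_span[0]
        ):
            raise ValueError("triplet must lie strictly between the anchors")

    @property
    def total_mismatches(self) -> int:
        return sum(self.anchor_mismatches)


def extract_activation_motif(
    rec: ProteinRecord,
    n_span: tuple[int, int],
    c_span: tuple[int, int],
    catalog: AnchorCatalog,
) -> tuple[str, tuple[int, int]] | None:
    """Pick the T-x-Y-like triplet between the anchor spans.

    Candidates are positions i in the open inter-anchor region whose residue
    is in ``catalog.first_residues`` with a Y two positions downstream
    (also inside the region). Preference: the candidate whose distance from
    triplet end to C-anchor start lies in ``offset_window`` and is closest to
    the C-anchor; failing any in-window candidate, the one closest to the
    C-anchor overall; ties (not geometrically possible for distinct starts)
    break leftmost. Returns None when no candidate exists.
    """
    seq = rec.residues
    lo = n_span[1] + 1  # first 1-based position of the open region
    hi = c_span[0] - 1  # last position of the open region
    candidates: list[tuple[int, int]] = []  # (offset to C-anchor, start)
    for i in range(lo, hi - 1):  # i+2 must be <= hi
        if seq[i - 1] in catalog.first_residues and seq[i + 1] == "Y":
            offset = c_span[0] - (i + 2) - 1
            candidates.append((offset, i))
    if not candidates:
        return None
    wlo, whi = catalog.offset_window
    in_window = [c for c in candidates if wlo <= c[0] <= whi]
    pool = in_window if in_window else candidates
    offset, start = min(pool, key=lambda c: (c[0], c[1]))
    return seq[start - 1 : start + 2], (start, start + 2)


def find_kinase_domain(
    rec: ProteinRecord, catalog: AnchorCatalog | None = None
) -> list[KinaseAnnotation]:
    """Locate kinase domains in one protein record.

    Each N-anchor hit is paired with the nearest downstream C-anchor hit that
    leaves a positive inter-anchor gap; the activation-loop triplet is then
    extracted with :func:`extract_activation_motif`. Pairs without an
    extractable triplet are dropped. Annotations are returned in sequence
    order; :func:`primary_annotation` selects the best one.
    """
    catalog = catalog or AnchorCatalog.default()
    n_hits = match_pattern(catalog.n_anchor, rec.residues, catalog.max_mismatches)
    c_hits = match_pattern(catalog.c_anchor, rec.residues, catalog.max_mismatches)
    annotations: list[KinaseAnnotation] = []
    for nh in n_hits:
        downstream = [ch for ch in c_hits if ch.start > nh.end + 1]
        if not downstream:
            continue
        ch = min(downstream, key=lambda h: h.start)
        extracted = extract_activation_motif(
            rec, (nh.start, nh.end), (ch.start, ch.end), catalog
        )
        if extracted is None:
            continue
        triplet, triplet_span = extracted
        annotations.append(
            KinaseAnnotation(
                record_id=rec.id,
                n_anchor_span=(nh.start, nh.end),
                c_anchor_span=(ch.start, ch.end),
                loop_span=(nh.end + 1, ch.start - 1),
                triplet=triplet,
                triplet_span=triplet_span,
                anchor_mismatches=(nh.mismatches, ch.mismatches),
                genus=rec.genus,
                species_epithet=rec.species_epithet,
                division=rec.division,
            )
        )
    return annotations


def primary_annotation(
    annotations: list[KinaseAnnotation],
) -> KinaseAnnotation | None:
    """The annotation with fewest total anchor mismatches, then leftmost."""
    if not annotations:
        return None
    return min(
        annotations, key=lambda a: (a.total_mismatches, a.n_anchor_span[0])
    )


def scan_records(
    records: list[ProteinRecord],
    catalog: AnchorCatalog | None = None,
    primary_only: bool = False,
) -> list[KinaseAnnotation]:
    """Scan many records; concatenated annotations in input order."""
    catalog = catalog or AnchorCatalog.default()
    out: list[KinaseAnnotation] = []
    for rec in records:
        anns = find_kinase_domain(rec, catalog)
        if primary_only:
            best = primary_annotation(anns)
            anns = [best] if best else []
        out.extend(anns)
    return out
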
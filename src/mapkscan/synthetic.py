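"""Seeded synthetic-data generators.

Three generators make every pipeline stage testable without any proteome
download:

* :func:`gen_kinase_cohort` — kinase-like proteins with the two conserved
  anchors and a chosen activation-loop triplet planted at known positions,
  plus the ground truth of what was planted;
* :func:`gen_alignment` — star-genealogy alignments (one random ancestor,
  independent per-sequence per-site substitution) with a controllable
  substitution probability;
* :func:`gen_triple` — three-sequence alignments realizing an exact target
  site partition for the relative-rate test.

All generators are pure functions of (spec, seed): the same seed yields
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import brentq

from .seqio import AMINO_ACIDS, Alignment, ProteinRecord
from .scan import AnchorCatalog

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
#: Background alphabet with no tyrosine, used downstream of the planted
#: triplet so the planted candidate is always the one nearest the C-anchor.
_AA_NO_Y = np.frombuffer(AMINO_ACIDS.replace("Y", "").encode(), dtype="S1")


def _rand_residues(rng: np.random.Generator, n: int, alphabet=_AA) -> str:
    return rng.choice(alphabet, size=n).tobytes().decode()


@dataclass(frozen=True)
class SpeciesSpec:
    genus: str
    epithet: str
    division: str
    motifs: tuple[str, ...]

    def __post_init__(self) -> None:
        for m in self.motifs:
            if len(m) != 3:
                raise ValueError(f"motif {m!r} must have length 3")


@dataclass(frozen=True)
class CohortSpec:
    """A synthetic multi-species MAPK cohort.

    ``anchor_mutation_budget`` is the number of substitutions applied to
    each planted anchor (scanners with at least this mismatch budget should
    recover every planted domain). ``background_length`` bounds the random
    flanks on either side of the domain.
    """

    species: tuple[SpeciesSpec, ...]
    anchor_mutation_budget: int = 0
    background_length: tuple[int, int] = (30, 80)
    seed: int = 0

    @classmethod
    def from_config(cls, path: str | Path) -> "CohortSpec":
        with open(path, encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
        species = tuple(
            SpeciesSpec(
                genus=s["genus"],
                epithet=s["epithet"],
                division=s.get("division", ""),
                motifs=tuple(str(m).upper() for m in s["motifs"]),
            )
            for s in cfg["species"]
        )
        return cls(
            species=species,
            anchor_mutation_budget=int(cfg.get("anchor_mutation_budget", 0)),
            background_length=tuple(cfg.get("background_length", (30, 80))),
            seed=int(cfg.get("seed", 0)),
        )


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth for one generated record."""

    record_id: str
    genus: str
    epithet: str
    division: str
    motif: str
    n_anchor_span: tuple[int, int]
    c_anchor_span: tuple[int, int]
    triplet_span: tuple[int, int]


def _mutate_anchor(anchor: str, budget: int, rng: np.random.Generator) -> str:
    """Substitute exactly ``budget`` positions with residues that differ."""
    if budget == 0:
        return anchor
    if budget > len(anchor):
        raise ValueError("mutation budget exceeds anchor length")
    positions = rng.choice(len(anchor), size=budget, replace=False)
    out = list(anchor)
    for p in positions:
        alternatives = [a for a in AMINO_ACIDS if a != out[p]]
        out[p] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def gen_kinase_cohort(
    spec: CohortSpec, catalog: AnchorCatalog | None = None
) -> tuple[list[ProteinRecord], list[PlantedTruth]]:
    """Generate kinase-like records with planted anchors and triplets.

    Domain layout per record: random N-flank, N-anchor (optionally mutated
    within the budget), loop prefix, triplet, a Y-free loop suffix whose
    length falls inside the catalog's offset window, C-anchor, random
    C-flank. Returns records plus the planted ground truth.
    """
    catalog = catalog or AnchorCatalog.default()
    rng = np.random.default_rng(spec.seed)
    n_anchor = str(catalog.n_anchor).replace("-", "")
    c_anchor = str(catalog.c_anchor).replace("-", "")
    lo_bg, hi_bg = spec.background_length
    wlo, whi = catalog.offset_window
    records: list[ProteinRecord] = []
    truths: list[PlantedTruth] = []
    for sp in spec.species:
        for k, motif in enumerate(sp.motifs, start=1):
            motif = motif.upper()
            rid = f"{sp.genus}_{sp.epithet}_{k}"
            pre = _rand_residues(rng, int(rng.integers(lo_bg, hi_bg + 1)))
            loop_pre = _rand_residues(rng, int(rng.integers(5, 13)))
            loop_post = _rand_residues(
                rng, int(rng.integers(wlo, whi + 1)), alphabet=_AA_NO_Y
            )
            post = _rand_residues(rng, int(rng.integers(lo_bg, hi_bg + 1)))
            na = _mutate_anchor(n_anchor, spec.anchor_mutation_budget, rng)
            ca = _mutate_anchor(c_anchor, spec.anchor_mutation_budget, rng)
            seq = pre + na + loop_pre + motif + loop_post + ca + post
            n_start = len(pre) + 1
            n_end = n_start + len(n_anchor) - 1
            t_start = n_end + len(loop_pre) + 1
            c_start = t_start + 3 + len(loop_post)
            records.append(
                ProteinRecord(
                    id=rid,
                    residues=seq,
                    genus=sp.genus,
                    species_epithet=sp.epithet,
                    division=sp.division,
                )
            )
            truths.append(
                PlantedTruth(
                    record_id=rid,
                    genus=sp.genus,
                    epithet=sp.epithet,
                    division=sp.division,
                    motif=motif,
                    n_anchor_span=(n_start, n_end),
                    c_anchor_span=(c_start, c_start + len(c_anchor) - 1),
                    triplet_span=(t_start, t_start + 2),
                )
            )
    return records, truths


def gen_alignment(m: int, n: int, rate: float, seed: int = 0) -> Alignment:
    """Star-genealogy alignment: a uniform random ancestral sequence, each
    of ``m`` descendants substituted independently per site with probability
    ``rate`` (replacement drawn uniformly over the 20 amino acids, so the
    realized change probability is 19/20 * rate)."""
    if m < 2:
        raise ValueError("need at least 2 sequences")
    if n < 1:
        raise ValueError("need at least 1 site")
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ancestor = rng.choice(_AA, size=n)
    records = []
    for i in range(1, m + 1):
        seq = ancestor.copy()
        hit = rng.random(n) < rate
        seq[hit] = rng.choice(_AA, size=int(hit.sum()))
        records.append((f"seq{i}", seq.tobytes().decode()))
    return Alignment(tuple(records))


def neutral_rate(m: int) -> float:
    """Substitution probability at which the star genealogy's two diversity
    estimators agree in expectation, i.e. E[k_hat] = E[S]/a1.

    Per column with substitution probability r (uniform replacement over 20
    residues): two sequences differ with probability (2r - r^2) * 19/20,
    and the column is monomorphic with probability q^m + 19 s^m where
    q = 1 - 19r/20 (a sequence shows the ancestral residue) and s = r/20
    (it shows one given non-ancestral residue). Solving
    (2r - r^2) * 19/20 = (1 - q^m - 19 s^m)/a1 centres Tajima's D near zero
    under this (non-coalescent) null.
    """
    a1 = sum(1.0 / i for i in range(1, m))

    def gap(r: float) -> float:
        q = 1.0 - 19.0 * r / 20.0
        s = r / 20.0
        return (2 * r - r * r) * 19.0 / 20.0 - (1.0 - q**m - 19.0 * s**m) / a1

    return float(brentq(gap, 1e-9, 0.999))


@dataclass(frozen=True)
class TripleSpec:
    """Exact target site partition for a three-sequence alignment.

    ``shared_pair_remainder`` columns carry an ambiguous residue ('X') in
    one sequence and are therefore dropped by complete deletion; all other
    categories survive it, so relative_rate_counts on the generated
    alignment returns exactly these counts.
    """

    identical_all: int
    divergent_all: int
    unique_a: int
    unique_b: int
    unique_c: int
    shared_pair_remainder: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.identical_all,
            self.divergent_all,
            self.unique_a,
            self.unique_b,
            self.unique_c,
            self.shared_pair_remainder,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all category counts must be >= 0")
        if sum(counts) < 1:
            raise ValueError("alignment must have at least one column")

    @property
    def n_sites(self) -> int:
        return (
            self.identical_all
            + self.divergent_all
            + self.unique_a
            + self.unique_b
            + self.unique_c
            + self.shared_pair_remainder
        )


def _pick_distinct(rng: np.random.Generator, k: int) -> list[str]:
    idx = rng.choice(len(_AA), size=k, replace=False)
    return [chr(_AA[i][0]) for i in idx]


def gen_triple(spec: TripleSpec) -> Alignment:
    """Three-sequence alignment (A, B, C) realizing ``spec`` exactly.

    Columns of each category are built explicitly and then shuffled; C is
    the outgroup by position.
    """
    rng = np.random.default_rng(spec.seed)
    cols: list[tuple[str, str, str]] = []
    for _ in range(spec.identical_all):
        (x,) = _pick_distinct(rng, 1)
        cols.append((x, x, x))
    for _ in range(spec.divergent_all):
        x, y, z = _pick_distinct(rng, 3)
        cols.append((x, y, z))
    for _ in range(spec.unique_a):
        x, y = _pick_distinct(rng, 2)
        cols.append((y, x, x))
    for _ in range(spec.unique_b):
        x, y = _pick_distinct(rng, 2)
        cols.append((x, y, x))
    for _ in range(spec.unique_c):
        x, y = _pick_distinct(rng, 2)
        cols.append((x, x, y))
    for _ in range(spec.shared_pair_remainder):
        (x,) = _pick_distinct(rng, 1)
        cols.append(("X", x, x))
    order = rng.permutation(len(cols))
    cols = [cols[i] for i in order]
    seqs = ["".join(c[i] for c in cols) for i in range(3)]
    return Alignment((("A", seqs[0]), ("B", seqs[1]), ("C", seqs[2])))
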
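"""Mock-community design: expected composition from measured copy
concentrations, mixing volumes and per-genome 16S copy numbers.

The central type here is :class:`CommunityProfile`, an ordered
strain -> fraction table used throughout the package for both designed
("original") and observed (sequenced or simulated) compositions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "StrainRecord",
    "MixComponent",
    "CommunityProfile",
    "expected_composition",
    "canonical_name",
    "load_strain_table",
    "load_paper_mocks",
    "paper_mock_percent_table",
    "MOCK_IDS",
]

MOCK_IDS = ("A", "B", "C", "D", "E", "F", "G", "H")

#: printed-rounding tolerance for percent tables (percentage points)
PERCENT_SUM_TOL = 0.05

_FRACTION_SUM_TOL = 1e-9


@dataclass(frozen=True)
class StrainRecord:
    """Reference metadata for one community member."""

    name: str
    accession: str
    genome_gc: float
    sixteen_s_copies: int
    genome_size: float  # megabases

    def __post_init__(self) -> None:
        if not 0.0 < self.genome_gc < 100.0:
            raise ValueError(f"genome_gc out of (0, 100): {self.genome_gc}")
        if self.sixteen_s_copies < 1:
            raise ValueError(f"sixteen_s_copies must be >= 1: {self.sixteen_s_copies}")
        if self.genome_size <= 0:
            raise ValueError(f"genome_size must be > 0: {self.genome_size}")


@dataclass(frozen=True)
class MixComponent:
    """One pipetted genomic-DNA input to a mock.

    ``concentration`` is in copies/uL of either the 16S gene itself
    (``mode="gene_copies"``, the ddPCR route: the assay primers target the
    gene directly) or of whole genomes (``mode="genome_copies"``, the
    fluorometer route, converted via the strain's 16S copy number).
    """

    strain: StrainRecord
    concentration: float
    volume: float
    mode: str = "gene_copies"

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.volume < 0:
            raise ValueError("volume must be >= 0")
        if self.mode not in ("gene_copies", "genome_copies"):
            raise ValueError(f"unknown mode: {self.mode!r}")

    @property
    def gene_copy_weight(self) -> float:
        w = self.concentration * self.volume
        if self.mode == "genome_copies":
            w *= self.strain.sixteen_s_copies
        return w


class CommunityProfile:
    """Ordered mapping of strain name -> fraction, summing to one.

    Parameters
    ----------
    strains :
        Strain labels, in a fixed order.
    fractions :
        Non-negative fractions, same length as ``strains``. Must sum to 1
        within 1e-9 unless ``renormalize=True``.
    renormalize :
        Rescale the values to sum exactly to 1 (ratios preserved). Use this
        when building a profile from rounded percentages.
    """

    __slots__ = ("_strains", "_fractions")

    def __init__(
        self,
        strains: Sequence[str],
        fractions: Sequence[float],
        *,
        renormalize: bool = False,
    ) -> None:
        strains = tuple(str(s) for s in strains)
        values = np.asarray(fractions, dtype=float)
        if len(strains) != values.size:
            raise ValueError("strains and fractions differ in length")
        if len(set(strains)) != len(strains):
            raise ValueError("duplicate strain labels")
        if values.size == 0:
            raise ValueError("empty profile")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("fractions must be finite and >= 0")
        total = values.sum()
        if renormalize:
            if total <= 0:
                raise ValueError("cannot renormalize an all-zero profile")
            values = values / total
        elif abs(total - 1.0) > _FRACTION_SUM_TOL:
            raise ValueError(f"fractions sum to {total!r}, not 1")
        self._strains = strains
        self._fractions = values
        self._fractions.setflags(write=False)

    @classmethod
    def from_percent(cls, strains: Sequence[str], percents: Sequence[float]) -> "CommunityProfile":
        """Build from (possibly rounded) percentages, renormalizing to 1."""
        return cls(strains, np.asarray(percents, dtype=float) / 100.0, renormalize=True)

    @classmethod
    def from_counts(cls, strains: Sequence[str], counts: Sequence[float]) -> "CommunityProfile":
        return cls(strains, counts, renormalize=True)

    @property
    def strains(self) -> tuple[str, ...]:
        return self._strains

    @property
    def fractions(self) -> np.ndarray:
        return self._fractions

    @property
    def percents(self) -> np.ndarray:
        return self._fractions * 100.0

    def __len__(self) -> int:
        return len(self._strains)

    def __getitem__(self, strain: str) -> float:
        try:
            return float(self._fractions[self._strains.index(strain)])
        except ValueError:
            raise KeyError(strain) from None

    def __contains__(self, strain: str) -> bool:
        return strain in self._strains

    def __iter__(self):
        return iter(self._strains)

    def items(self) -> Iterable[tuple[str, float]]:
        return zip(self._strains, self._fractions.tolist())

    def as_dict(self) -> dict[str, float]:
        return dict(self.items())

    def reorder(self, strains: Sequence[str]) -> "CommunityProfile":
        """Return the same profile with strains in the given order."""
        if set(strains) != set(self._strains) or len(strains) != len(self._strains):
            raise ValueError("reorder requires the same strain set")
        return CommunityProfile(strains, [self[s] for s in strains])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CommunityProfile):
            return NotImplemented
        return self._strains == other._strains and np.array_equal(
            self._fractions, other._fractions
        )

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        body = ", ".join(f"{s}={f:.4f}" for s, f in self.items())
        return f"CommunityProfile({body})"


# --- strain-name canonicalization -------------------------------------------
#
# Canonical labels are the short binomials used in the packaged fixtures.
# The table absorbs current genus reassignments (Limosilactobacillus,
# Lacticaseibacillus) and optional subspecies suffixes.

_CANONICAL = (
    "L. acidophilus",
    "L. fermentum",
    "L. gasseri",
    "L. paracasei subsp. paracasei",
    "L. reuteri",
    "B. animalis subsp. lactis",
    "B. breve",
    "L. lactis",
)

_NAME_SYNONYMS: dict[str, str] = {
    "lactobacillus acidophilus": "L. acidophilus",
    "l. acidophilus": "L. acidophilus",
    "limosilactobacillus fermentum": "L. fermentum",
    "lactobacillus fermentum": "L. fermentum",
    "l. fermentum": "L. fermentum",
    "lactobacillus gasseri": "L. gasseri",
    "l. gasseri": "L. gasseri",
    "lacticaseibacillus paracasei subsp. paracasei": "L. paracasei subsp. paracasei",
    "lactobacillus paracasei subsp. paracasei": "L. paracasei subsp. paracasei",
    "lacticaseibacillus paracasei": "L. paracasei subsp. paracasei",
    "lactobacillus paracasei": "L. paracasei subsp. paracasei",
    "l. paracasei subsp. paracasei": "L. paracasei subsp. paracasei",
    "l. paracasei": "L. paracasei subsp. paracasei",
    "limosilactobacillus reuteri": "L. reuteri",
    "lactobacillus reuteri": "L. reuteri",
    "l. reuteri": "L. reuteri",
    "bifidobacterium animalis subsp. lactis": "B. animalis subsp. lactis",
    "bifidobacterium animalis": "B. animalis subsp. lactis",
    "b. animalis subsp. lactis": "B. animalis subsp. lactis",
    "b. animalis": "B. animalis subsp. lactis",
    "bifidobacterium breve": "B. breve",
    "b. breve": "B. breve",
    "lactococcus lactis subsp. lactis": "L. lactis",
    "lactococcus lactis": "L. lactis",
    "l. lactis subsp. lactis": "L. lactis",
    "l. lactis": "L. lactis",
}


def canonical_name(name: str) -> str:
    """Map a strain label to its canonical short binomial.

    Unknown labels are returned unchanged (stripped), so foreign taxa pass
    through profile operations untouched.
    """
    key = " ".join(name.split()).lower()
    return _NAME_SYNONYMS.get(key, " ".join(name.split()))


# --- operations --------------------------------------------------------------


def expected_composition(components: Sequence[MixComponent]) -> CommunityProfile:
    """Designed ("original") composition of a mock from its mix sheet.

    Each component contributes weight ``concentration * volume`` 16S-gene
    copies (times the strain's 16S copy number in ``genome_copies`` mode);
    fractions are the normalized weights.
    """
    components = list(components)
    if len(components) < 2:
        raise ValueError("a mock needs at least two components")
    modes = {c.mode for c in components}
    if len(modes) != 1:
        raise ValueError(f"mixed concentration modes: {sorted(modes)}")
    weights = np.array([c.gene_copy_weight for c in components], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("all component weights are zero")
    names = [canonical_name(c.strain.name) for c in components]
    return CommunityProfile(names, weights, renormalize=True)


# --- packaged fixtures -------------------------------------------------------


def _read_packaged_tsv(filename: str) -> list[dict[str, str]]:
    text = resources.files("mockbias.data").joinpath(filename).read_text(encoding="utf-8")
    rows = [r for r in text.splitlines() if r and not r.startswith("#")]
    reader = csv.DictReader(rows, delimiter="\t")
    return list(reader)


def load_strain_table() -> dict[str, StrainRecord]:
    """The eight-strain reference roster (name -> record)."""
    out: dict[str, StrainRecord] = {}
    for row in _read_packaged_tsv("strains.tsv"):
        rec = StrainRecord(
            name=row["name"],
            accession=row["accession"],
            genome_gc=float(row["genome_gc"]),
            sixteen_s_copies=int(row["sixteen_s_copies"]),
            genome_size=float(row["genome_size_mb"]),
        )
        out[rec.name] = rec
    return out


def paper_mock_percent_table() -> dict[str, dict[str, float]]:
    """Printed percent compositions of mocks A-H, exactly as published
    (two decimals, may not sum to exactly 100)."""
    table: dict[str, dict[str, float]] = {}
    for row in _read_packaged_tsv("mock_compositions.tsv"):
        table.setdefault(row["mock"], {})[row["strain"]] = float(row["percent"])
    return table


def load_paper_mocks() -> dict[str, CommunityProfile]:
    """The eight designed mock compositions as normalized profiles."""
    out: dict[str, CommunityProfile] = {}
    for mock_id, percents in paper_mock_percent_table().items():
        out[mock_id] = CommunityProfile.from_percent(
            list(percents.keys()), list(percents.values())
        )
    return out


def read_mix_sheet(path, strains: Mapping[str, StrainRecord] | None = None) -> list[MixComponent]:
    """Read a TSV mix sheet: strain, concentration, volume[, mode].

    Strain names are canonicalized; unknown strains get a placeholder record
    (metadata-dependent modes then require a roster entry).
    """
    strains = dict(strains) if strains is not None else load_strain_table()
    components = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            name = canonical_name(row["strain"])
            mode = row.get("mode") or "gene_copies"
            rec = strains.get(name)
            if rec is None:
                if mode == "genome_copies":
                    raise ValueError(f"unknown strain {name!r} needs a roster entry for genome_copies mode")
                rec = StrainRecord(name=name, accession="NA", genome_gc=50.0, sixteen_s_copies=1, genome_size=1.0)
            components.append(
                MixComponent(
                    strain=rec,
                    concentration=float(row["concentration"]),
                    volume=float(row["volume"]),
                    mode=mode,
                )
            )
    return components
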
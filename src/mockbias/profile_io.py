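"""Ingestion of classified-read count tables: mothur "shared" dialect and
plain sample-by-taxon TSV, rarefaction to fixed depth, misclassification
aliasing and conversion to community profiles.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, TextIO

import numpy as np
import pandas as pd

from mockbias.mock_design import CommunityProfile, canonical_name

log = logging.getLogger(__name__)

__all__ = [
    "AbundanceTable",
    "read_shared_table",
    "write_table",
    "rarefy",
    "apply_alias",
    "to_profile",
    "load_default_aliases",
    "DEFAULT_RAREFACTION_DEPTH",
]

DEFAULT_RAREFACTION_DEPTH = 10_000


@dataclass(frozen=True)
class AbundanceTable:
    """Sample-by-taxon matrix of non-negative integer read counts.

    Wraps a :class:`pandas.DataFrame` with unique sample index and unique
    taxon columns. Taxa absent from a sample are explicit zero cells, so the
    matrix shape is shared across samples.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if df.columns.has_duplicates:
            raise ValueError("duplicate taxon labels")
        if not np.issubdtype(df.values.dtype, np.integer):
            raise ValueError("counts must be integers")
        if (df.values < 0).any():
            raise ValueError("counts must be >= 0")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    def sample_total(self, sample_id: str) -> int:
        return int(self.counts.loc[sample_id].sum())


def read_shared_table(source: str | Path | TextIO) -> AbundanceTable:
    """Read a count table, auto-detecting the dialect from header tokens.

    mothur "shared" files start with ``label<TAB>Group<TAB>numOtus``; anything
    else is treated as a plain TSV whose first column is the sample id.
    """
    if isinstance(source, (str, Path)):
        with open(source, newline="", encoding="utf-8") as fh:
            return read_shared_table(fh)
    rows = [r for r in csv.reader(source, delimiter="\t") if r]
    if not rows:
        raise ValueError("empty table")
    header = rows[0]
    width = len(header)
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ValueError(f"ragged row at line {i}: {len(row)} fields, expected {width}")
    if [h.strip().lower() for h in header[:3]] == ["label", "group", "numotus"]:
        taxa = [h.strip() for h in header[3:]]
        samples, data = [], []
        for row in rows[1:]:
            if int(row[2]) != len(taxa):
                raise ValueError(
                    f"numOtus={row[2]} disagrees with {len(taxa)} taxon columns"
                )
            samples.append(row[1].strip())
            data.append([_parse_count(v) for v in row[3:]])
    else:
        taxa = [h.strip() for h in header[1:]]
        samples = [row[0].strip() for row in rows[1:]]
        data = [[_parse_count(v) for v in row[1:]] for row in rows[1:]]
    df = pd.DataFrame(data, index=samples, columns=taxa, dtype=np.int64)
    return AbundanceTable(df)


def _parse_count(value: str) -> int:
    v = value.strip()
    try:
        n = int(v)
    except ValueError:
        raise ValueError(f"non-integer count {v!r}") from None
    if n < 0:
        raise ValueError(f"negative count {v!r}")
    return n


def write_table(table: AbundanceTable, dest: str | Path | TextIO) -> None:
    """Write as plain TSV (first column ``sample``)."""
    df = table.counts.copy()
    df.index.name = "sample"
    if isinstance(dest, (str, Path)):
        df.to_csv(dest, sep="\t")
    else:
        df.to_csv(dest, sep="\t", lineterminator="\n")


def rarefy(
    table: AbundanceTable,
    depth: int = DEFAULT_RAREFACTION_DEPTH,
    seed: int | np.random.Generator | None = None,
) -> AbundanceTable:
    """Subsample each sample to ``depth`` reads without replacement.

    Each sample's rarefied counts are one multivariate-hypergeometric draw,
    so per-sample totals equal ``depth`` exactly and depth == total returns
    the sample unchanged.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = {}
    for sample in table.samples:
        counts = table.counts.loc[sample].to_numpy()
        total = int(counts.sum())
        if total < depth:
            raise ValueError(
                f"sample {sample!r} has only {total} reads; cannot rarefy to {depth}"
            )
        out[sample] = rng.multivariate_hypergeometric(counts, depth)
    df = pd.DataFrame.from_dict(out, orient="index", dtype=np.int64)
    df.columns = table.taxa
    return AbundanceTable(df)


def apply_alias(table: AbundanceTable, aliases: Mapping[str, str]) -> AbundanceTable:
    """Fold aliased labels into their canonical strain labels.

    Counts of a reported label are added to its canonical label's column;
    labels not in the map pass through untouched (and are logged).
    """
    rename = {t: aliases.get(t, t) for t in table.taxa}
    unknown = sorted(t for t in table.taxa if t not in aliases)
    if aliases and unknown:
        log.info("labels passed through unaliased: %s", unknown)
    df = table.counts.rename(columns=rename)
    df = df.T.groupby(level=0, sort=False).sum().T
    return AbundanceTable(df.astype(np.int64))


def to_profile(table: AbundanceTable, sample_id: str, *, canonicalize: bool = True) -> CommunityProfile:
    """One sample's counts as a normalized community profile."""
    counts = table.counts.loc[sample_id]
    total = counts.sum()
    if total <= 0:
        raise ValueError(f"sample {sample_id!r} has zero total reads")
    names = [canonical_name(t) if canonicalize else t for t in table.taxa]
    return CommunityProfile.from_counts(names, counts.to_numpy())


def load_default_aliases() -> dict[str, str]:
    """The packaged reported-label -> canonical-strain alias map.

    Ships the known classifier confusions but is applied only on request.
    """
    text = resources.files("mockbias.data").joinpath("aliases.tsv").read_text(encoding="utf-8")
    rows = [r for r in text.splitlines() if r and not r.startswith("#")]
    return {row["reported"]: row["canonical"] for row in csv.DictReader(rows, delimiter="\t")}
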
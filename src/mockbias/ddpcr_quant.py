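"""Poisson-corrected absolute quantification from droplet-digital-PCR
droplet counts.

A droplet partition with positive fraction ``p`` implies a mean template
load per droplet of ``lambda = -ln(1 - p)``; dividing by droplet volume and
multiplying by the dilution factor gives copies per microliter of stock.
"""

from __future__ import annotations

import csv
import io
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "DropletAssay",
    "CopyEstimate",
    "SaturationError",
    "poisson_lambda",
    "copies_per_microliter",
    "replicate_summary",
    "read_droplet_table",
    "write_estimates_table",
    "DEFAULT_DROPLET_VOLUME_NL",
]

#: Instrument-typical droplet volume (nanoliters); not a measured constant of
#: this workflow, so every operation accepts an override.
DEFAULT_DROPLET_VOLUME_NL = 0.85


class SaturationError(ValueError):
    """All droplets positive: the Poisson estimate is undefined."""


@dataclass(frozen=True)
class DropletAssay:
    """Droplet counts for one ddPCR well."""

    sample_id: str
    total_droplets: int
    positive_droplets: int
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_NL  # nanoliters
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.total_droplets <= 0:
            raise ValueError("total_droplets must be > 0")
        if not 0 <= self.positive_droplets <= self.total_droplets:
            raise ValueError(
                f"positive_droplets {self.positive_droplets} outside "
                f"[0, {self.total_droplets}]"
            )
        if self.droplet_volume <= 0:
            raise ValueError("droplet_volume must be > 0")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")

    @property
    def positive_fraction(self) -> float:
        return self.positive_droplets / self.total_droplets


@dataclass(frozen=True)
class CopyEstimate:
    """Mean copies per droplet and the dilution-corrected concentration."""

    sample_id: str
    lambda_per_droplet: float
    copies_per_microliter: float


def poisson_lambda(assay: DropletAssay) -> float:
    """Mean template copies per droplet, ``-ln(1 - p)``.

    Raises
    ------
    SaturationError
        If every droplet is positive (p = 1), where the estimate diverges.
    """
    p = assay.positive_fraction
    if p >= 1.0:
        raise SaturationError(
            f"{assay.sample_id}: all {assay.total_droplets} droplets positive; "
            "copy load is not estimable"
        )
    return -math.log1p(-p)


def copies_per_microliter(assay: DropletAssay) -> CopyEstimate:
    """Dilution-corrected concentration of the undiluted stock.

    ``copies/uL = lambda / droplet_volume(uL) * dilution_factor`` with the
    droplet volume converted from nanoliters.
    """
    lam = poisson_lambda(assay)
    volume_ul = assay.droplet_volume * 1e-3
    conc = lam / volume_ul * assay.dilution_factor
    return CopyEstimate(assay.sample_id, lam, conc)


def replicate_summary(estimates: Sequence[CopyEstimate]) -> tuple[float, float]:
    """Mean and sample standard deviation (n-1) of replicate concentrations.

    A single replicate yields SD 0 with a warning rather than an error.
    """
    if len(estimates) == 0:
        raise ValueError("no estimates to summarize")
    values = np.array([e.copies_per_microliter for e in estimates], dtype=float)
    mean = float(values.mean())
    if values.size == 1:
        log.warning(
            "replicate_summary: single replicate for %s; reporting SD = 0",
            estimates[0].sample_id,
        )
        return mean, 0.0
    return mean, float(values.std(ddof=1))


# --- I/O ---------------------------------------------------------------------

_REQUIRED_COLUMNS = ("sample_id", "total_droplets", "positive_droplets")


def read_droplet_table(
    source: str | TextIO,
    *,
    droplet_volume: float | None = None,
    dilution_factor: float | None = None,
) -> list[DropletAssay]:
    """Read a delimited droplet-count table (comma or tab, sniffed from the
    header). Columns: sample_id, total_droplets, positive_droplets and
    optionally dilution_factor / droplet_volume; keyword overrides win.
    """
    if isinstance(source, str):
        with open(source, newline="", encoding="utf-8") as fh:
            return read_droplet_table(
                io.StringIO(fh.read()),
                droplet_volume=droplet_volume,
                dilution_factor=dilution_factor,
            )
    header = source.readline()
    delimiter = "\t" if header.count("\t") >= header.count(",") else ","
    fields = [f.strip() for f in header.rstrip("\n").split(delimiter)]
    missing = [c for c in _REQUIRED_COLUMNS if c not in fields]
    if missing:
        raise ValueError(f"droplet table is missing columns: {missing}")
    assays = []
    for row in csv.DictReader(source, fieldnames=fields, delimiter=delimiter):
        kwargs = dict(
            sample_id=row["sample_id"],
            total_droplets=int(row["total_droplets"]),
            positive_droplets=int(row["positive_droplets"]),
        )
        vol = droplet_volume if droplet_volume is not None else row.get("droplet_volume")
        if vol is not None and vol != "":
            kwargs["droplet_volume"] = float(vol)
        dil = dilution_factor if dilution_factor is not None else row.get("dilution_factor")
        if dil is not None and dil != "":
            kwargs["dilution_factor"] = float(dil)
        assays.append(DropletAssay(**kwargs))
    return assays


def write_estimates_table(estimates: Iterable[CopyEstimate], dest: str | TextIO) -> None:
    """Write per-sample estimates as TSV."""
    if isinstance(dest, str):
        with open(dest, "w", newline="", encoding="utf-8") as fh:
            write_estimates_table(estimates, fh)
            return
    writer = csv.writer(dest, delimiter="\t", lineterminator="\n")
    writer.writerow(["sample_id", "lambda_per_droplet", "copies_per_microliter"])
    for est in estimates:
        writer.writerow(
            [est.sample_id, f"{est.lambda_per_droplet:.6g}", f"{est.copies_per_microliter:.6g}"]
        )
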
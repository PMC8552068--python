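"""Bias statistics for mock-community sequencing: per-strain relative
differences, the +/-0.5 representation rule, and the Bias Index.

For a mock with designed fractions ``x_i`` and observed fractions ``xbar_i``
over the same N strains:

    d_i = (xbar_i - x_i) / x_i
    BI  = sqrt( sum_i d_i**2 / (N - 1) )

``d_i`` is scale-free, so profiles may be given in percent or fraction space
interchangeably. BI is zero iff the profiles are identical, and a strain is
"greatly" over/underrepresented when ``|d_i|`` strictly exceeds the
threshold (default 0.5).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

from mockbias.mock_design import CommunityProfile, canonical_name

__all__ = [
    "BiasReport",
    "relative_difference",
    "classify_representation",
    "bias_index",
    "bias_report",
    "bi_matrix",
    "load_paper_srrs",
    "paper_observed_profile",
    "GREATLY_OVER",
    "GREATLY_UNDER",
    "COMPARABLE",
    "DEFAULT_THRESHOLD",
]

GREATLY_OVER = "greatly_over"
GREATLY_UNDER = "greatly_under"
COMPARABLE = "comparable"

DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class BiasReport:
    """Per-strain relative differences and the Bias Index for one
    (mock, platform/region) comparison."""

    mock_id: str
    tag: str
    strains: tuple[str, ...]
    relative_differences: tuple[float, ...]
    labels: tuple[str, ...]
    bias_index: float
    threshold: float = DEFAULT_THRESHOLD

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mock": self.mock_id,
                "tag": self.tag,
                "strain": self.strains,
                "relative_difference": self.relative_differences,
                "label": self.labels,
            }
        )


def _aligned(original: CommunityProfile, observed: CommunityProfile) -> tuple[np.ndarray, np.ndarray]:
    if set(original.strains) != set(observed.strains):
        missing = set(original.strains) - set(observed.strains)
        extra = set(observed.strains) - set(original.strains)
        raise ValueError(
            f"strain sets differ (missing from observed: {sorted(missing)}; "
            f"not in original: {sorted(extra)})"
        )
    obs = observed.reorder(original.strains)
    x = original.fractions
    if np.any(x <= 0):
        zero = [s for s, f in original.items() if f <= 0]
        raise ValueError(f"original fractions must be > 0; zero for {zero}")
    return x, obs.fractions


def relative_difference(
    original: CommunityProfile, observed: CommunityProfile
) -> dict[str, float]:
    """Per-strain ``(observed - original) / original``.

    Positive values mean overrepresentation in the observed profile,
    negative underrepresentation.
    """
    x, xbar = _aligned(original, observed)
    d = (xbar - x) / x
    return dict(zip(original.strains, d.tolist()))


def classify_representation(
    d: Mapping[str, float] | Sequence[float], threshold: float = DEFAULT_THRESHOLD
):
    """Label each relative difference: strictly above +threshold ->
    ``greatly_over``, strictly below -threshold -> ``greatly_under``, else
    ``comparable`` (|d| == threshold is comparable)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")

    def label(v: float) -> str:
        if v > threshold:
            return GREATLY_OVER
        if v < -threshold:
            return GREATLY_UNDER
        return COMPARABLE

    if isinstance(d, Mapping):
        return {k: label(v) for k, v in d.items()}
    return [label(v) for v in d]


def bias_index(original: CommunityProfile, observed: CommunityProfile) -> float:
    """The Bias Index: sqrt of the (N-1)-normalized sum of squared
    relative differences."""
    x, xbar = _aligned(original, observed)
    n = x.size
    if n < 2:
        raise ValueError(f"Bias Index needs >= 2 strains, got {n}")
    d = (xbar - x) / x
    return math.sqrt(float(np.sum(d * d)) / (n - 1))


def bias_report(
    original: CommunityProfile,
    observed: CommunityProfile,
    *,
    mock_id: str = "",
    tag: str = "",
    threshold: float = DEFAULT_THRESHOLD,
) -> BiasReport:
    """Bundle relative differences, labels and BI for one comparison."""
    d = relative_difference(original, observed)
    labels = classify_representation(d, threshold)
    return BiasReport(
        mock_id=mock_id,
        tag=tag,
        strains=original.strains,
        relative_differences=tuple(d[s] for s in original.strains),
        labels=tuple(labels[s] for s in original.strains),
        bias_index=bias_index(original, observed),
        threshold=threshold,
    )


def bi_matrix(
    originals: Mapping[str, CommunityProfile],
    observations: Sequence[tuple[str, str, CommunityProfile]],
) -> pd.DataFrame:
    """Bias Index per (mock, tag) over a set of tagged observed profiles.

    ``observations`` are ``(mock_id, tag, profile)`` triples; the result is a
    mock-by-tag table with NaN where a combination was not observed.
    """
    entries: dict[tuple[str, str], float] = {}
    for mock_id, tag, profile in observations:
        if mock_id not in originals:
            raise KeyError(f"unresolvable mock id {mock_id!r}")
        entries[(mock_id, tag)] = bias_index(originals[mock_id], profile)
    mocks = sorted({m for m, _ in entries})
    tags = sorted({t for _, t in entries})
    df = pd.DataFrame(np.nan, index=mocks, columns=tags)
    for (m, t), v in entries.items():
        df.loc[m, t] = v
    df.index.name = "mock"
    return df


def write_bias_report(reports: Sequence[BiasReport], dest: str | TextIO) -> None:
    """Per-strain TSV across one or more comparisons."""
    frame = pd.concat([r.as_frame() for r in reports], ignore_index=True)
    if isinstance(dest, str):
        frame.to_csv(dest, sep="\t", index=False)
    else:
        frame.to_csv(dest, sep="\t", index=False, lineterminator="\n")


# --- published sequence-read-ratio fixture -----------------------------------


def load_paper_srrs() -> pd.DataFrame:
    """Published per-strain sequence-read ratios (percent) keyed by
    platform, region, mock and strain."""
    text = resources.files("mockbias.data").joinpath("srr_results.tsv").read_text(encoding="utf-8")
    rows = [r for r in text.splitlines() if r and not r.startswith("#")]
    records = list(csv.DictReader(rows, delimiter="\t"))
    df = pd.DataFrame(records)
    df["percent"] = df["percent"].astype(float)
    df["strain"] = df["strain"].map(canonical_name)
    return df


def paper_relative_differences(platform: str, region: str, mock_id: str) -> dict[str, float]:
    """Per-strain d_i from the published percent tables.

    Works on partial rosters (only the strains whose ratios were printed),
    comparing raw printed percents: d = (SRR - design) / design.
    """
    from mockbias.mock_design import paper_mock_percent_table

    design = paper_mock_percent_table()[mock_id]
    srrs = load_paper_srrs()
    sel = srrs[
        (srrs["platform"] == platform)
        & (srrs["region"] == region)
        & (srrs["mock"] == mock_id)
    ]
    if sel.empty:
        raise KeyError(f"no published ratios for {platform}/{region}/mock {mock_id}")
    out = {}
    for _, row in sel.iterrows():
        x = design[row["strain"]]
        out[row["strain"]] = (row["percent"] - x) / x
    return out


def paper_observed_profile(platform: str, region: str, mock_id: str) -> CommunityProfile:
    """Observed profile reconstructed from the published ratios.

    Only combinations whose full strain roster was published (the two-member
    mocks B and F) can be reconstructed; others raise ``ValueError``.
    """
    from mockbias.mock_design import load_paper_mocks

    srrs = load_paper_srrs()
    sel = srrs[
        (srrs["platform"] == platform)
        & (srrs["region"] == region)
        & (srrs["mock"] == mock_id)
    ]
    roster = load_paper_mocks()[mock_id].strains
    have = set(sel["strain"])
    if have != set(roster):
        raise ValueError(
            f"published ratios for {platform}/{region}/mock {mock_id} cover "
            f"{sorted(have)}, not the full roster {sorted(roster)}"
        )
    percents = {row["strain"]: row["percent"] for _, row in sel.iterrows()}
    return CommunityProfile.from_percent(roster, [percents[s] for s in roster])
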
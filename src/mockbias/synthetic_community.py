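"""Synthetic observed-community generator: multiplicative per-strain
amplification bias, multinomial read sampling at fixed depth, and an
optional row-stochastic taxonomic-confusion step, plus recovery of the
bias factors from observed fractions.

The generative model is

    g_i = b_i x_i / sum_j b_j x_j          (biased expected fractions)
    counts ~ Multinomial(depth, g)         (read sampling)
    reads of true strain i are reassigned to reported labels
    multinomially with probabilities confusion[i, :]

which makes the relative-difference statistic of
:mod:`mockbias.bias_metrics` equal to ``g_i/x_i - 1`` in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from mockbias.mock_design import CommunityProfile
from mockbias.profile_io import AbundanceTable

__all__ = [
    "BiasModel",
    "SimulatedSample",
    "biased_expectation",
    "simulate_sample",
    "simulate_table",
    "recover_bias",
    "bias_from_efficiencies",
    "load_scenario",
]

_ROW_SUM_TOL = 1e-9


def bias_from_efficiencies(efficiencies: Mapping[str, float], cycles: int) -> dict[str, float]:
    """Per-cycle efficiencies e in (0, 1] over c cycles -> b = (1+e)^c."""
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    out = {}
    for strain, e in efficiencies.items():
        if not 0 < e <= 1:
            raise ValueError(f"efficiency for {strain} outside (0, 1]: {e}")
        out[strain] = (1.0 + e) ** cycles
    return out


@dataclass(frozen=True)
class BiasModel:
    """Simulator parameters: bias factor per strain, read depth, optional
    confusion matrix (rows = true strains, columns = reported labels, rows
    sum to 1), and the master seed."""

    bias: Mapping[str, float]
    depth: int = 10_000
    confusion: pd.DataFrame | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        for strain, b in self.bias.items():
            if b <= 0:
                raise ValueError(f"bias factor for {strain} must be > 0: {b}")
        if self.confusion is not None:
            sums = self.confusion.to_numpy(dtype=float).sum(axis=1)
            if np.any(np.abs(sums - 1.0) > _ROW_SUM_TOL):
                raise ValueError("confusion rows must each sum to 1")
            if (self.confusion.to_numpy(dtype=float) < 0).any():
                raise ValueError("confusion entries must be >= 0")

    @classmethod
    def from_efficiencies(
        cls,
        efficiencies: Mapping[str, float],
        cycles: int,
        **kwargs,
    ) -> "BiasModel":
        return cls(bias=bias_from_efficiencies(efficiencies, cycles), **kwargs)

    def rng(self, substream: int = 0) -> np.random.Generator:
        """Independent substream derived from the master seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(substream + 1)[substream])


@dataclass(frozen=True)
class SimulatedSample:
    """One simulated sequencing run of a known community."""

    true_composition: CommunityProfile
    expected_observed: CommunityProfile
    counts: pd.Series  # per reported label, sums to depth
    seed: int


def _bias_vector(x: CommunityProfile, model: BiasModel) -> np.ndarray:
    missing = [s for s in x.strains if s not in model.bias]
    if missing:
        raise ValueError(f"no bias factor for strains: {missing}")
    return np.array([model.bias[s] for s in x.strains], dtype=float)


def biased_expectation(x: CommunityProfile, model: BiasModel) -> CommunityProfile:
    """Expected observed fractions ``g_i = b_i x_i / sum_j b_j x_j``."""
    b = _bias_vector(x, model)
    w = b * x.fractions
    return CommunityProfile(x.strains, w / w.sum())


def simulate_sample(
    x: CommunityProfile,
    model: BiasModel,
    *,
    substream: int = 0,
) -> SimulatedSample:
    """Draw one sample: Multinomial(depth, g), then per-true-strain
    multinomial redistribution across reported labels if a confusion matrix
    is configured. Reproducible given (seed, substream)."""
    g = biased_expectation(x, model)
    rng = model.rng(substream)
    raw = rng.multinomial(model.depth, g.fractions)
    if model.confusion is None:
        counts = pd.Series(raw, index=list(x.strains))
    else:
        conf = model.confusion
        missing = [s for s in x.strains if s not in conf.index]
        if missing:
            raise ValueError(f"confusion matrix lacks rows for: {missing}")
        reported = list(conf.columns)
        acc = np.zeros(len(reported), dtype=np.int64)
        for i, strain in enumerate(x.strains):
            if raw[i] == 0:
                continue
            acc += rng.multinomial(raw[i], conf.loc[strain].to_numpy(dtype=float))
        counts = pd.Series(acc, index=reported)
    return SimulatedSample(
        true_composition=x,
        expected_observed=g,
        counts=counts,
        seed=model.seed,
    )


def simulate_table(
    x: CommunityProfile,
    model: BiasModel,
    n_replicates: int = 1,
    *,
    sample_prefix: str = "sim",
) -> AbundanceTable:
    """Replicated samples as an abundance table (one substream each), in the
    same shape :mod:`mockbias.profile_io` reads."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rows = {}
    for r in range(n_replicates):
        sample = simulate_sample(x, model, substream=r)
        rows[f"{sample_prefix}_{r + 1}"] = sample.counts
    df = pd.DataFrame(rows).T.fillna(0).astype(np.int64)
    return AbundanceTable(df)


def recover_bias(
    x: CommunityProfile,
    observed: CommunityProfile | Mapping[str, float],
) -> dict[str, float]:
    """Invert :func:`biased_expectation`: ``b_i proportional to g_i / x_i``,
    normalized to geometric mean 1. Exact in the noiseless case."""
    if isinstance(observed, CommunityProfile):
        obs = {s: observed[s] for s in observed.strains}
    else:
        obs = dict(observed)
    missing = [s for s in x.strains if s not in obs]
    if missing:
        raise ValueError(f"observed fractions missing strains: {missing}")
    ratios = []
    for s in x.strains:
        if x[s] <= 0:
            raise ValueError(f"original fraction for {s} must be > 0")
        if obs[s] <= 0:
            raise ValueError(f"observed fraction for {s} is zero (strain dropped out)")
        ratios.append(obs[s] / x[s])
    ratios = np.array(ratios)
    bhat = ratios / np.exp(np.mean(np.log(ratios)))
    return dict(zip(x.strains, bhat.tolist()))


def load_scenario(path: str) -> tuple[CommunityProfile, BiasModel, int]:
    """Read a declarative simulation scenario (YAML).

    Keys: ``composition`` (strain -> fraction or percent), ``bias``
    (strain -> b) or ``efficiencies`` + ``cycles``, ``depth``, ``seed``,
    ``replicates``, optional ``confusion`` (true strain -> {label: prob}).
    Returns (composition, model, n_replicates).
    """
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    comp = cfg["composition"]
    strains = list(comp.keys())
    values = np.array([float(comp[s]) for s in strains])
    x = CommunityProfile(strains, values / values.sum())
    if "bias" in cfg:
        bias = {s: float(v) for s, v in cfg["bias"].items()}
    elif "efficiencies" in cfg:
        bias = bias_from_efficiencies(
            {s: float(v) for s, v in cfg["efficiencies"].items()}, int(cfg["cycles"])
        )
    else:
        bias = {s: 1.0 for s in strains}
    confusion = None
    if "confusion" in cfg:
        confusion = pd.DataFrame(cfg["confusion"]).T.fillna(0.0)
    model = BiasModel(
        bias=bias,
        depth=int(cfg.get("depth", 10_000)),
        confusion=confusion,
        seed=int(cfg.get("seed", 0)),
    )
    return x, model, int(cfg.get("replicates", 1))
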
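"""LUMIER-like synthetic binding datasets.

The generator emulates the statistical structure of quantitative pull-down
titrations without reproducing raw luminescence physics: a dilution series
over prey:bait ratios, multiplicative (intensity-like) Gaussian noise on the
signal, Western-blot-style relative error on the measured ratios, technical
replicates within biological replicates, log-normal expression jitter across
biological replicates, and per-replicate normalization by the measured
signal at the saturating design point.  The latter reproduces the
experimental artifact that normalized values can slightly exceed 1: the
normalizer itself is a noisy measurement.

Defaults follow the study design: six log-spaced ratios between 0.25 and 4
plus a saturation point, two technical replicates in each of three
biological replicates.

All randomness derives from a single integer seed through numpy's PCG64
generator (``numpy.random.default_rng``); a given configuration is
bit-reproducible, and competition suites draw per-dataset substreams from
``numpy.random.SeedSequence.spawn`` so datasets are independent yet jointly
deterministic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binding_models import SATURATION_RATIO
from .fitting import predict_curve

__all__ = [
    "DATASET_COLUMNS",
    "DEFAULT_PREY_RATIOS",
    "SyntheticConfig",
    "generate",
    "generate_competition_suite",
    "write_dataset",
    "read_dataset",
]

#: Canonical column order of the binding-dataset CSV dialect.
DATASET_COLUMNS = [
    "experiment_id",
    "bait",
    "prey",
    "competitor",
    "prey_ratio",
    "competitor_ratio",
    "signal",
    "signal_sd",
    "replicate",
    "replicate_type",
]

#: Six log-spaced prey:bait ratios spanning 0.25-4, plus the saturation point.
DEFAULT_PREY_RATIOS = tuple(np.geomspace(0.25, 4.0, 6)) + (SATURATION_RATIO,)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one synthetic titration experiment."""

    model: str = "single"
    params: Mapping[str, float] = field(default_factory=lambda: {"kd": 1.0})
    prey_ratios: Sequence[float] = DEFAULT_PREY_RATIOS
    competitor_ratio: float = 0.0
    noise: float = 0.05  # relative sd of the multiplicative signal noise
    ratio_noise: float = 0.0  # relative sd of the measured-ratio error
    technical_replicates: int = 2
    biological_replicates: int = 3
    biological_sd: float = 0.0  # log-normal sd of expression jitter
    noisy_normalizer: bool = True  # normalize by the measured saturation signal
    seed: int = 0
    experiment_id: str = "sim"
    bait: str = "GL3"
    prey: str = "TTG1"
    competitor: str = ""

    def __post_init__(self):
        if self.noise < 0 or self.ratio_noise < 0 or self.biological_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if len(self.prey_ratios) == 0:
            raise ValueError("the ratio design must be non-empty")
        if self.technical_replicates < 1 or self.biological_replicates < 1:
            raise ValueError("replicate counts must be at least 1")
        if self.model not in (
            "single",
            "competitive",
            "cooperative",
            "inhibitor",
            "dimer-network",
        ):
            raise ValueError(f"unknown generating model {self.model!r}")

    def metadata(self) -> dict:
        meta = asdict(self)
        meta["params"] = dict(self.params)
        meta["prey_ratios"] = [float(r) for r in self.prey_ratios]
        return meta


def generate(config: SyntheticConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate one binding dataset under the configured model.

    For every biological replicate the true prey ratios are the design
    ratios times a log-normal expression factor; within it, each technical
    measurement draws an independent ratio-measurement error (recorded in
    ``prey_ratio``) and multiplicative signal noise.  Signals are then
    normalized by that replicate's mean measured signal at the saturation
    design point, so the normalizer carries noise exactly as in the assay.

    The true generating parameters and the seed are embedded in
    ``DataFrame.attrs["metadata"]`` for downstream recovery scoring.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)

    design = np.asarray(config.prey_ratios, dtype=float)
    i_sat = int(np.argmax(design))
    rows = []
    for b in range(config.biological_replicates):
        expr = (
            float(np.exp(rng.normal(0.0, config.biological_sd)))
            if config.biological_sd > 0
            else 1.0
        )
        true_ratios = design * expr
        clean = predict_curve(
            config.model, config.params, true_ratios, config.competitor_ratio
        )
        tech_signals = np.empty((config.technical_replicates, len(design)))
        tech_ratios = np.empty_like(tech_signals)
        for t in range(config.technical_replicates):
            ratio_err = rng.normal(0.0, config.ratio_noise, len(design))
            signal_err = rng.normal(0.0, config.noise, len(design))
            tech_ratios[t] = true_ratios * (1.0 + ratio_err)
            tech_signals[t] = clean * (1.0 + signal_err)
        # normalize by this replicate's measured saturation signal (the
        # experimental convention: the normalizer itself is noisy), or by
        # the noise-free saturation value when the artifact is switched off
        if config.noisy_normalizer:
            normalizer = float(np.mean(tech_signals[:, i_sat]))
        else:
            normalizer = float(clean[i_sat])
        if normalizer <= 0:
            raise RuntimeError("saturation signal is non-positive; cannot normalize")
        tech_signals = tech_signals / normalizer
        # nominal per-point measurement error on the normalized scale
        nominal_sd = config.noise * clean / normalizer
        for t in range(config.technical_replicates):
            for j in range(len(design)):
                rows.append(
                    {
                        "experiment_id": config.experiment_id,
                        "bait": config.bait,
                        "prey": config.prey,
                        "competitor": config.competitor,
                        "prey_ratio": tech_ratios[t, j],
                        "competitor_ratio": config.competitor_ratio,
                        "signal": tech_signals[t, j],
                        "signal_sd": nominal_sd[j] if config.noise > 0 else 0.0,
                        "replicate": f"b{b + 1}_t{t + 1}",
                        "replicate_type": "technical"
                        if config.technical_replicates > 1
                        else "biological",
                    }
                )
    data = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    data.attrs["metadata"] = config.metadata()
    return data


def generate_competition_suite(
    alpha: float,
    kds: Mapping[str, float],
    competitor_ratios: Sequence[float] = (2.0, 1.0),
    config: SyntheticConfig | None = None,
) -> list[pd.DataFrame]:
    """One dataset per competitor:bait ratio, on independent substreams.

    ``kds`` supplies ``kd_prey``/``kd_comp`` (and ``kd_dimer`` when the base
    configuration's model is the dimer network).  Each dataset keeps the full
    replicate structure of the base configuration; the title prey is titrated
    while the competitor sits at the fixed ratio.
    """
    if config is None:
        config = SyntheticConfig(model="cooperative", prey="TTG1", competitor="GL1")
    params = dict(kds)
    params["alpha"] = float(alpha)
    streams = np.random.SeedSequence(config.seed).spawn(len(competitor_ratios))
    out = []
    for i, (z0, stream) in enumerate(zip(competitor_ratios, streams)):
        cfg = replace(
            config,
            params=params,
            competitor_ratio=float(z0),
            experiment_id=f"{config.experiment_id}_comp{i + 1}",
        )
        out.append(generate(cfg, rng=np.random.default_rng(stream)))
    return out


def write_dataset(data: pd.DataFrame, path: str | Path) -> None:
    """Write the dataset CSV and a JSON metadata sidecar (``<path>.meta.json``)."""
    path = Path(path)
    data.to_csv(path, index=False)
    meta = data.attrs.get("metadata")
    if meta is not None:
        with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)


def read_dataset(path: str | Path) -> pd.DataFrame:
    """Read a dataset CSV, re-attaching the metadata sidecar if present."""
    path = Path(path)
    data = pd.read_csv(path, keep_default_na=False)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        with open(meta_path) as fh:
            data.attrs["metadata"] = json.load(fh)
    return data
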
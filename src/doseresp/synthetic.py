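"""Seeded synthetic dose-response fixtures with known 4PL ground truth.

The generator emulates a 72 h viability screen read out over ten
concentrations log-spaced from 5 pM to 10 uM: the clean signal is a 4PL
curve in percent inhibition, replicate wells add homoscedastic Gaussian
noise, and optional outlier wells add a fixed positive shift.  Responses
are then expressed in any of the four input conventions so the reader's
conversion path is exercised on the way back in.  Everything is fully
determined by the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .conventions import PERCENT_INHIBITION, ResponseConvention, from_percent_inhibition
from .model import LogisticParams, _logistic
from .series import DoseResponseSeries

__all__ = [
    "DEFAULT_CONCENTRATIONS",
    "SyntheticSpec",
    "SyntheticSeries",
    "generate",
    "simulate_batch",
    "write_fixture",
]

# ten points, 5 pM .. 10 uM
DEFAULT_CONCENTRATIONS = np.geomspace(5e-12, 1e-5, 10)


@dataclass
class SyntheticSpec:
    """Ground truth and noise model for one synthetic series."""

    response_min: float = 0.0
    response_max: float = 100.0
    hillslope: float = 1.0
    log10_ic50: float = -7.5
    concentrations: np.ndarray = field(default_factory=lambda: DEFAULT_CONCENTRATIONS.copy())
    n_replicates: int = 3
    noise_sd: float = 2.0
    outlier_rate: float = 0.0
    outlier_shift: float = 40.0
    convention: ResponseConvention = PERCENT_INHIBITION
    seed: int = 0
    sample_id: str = "S1"
    drug_id: str = "D1"

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.outlier_rate <= 1.0):
            raise ValueError("outlier_rate must lie in [0, 1]")
        if np.any(self.concentrations <= 0) or np.unique(self.concentrations).size != self.concentrations.size:
            raise ValueError("concentrations must be positive and distinct")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def true_params(self) -> LogisticParams:
        return LogisticParams(
            self.response_min, self.response_max, self.hillslope, self.log10_ic50
        )


@dataclass
class SyntheticSeries:
    """A generated series plus its spreadsheet-shaped frame and ground truth."""

    series: DoseResponseSeries          # canonical percent inhibition
    frame: pd.DataFrame                 # rows in the requested convention
    truth: dict


def generate(spec: SyntheticSpec) -> SyntheticSeries:
    """Draw one series from the spec, deterministically in the seed.

    Noise and outlier draws are ordered so that ``outlier_rate=0`` and
    ``noise_sd=0`` each leave the remaining draws (hence the output)
    bit-for-bit unchanged.
    """
    rng = np.random.default_rng(spec.seed)
    conc = np.sort(spec.concentrations)
    clean = _logistic(np.log10(conc), *spec.true_params.as_tuple())
    shape = (conc.size, spec.n_replicates)
    responses = np.tile(clean[:, None], (1, spec.n_replicates))
    if spec.noise_sd > 0:
        responses = responses + rng.normal(0.0, spec.noise_sd, shape)
    if spec.outlier_rate > 0:
        hits = rng.random(shape) < spec.outlier_rate
        responses = responses + np.where(hits, spec.outlier_shift, 0.0)
    series = DoseResponseSeries(
        sample_id=spec.sample_id,
        drug_id=spec.drug_id,
        concentrations=conc,
        responses=responses,
    )
    conv = from_percent_inhibition(responses, spec.convention)
    frame = pd.DataFrame(
        {
            "sample": spec.sample_id,
            "drug": spec.drug_id,
            "concentration": conc,
        }
    )
    for j in range(spec.n_replicates):
        frame[f"response{j + 1}"] = conv[:, j]
    truth = {
        "sample": spec.sample_id,
        "drug": spec.drug_id,
        "response_min": spec.response_min,
        "response_max": spec.response_max,
        "hillslope": spec.hillslope,
        "log10_ic50": spec.log10_ic50,
        "noise_sd": spec.noise_sd,
        "outlier_rate": spec.outlier_rate,
        "seed": spec.seed,
    }
    return SyntheticSeries(series=series, frame=frame, truth=truth)


def simulate_batch(
    n_samples: int = 2,
    n_drugs: int = 3,
    seed: int = 0,
    noise_sd: float = 2.0,
    n_replicates: int = 3,
    outlier_rate: float = 0.0,
    convention: ResponseConvention = PERCENT_INHIBITION,
) -> list:
    """A batch of series with per-(sample, drug) true parameters drawn once.

    Midpoints span the interior of the tested range, maxima and slopes vary
    so the batch exercises potency, efficacy and cooperativity differences.
    """
    master = np.random.default_rng(seed)
    out = []
    for i in range(n_samples):
        for j in range(n_drugs):
            sub_seed = int(master.integers(0, 2**31 - 1))
            rng = np.random.default_rng(sub_seed)
            spec = SyntheticSpec(
                response_min=float(rng.uniform(-2.0, 5.0)),
                response_max=float(rng.uniform(60.0, 100.0)),
                hillslope=float(rng.uniform(0.6, 2.5)),
                log10_ic50=float(rng.uniform(-9.5, -6.0)),
                n_replicates=n_replicates,
                noise_sd=noise_sd,
                outlier_rate=outlier_rate,
                convention=convention,
                seed=sub_seed,
                sample_id=f"S{i + 1}",
                drug_id=f"D{j + 1}",
            )
            out.append(generate(spec))
    return out


def write_fixture(generated, path) -> Path:
    """Write a batch of synthetic series to a spreadsheet plus a truth sidecar.

    The main file is ingestible by :func:`doseresp.io.read_batch` with the
    default schema; ground truth goes to ``<stem>.truth.csv`` next to it.
    """
    generated = list(generated)
    if not generated:
        raise ValueError("write_fixture needs at least one series")
    path = Path(path)
    frame = pd.concat([g.frame for g in generated], ignore_index=True)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        frame.to_excel(path, index=False)
    else:
        frame.to_csv(path, index=False)
    truth = pd.DataFrame([g.truth for g in generated])
    truth_path = path.with_name(path.stem + ".truth.csv")
    truth.to_csv(truth_path, index=False)
    return path
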
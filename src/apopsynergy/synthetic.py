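"""Synthetic observation datasets with the experiments' noise structure.

Three generators mirror the study's readouts:

* caspase activity fold-change time courses (population averages with
  multiplicative lognormal replicate noise, ≥3 replicates);
* cFLIP immunoblot densitometry: per-lane intensities carry a shared
  lane scale and independent lognormal noise, and the reported value is
  the ratio of the cFLIP band to a loading-control band, so the lane
  scale cancels exactly;
* 24 h crystal-violet viability fractions with additive truncated
  Gaussian noise, normalised to the untreated replicate mean.

Each dataset records its ground-truth provenance (generating model,
noise model, seed) so parameter-recovery experiments are
self-describing.  Identical arguments reproduce byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import ModelVariant
from .network import default_grid
from .population import PopulationSpec, run_population, to_fold_change, viability
from .ros_cflip import cflip_fold_change, simulate_ros_cflip

__all__ = [
    "ObservationDataset",
    "generate_caspase_activity",
    "generate_cflip_densitometry",
    "generate_viability",
    "CASPASE_SAMPLING_TIMES",
    "replicate_significance",
]

#: LY30 caspase-activity sampling grid (minutes 0, 30, 60, 120, 180,
#: 240 expressed in hours)
CASPASE_SAMPLING_TIMES = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0)

#: cFLIP densitometry sampling grid (hours)
CFLIP_SAMPLING_TIMES = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0)


@dataclass
class ObservationDataset:
    """Tidy (readout, time, replicate, value) table plus provenance."""

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        required = {"readout", "time", "replicate", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"observation table missing columns {missing}")

    def validate(self, min_replicates: int = 3):
        """Structural checks: replicate counts and value ranges."""
        counts = self.data.groupby(["readout", "time"])["replicate"].nunique()
        if (counts < min_replicates).any():
            bad = counts[counts < min_replicates]
            raise ValueError(f"fewer than {min_replicates} replicates at "
                             f"{list(bad.index)}")
        fold = self.data[self.data["readout"].str.contains("fold")]
        if (fold["value"] <= 0).any():
            raise ValueError("fold-change values must be positive")
        return self

    def to_csv(self, path):
        self.data.to_csv(path, index=False)


def _lognormal_factors(rng, cv, size):
    """Multiplicative noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv ** 2)
    return rng.lognormal(-sigma2 / 2, np.sqrt(sigma2), size=size)


def generate_caspase_activity(variant: ModelVariant, spec: PopulationSpec,
                              times=CASPASE_SAMPLING_TIMES,
                              noise_cv: float = 0.1, n_reps: int = 3,
                              seed: int = 0,
                              readout_tag: str = "caspase8_like",
                              ) -> ObservationDataset:
    """Replicate caspase activity fold-changes from a population run."""
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    times = np.asarray(times, dtype=float)
    grid = default_grid(max(float(times.max()), 1.0))
    if times.max() > grid[-1] or times.min() < grid[0]:
        raise ValueError("requested times outside simulation window")
    result = run_population(variant, spec, grid)
    series = to_fold_change(result, readout_tag)
    truth = np.array([series.at(t) for t in times])
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_reps + 1):
        noisy = truth * _lognormal_factors(rng, noise_cv, len(times))
        for t, v in zip(times, noisy):
            rows.append((f"{readout_tag}_fold", t, rep, v))
    return ObservationDataset(
        pd.DataFrame(rows, columns=["readout", "time", "replicate", "value"]),
        metadata={"variant": variant.variant_tag, "noise_cv": noise_cv,
                  "noise_model": "lognormal", "seed": seed,
                  "population": spec, "truth": dict(zip(times, truth))},
    )


def generate_cflip_densitometry(network, times=CFLIP_SAMPLING_TIMES,
                                noise_cv: float = 0.1, n_reps: int = 3,
                                seed: int = 0, ly30_dose_um: float = 25.0,
                                interventions=(),
                                ) -> ObservationDataset:
    """Blot-style cFLIP fold-changes with loading-control normalisation.

    Each lane's raw band intensity is ``fold * lane_scale * noise``;
    the loading control is ``lane_scale * noise'``; the reported value
    divides the two, cancelling the lane scale exactly.
    """
    times = np.asarray(times, dtype=float)
    traj = simulate_ros_cflip(network, ly30_dose_um, interventions,
                              t_end=max(float(times.max()), 1.0))
    truth = cflip_fold_change(traj, times)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_reps + 1):
        lane_scale = rng.uniform(0.5, 2.0, size=len(times))
        band = truth * lane_scale * _lognormal_factors(rng, noise_cv,
                                                       len(times))
        control = lane_scale * _lognormal_factors(rng, noise_cv, len(times))
        for t, v in zip(times, band / control):
            rows.append(("cflip_fold", t, rep, v))
    return ObservationDataset(
        pd.DataFrame(rows, columns=["readout", "time", "replicate", "value"]),
        metadata={"noise_cv": noise_cv, "noise_model": "lognormal-ratio",
                  "seed": seed, "ly30_dose_um": ly30_dose_um,
                  "truth": dict(zip(times, truth)),
                  "parameters": dict(network.parameters)},
    )


def generate_viability(variants: dict[str, ModelVariant],
                       spec: PopulationSpec, noise_sd: float = 0.05,
                       n_reps: int = 3, seed: int = 0, t: float = 24.0,
                       ) -> ObservationDataset:
    """Crystal-violet-style viability fractions at 24 h per variant.

    Additive Gaussian noise truncated to [0, 1]; values are divided by
    the untreated replicate mean (1.0 when no untreated variant is
    supplied, mirroring normalisation to a perfect control).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    raw = {}
    truth = {}
    for tag, variant in variants.items():
        result = run_population(variant, spec, default_grid(t))
        v = viability(result, t)
        truth[tag] = v
        draws = v + rng.normal(0.0, noise_sd, size=n_reps)
        raw[tag] = np.clip(draws, 0.0, 1.0)
    baseline = raw.get("untreated")
    norm = baseline.mean() if baseline is not None else 1.0
    if norm <= 0:
        raise ValueError("untreated viability collapsed to zero")
    rows = []
    for tag, draws in raw.items():
        for rep, v in enumerate(draws, start=1):
            rows.append((f"viability_{tag}", t, rep, v / norm))
    return ObservationDataset(
        pd.DataFrame(rows, columns=["readout", "time", "replicate", "value"]),
        metadata={"noise_sd": noise_sd, "noise_model": "truncated-gaussian",
                  "seed": seed, "population": spec, "truth": truth},
    )


def replicate_significance(dataset: ObservationDataset, readout: str,
                           time: float, null_value: float = 1.0,
                           alternative: str = "greater") -> float:
    """One-tailed one-sample t-test p-value of replicates against a null.

    A thin convenience for sanity-checking that generated effects are
    detectable at the replicate level; not an analysis method.
    """
    values = dataset.data.query(
        "readout == @readout and time == @time")["value"]
    if len(values) < 2:
        raise ValueError("need >= 2 replicates for a t-test")
    res = stats.ttest_1samp(values, null_value, alternative=alternative)
    return float(res.pvalue)
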
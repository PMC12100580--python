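"""Oviposition-preference and larval-survival statistics.

A two-choice assay offers gravid females a fresh+blood substrate at 37 °C
(the one obligate parasites favour) against rotten meat at 25 °C. Each
replicate yields egg counts on the two substrates; replicates without any
eggs are "no oviposition" and excluded from the preference index.

The preference index (PI) of a valid replicate is the fraction of eggs on
the fresh substrate; the species PI is the mean over valid replicates.
For regression against expression the species PI goes through a modified
logit, ln((1+PI)/(2-PI)), which is finite at the boundary values 0 and 1
that saturated species actually produce (ln(1/2) and ln 2 respectively)
and antisymmetric about PI = 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import io as cio


class InvalidTrialError(ValueError):
    """Raised for a replicate with zero total eggs (no oviposition)."""


@dataclass(frozen=True)
class OvipositionTrial:
    species: str
    eggs_fresh: int
    eggs_rotten: int

    def __post_init__(self) -> None:
        if self.eggs_fresh < 0 or self.eggs_rotten < 0:
            raise ValueError("egg counts must be nonnegative")
        if self.eggs_fresh != int(self.eggs_fresh) or self.eggs_rotten != int(self.eggs_rotten):
            raise ValueError("egg counts must be integers")

    @property
    def valid(self) -> bool:
        return self.eggs_fresh + self.eggs_rotten > 0


@dataclass(frozen=True)
class SpeciesPreference:
    species: str
    pi_mean: float
    pi_sd: float
    logit_pi: float
    n_valid: int
    n_no_oviposition: int


@dataclass(frozen=True)
class SurvivalRecord:
    species: str
    diet: str  # "fresh37" or "rotten25"
    n_eggs: int
    n_emerged: int

    def __post_init__(self) -> None:
        if self.n_eggs <= 0:
            raise ValueError("n_eggs must be positive")
        if not 0 <= self.n_emerged <= self.n_eggs:
            raise ValueError("n_emerged must lie in [0, n_eggs]")


@dataclass(frozen=True)
class WeightSample:
    time_h: float
    weights_g: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.weights_g) == 0:
            raise ValueError("empty weight sample")
        if any(w <= 0 for w in self.weights_g):
            raise ValueError("larval weights must be positive")


def preference_index(trial: OvipositionTrial) -> float:
    """PI = eggs on fresh / total eggs for one valid replicate."""
    total = trial.eggs_fresh + trial.eggs_rotten
    if total == 0:
        raise InvalidTrialError(
            f"{trial.species}: no eggs laid; replicate is not a valid PI observation"
        )
    return trial.eggs_fresh / total


def logit_pi(pi: float) -> float:
    """Modified logit ln((1+PI)/(2-PI)), finite on the closed interval [0, 1].

    Maps 0 -> -ln 2, 0.5 -> 0, 1 -> ln 2; strictly increasing and
    antisymmetric: logit_pi(p) + logit_pi(1-p) = 0.
    """
    if not 0.0 <= pi <= 1.0:
        raise ValueError(f"PI must lie in [0, 1], got {pi}")
    return math.log((1.0 + pi) / (2.0 - pi))


def species_preference(trials: Sequence[OvipositionTrial]) -> SpeciesPreference:
    """Summarise one species' replicates: mean/sd PI over valid trials only.

    The sd uses the n-1 denominator; a single valid trial reports sd 0.0.
    Raises InvalidTrialError if no replicate had any eggs.
    """
    if not trials:
        raise InvalidTrialError("no trials provided")
    species = trials[0].species
    if any(t.species != species for t in trials):
        raise ValueError("species_preference expects trials from one species")
    pis = [preference_index(t) for t in trials if t.valid]
    n_skip = sum(1 for t in trials if not t.valid)
    if not pis:
        raise InvalidTrialError(f"{species}: no oviposition in any replicate")
    mean = float(np.mean(pis))
    sd = float(np.std(pis, ddof=1)) if len(pis) > 1 else 0.0
    return SpeciesPreference(
        species=species, pi_mean=mean, pi_sd=sd, logit_pi=logit_pi(mean),
        n_valid=len(pis), n_no_oviposition=n_skip,
    )


def survival_rate(record: SurvivalRecord) -> float:
    """Percent of eggs that emerged as adults."""
    return 100.0 * record.n_emerged / record.n_eggs


def weight_trajectory(samples: Iterable[WeightSample]) -> pd.DataFrame:
    """Per-timepoint mean and sample sd of larval masses, ordered by time."""
    samples = list(samples)
    if not samples:
        raise ValueError("no weight samples")
    times = [s.time_h for s in samples]
    if len(times) != len(set(times)):
        raise ValueError("duplicate time points in weight trajectory")
    rows = []
    for s in sorted(samples, key=lambda s: s.time_h):
        w = np.asarray(s.weights_g, dtype=float)
        sd = float(np.std(w, ddof=1)) if len(w) > 1 else 0.0
        rows.append({"time_h": s.time_h, "mean_g": float(np.mean(w)), "sd_g": sd})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# table-level entry points used by the CLI

TRIALS_SCHEMA = {"species": str, "replicate": str, "eggs_fresh": int, "eggs_rotten": int}
SURVIVAL_SCHEMA = {"species": str, "diet": str, "n_eggs": int, "n_emerged": int}
WEIGHTS_SCHEMA = {"time_h": float, "weight_g": float}


def trials_from_table(df: pd.DataFrame) -> dict[str, list[OvipositionTrial]]:
    out: dict[str, list[OvipositionTrial]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.species, []).append(
            OvipositionTrial(row.species, int(row.eggs_fresh), int(row.eggs_rotten))
        )
    return out


def behaviour_summary(
    trials_df: pd.DataFrame, survival_df: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Species-level table of survival percentages and preference statistics.

    Mirrors the layout: species, survival on each diet (percent, 2 dp in
    text output), PI mean, PI sd, logit PI, valid/no-oviposition counts.
    Species whose females never oviposited get NA preference columns.
    """
    surv: dict[tuple[str, str], float] = {}
    if survival_df is not None:
        for row in survival_df.itertuples(index=False):
            rec = SurvivalRecord(row.species, row.diet, int(row.n_eggs), int(row.n_emerged))
            surv[(rec.species, rec.diet)] = survival_rate(rec)
    rows = []
    for species, trials in trials_from_table(trials_df).items():
        try:
            pref = species_preference(trials)
            pref_cols = {
                "pi_mean": pref.pi_mean, "pi_sd": pref.pi_sd, "pi_logit": pref.logit_pi,
                "n_valid": pref.n_valid, "n_no_oviposition": pref.n_no_oviposition,
            }
        except InvalidTrialError:
            pref_cols = {
                "pi_mean": np.nan, "pi_sd": np.nan, "pi_logit": np.nan,
                "n_valid": 0, "n_no_oviposition": len(trials),
            }
        rows.append({
            "species": species,
            "survival_fresh_pct": surv.get((species, "fresh37"), np.nan),
            "survival_rotten_pct": surv.get((species, "rotten25"), np.nan),
            **pref_cols,
        })
    return pd.DataFrame(rows).sort_values("species", ignore_index=True)


def run_behaviour(trials_path, survival_path=None, weights_path=None, out_dir="."):
    """CLI worker: read the TSVs, write the summary (and weight trajectory)."""
    from pathlib import Path

    trials_df = cio.read_table(trials_path, TRIALS_SCHEMA)
    survival_df = cio.read_table(survival_path, SURVIVAL_SCHEMA) if survival_path else None
    summary = behaviour_summary(trials_df, survival_df)
    out = Path(out_dir)
    cio.write_table(summary, out / "behaviour_summary.tsv")
    if weights_path:
        wdf = cio.read_table(weights_path, WEIGHTS_SCHEMA)
        samples = [
            WeightSample(t, tuple(g["weight_g"]))
            for t, g in wdf.groupby("time_h", sort=True)
        ]
        cio.write_table(weight_trajectory(samples), out / "weight_trajectory.tsv")
    return summary
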
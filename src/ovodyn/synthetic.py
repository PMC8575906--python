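"""Seeded synthetic populations with known ground truth.

The generator emulates a serial-spawning teleost cohort sampled across a
spawning cycle, together with the two observation channels the pipeline
consumes:

* **Latent state.** Each female gets a latent spawning stage (oocyte-ratio
  category 0–4). Per-phase truth is parameterised as relative-fecundity
  trajectories (oocytes per g body weight) indexed by stage — flat reservoirs
  of small previtellogenic oocytes, a declining PVO4c pool whose prespawning
  minus spent difference is the programmed de novo influx, and dome-shaped
  cortical-alveoli/vitellogenic waves. True packing densities follow via
  opd = RF / (OW/W).
* **Wholemount channel.** Measured diameters are a multinomial draw over
  phases weighted by true density times a per-phase detection probability
  (previtellogenic oocytes are heavily under-detected, hiding under the
  large vitellogenic oocytes), with per-phase truncated-normal diameters on
  the formalin scale and the sub-100 µm washout applied.
* **Histology channel.** Expected volume fractions invert the packing
  density equation exactly (including the third central moment of the
  diameter distribution, so the cubic-mean diameter estimator is unbiased);
  grid hits are multinomial over 500 Weibel points with OTHERS absorbing the
  residual probability, and three through-the-nucleus axis pairs per phase
  are drawn at the histology scale (formalin diameter ÷ true shrinkage).

Identical (config, seed) pairs produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core_types import (
    FEMALES_COLUMNS,
    AXES_COLUMNS,
    HITS_COLUMNS,
    WHOLEMOUNT_COLUMNS,
    OPD_PHASES,
    PVO_PHASES,
    PhaseCode,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate_population",
    "simulate_wholemount",
    "simulate_histology",
    "generate_dataset",
    "write_dataset",
    "true_diameter_crossing",
    "DEFAULT_RF_TRAJECTORIES",
    "DEFAULT_DIAMETER_MEANS",
]

#: phases carrying a packing density, in developmental order (PVO2..GVBD)
PHASES: tuple[str, ...] = tuple(p.value for p in OPD_PHASES)
_PVO_SET = {p.value for p in PVO_PHASES}

#: per-phase true relative fecundity (oocytes per g body weight) indexed by
#: latent stage ORC0..ORC4. Small PVO reservoirs are flat in the thousands;
#: PVO4c declines 200 -> 40 (programmed influx 160); the prespawning
#: PVO4c..GVBD aggregate sums to 528; cortical-alveoli and vitellogenic
#: phases rise into early spawning then drain to near zero when spent.
DEFAULT_RF_TRAJECTORIES: dict[str, tuple[float, ...]] = {
    "PVO2": (2600.0, 2600.0, 2600.0, 2600.0, 2600.0),
    "PVO3": (2000.0, 2000.0, 2000.0, 2000.0, 2000.0),
    "PVO4a": (110.0, 90.0, 80.0, 70.0, 60.0),
    "PVO4b": (80.0, 70.0, 60.0, 50.0, 45.0),
    "PVO4c": (200.0, 160.0, 120.0, 80.0, 40.0),
    "CA": (120.0, 180.0, 60.0, 15.0, 2.0),
    "VO1": (208.0, 330.0, 110.0, 25.0, 1.0),
    "VO2": (0.0, 140.0, 55.0, 14.0, 1.0),
    "VO3": (0.0, 90.0, 35.0, 9.0, 0.5),
    "GVM": (0.0, 40.0, 20.0, 7.0, 0.3),
    "GVBD": (0.0, 20.0, 10.0, 4.0, 0.2),
}

#: formalin-scale mean diameters (µm), anchored to the printed landmarks
#: (185 µm legacy threshold at PVO4a, 230 µm at PVO4c, 1100 µm cap)
DEFAULT_DIAMETER_MEANS: dict[str, float] = {
    "PVO2": 110.0,
    "PVO3": 140.0,
    "PVO4a": 185.0,
    "PVO4b": 210.0,
    "PVO4c": 230.0,
    "CA": 280.0,
    "VO1": 350.0,
    "VO2": 500.0,
    "VO3": 700.0,
    "GVM": 850.0,
    "GVBD": 950.0,
}

_STAGE_BY_ORC = {0: 5, 1: 6, 2: 6, 3: 6, 4: 7}
_MONTH_BY_ORC = {0: 1, 1: 4, 2: 5, 3: 6, 4: 7}


@dataclass
class SimulationConfig:
    """Study conditions of a synthetic cohort. Defaults mirror the field
    design the pipeline targets: 150 histology females, one 500-point grid
    and three axis profiles each, heavy wholemount under-detection of PVOs."""

    n_females: int = 150
    year: int = 2019
    #: latent stage probabilities for ORC0..ORC4 (prespawning-heavy January
    #: sample plus a long spent tail, as in late-season field collections)
    orc_probs: tuple[float, ...] = (0.30, 0.125, 0.125, 0.15, 0.30)
    rf_trajectories: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_RF_TRAJECTORIES)
    )
    #: between-female lognormal CV on each phase RF (deviates clipped ±2.5 σ)
    rf_cv: float = 0.20
    #: ovary-to-body weight ratio by latent stage (drives GSI decline)
    gsi_by_orc: tuple[float, ...] = (0.06, 0.12, 0.09, 0.06, 0.02)
    gsi_cv: float = 0.15
    diameter_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIAMETER_MEANS)
    )
    #: within-phase CV of through-the-nucleus histology profiles — small, as
    #: the rich phase scheme is designed to keep within-phase variance low
    diameter_cv: float = 0.05
    #: within-phase CV of wholemount diameters — broad, since the wholemount
    #: channel sweeps the whole growth continuum binned into phases and its
    #: smoothed size distributions are smooth, not comb-like
    wholemount_diameter_cv: float = 0.15
    shape_k_mean: float = 1.05
    shape_k_sd: float = 0.04
    shrinkage_factor_true: float = 1.11
    grid_points: int = 500
    profiles_per_phase: int = 3
    #: wholemount detection probability of PVO-group vs developing phases
    pvo_detection: float = 0.10
    dev_detection: float = 1.0
    n_wholemount: int = 400
    n_images: int = 3
    # length-weight population model (cm, g)
    lw_a: float = 0.004
    lw_b: float = 3.13
    lw_sd_log: float = 0.08  # natural-log residual sd
    tl_mean: float = 34.0
    tl_sd: float = 3.0
    tl_range: tuple[float, float] = (25.0, 45.0)
    # structure annotations (probability of presence, volume fraction when present)
    pof_prob_spawning: float = 0.6
    pof_vv: float = 0.02
    atresia_early_prob_late: float = 0.3
    atresia_early_vv: float = 0.01
    atresia_late_prob_late: float = 0.4
    atresia_late_vv: float = 0.015
    atr_pvo_prob: float = 0.0
    atr_pvo_vv: float = 0.08
    #: hard cap on summed volume fractions before OTHERS
    max_total_vv: float = 0.95

    @property
    def pvo4c_influx_true(self) -> float:
        traj = self.rf_trajectories["PVO4c"]
        return traj[0] - traj[4]

    def validate(self) -> None:
        if self.n_females < 1:
            raise ValueError("n_females must be >= 1")
        if abs(sum(self.orc_probs) - 1.0) > 1e-9 or any(p < 0 for p in self.orc_probs):
            raise ValueError("orc_probs must be a probability vector over ORC0..ORC4")
        means = [self.diameter_means[p] for p in PHASES]
        if any(b <= a for a, b in zip(means, means[1:])):
            raise ValueError("phase diameter means must strictly increase with order")
        if any(self.diameter_means[p] > 230.0 for p in PHASES if p in _PVO_SET):
            raise ValueError("PVO diameter means must lie at or below 230 um")
        if any(
            not 230.0 < self.diameter_means[p] <= 1100.0
            for p in PHASES
            if p not in _PVO_SET
        ):
            raise ValueError("developing-phase diameter means must lie in (230, 1100] um")
        if self.pvo4c_influx_true < 0:
            raise ValueError("PVO4c trajectory must not rise from ORC0 to ORC4")
        for p in (self.pvo_detection, self.dev_detection):
            if not 0.0 <= p <= 1.0:
                raise ValueError("detection probabilities must lie in [0, 1]")
        if not self.shrinkage_factor_true > 0:
            raise ValueError("true shrinkage factor must be positive")
        # deterministic overpacking check at the configuration means
        for orc in range(5):
            vv = sum(
                self._expected_vv(p, self.rf_trajectories[p][orc] / self.gsi_by_orc[orc])
                for p in PHASES
            )
            if vv > self.max_total_vv:
                raise ValueError(
                    f"overpacked ovary: expected volume fractions sum to {vv:.2f} at ORC{orc}"
                )

    def _expected_vv(self, phase: str, opd_per_g: float) -> float:
        """Invert the packing-density equation: expected V_V for a true density."""
        mu = self.diameter_means[phase]
        sd = self.diameter_cv * mu
        ed3 = mu**3 + 3.0 * mu * sd**2  # E[OD^3] for a normal diameter
        k = self.shape_k_mean
        rho = 1.047  # stage-specific value applied at draw time; bound check only
        return opd_per_g * rho * (math.pi / 6.0) * (8.0 * k / (1.0 + k) ** 3) * ed3 * 1e-12


@dataclass
class GroundTruth:
    """Per-female and population truth backing every synthetic table row."""

    females: pd.DataFrame  # female_id, orc_true, gsi_true, kn_true, gsi_tl_true
    rf_true: pd.DataFrame  # female_id, phase, rf_true, opd_true
    influx_true: float
    lw_a_true: float
    lw_b_true: float


@dataclass
class SyntheticDataset:
    females: pd.DataFrame
    wholemount: pd.DataFrame
    histology_hits: pd.DataFrame
    histology_axes: pd.DataFrame
    truth: GroundTruth
    config: SimulationConfig


def _clipped_lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with deviates clipped at ±2.5 σ."""
    if cv <= 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    z = np.clip(rng.standard_normal(size), -2.5, 2.5)
    return np.exp(sigma * z - 0.5 * sigma**2)


def generate_population(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw biometry and latent per-phase truth for one cohort."""
    config.validate()
    n = config.n_females
    orc = rng.choice(5, size=n, p=np.asarray(config.orc_probs))
    tl = np.clip(
        rng.normal(config.tl_mean, config.tl_sd, size=n), *config.tl_range
    )
    w = config.lw_a * tl**config.lw_b * np.exp(rng.normal(0.0, config.lw_sd_log, size=n))
    gsi = np.array([config.gsi_by_orc[o] for o in orc]) * _clipped_lognormal(
        rng, config.gsi_cv, n
    )
    ow = gsi * w
    ids = [f"F{i:04d}" for i in range(1, n + 1)]
    females = pd.DataFrame(
        {
            "female_id": ids,
            "capture_date": [
                _dt.date(config.year, _MONTH_BY_ORC[int(o)], 15) for o in orc
            ],
            "total_length_cm": np.round(tl, 2),
            "body_weight_g": np.round(w, 1),
            "ovary_weight_g": np.round(ow, 3),
            "maturity_stage": [_STAGE_BY_ORC[int(o)] for o in orc],
            "prespawning_flag": orc == 0,
        }
    )

    rf_rows = []
    for i, fid in enumerate(ids):
        noise = _clipped_lognormal(rng, config.rf_cv, len(PHASES))
        for j, phase in enumerate(PHASES):
            rf = config.rf_trajectories[phase][orc[i]] * noise[j]
            rf_rows.append((fid, phase, rf, rf / gsi[i]))
    rf_true = pd.DataFrame(rf_rows, columns=["female_id", "phase", "rf_true", "opd_true"])

    kn_true = w / (config.lw_a * tl**config.lw_b)
    truth = GroundTruth(
        females=pd.DataFrame(
            {
                "female_id": ids,
                "orc_true": orc,
                "gsi_true": gsi,
                "kn_true": kn_true,
                "gsi_tl_true": 1e4 * ow / tl**config.lw_b,
            }
        ),
        rf_true=rf_true,
        influx_true=config.pvo4c_influx_true,
        lw_a_true=config.lw_a,
        lw_b_true=config.lw_b,
    )
    return females, truth


def _phase_diameter_sampler(config: SimulationConfig, phase: str):
    mu = config.diameter_means[phase]
    sd = config.wholemount_diameter_cv * mu
    a, b = (100.0 - mu) / sd, (1100.0 - mu) / sd
    return stats.truncnorm(a, b, loc=mu, scale=sd)


def simulate_wholemount(
    truth: GroundTruth, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Formalin-scale diameter measurements under the detection model."""
    rf = truth.rf_true.pivot(index="female_id", columns="phase", values="opd_true")
    rows = []
    for fid in truth.females["female_id"]:
        weights = np.array(
            [
                rf.at[fid, p]
                * (config.pvo_detection if p in _PVO_SET else config.dev_detection)
                for p in PHASES
            ]
        )
        total = weights.sum()
        if total <= 0:
            continue
        counts = rng.multinomial(config.n_wholemount, weights / total)
        diam = np.concatenate(
            [
                _phase_diameter_sampler(config, p).rvs(size=c, random_state=rng)
                for p, c in zip(PHASES, counts)
                if c > 0
            ]
        )
        rng.shuffle(diam)
        for i, d in enumerate(diam):
            rows.append((fid, 1 + i % config.n_images, round(float(d), 1)))
    return pd.DataFrame(rows, columns=WHOLEMOUNT_COLUMNS)


def simulate_histology(
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
    stages: Optional[Mapping[str, int]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Weibel-grid hits and axis-pair tables for the whole cohort.

    Volume fractions are the exact inverse of the packing-density equation at
    each female's true densities, so running the stereology chain on the
    noiseless expectations recovers the truth (closed loop). Raises
    "overpacked ovary" if a female's summed fractions exceed the cap even
    after the configured guard.
    """
    orc_by_id = dict(
        zip(truth.females["female_id"], truth.females["orc_true"].astype(int))
    )
    opd = truth.rf_true.pivot(index="female_id", columns="phase", values="opd_true")
    hit_rows = []
    axis_rows = []
    for fid, orc in orc_by_id.items():
        rho = 1.020 if _STAGE_BY_ORC[orc] in (3, 4, 5) else 1.047
        vv = {}
        for p in PHASES:
            mu = config.diameter_means[p]
            sd = config.diameter_cv * mu
            ed3 = mu**3 + 3.0 * mu * sd**2
            k = config.shape_k_mean
            vv[p] = (
                opd.at[fid, p]
                * rho
                * (math.pi / 6.0)
                * (8.0 * k / (1.0 + k) ** 3)
                * ed3
                * 1e-12
            )
        # structure annotations
        structures = {}
        if orc >= 1 and rng.random() < config.pof_prob_spawning:
            structures["POF"] = config.pof_vv
        if orc >= 3:
            if rng.random() < config.atresia_early_prob_late:
                structures["ATR_EARLY_ALPHA"] = config.atresia_early_vv
            if rng.random() < config.atresia_late_prob_late:
                structures["ATR_LATE_ALPHA"] = config.atresia_late_vv
        if rng.random() < config.atr_pvo_prob:
            structures["ATR_PVO"] = config.atr_pvo_vv
        total = sum(vv.values()) + sum(structures.values())
        if total > config.max_total_vv:
            raise ValueError(
                f"overpacked ovary for female {fid}: volume fractions sum to {total:.2f}"
            )
        labels = list(vv) + list(structures) + ["OTHERS"]
        probs = list(vv.values()) + list(structures.values()) + [1.0 - total]
        hits = rng.multinomial(config.grid_points, probs)
        area = float(rng.uniform(40.0, 150.0))
        for label, h in zip(labels, hits):
            hit_rows.append((fid, label, int(h), config.grid_points, round(area, 1)))
        # axis pairs at histology scale for every phase truly present
        for p in PHASES:
            if opd.at[fid, p] <= 0:
                continue
            mu = config.diameter_means[p]
            sd = config.diameter_cv * mu
            od_f = rng.normal(mu, sd, size=config.profiles_per_phase)
            od_f = np.clip(od_f, 0.3 * mu, None)
            od_h = od_f / config.shrinkage_factor_true
            ks = np.maximum(
                rng.normal(config.shape_k_mean, config.shape_k_sd, size=od_h.size), 1.0
            )
            s_ax = 2.0 * od_h / (1.0 + ks)
            l_ax = ks * s_ax
            for L, S in zip(l_ax, s_ax):
                axis_rows.append((fid, p, round(float(L), 2), round(float(S), 2)))
    hits_df = pd.DataFrame(hit_rows, columns=HITS_COLUMNS)
    axes_df = pd.DataFrame(axis_rows, columns=AXES_COLUMNS)
    return hits_df, axes_df


def generate_dataset(config: Optional[SimulationConfig] = None, seed: int = 42) -> SyntheticDataset:
    """Generate the four observation tables plus ground truth for one cohort."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    females, truth = generate_population(config, rng)
    wholemount = simulate_wholemount(truth, config, rng)
    hits, axes = simulate_histology(truth, config, rng)
    return SyntheticDataset(females, wholemount, hits, axes, truth, config)


def write_dataset(dataset: SyntheticDataset, out_dir) -> dict[str, str]:
    """Write the CSV schemas plus ground_truth.csv; returns the path map."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in [
        ("females", dataset.females),
        ("wholemount", dataset.wholemount),
        ("histology_hits", dataset.histology_hits),
        ("histology_axes", dataset.histology_axes),
        ("ground_truth", dataset.truth.rf_true.merge(dataset.truth.females, on="female_id")),
    ]:
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = str(p)
    return paths


def zero_influx_config(**overrides) -> SimulationConfig:
    """The determinate-spawner null: a flat PVO4c trajectory (influx 0)."""
    cfg = SimulationConfig(**overrides)
    traj = dict(cfg.rf_trajectories)
    traj["PVO4c"] = (120.0,) * 5
    return dataclasses.replace(cfg, rf_trajectories=traj)


def true_diameter_crossing(
    config: SimulationConfig, orc: int = 1, window: tuple[float, float] = (150.0, 400.0)
) -> float:
    """Numeric crossing of detected PVO vs developing diameter densities.

    The population truth behind the mixture-threshold estimator: the smallest
    diameter in ``window`` where the detection-weighted developing-phase
    density first exceeds the detection-weighted PVO density at latent stage
    ``orc``.
    """
    weights = {
        p: config.rf_trajectories[p][orc]
        * (config.pvo_detection if p in _PVO_SET else config.dev_detection)
        for p in PHASES
    }

    def side_density(x: float, pvo: bool) -> float:
        tot = 0.0
        for p, w in weights.items():
            if (p in _PVO_SET) != pvo or w <= 0:
                continue
            mu = config.diameter_means[p]
            sd = config.wholemount_diameter_cv * mu
            tot += w * stats.norm.pdf(x, mu, sd)
        return tot

    f = lambda x: side_density(x, pvo=False) - side_density(x, pvo=True)
    grid = np.linspace(window[0], window[1], 1024)
    vals = np.array([f(x) for x in grid])
    idx = np.flatnonzero((vals[:-1] < 0) & (vals[1:] >= 0))
    if idx.size == 0:
        raise ValueError("no density crossing inside the window")
    i = idx[0]
    return float(optimize.brentq(f, grid[i], grid[i + 1], xtol=1e-6))
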
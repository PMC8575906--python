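"""Fecundity measures and the de novo recruitment / batch-number calculus.

Packing densities become counts per female via NO_i = OPD_i × OW (ovary
weight), then relative fecundities RF_i = NO_i / W (per g body weight) and
RF_TL_i = 100 · NO_i / TL^b. Grouping RF by oocyte-ratio category (ORC)
exposes the drawdown of each phase across the spawning season; the decline
of the most advanced previtellogenic phase (PVO4c by default) from
prespawning (ORC0) to spent (ORC4) measures the de novo influx of oocytes
into the maturing pool — the quantitative hallmark of an indeterminate
spawner. Adding that influx to the prespawning standing stock and dividing
by a batch fecundity yields the number of egg batches a typical female
produces.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .biometrics import DEFAULT_ALLOMETRIC_B
from .core_types import ATRESIA_CODES, OPD_PHASES, PhaseCode

__all__ = [
    "AGGREGATE_PHASES",
    "fecundity_table",
    "rf_by_orc",
    "denovo_influx",
    "BatchEstimate",
    "total_potential_and_batches",
    "threshold_sensitivity",
    "standard_individual",
    "structure_prevalence",
    "RecruitmentSummary",
]

#: phases summed in the "potential fecundity" aggregate (PVO4c → GVBD)
AGGREGATE_PHASES: tuple[str, ...] = tuple(
    p.value for p in OPD_PHASES if p >= PhaseCode.PVO4c
)
#: the legacy aggregate additionally counts PVO4a and PVO4b
LEGACY_AGGREGATE_PHASES: tuple[str, ...] = tuple(
    p.value for p in OPD_PHASES if p >= PhaseCode.PVO4a
)


def fecundity_table(
    opd_table: pd.DataFrame,
    females: pd.DataFrame,
    b: float = DEFAULT_ALLOMETRIC_B,
) -> pd.DataFrame:
    """Per-female × per-phase fecundity measures NO, RF and RF_TL.

    ``opd_table`` is the long stereology output (only oocyte-phase rows with
    a finite packing density are used); ``females`` supplies OW, W and TL.
    """
    meta = females.set_index("female_id")
    phases = opd_table[opd_table["phase"].isin([p.value for p in OPD_PHASES])]
    rows = []
    for r in phases.itertuples(index=False):
        fid = str(r.female_id)
        if fid not in meta.index:
            raise KeyError(f"female {fid} in packing-density table missing from biometry")
        ow = float(meta.at[fid, "ovary_weight_g"])
        w = float(meta.at[fid, "body_weight_g"])
        tl = float(meta.at[fid, "total_length_cm"])
        no = float(r.opd_per_g) * ow
        rows.append((fid, r.phase, no, no / w, 100.0 * no / tl**b))
    if not rows:
        raise ValueError("empty packing-density table")
    return pd.DataFrame(rows, columns=["female_id", "phase", "NO", "RF", "RF_TL"])


def _attach_groups(
    fec: pd.DataFrame, orc: pd.DataFrame, females: pd.DataFrame
) -> pd.DataFrame:
    years = females.set_index("female_id")["capture_date"].map(lambda d: d.year)
    df = fec.merge(orc[["female_id", "ORC"]], on="female_id", how="inner")
    if df.empty:
        raise ValueError("empty join between fecundity and ORC tables")
    df["year"] = df["female_id"].map(years)
    return df


def rf_by_orc(
    fec: pd.DataFrame, orc: pd.DataFrame, females: pd.DataFrame
) -> pd.DataFrame:
    """Mean RF with a normal-approximation 95% CI per phase × ORC × year.

    Cells with a single female get an undefined (NaN) CI and are flagged via
    ``ci_defined`` rather than bootstrapped.
    """
    df = _attach_groups(fec, orc, females)
    rows = []
    for (phase, orc_cat, year), grp in df.groupby(["phase", "ORC", "year"], sort=True):
        vals = grp["RF"].to_numpy()
        mean = float(np.mean(vals))
        n = int(vals.size)
        if n >= 2:
            se = float(np.std(vals, ddof=1) / math.sqrt(n))
            lo, hi = mean - 1.96 * se, mean + 1.96 * se
            defined = True
        else:
            se, lo, hi, defined = float("nan"), float("nan"), float("nan"), False
        rows.append((phase, int(orc_cat), int(year), mean, se, lo, hi, n, defined))
    return pd.DataFrame(
        rows,
        columns=["phase", "ORC", "year", "mean_RF", "se", "ci_low", "ci_high", "n", "ci_defined"],
    )


def denovo_influx(
    summary: pd.DataFrame,
    phase: str = "PVO4c",
    year: Optional[int] = None,
) -> tuple[float, float]:
    """De novo influx = mean RF_phase(ORC0) − mean RF_phase(ORC4).

    Returns ``(influx, se)`` where the standard error combines the two cell
    SEs in quadrature (NaN if either is undefined). A negative influx — the
    determinate-spawner signature — is reported with a warning, not clamped.
    """
    sel = summary[summary["phase"] == phase]
    if year is not None:
        sel = sel[sel["year"] == year]
    cell0 = sel[sel["ORC"] == 0]
    cell4 = sel[sel["ORC"] == 4]
    if cell0.empty or cell4.empty:
        raise ValueError(
            f"cannot quantify influx for {phase}: ORC0 and ORC4 cells must both be populated"
        )

    def _pool(cells: pd.DataFrame) -> tuple[float, float]:
        # weighted across years if more than one row survives the filter
        w = cells["n"].to_numpy(dtype=float)
        m = float(np.average(cells["mean_RF"].to_numpy(), weights=w))
        se2 = np.nansum((w / w.sum()) ** 2 * cells["se"].to_numpy() ** 2)
        return m, float(math.sqrt(se2))

    m0, s0 = _pool(cell0)
    m4, s4 = _pool(cell4)
    influx = m0 - m4
    if influx < 0:
        warnings.warn(
            f"negative de novo influx for {phase}: ORC0 mean below ORC4 mean", RuntimeWarning
        )
    return influx, float(math.hypot(s0, s4))


@dataclass
class BatchEstimate:
    batch_fecundity: float  # oocytes per g body weight
    ratio: float  # unrounded total / batch fecundity
    n_batches: int  # nearest integer


def total_potential_and_batches(
    rf_orc0_aggregate: float,
    influx: float,
    batch_fecundities: Sequence[float],
) -> tuple[float, list[BatchEstimate]]:
    """Season total potential RF and batch counts per batch-fecundity value.

    total = prespawning aggregate (RF summed PVO4c→GVBD at ORC0) + de novo
    influx; batches = total / batch fecundity, rounded to nearest integer and
    reported alongside the unrounded ratio.
    """
    if rf_orc0_aggregate < 0 or influx < 0:
        raise ValueError("aggregate and influx must be non-negative")
    total = rf_orc0_aggregate + influx
    estimates = []
    for f in batch_fecundities:
        if not f > 0:
            raise ValueError(f"batch fecundity must be positive, got {f}")
        ratio = total / f
        estimates.append(BatchEstimate(float(f), float(ratio), int(round(ratio))))
    return float(total), estimates


def threshold_sensitivity(
    fec: pd.DataFrame,
    orc: pd.DataFrame,
    females: pd.DataFrame,
    lower_phase_a: str = "PVO4a",
    lower_phase_b: str = "PVO4c",
    orc_range: Sequence[int] = (1, 2, 3),
) -> pd.DataFrame:
    """Percent reduction in aggregated RF when the lower phase bound moves
    from ``lower_phase_a`` (legacy) to ``lower_phase_b`` (revised).

    Per female the RF sum from each lower bound up to GVBD is formed first;
    the per-female percent reduction 100·(1 − Σb/Σa) is then averaged per
    year (the paired design). The comparison covers actively spawning
    females (``orc_range``, default ORC1–3): prespawning and spent fish hold
    little beyond previtellogenic oocytes and would dominate the statistic.
    Females whose revised aggregate is zero while the legacy one is not —
    e.g. fish retaining only the smaller PVO phases — drop out of the
    pairing.
    """
    pa = PhaseCode(lower_phase_a)
    pb = PhaseCode(lower_phase_b)
    if not pa < pb:
        raise ValueError("legacy lower phase must precede the revised one")
    phases_a = {p.value for p in OPD_PHASES if p >= pa}
    phases_b = {p.value for p in OPD_PHASES if p >= pb}
    df = _attach_groups(fec, orc, females)
    df = df[df["ORC"].isin(set(orc_range))]
    if df.empty:
        raise ValueError("no females inside the requested ORC range")
    rows = []
    for (fid, year), grp in df.groupby(["female_id", "year"], sort=True):
        sum_a = grp.loc[grp["phase"].isin(phases_a), "RF"].sum()
        sum_b = grp.loc[grp["phase"].isin(phases_b), "RF"].sum()
        if sum_a <= 0 or sum_b <= 0:
            if sum_a > 0:  # only the legacy-side phases present: unpaired
                continue
            rows.append((fid, int(year), 0.0))
            continue
        rows.append((fid, int(year), 100.0 * (1.0 - sum_b / sum_a)))
    if not rows:
        raise ValueError("no paired females for the threshold sensitivity")
    per_female = pd.DataFrame(rows, columns=["female_id", "year", "pct_reduction"])
    return (
        per_female.groupby("year")["pct_reduction"]
        .agg(mean_pct_reduction="mean", n="size")
        .reset_index()
    )


def standard_individual(
    fec: pd.DataFrame,
    orc: pd.DataFrame,
    females: pd.DataFrame,
    phases: Sequence[str] = AGGREGATE_PHASES,
) -> pd.DataFrame:
    """Grand-mean RF of a "standard individual" per ORC × year.

    For each cell the grand mean RF of every phase in ``phases`` is computed
    and summed; per-phase contributions are retained for stacked reporting.
    Columns: year, ORC, phase, mean_RF_contribution, total_RF (repeated per
    phase row for convenience).
    """
    df = _attach_groups(fec, orc, females)
    df = df[df["phase"].isin(set(phases))]
    contrib = (
        df.groupby(["year", "ORC", "phase"], sort=True)["RF"].mean().reset_index(name="mean_RF_contribution")
    )
    totals = contrib.groupby(["year", "ORC"])["mean_RF_contribution"].transform("sum")
    contrib["total_RF"] = totals
    return contrib


def structure_prevalence(
    opd_table: pd.DataFrame,
    orc: pd.DataFrame,
    females: pd.DataFrame,
    structures: Sequence[str] = tuple(c.value for c in ATRESIA_CODES) + ("POF",),
    by: str = "ORC",
) -> pd.DataFrame:
    """Prevalence (% of females with V_V > 0) and mean V_V per group.

    ``by`` selects the grouping: "ORC" (with year) or "month" (with year).
    Groups with no females are simply absent from the output.
    """
    meta = females.set_index("female_id")
    sel = opd_table[opd_table["phase"].isin(set(structures))].copy()
    sel["female_id"] = sel["female_id"].astype(str)
    if by == "ORC":
        keys = orc.set_index("female_id")["ORC"]
        sel["group"] = sel["female_id"].map(keys)
    elif by == "month":
        sel["group"] = sel["female_id"].map(meta["capture_date"].map(lambda d: d.month))
    else:
        raise ValueError("grouping must be 'ORC' or 'month'")
    sel["year"] = sel["female_id"].map(meta["capture_date"].map(lambda d: d.year))
    sel = sel.dropna(subset=["group"])
    rows = []
    for (structure, group, year), grp in sel.groupby(["phase", "group", "year"], sort=True):
        vv = grp["V_V"].to_numpy(dtype=float)
        rows.append(
            (
                structure,
                group,
                int(year),
                100.0 * float(np.mean(vv > 0)),
                float(np.mean(vv)),
                int(vv.size),
            )
        )
    return pd.DataFrame(
        rows, columns=["structure", by, "year", "prevalence_pct", "mean_V_V", "n"]
    )


@dataclass
class RecruitmentSummary:
    """Bundle of the recruitment outputs produced by the full pipeline."""

    rf_by_orc: pd.DataFrame
    influx: float
    influx_se: float
    rf_orc0_aggregate: float
    total_potential_rf: float
    batch_estimates: list[BatchEstimate]
    standard_individual: pd.DataFrame
    sensitivity: Optional[pd.DataFrame] = None
    caveats: list[str] = field(default_factory=list)


def orc0_aggregate(
    fec: pd.DataFrame,
    orc: pd.DataFrame,
    females: pd.DataFrame,
    phases: Sequence[str] = AGGREGATE_PHASES,
    year: Optional[int] = None,
) -> tuple[float, float]:
    """Prespawning standing stock: mean over ORC0 females of their per-female
    RF summed across ``phases`` (per-female sums first, then the mean).

    Returns ``(mean, se)``. The alternative sum-of-phase-means aggregate
    equals this one up to cell-imbalance and is reported by the pipeline for
    comparison.
    """
    df = _attach_groups(fec, orc, females)
    if year is not None:
        df = df[df["year"] == year]
    df = df[(df["ORC"] == 0) & df["phase"].isin(set(phases))]
    if df.empty:
        raise ValueError("no prespawning (ORC0) females with aggregate phases")
    sums = df.groupby("female_id")["RF"].sum()
    mean = float(sums.mean())
    se = float(sums.std(ddof=1) / math.sqrt(len(sums))) if len(sums) >= 2 else float("nan")
    return mean, se
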
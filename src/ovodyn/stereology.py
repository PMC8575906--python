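"""Stereological estimation of phase-specific oocyte packing densities.

The chain runs: Weibel-grid point counts → volume fractions (Delesse
principle: on an isotropic random section the areal fraction of a component
equals its volume fraction) → phase-specific packing density (oocytes per
gram of ovary) via the packing-density equation

    log10 OPD_i = log10[ V_Vi · (1/ρ_o) · (1+k_i)³ / (8 k_i) ]
                  + C − 3·log10(cOD_vi)

where ``V_Vi`` is the volume fraction of phase-i oocytes, ``ρ_o`` the ovary
specific gravity (g cm⁻³), ``k_i = L/S`` the mean profile shape factor,
``cOD_vi`` the shrinkage-corrected mean volume-based diameter (µm), and
``C = log10((6/π)·10¹²) ≈ 12.28`` the unit constant converting µm³ sphere
volumes to cm³ per gram. All logarithms are base 10 — forced by the printed
constant. The shape term follows from modelling oocytes as prolate spheroids
with axes (L, S, S): with OD = (L+S)/2 the spheroid volume is
(π/6)·OD³·8k/(1+k)³, so dividing the occupied volume per gram by it yields
exactly the equation above (derivation in docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence, Union

import numpy as np
import pandas as pd

from .core_types import (
    OPD_PHASES,
    STRUCTURE_CODES,
    HistologySample,
    PhaseCode,
)

__all__ = [
    "OPD_CONSTANT_PRINTED",
    "OPD_CONSTANT_EXACT",
    "opd_unit_constant",
    "VolumeFractionTable",
    "delesse_volume_fractions",
    "shape_factor",
    "volume_based_diameter",
    "shrinkage_correct",
    "specific_gravity_for_stage",
    "specific_gravity_from_submersion",
    "opd",
    "opd_table_for_female",
    "opd_tables",
    "DEFAULT_SHRINKAGE_FACTOR",
]

#: constant as printed in the packing-density literature (2 decimals)
OPD_CONSTANT_PRINTED: float = 12.28
#: exact value of log10((6/π)·10¹²) for µm diameters and g·cm⁻³ gravities
OPD_CONSTANT_EXACT: float = math.log10(6.0 / math.pi * 1e12)

#: default multiplicative correction restoring histology-scale diameters to
#: the formalin-preserved scale (~10% linear shrinkage in resin histology).
#: The appropriate factor is protocol-specific — override via configuration.
DEFAULT_SHRINKAGE_FACTOR: float = 1.11

ConstantMode = Literal["printed", "exact"]


def opd_unit_constant(mode: ConstantMode = "printed") -> float:
    """Return the unit-conversion constant C of the packing-density equation."""
    if mode == "printed":
        return OPD_CONSTANT_PRINTED
    if mode == "exact":
        return OPD_CONSTANT_EXACT
    raise ValueError(f"constant_mode must be 'printed' or 'exact', got {mode!r}")


@dataclass
class VolumeFractionTable:
    """Per-structure volume fractions for one female's section."""

    female_id: str
    fractions: dict[str, float]

    def __getitem__(self, code: Union[PhaseCode, str]) -> float:
        key = code.value if isinstance(code, PhaseCode) else str(code)
        return self.fractions.get(key, 0.0)


def delesse_volume_fractions(sample: HistologySample) -> VolumeFractionTable:
    """Convert grid-point hits to volume fractions via the Delesse principle.

    Fractions are hits over the total number of *assigned* points, so the
    annotated structures (including OTHERS) sum to exactly 1.
    """
    total = sum(sample.grid_hits.values())
    if total <= 0:
        raise ValueError(f"female {sample.female_id}: empty grid count")
    return VolumeFractionTable(
        female_id=sample.female_id,
        fractions={code: hits / total for code, hits in sample.grid_hits.items()},
    )


def shape_factor(long_axis: float, short_axis: float) -> float:
    """Profile shape factor k = L/S (dimensionless, ≥ 1)."""
    if not short_axis > 0:
        raise ValueError("short axis must be > 0")
    if long_axis < short_axis:
        raise ValueError(
            f"long axis {long_axis} < short axis {short_axis}: axes swapped upstream?"
        )
    return long_axis / short_axis


def volume_based_diameter(axes: Sequence[tuple[float, float]]) -> float:
    """Cubic-mean oocyte diameter OD_v = [Σ OD³ / n]^(1/3) from (L, S) pairs.

    Per-profile OD is the arithmetic mean (L+S)/2. The cubic mean is the
    diameter of the sphere of average volume; by the power-mean inequality it
    is never below the arithmetic mean of the ODs.
    """
    if len(axes) == 0:
        raise ValueError("no measurements for phase")
    ods = np.array([(L + S) / 2.0 for L, S in axes], dtype=float)
    if np.any(ods <= 0):
        raise ValueError("non-positive diameter derived from axis pair")
    return float(np.cbrt(np.mean(ods**3)))


def shrinkage_correct(od_histology: float, correction_factor: float) -> float:
    """Rescale a histology-scale diameter to the formalin-preserved scale."""
    if not correction_factor > 0:
        raise ValueError("shrinkage correction factor must be > 0")
    return od_histology * correction_factor


def specific_gravity_for_stage(maturity_stage: int) -> float:
    """Ovary specific gravity (g cm⁻³) by IMR maturity stage.

    Maturing ovaries (stages 3–5) are less dense (1.020) than spawning,
    spent and recovering ovaries (stages 6–8: 1.047), as established by
    whole-ovary submersion in saline of gravity 1.007.
    """
    if maturity_stage in (3, 4, 5):
        return 1.020
    if maturity_stage in (6, 7, 8):
        return 1.047
    if maturity_stage in (1, 2):
        raise ValueError("no gravity defined for juveniles (stages 1-2)")
    raise ValueError(f"invalid maturity stage {maturity_stage}")


def specific_gravity_from_submersion(ovary_weight: float, ovary_volume: float) -> float:
    """Direct gravity estimate ρ = weight/volume from the submersion method."""
    if not ovary_volume > 0:
        raise ValueError("ovary volume must be > 0")
    if not ovary_weight > 0:
        raise ValueError("ovary weight must be > 0")
    return ovary_weight / ovary_volume


def opd(
    v_v: float,
    rho_o: float,
    k: float,
    cod_v: float,
    constant_mode: ConstantMode = "printed",
) -> tuple[float, float]:
    """Phase-specific packing density (log10 and linear oocytes g⁻¹).

    Parameters
    ----------
    v_v : volume fraction of the phase, in [0, 1].
    rho_o : ovary specific gravity, g cm⁻³.
    k : mean shape factor L/S, ≥ 1.
    cod_v : shrinkage-corrected volume-based diameter, µm, > 0.
    constant_mode : 'printed' uses 12.28 (reproducing published numbers);
        'exact' uses log10((6/π)·10¹²) ≈ 12.28106.

    Returns ``(opd_log10, opd)``. A zero volume fraction yields
    ``(-inf, 0.0)`` so spent ovaries process cleanly.
    """
    if not 0.0 <= v_v <= 1.0:
        raise ValueError(f"volume fraction must be in [0,1], got {v_v}")
    if not rho_o > 0:
        raise ValueError("specific gravity must be > 0")
    if not k >= 1.0:
        raise ValueError(f"shape factor must be >= 1, got {k}")
    if not cod_v > 0:
        raise ValueError("corrected volume-based diameter must be > 0")
    if v_v == 0.0:
        return float("-inf"), 0.0
    c = opd_unit_constant(constant_mode)
    log10_opd = (
        math.log10(v_v * (1.0 / rho_o) * (1.0 + k) ** 3 / (8.0 * k))
        + c
        - 3.0 * math.log10(cod_v)
    )
    return log10_opd, 10.0**log10_opd


_OPD_PHASE_CODES = tuple(p.value for p in OPD_PHASES)
_STRUCTURE_CODE_STRS = tuple(p.value for p in STRUCTURE_CODES)


def opd_table_for_female(
    histology: HistologySample,
    maturity_stage: int,
    correction_factor: float = DEFAULT_SHRINKAGE_FACTOR,
    constant_mode: ConstantMode = "printed",
) -> pd.DataFrame:
    """Full per-phase packing-density table for one female.

    Composes Delesse volume fractions, shape factors, volume-based diameters,
    shrinkage correction and the packing-density equation for every phase
    PVO2→GVBD. PVO1 (too few grid hits to quantify) and HYD (irregular after
    dehydration) are excluded by design; structure annotations (atresia, POF,
    OTHERS) get a volume fraction but no packing density.

    Raises if a phase has grid hits but no axis measurements — that is a data
    error, not a computable case.
    """
    vv = delesse_volume_fractions(histology)
    rho = specific_gravity_for_stage(maturity_stage)
    rows = []
    for code in _OPD_PHASE_CODES:
        frac = vv[code]
        axes = histology.axes_for_phase(code)
        if frac > 0 and not axes:
            raise ValueError(
                f"female {histology.female_id}: phase {code} has grid hits "
                "but no axis measurements"
            )
        if axes:
            ks = [shape_factor(L, S) for L, S in axes]
            k_mean = float(np.mean(ks))
            cod_v = shrinkage_correct(volume_based_diameter(axes), correction_factor)
            log10_opd, lin = opd(frac, rho, k_mean, cod_v, constant_mode)
        else:
            k_mean = float("nan")
            cod_v = float("nan")
            log10_opd, lin = float("-inf"), 0.0
        rows.append((histology.female_id, code, frac, k_mean, cod_v, log10_opd, lin, rho))
    for code in _STRUCTURE_CODE_STRS:
        frac = vv[code]
        rows.append(
            (histology.female_id, code, frac, float("nan"), float("nan"), float("nan"), float("nan"), rho)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "female_id",
            "phase",
            "V_V",
            "k_mean",
            "cOD_v_um",
            "opd_log10",
            "opd_per_g",
            "rho_o",
        ],
    )


def opd_tables(
    samples: Iterable[HistologySample],
    stages: dict[str, int],
    correction_factor: float = DEFAULT_SHRINKAGE_FACTOR,
    constant_mode: ConstantMode = "printed",
) -> pd.DataFrame:
    """Concatenate :func:`opd_table_for_female` over a cohort.

    ``stages`` maps female_id → IMR maturity stage (from the biometry table).
    Females lacking a stage entry raise ``KeyError``.
    """
    tables = []
    for sample in samples:
        if sample.female_id not in stages:
            raise KeyError(f"no maturity stage for female {sample.female_id}")
        tables.append(
            opd_table_for_female(
                sample, stages[sample.female_id], correction_factor, constant_mode
            )
        )
    if not tables:
        raise ValueError("no histology samples supplied")
    return pd.concat(tables, ignore_index=True)
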
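"""End-to-end orchestration: tables in, recruitment report out.

``run_pipeline`` composes the stages in the order the analysis demands:
spawning-stage classification from wholemount diameters, biometric indices,
stereological packing densities, fecundity measures, and finally the
recruitment summary (RF-by-ORC grids, de novo influx, batch numbers,
threshold sensitivity). Warnings from any stage are collected into the
report's caveats section instead of being lost to stderr.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import biometrics, core_types, fecundity, stereology, ultrametric

logger = logging.getLogger("ovodyn")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_report"]


@dataclass
class PipelineConfig:
    """Paths and analysis constants for a full pipeline run.

    The defaults embody the standard settings: a 230 µm previtellogenic/
    developing split (185 µm legacy preset for sensitivity work), the
    100–1100 µm analysable window, printed-constant packing densities and
    batch fecundities of 40, 30 and 34 oocytes per g body weight.
    """

    females: str = "females.csv"
    wholemount: str = "wholemount.csv"
    histology_hits: str = "histology_hits.csv"
    histology_axes: str = "histology_axes.csv"
    out_dir: Optional[str] = None
    pvo_max: float = ultrametric.DEFAULT_PVO_MAX
    legacy_threshold: float = ultrametric.LEGACY_PVO_MAX
    min_d: float = ultrametric.MIN_DIAMETER
    max_d: float = ultrametric.MAX_DIAMETER
    shrinkage_factor: float = stereology.DEFAULT_SHRINKAGE_FACTOR
    constant_mode: str = "printed"
    b_override: Optional[float] = None
    batch_fecundities: tuple[float, ...] = (40.0, 30.0, 34.0)
    influx_phase: str = "PVO4c"
    mixture_max_females: int = 28
    #: fit window cap for the threshold mixture (advanced cohorts excluded)
    mixture_fit_max_d: float = 500.0
    bandwidth: Optional[float] = None
    seed: int = 42

    def validate(self) -> None:
        if not (100.0 <= self.min_d < self.pvo_max < self.max_d <= 1150.0):
            raise ValueError(
                "diameter settings must satisfy 100 <= min_d < pvo_max < max_d <= 1150"
            )
        if self.constant_mode not in ("printed", "exact"):
            raise ValueError("constant_mode must be 'printed' or 'exact'")
        if not self.shrinkage_factor > 0:
            raise ValueError("shrinkage factor must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "batch_fecundities" in data:
            data["batch_fecundities"] = tuple(data["batch_fecundities"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["batch_fecundities"] = list(self.batch_fecundities)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def config_hash(self) -> str:
        """Hash of the analysis settings (output location excluded)."""
        data = dataclasses.asdict(self)
        data.pop("out_dir", None)
        payload = json.dumps(data, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    orc: pd.DataFrame
    biometrics: pd.DataFrame
    length_weight: biometrics.LengthWeightFit
    opd: pd.DataFrame
    fecundity: pd.DataFrame
    summary: fecundity.RecruitmentSummary
    structure_prevalence: pd.DataFrame
    threshold_mean: Optional[float]
    threshold_ci: Optional[tuple[float, float]]
    mixture_fits: list = field(default_factory=list)
    orc_frequency: Optional[pd.DataFrame] = None
    report: str = ""
    caveats: list[str] = field(default_factory=list)


def _orc_frequency(orc: pd.DataFrame, females: pd.DataFrame) -> pd.DataFrame:
    meta = females.set_index("female_id")["capture_date"]
    df = orc.copy()
    df["year"] = df["female_id"].map(meta.map(lambda d: d.year))
    df["month"] = df["female_id"].map(meta.map(lambda d: d.month))
    counts = df.groupby(["year", "month", "ORC"]).size().reset_index(name="n")
    totals = counts.groupby(["year", "month"])["n"].transform("sum")
    counts["pct"] = 100.0 * counts["n"] / totals
    return counts


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    Reads the four CSV tables, runs every stage, optionally writes all output
    tables plus a Markdown report to ``config.out_dir``, and returns the
    in-memory result. Stage failures propagate with stage context.
    """
    config.validate()
    caveats: list[str] = []

    def _read(reader, path, name):
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"{name} input missing: {p}")
        return reader(p)

    females = _read(core_types.read_females, config.females, "biometry")
    wholemount = _read(core_types.read_wholemount, config.wholemount, "wholemount")
    hits = _read(core_types.read_histology_hits, config.histology_hits, "histology hits")
    axes = _read(core_types.read_histology_axes, config.histology_axes, "histology axes")

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # --- spawning stage ------------------------------------------------
        orc_df, cleaning = ultrametric.orc_table(
            wholemount,
            females,
            pvo_max=config.pvo_max,
            min_d=config.min_d,
            max_d=config.max_d,
        )
        n_flagged = sum(r.flagged_sub_minimum for r in cleaning)
        if n_flagged:
            caveats.append(
                f"{n_flagged} female(s) had sub-{config.min_d:.0f} um raw detections"
            )
        orc_freq = _orc_frequency(orc_df, females)

        # --- mixture threshold --------------------------------------------
        samples = core_types.wholemount_samples(wholemount)
        spawning_ids = orc_df.loc[orc_df["ORC"].isin((1, 2, 3)), "female_id"]
        fits = []
        for fid in spawning_ids.iloc[: config.mixture_max_females]:
            try:
                cleaned, _ = ultrametric.clean_wholemount(
                    samples[fid].diameters, config.min_d, config.max_d, fid
                )
                fits.append(
                    ultrametric.fit_gamma_gaussian_mixture(
                        cleaned, seed=config.seed, upper_limit=config.mixture_fit_max_d
                    )
                )
            except (ValueError, AssertionError) as exc:
                logger.debug("mixture fit skipped for %s: %s", fid, exc)
        threshold_mean = threshold_ci = None
        try:
            threshold_mean, threshold_ci = ultrametric.threshold_summary(fits)
        except ValueError:
            caveats.append("fewer than two converged mixture fits; no threshold summary")

        # --- biometrics ----------------------------------------------------
        bio_df, lw_fit = biometrics.biometrics_table(females, b_override=config.b_override)
        b_used = config.b_override if config.b_override is not None else lw_fit.b

        # --- stereology ----------------------------------------------------
        hist_samples = core_types.histology_samples(hits, axes)
        stages = females.set_index("female_id")["maturity_stage"].to_dict()
        try:
            opd_df = stereology.opd_tables(
                hist_samples.values(),
                stages,
                correction_factor=config.shrinkage_factor,
                constant_mode=config.constant_mode,  # type: ignore[arg-type]
            )
        except Exception as exc:
            raise RuntimeError(f"stereology stage failed: {exc}") from exc

        # --- fecundity & recruitment ---------------------------------------
        fec_df = fecundity.fecundity_table(opd_df, females, b=b_used)
        rf_grid = fecundity.rf_by_orc(fec_df, orc_df, females)
        try:
            influx, influx_se = fecundity.denovo_influx(
                rf_grid, phase=config.influx_phase
            )
        except ValueError as exc:
            raise RuntimeError(f"recruitment stage failed: {exc}") from exc
        agg0, _agg0_se = fecundity.orc0_aggregate(fec_df, orc_df, females)
        total, batches = fecundity.total_potential_and_batches(
            agg0, max(influx, 0.0), config.batch_fecundities
        )
        std_ind = fecundity.standard_individual(fec_df, orc_df, females)
        try:
            sens = fecundity.threshold_sensitivity(fec_df, orc_df, females)
        except ValueError as exc:
            sens = None
            caveats.append(f"threshold sensitivity unavailable: {exc}")
        prevalence = fecundity.structure_prevalence(opd_df, orc_df, females)

    for w in caught:
        caveats.append(str(w.message))
    n1_cells = int((~rf_grid["ci_defined"]).sum())
    if n1_cells:
        caveats.append(f"{n1_cells} RF cells have n=1 (no CI)")

    summary = fecundity.RecruitmentSummary(
        rf_by_orc=rf_grid,
        influx=influx,
        influx_se=influx_se,
        rf_orc0_aggregate=agg0,
        total_potential_rf=total,
        batch_estimates=batches,
        standard_individual=std_ind,
        sensitivity=sens,
        caveats=caveats,
    )
    result = PipelineResult(
        orc=orc_df,
        biometrics=bio_df,
        length_weight=lw_fit,
        opd=opd_df,
        fecundity=fec_df,
        summary=summary,
        structure_prevalence=prevalence,
        threshold_mean=threshold_mean,
        threshold_ci=threshold_ci,
        mixture_fits=fits,
        orc_frequency=orc_freq,
        caveats=caveats,
    )
    result.report = write_report(result, config)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        orc_df.to_csv(out / "orc.csv", index=False)
        bio_df.to_csv(out / "biometrics.csv", index=False)
        opd_df.to_csv(out / "opd.csv", index=False)
        fec_df.to_csv(out / "fecundity.csv", index=False)
        rf_grid.to_csv(out / "recruitment_summary.csv", index=False)
        prevalence.to_csv(out / "structure_prevalence.csv", index=False)
        if fits:
            pd.DataFrame(
                [
                    {
                        "gamma_shape": f.gamma_shape,
                        "gamma_scale": f.gamma_scale,
                        "normal_mean": f.normal_mean,
                        "normal_sd": f.normal_sd,
                        "weight": f.weight,
                        "threshold_um": f.threshold,
                        "converged": f.converged,
                    }
                    for f in fits
                ]
            ).to_csv(out / "mixture.csv", index=False)
        (out / "report.md").write_text(result.report, encoding="utf-8")
    return result


def write_report(result: PipelineResult, config: PipelineConfig) -> str:
    """Render the Markdown analysis report."""
    s = result.summary
    lines = [
        "# Oocyte recruitment analysis report",
        "",
        f"- config hash: `{config.config_hash()}`, seed {config.seed}",
        f"- PVO/developing split: {config.pvo_max:.0f} um "
        f"(legacy preset {config.legacy_threshold:.0f} um); analysable window "
        f"[{config.min_d:.0f}, {config.max_d:.0f}] um",
        f"- shrinkage factor {config.shrinkage_factor}, packing-density constant mode "
        f"'{config.constant_mode}'",
        "",
        "## Length-weight and condition",
        "",
        f"W = {result.length_weight.a:.4g} * TL^{result.length_weight.b:.3f} "
        f"(b 95% CI half-width {result.length_weight.b_ci95:.3f}, "
        f"R^2 = {result.length_weight.r_squared:.3f}, n = {result.length_weight.n})",
        "",
        "## Mixture threshold",
        "",
    ]
    if result.threshold_mean is not None and result.threshold_ci is not None:
        lines.append(
            f"Mean PVO/developing diameter threshold over {len(result.mixture_fits)} "
            f"fitted females: {result.threshold_mean:.1f} um "
            f"(95% CI {result.threshold_ci[0]:.1f}-{result.threshold_ci[1]:.1f} um)."
        )
    else:
        lines.append("No across-female threshold summary available.")
    lines += [
        "",
        "## Spawning-stage composition (% per month)",
        "",
        result.orc_frequency.to_string(index=False) if result.orc_frequency is not None else "n/a",
        "",
        "## Recruitment",
        "",
        f"- prespawning (ORC0) aggregate RF (PVO4c-GVBD, per-female sums then mean): "
        f"{s.rf_orc0_aggregate:.1f} oocytes g^-1 body weight",
        f"- de novo influx ({config.influx_phase}, ORC0 minus ORC4): "
        f"{s.influx:.1f} +/- {1.96 * s.influx_se:.1f} oocytes g^-1",
        f"- total potential RF: {s.total_potential_rf:.1f} oocytes g^-1",
        "",
        "| batch fecundity (oocytes g^-1) | batches (ratio) | batches (rounded) |",
        "|---|---|---|",
    ]
    for b in s.batch_estimates:
        lines.append(f"| {b.batch_fecundity:g} | {b.ratio:.2f} | {b.n_batches} |")
    if s.sensitivity is not None:
        lines += [
            "",
            "## Threshold sensitivity (legacy vs revised lower phase bound)",
            "",
            s.sensitivity.to_string(index=False),
            "",
            "No atresia adjustment is applied to the influx; atresia volume",
            "fractions are reported separately below.",
        ]
    lines += [
        "",
        "## Structure prevalence",
        "",
        result.structure_prevalence.to_string(index=False)
        if not result.structure_prevalence.empty
        else "no structure annotations",
        "",
        "## Caveats",
        "",
    ]
    lines += [f"- {c}" for c in result.caveats] or ["- none"]
    return "\n".join(lines) + "\n"
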
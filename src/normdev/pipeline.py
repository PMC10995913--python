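"""End-to-end orchestration: simulate/ingest -> fit -> calibrate -> predict
-> metrics -> inference, driven by a YAML config or a :class:`RunConfig`.

Outputs are plain CSV/JSON/Markdown in the configured output directory.
A rerun with the same config and seed is bit-identical (the run log
deliberately carries no timestamps).
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigurationError
from .io import read_roi_table, write_roi_table
from .metrics import (
    DEFAULT_THRESHOLD,
    LIBERAL_THRESHOLD,
    binarize_outliers,
    hamming_matrix,
    regional_outlier_proportion,
    summarize_participants,
)
from .model import fit_normative_model, predict_zscores, recalibrate_site, save_model
from .simulate import (
    SCORE_COLUMNS,
    GroupSpec,
    SimulationConfig,
    default_config,
    generate_clinical_cohort,
    generate_reference_cohort,
)
from .stats import (
    adjusted_regression,
    fdr_adjust,
    flag_extreme_participants,
    group_contrast,
    mann_whitney,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``simulation`` or (``reference_path``, ``clinical_path``)
    must be provided.
    """

    out_dir: str = "normdev_out"
    seed: int = 0
    simulation: SimulationConfig | None = None
    reference_path: str | None = None
    clinical_path: str | None = None
    z_threshold: float = DEFAULT_THRESHOLD
    alt_threshold: float | None = LIBERAL_THRESHOLD
    min_site_controls: int = 10
    two_tailed: bool = False
    exclude_extremes: bool = False
    regions: list[str] | None = None  # restrict fit/analysis to these regions

    def validate(self) -> None:
        sim = self.simulation is not None
        paths = self.reference_path is not None or self.clinical_path is not None
        if sim == paths:
            raise ConfigurationError(
                "exactly one of a simulation block or input paths must be configured"
            )
        if paths and (self.reference_path is None or self.clinical_path is None):
            raise ConfigurationError("both reference_path and clinical_path are required")
        if not self.z_threshold < 0:
            raise ConfigurationError("z_threshold must be negative")
        if self.alt_threshold is not None and not self.alt_threshold < 0:
            raise ConfigurationError("alt_threshold must be negative")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "simulation"})
        if sim is not None:
            groups = {
                name: GroupSpec(**spec) for name, spec in (sim.pop("group_specs", {}) or {}).items()
            }
            if isinstance(sim.get("age_range"), list):
                sim["age_range"] = tuple(sim["age_range"])
            if isinstance(sim.get("clinical_age_range"), list):
                sim["clinical_age_range"] = tuple(sim["clinical_age_range"])
            if groups:
                cfg.simulation = default_config(**sim, group_specs=groups)
            else:
                cfg.simulation = default_config(**sim)
            cfg.simulation.seed = int(cfg.seed)
        return cfg

    def echo(self) -> str:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = dataclasses.asdict(self.simulation)
            tc = d["simulation"].get("trajectory_coeffs")
            if tc is not None:
                d["simulation"]["trajectory_coeffs"] = np.asarray(tc).tolist()
        return yaml.safe_dump(d, sort_keys=True, default_flow_style=False)


def _patient_groups(clinical: pd.DataFrame) -> list[str]:
    return [g for g in pd.unique(clinical["group"]) if g != "Control"]


def _metrics_bundle(z, clinical, threshold, two_tailed, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    o = binarize_outliers(z, threshold, two_tailed=two_tailed)
    summaries = summarize_participants(z, o)
    groups = clinical.set_index("participant_id").loc[z.index, "group"]
    summaries.insert(0, "group", groups)
    summaries.to_csv(out / "participant_summaries.csv")
    props, peaks = regional_outlier_proportion(o, groups)
    props.to_csv(out / "regional_proportions.csv")
    peaks.to_csv(out / "regional_peaks.csv")
    hamming = hamming_matrix(o, groups)
    medians = []
    for g, res in hamming.items():
        res.to_frame().to_csv(out / f"hamming_{g}.csv")
        medians.append(pd.DataFrame({"participant_id": res.ids, "group": g,
                                     "median_hamming": res.medians.to_numpy()}))
    med_df = pd.concat(medians, ignore_index=True)
    med_df.to_csv(out / "hamming_medians.csv", index=False)
    return {"outliers": o, "summaries": summaries, "proportions": props,
            "hamming": hamming, "medians": med_df}


def _stats_bundle(bundle, o, clinical, out: Path, suffix: str = "", exclude: list | None = None):
    """Group contrasts, regional rank tests, and clinical associations."""
    summaries = bundle["summaries"]
    med_df = bundle["medians"]
    if exclude:
        summaries = summaries.drop(index=[i for i in exclude if i in summaries.index])
        med_df = med_df[~med_df["participant_id"].isin(exclude)]
        o = o.drop(index=[i for i in exclude if i in o.index])
    meta = clinical.set_index("participant_id")
    pat_groups = _patient_groups(clinical)
    df = summaries.join(meta[["age", "sex"]])

    rows = []
    for a, b in itertools.combinations(pat_groups, 2):
        for outcome in ("total_outlier_count", "mean_regional_z"):
            try:
                r = group_contrast(df.reset_index(), outcome, (a, b))
            except Exception:
                continue
            rows.append({"contrast": f"{a}_vs_{b}", "outcome": outcome, "method": "ols",
                         "estimate": r.beta, "se": r.se, "stat": r.t, "p": r.p, "n": r.n})
        ma = med_df.loc[med_df["group"] == a, "median_hamming"]
        mb = med_df.loc[med_df["group"] == b, "median_hamming"]
        if len(ma) and len(mb):
            mw = mann_whitney(ma, mb)
            rows.append({"contrast": f"{a}_vs_{b}", "outcome": "median_hamming",
                         "method": "mannwhitney", "estimate": float(ma.median() - mb.median()),
                         "se": np.nan, "stat": mw.U, "p": mw.p, "n": mw.n1 + mw.n2})
    group_stats = pd.DataFrame(rows)
    group_stats.to_csv(out / f"group_stats{suffix}.csv", index=False)

    reg_rows = []
    groups = meta.loc[o.index, "group"]
    for a, b in itertools.combinations(pat_groups, 2):
        oa = o.loc[groups == a]
        ob = o.loc[groups == b]
        if len(oa) == 0 or len(ob) == 0:
            continue
        ps = []
        for region in o.columns:
            mw = mann_whitney(oa[region], ob[region])
            ps.append((region, mw.U, mw.p))
        q = fdr_adjust([p for _, _, p in ps])
        for (region, U, p), qi in zip(ps, q):
            reg_rows.append({"contrast": f"{a}_vs_{b}", "region": region, "W": U, "p": p, "q": qi})
    pd.DataFrame(reg_rows).to_csv(out / f"regional_tests{suffix}.csv", index=False)

    assoc_rows = []
    scores = [c for c in SCORE_COLUMNS if c in clinical.columns]
    for g in pat_groups:
        sub = df.reset_index().merge(
            clinical[["participant_id", "group"] + scores], on="participant_id"
        )
        sub = sub[sub["group_y"] == g] if "group_y" in sub else sub[sub["group"] == g]
        for score in scores:
            try:
                r = adjusted_regression(sub["total_outlier_count"], sub[score],
                                        sub["age"], sub["sex"], predictor_name=score)
            except Exception:
                continue
            assoc_rows.append({"group": g, "measure": score, "beta": r.beta, "se": r.se,
                               "t": r.t, "p": r.p, "n": r.n})
    assoc = pd.DataFrame(assoc_rows)
    assoc.to_csv(out / f"associations{suffix}.csv", index=False)
    return group_stats, assoc


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the output bundle.

    Returns a dict with the in-memory tables (model, z-scores, metrics,
    statistics) for programmatic use.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulation is not None:
        sim = config.simulation
        sim.seed = int(config.seed)
        reference, ref_truth = generate_reference_cohort(sim)
        clinical, clin_truth = generate_clinical_cohort(sim, ref_truth)
        write_roi_table(reference, out / "reference.csv")
        write_roi_table(clinical, out / "clinical.csv")
        ref_truth.to_json(out / "reference_truth.json")
        clin_truth.to_json(out / "clinical_truth.json")
    else:
        reference = read_roi_table(config.reference_path, regions=config.regions)
        clinical = read_roi_table(config.clinical_path, regions=config.regions)

    model = fit_normative_model(reference, regions=config.regions)
    for site in pd.unique(clinical["site"]):
        controls = clinical[(clinical["site"] == site) & (clinical["group"] == "Control")]
        model = recalibrate_site(model, controls, min_controls=config.min_site_controls)
    save_model(model, out / "model.json")

    patients = clinical[clinical["group"] != "Control"]
    z = predict_zscores(model, patients)
    z.to_csv(out / "zscores.csv")

    bundle = _metrics_bundle(z, clinical, config.z_threshold, config.two_tailed, out)
    group_stats, assoc = _stats_bundle(bundle, bundle["outliers"], clinical, out)

    flagged = flag_extreme_participants(
        bundle["summaries"]["total_outlier_count"], bundle["summaries"]["group"]
    )
    pd.Series(flagged, name="participant_id", dtype=object).to_csv(
        out / "extreme_participants.csv", index=False
    )
    if config.exclude_extremes and flagged:
        _stats_bundle(bundle, bundle["outliers"], clinical, out,
                      suffix="_sensitivity", exclude=flagged)

    alt_bundle = None
    if config.alt_threshold is not None:
        alt_dir = out / f"threshold_{abs(config.alt_threshold):g}"
        alt_bundle = _metrics_bundle(z, clinical, config.alt_threshold,
                                     config.two_tailed, alt_dir)
        _stats_bundle(alt_bundle, alt_bundle["outliers"], clinical, alt_dir)

    _write_report(out, config, bundle, group_stats, assoc, flagged)
    (out / "run_log.txt").write_text(
        f"normdev {__version__}\nseed: {config.seed}\n---\n{config.echo()}"
    )
    return {"model": model, "zscores": z, "metrics": bundle, "alt_metrics": alt_bundle,
            "group_stats": group_stats, "associations": assoc, "flagged": flagged,
            "clinical": clinical, "reference": reference, "out_dir": out}


def _write_report(out: Path, config: RunConfig, bundle, group_stats, assoc, flagged) -> None:
    lines = ["# normdev run report", ""]
    lines.append(f"Outlier threshold: z < {config.z_threshold}")
    lines.append("")
    lines.append("## Per-group total outlier count")
    lines.append("")
    summ = bundle["summaries"].groupby("group")["total_outlier_count"].agg(["count", "mean", "std"])
    lines.append(summ.round(2).to_string())
    lines.append("")
    lines.append("## Per-group median Hamming distance")
    lines.append("")
    med = bundle["medians"].groupby("group")["median_hamming"].agg(["count", "median", "mean"])
    lines.append(med.round(2).to_string())
    lines.append("")
    if len(group_stats):
        lines.append("## Group contrasts (age/sex adjusted; rank tests for Hamming)")
        lines.append("")
        lines.append(group_stats.round(4).to_string(index=False))
        lines.append("")
    if len(assoc):
        lines.append("## Clinical associations (total outlier count ~ score + age + sex)")
        lines.append("")
        lines.append(assoc.round(4).to_string(index=False))
        lines.append("")
    lines.append(f"Extreme participants flagged (count > Q3 + 3 IQR within group): {flagged or 'none'}")
    lines.append("")
    (out / "report.md").write_text("\n".join(lines))
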
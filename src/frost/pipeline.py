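"""End-to-end orchestration of the freezing-resistance analysis.

Stages run in method order: thermogram exotherm detection → damage / LT50
→ mechanism classification → community functional components → trend and
contrast statistics.  Each stage writes its tidy table under the output
directory and contributes a section to a JSON report; identical inputs,
configuration and seed produce an identical report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import community as comm
from . import damage as dmg
from . import io as fio
from . import mechanism as mech
from . import stats as fstats
from . import thermogram as tgm
from .errors import FrostError, InputError

logger = logging.getLogger(__name__)

#: functional traits screened for correlations with freezing resistance
AUX_TRAIT_COLUMNS = ("hmax_cm", "sla_mm2_mg", "ldmc_mg_g", "seed_mass_mg")


@dataclass(frozen=True)
class RunConfig:
    traces_path: str
    damage_path: str
    community_path: str
    traits_path: str | None = None        # growth forms + functional traits
    out_dir: str = "frost_out"
    alpha: float = 0.05
    exclude_species: tuple[str, ...] = ("Festuca_curvifolia",)
    exotherm: tgm.ExothermConfig = field(default_factory=tgm.ExothermConfig)
    lt50_mode: str = "mean"               # "mean" | "replicate"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise InputError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.lt50_mode not in ("mean", "replicate"):
            raise InputError(f"lt50_mode must be 'mean' or 'replicate'")


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except FrostError as exc:
                raise FrostError(f"stage {name!r}: {exc}") from exc
        return inner
    return wrap


@_stage("thermogram")
def _run_thermogram(config: RunConfig):
    traces = fio.read_traces(config.traces_path)
    results = [tgm.detect_exotherm(tr, config.exotherm) for tr in traces]
    leaf_table = pd.DataFrame([{
        "species_id": r.species_id, "leaf_id": r.leaf_id,
        "detected": r.detected, "nt_C": r.nt_C, "fp_C": r.fp_C,
        "onset_index": r.onset_index} for r in results])
    summary = tgm.summarize_species_thermal(results)
    nt_replicates = {
        s: [r.nt_C for r in results if r.species_id == s and r.detected]
        for s in leaf_table["species_id"].unique()}
    return leaf_table, summary, nt_replicates


@_stage("damage")
def _run_damage(config: RunConfig):
    records = fio.read_damage_records(config.damage_path)
    assays = dmg.assays_from_frame(records)
    lt50_table, phi_table = dmg.damage_results_table(assays)
    lt50_replicates = {a.species_id: dmg.lt50_per_replicate(a)
                       for a in assays} if config.lt50_mode == "replicate" \
        else {}
    return lt50_table, phi_table, lt50_replicates


@_stage("mechanism")
def _run_mechanism(config: RunConfig, nt_replicates, lt50_table,
                   lt50_replicates, community):
    rows = []
    profiles: dict[str, str] = {}
    for row in lt50_table.itertuples():
        nts = nt_replicates.get(row.species_id, [])
        if len(nts) < 3:
            logger.warning("species %s: only %d detected NT replicates; "
                           "mechanism not classified", row.species_id,
                           len(nts))
            continue
        if row.censored == "below_range":
            lt_sample: list[float] = [float("nan")]
        elif row.censored == "above_range":
            lt_sample = [-4.9]  # damage already >50 % at the warmest test;
                                # compare against just above that bound
        elif config.lt50_mode == "replicate" and \
                len(lt50_replicates.get(row.species_id, [])) >= 3:
            lt_sample = lt50_replicates[row.species_id]
        else:
            lt_sample = [row.lt50_C]
        cls = mech.classify_mechanism(nts, lt_sample, config.alpha)
        profiles[row.species_id] = cls.value
        rows.append({"species_id": row.species_id, "mechanism": cls.value,
                     "p_value": cls.p_value, "test_used": cls.test_used})
    table = pd.DataFrame(rows)
    proportions = mech.mechanism_proportions(community, profiles)
    return table, proportions, profiles


@_stage("community")
def _run_community(config: RunConfig, community, summary, lt50_table):
    fp_trait = comm.TraitVector("FP", summary.set_index(
        "species_id")["fp_mean_C"])
    lt_trait = comm.TraitVector("LT50", lt50_table.set_index(
        "species_id")["lt50_C"])
    cm = community
    for species in config.exclude_species:
        cm = comm.exclude_engineer(cm, species)
    return comm.functional_components_table(cm, [fp_trait, lt_trait])


@_stage("stats")
def _run_stats(config: RunConfig, components, proportions, summary,
               lt50_table, traits):
    report: dict = {"regressions": {}, "proportion_trends": {},
                    "growth_form_contrasts": {}, "correlations": {}}
    for trait_id, grp in components.groupby("trait"):
        for metric in ("cwm", "fd_rao"):
            fit = fstats.linear_trend(grp[metric], grp["altitude_m"])
            report["regressions"][f"{metric}_{trait_id}"] = vars(fit)
    for cls in ("ft", "fa", "fs"):
        fit = fstats.linear_trend(proportions[cls], proportions["altitude_m"])
        report["proportion_trends"][cls] = vars(fit)

    if traits is not None and "growth_form" in traits.columns:
        merged = traits.merge(summary, on="species_id", how="inner") \
                       .merge(lt50_table, on="species_id", how="inner")
        for trait_id, col in (("FP", "fp_mean_C"), ("LT50", "lt50_C")):
            try:
                contrast = fstats.kruskal_nemenyi(
                    merged[col], merged["growth_form"], config.alpha)
            except InputError as exc:
                logger.warning("growth-form contrast for %s skipped: %s",
                               trait_id, exc)
                continue
            report["growth_form_contrasts"][trait_id] = {
                "kw_statistic": contrast.kw_statistic,
                "kw_p": contrast.kw_p,
                "pairwise": {f"{a}|{b}": p
                             for (a, b), p in sorted(contrast.pairwise.items())},
                "letters": contrast.letters,
            }
        for aux in AUX_TRAIT_COLUMNS:
            if aux not in merged.columns:
                continue
            for trait_id, col in (("FP", "fp_mean_C"), ("LT50", "lt50_C")):
                try:
                    res = fstats.trait_correlation(merged[aux], merged[col])
                except InputError:
                    continue
                report["correlations"][f"{aux}~{trait_id}"] = vars(res)
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; write tables and report.json; return the report."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(),
                                      logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    leaf_table, summary, nt_replicates = _run_thermogram(config)
    lt50_table, phi_table, lt50_replicates = _run_damage(config)
    community = fio.read_community(config.community_path)
    traits = (fio.read_trait_table(config.traits_path)
              if config.traits_path else None)
    mech_table, proportions, profiles = _run_mechanism(
        config, nt_replicates, lt50_table, lt50_replicates, community)
    components = _run_community(config, community, summary, lt50_table)
    stats_report = _run_stats(config, components, proportions, summary,
                              lt50_table, traits)

    fio.write_table(leaf_table, out / "leaf_exotherms.csv")
    fio.write_table(summary, out / "species_thermal.csv")
    fio.write_table(lt50_table, out / "species_lt50.csv")
    fio.write_table(phi_table, out / "phi_curves.csv")
    fio.write_table(mech_table, out / "mechanism.csv")
    fio.write_table(proportions, out / "mechanism_proportions.csv")
    fio.write_table(components, out / "functional_components.csv")

    mech_counts = mech_table["mechanism"].value_counts().to_dict() \
        if len(mech_table) else {}
    report = {
        "config": {
            "alpha": config.alpha,
            "exclude_species": list(config.exclude_species),
            "lt50_mode": config.lt50_mode,
            "rise_threshold_K": config.exotherm.rise_threshold_K,
        },
        "thermogram": {
            "n_leaves": int(len(leaf_table)),
            "n_detected": int(leaf_table["detected"].sum()),
            "n_species_summarized": int(len(summary)),
        },
        "damage": {
            "n_species": int(len(lt50_table)),
            "n_censored": int((lt50_table["censored"] != "none").sum()),
            "mean_lt50_C": float(np.nanmean(lt50_table["lt50_C"]))
            if len(lt50_table) else float("nan"),
        },
        "mechanism": {
            "counts": {k: int(v) for k, v in sorted(mech_counts.items())},
            "n_classified": int(len(mech_table)),
        },
        "community": {
            "n_plots": int(components["plot_id"].nunique()),
            "traits": sorted(components["trait"].unique().tolist()),
        },
        "stats": stats_report,
    }
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
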
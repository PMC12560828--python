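"""Full-screen pipeline: bind the stages over a set of input CSVs.

Stages run in the order vial-effect diagnostics -> BMC modeling ->
behavioral LEL -> body burden -> logKow potency -> transcriptomic
summaries -> docking ranks, each only when its input table is present;
a missing input for a requested stage raises a named error while the
other stages proceed.  Every run writes per-stage CSVs and a manifest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bmc as bmcmod
from . import burden as burdenmod
from . import docking as dockmod
from . import io as vio
from . import kow as kowmod
from . import lpr as lprmod
from . import transcripts as txmod
from . import vialfx as vfxmod
from .design import AssaySchedule

log = logging.getLogger("vialtox")

__all__ = ["PipelineConfig", "run_pipeline", "bmc_table"]


@dataclass
class PipelineConfig:
    """Paths and statistical knobs for a pipeline run.

    Unset paths simply skip the corresponding stage.  Defaults
    reproduce the screen's standard settings: BMR 0.5 extra risk,
    alpha 0.05, likelihood-ratio cutoff 1.3528 (one-sided 95% per
    bound), BMCu:BMCl validity ratio 40, per-period Holm families,
    competition ranking for docking ties.
    """

    outdir: str = "vialtox_out"
    morphology: str | None = None
    traces: str | None = None
    body_burden: str | None = None
    logkow: str | None = None
    de_table: str | None = None
    counts: str | None = None
    docking: str | None = None
    bmr: float = 0.5
    alpha: float = 0.05
    lr_cutoff: float | None = None
    max_bound_ratio: float = 40.0
    top_k: int = 10
    endpoint: str = "ANY"
    quadrature_nodes: int = 25
    seed: int = 0
    schedule: AssaySchedule = field(default_factory=AssaySchedule)

    @classmethod
    def from_yaml(cls, path):
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def echo(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__
             if k != "schedule"}
        d["schedule_epochs"] = [list(e) for e in self.schedule.epochs]
        return d


def bmc_table(morph: pd.DataFrame, endpoints=None, bmr: float = 0.5,
              alpha: float = 0.05, cutoff: float | None = None,
              max_ratio: float = 40.0) -> pd.DataFrame:
    """Per chemical x endpoint BMC table with bounds and verdicts."""
    rows = []
    endpoints = endpoints or sorted(morph["endpoint"].unique())
    for chem, sub in morph.groupby("chemical", sort=True):
        for ep in endpoints:
            if not (sub["endpoint"] == ep).any():
                continue
            model = bmcmod.BenchmarkDoseModel.from_observations(sub, ep)
            res = model.fit()
            rep = res.report(bmr, alpha, cutoff)
            rep = bmcmod.report_bmc(rep, model.dose, max_ratio) \
                if rep.reason != "no response" else rep
            rows.append((chem, ep, rep.bmc, rep.bmcl, rep.bmcu, rep.valid,
                         rep.reason))
    return pd.DataFrame(rows, columns=["chemical", "endpoint", "bmc", "bmcl",
                                       "bmcu", "valid", "reason"])


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages with available inputs; return output paths."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs = []
    tables: dict[str, pd.DataFrame] = {}

    morph = vio.read_morphology(config.morphology) if config.morphology else None
    if morph is not None:
        vfx = vfxmod.vial_effect_table(morph, config.endpoint,
                                       config.quadrature_nodes)
        tables["vial_effect"] = vfx
        outputs.append(vio.write_table(vfx, out / "vial_effect.csv"))
        bmct = bmc_table(morph, bmr=config.bmr, alpha=config.alpha,
                         cutoff=config.lr_cutoff,
                         max_ratio=config.max_bound_ratio)
        tables["bmc"] = bmct
        outputs.append(vio.write_table(bmct, out / "bmc.csv"))
    else:
        log.info("no morphology table: skipping vial-effect and BMC stages")

    if config.traces:
        traces = vio.read_traces(config.traces)
        retained, removed = lprmod.apply_exclusions(traces)
        aucs = lprmod.auc_table(retained, config.schedule)
        lels = lprmod.lel_table(lprmod.call_lel(aucs, config.alpha))
        tables["lel"] = lels
        outputs.append(vio.write_table(lels, out / "lel.csv"))
        if removed:
            log.info("treatments removed by the 30%% exclusion rule: %s",
                     removed)
    else:
        log.info("no trace table: skipping LPR stage")

    if config.body_burden:
        bb = vio.read_body_burden(config.body_burden)
        tables["body_burden"] = burdenmod.body_burden_table(bb)
        outputs.append(vio.write_table(tables["body_burden"],
                                       out / "body_burden.csv"))
        tables["timepoints"] = burdenmod.compare_timepoints(bb)
        outputs.append(vio.write_table(tables["timepoints"],
                                       out / "burden_timepoints.csv"))
        if bb["chemical"].nunique() >= 2:
            _, _, letters = burdenmod.compare_chemicals_24h(bb)
            tables["burden_letters"] = letters
            outputs.append(vio.write_table(letters,
                                           out / "burden_letters.csv"))
    else:
        log.info("no body-burden table: skipping burden stage")

    if config.logkow and "bmc" in tables:
        kow = vio.read_logkow(config.logkow)
        anyb = tables["bmc"].query("endpoint == @config.endpoint")
        merged = kow.merge(
            anyb.loc[anyb.valid, ["chemical", "bmc"]], on="chemical",
            how="left")
        rows = []
        try:
            model = kowmod.PotencyModel.from_dataframe(merged)
        except ValueError as err:
            log.warning("potency stage skipped: %s", err)
            model = None
        if model is not None:
            for label, excl in (("A", False), ("B", True)):
                try:
                    r = model.fit(exclude_outliers=excl)
                except ValueError as err:
                    log.info("potency model %s not fit: %s", label, err)
                    continue
                rows.append((label, r.slope, r.intercept, r.r2, r.p_value,
                             r.avg_rel_error_pct, len(r.chemicals),
                             ";".join(r.outliers_removed)))
            tables["potency"] = pd.DataFrame(rows, columns=[
                "model", "slope", "intercept", "r2", "p_value",
                "avg_rel_error_pct", "n", "outliers_removed"])
            outputs.append(vio.write_table(tables["potency"],
                                           out / "potency_model.csv"))
    elif config.logkow:
        log.info("logkow table given but no BMC table: skipping potency model")

    if config.de_table:
        de = vio.read_de_table(config.de_table)
        degs = txmod.tally_frequent_degs(de)
        tables["frequent_degs"] = degs
        outputs.append(vio.write_table(degs, out / "frequent_degs.csv"))
        if "bmc" in tables and not degs.empty:
            anyb = tables["bmc"].query("endpoint == @config.endpoint")
            try:
                corr = txmod.correlate_potency(
                    de, anyb.loc[anyb.valid, ["chemical", "bmc"]],
                    degs["gene"].tolist())
            except ValueError as err:
                log.warning("potency correlation skipped: %s", err)
            else:
                tables["potency_correlation"] = corr
                outputs.append(vio.write_table(
                    corr, out / "potency_correlation.csv"))
    if config.counts:
        counts = vio.read_counts(config.counts)
        normed, factors = txmod.upper_quartile_normalize(counts)
        p = out / "normalized_counts.csv"
        normed.to_csv(p)
        outputs.append(p)
        outputs.append(vio.write_table(
            factors.rename_axis("sample").reset_index(), out / "uq_factors.csv"))

    if config.docking:
        dock = vio.read_docking(config.docking)
        mins = dockmod.reduce_min_energy(dock)
        ranks = dockmod.rank_proteins(mins)
        proteins, member = dockmod.top_k_membership(ranks, config.top_k)
        p = out / "protein_ranks.csv"
        ranks.to_csv(p)
        outputs.append(p)
        p = out / "top_k_membership.csv"
        member.to_csv(p)
        outputs.append(p)
    else:
        log.info("no docking table: skipping docking stage")

    inputs = {k: getattr(config, k) for k in
              ("morphology", "traces", "body_burden", "logkow", "de_table",
               "counts", "docking")}
    manifest = vio.write_manifest(out, config.echo(), inputs, outputs)
    return {"outputs": [str(p) for p in outputs], "manifest": str(manifest),
            "tables": tables}
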
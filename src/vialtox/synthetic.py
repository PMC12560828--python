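"""Synthetic screening data with known ground truth.

Generates the four input tables the analysis stages consume — per-embryo
morphology outcomes, per-well photomotor movement traces, measured
tissue-extract concentrations, and docking-energy tables — under the
same statistical structure the pipeline assumes, so every stage can be
tested against the generating parameters without any external data.

Morphology outcomes follow the three-parameter log-logistic
dose-response curve with a Normal vial random intercept added on the
logit of the conditional response probability; movement traces are
log-normal per 6-s bin with period-specific means and a dark-phase
shift in affected treatments; measured concentrations carry
multiplicative log-normal noise around the value implied by the true
uptake ratio; docking energies are Normal around a per-chemical mean
with planted high-affinity proteins shifted lower.

Each generator takes an explicit integer seed and owns its own
pseudo-random stream; no global state is touched, and a fixed seed
reproduces byte-identical tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

from .burden import molecular_weight
from .design import AssaySchedule, ScreenDesign, TruthParams

__all__ = [
    "simulate_morphology",
    "simulate_lpr",
    "simulate_body_burden",
    "simulate_docking",
    "write_synthetic_bundle",
]


def _conditional_probability(dose, truth: TruthParams, u):
    """Vial-conditional response probability.

    The population curve is p(d) = g + (1-g)/(1+exp(-a-b ln d)) with
    a = -b ln(BMC50); the vial intercept u is added on the logit of the
    conditional probability.  The dose-effect term is defined as 0 at
    d=0, so a control with g=0 responds with probability 0 regardless
    of u.
    """
    g = truth.g
    if dose > 0:
        eta = truth.slope_b * (np.log(dose) - np.log(truth.bmc50_true))
        p = g + (1.0 - g) * special.expit(eta)
    else:
        p = g
    if p <= 0.0:
        return np.zeros_like(u)
    if p >= 1.0:
        return np.ones_like(u)
    return special.expit(special.logit(p) + u)


def simulate_morphology(design: ScreenDesign, truth: TruthParams, seed: int,
                        chemical: str = "chem") -> pd.DataFrame:
    """Per-embryo binary outcomes for one chemical.

    Returns a long-format table with one row per embryo x endpoint:
    columns chemical, conc_um, vial, embryo, endpoint, response.  All
    endpoints in the design share the same generating curve.
    """
    rng = np.random.default_rng(seed)
    rows = []
    vial_id = 0
    for dose in design.concentrations:
        for v in range(design.vials_per_treatment):
            vial_id += 1
            u = rng.normal(0.0, truth.sigma_vial) if truth.sigma_vial > 0 else 0.0
            p = float(_conditional_probability(dose, truth, np.asarray(u)))
            for endpoint in design.endpoints:
                y = rng.random(design.embryos_per_vial) < p
                for e, yi in enumerate(y):
                    rows.append((chemical, dose, f"V{vial_id:03d}", e + 1,
                                 endpoint, int(yi)))
    return pd.DataFrame(rows, columns=["chemical", "conc_um", "vial",
                                       "embryo", "endpoint", "response"])


def simulate_lpr(design: ScreenDesign, truth: TruthParams,
                 schedule: AssaySchedule, seed: int,
                 chemical: str = "chem",
                 effect_threshold_um: float = 25.0,
                 baseline_log_light: float = 1.0,
                 baseline_log_dark: float = 2.5,
                 log_sd: float = 0.6,
                 exclusion_prob: float = 0.0) -> pd.DataFrame:
    """Per-well 6-s-bin movement traces for one chemical.

    Movement in each bin is log-normal with a period-specific log-mean;
    wells at concentrations >= ``effect_threshold_um`` have their
    dark-period log-mean shifted by ``truth.lpr_effect`` (negative =
    hypoactivity).  Wells are flagged excluded (dead/malformed) with
    probability ``exclusion_prob``.
    """
    rng = np.random.default_rng(seed)
    starts = schedule.bin_starts()
    period = np.empty(starts.size, dtype=object)
    for pname, s, e in schedule.epochs:
        period[(starts >= s) & (starts < e)] = pname
    mu = np.where(period == "dark", baseline_log_dark, baseline_log_light)
    frames = []
    well_no = 0
    for dose in design.concentrations:
        shift = truth.lpr_effect if (dose > 0 and dose >= effect_threshold_um) else 0.0
        mu_d = mu + np.where(period == "dark", shift, 0.0)
        for _ in range(design.embryos_per_treatment):
            well_no += 1
            excluded = bool(rng.random() < exclusion_prob)
            movement = np.exp(rng.normal(mu_d, log_sd))
            frames.append(pd.DataFrame({
                "plate": 1 + (well_no - 1) // 96,
                "well": f"W{well_no:04d}",
                "chemical": chemical,
                "conc_um": dose,
                "excluded": excluded,
                "t_start_s": starts,
                "movement": movement,
            }))
    return pd.concat(frames, ignore_index=True)


def simulate_body_burden(chemicals, truths, seed: int,
                         timepoints=(24, 48), n_replicates: int = 3,
                         reduction_48h=0.7,
                         nominal_um: float = 20.0,
                         exposure_volume_ml: float = 2.0,
                         n_fish: int = 32,
                         sample_volume_ml: float = 0.5) -> pd.DataFrame:
    """Measured extract concentrations (ng/mL) for pooled samples.

    The true total chemical per pooled sample is
    ``uptake_true * nominal nmol * n_fish`` at 24 hpf, reduced by
    ``reduction_48h`` (scalar or per-chemical mapping, fraction lost)
    at 48 hpf; the measured ng/mL value carries multiplicative
    LogNormal(0, cv) noise.  With cv=0 the body-burden equations invert
    the generator exactly.
    """
    rng = np.random.default_rng(seed)
    nominal_nmol = nominal_um * exposure_volume_ml  # uM x mL = nmol
    rows = []
    for chem in chemicals:
        truth = truths[chem] if isinstance(truths, dict) else truths
        mw = molecular_weight(chem)
        red = (reduction_48h.get(chem, 0.7)
               if isinstance(reduction_48h, dict) else reduction_48h)
        for tp in timepoints:
            frac = 1.0 if tp == min(timepoints) else 1.0 - red
            per_embryo_nmol = truth.uptake_true * nominal_nmol * frac
            total_nmol = per_embryo_nmol * n_fish
            true_ng_ml = total_nmol * mw / sample_volume_ml
            for rep in range(1, n_replicates + 1):
                noise = (np.exp(rng.normal(0.0, truth.measurement_cv))
                         if truth.measurement_cv > 0 else 1.0)
                rows.append((chem, tp, rep, true_ng_ml * noise,
                             sample_volume_ml, n_fish, nominal_um,
                             exposure_volume_ml))
    return pd.DataFrame(rows, columns=[
        "chemical", "timepoint_hpf", "replicate", "ng_per_mL",
        "sample_volume_mL", "n_fish", "nominal_um", "exposure_volume_mL"])


def simulate_docking(chemicals, proteins, planted=(), seed: int = 0,
                     n_pockets: int = 3,
                     methods=("sequence", "structure"),
                     sigma: float = 0.8,
                     planted_shift: float = -4.0,
                     mean_range=(-7.5, -5.5)) -> pd.DataFrame:
    """Long-format docking-energy table (kcal/mol).

    Each (chemical, protein, pocket, method) energy is Normal around a
    per-chemical mean drawn uniformly from ``mean_range`` (emulating
    the between-chemical variability in mean binding energy that makes
    raw energies incomparable); proteins in ``planted`` are shifted by
    ``planted_shift`` (more negative = stronger binder).
    """
    if n_pockets < 1:
        raise ValueError("need at least one pocket per protein")
    rng = np.random.default_rng(seed)
    planted = set(planted)
    rows = []
    for chem in chemicals:
        mu_chem = rng.uniform(*mean_range)
        for prot in proteins:
            shift = planted_shift if prot in planted else 0.0
            for pocket in range(1, n_pockets + 1):
                for method in methods:
                    e = rng.normal(mu_chem + shift, sigma)
                    rows.append((chem, prot, f"P{pocket}", method, e))
    return pd.DataFrame(rows, columns=["chemical", "protein", "pocket",
                                       "method", "energy_kcal_mol"])


def write_synthetic_bundle(outdir, chemicals, truths, seed: int,
                           design: ScreenDesign | None = None,
                           schedule: AssaySchedule | None = None,
                           proteins=None, planted=()) -> dict:
    """Write a complete synthetic screen to ``outdir`` as CSVs.

    Produces morphology.csv, traces.csv, body_burden.csv, docking.csv
    and a manifest.json recording the design, per-chemical truth
    parameters, and seed.  Per-table seeds are derived from ``seed``
    via numpy's seed-spawning so tables are independent but jointly
    reproducible.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = design or ScreenDesign()
    schedule = schedule or AssaySchedule()
    proteins = list(proteins) if proteins is not None else [
        f"PROT{i:02d}" for i in range(1, 21)]
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]

    morph = pd.concat(
        [simulate_morphology(design, truths[c], seeds[0] + i, chemical=c)
         for i, c in enumerate(chemicals)], ignore_index=True)
    traces = pd.concat(
        [simulate_lpr(design, truths[c], schedule, seeds[1] + i, chemical=c)
         for i, c in enumerate(chemicals)], ignore_index=True)
    burden = simulate_body_burden(chemicals, truths, seeds[2])
    docking = simulate_docking(chemicals, proteins, planted, seeds[3])

    morph.to_csv(outdir / "morphology.csv", index=False)
    traces.to_csv(outdir / "traces.csv", index=False)
    burden.to_csv(outdir / "body_burden.csv", index=False)
    docking.to_csv(outdir / "docking.csv", index=False)

    manifest = {
        "seed": int(seed),
        "table_seeds": seeds,
        "design": {
            "concentrations": list(design.concentrations),
            "vials_per_treatment": design.vials_per_treatment,
            "embryos_per_vial": design.embryos_per_vial,
            "endpoints": list(design.endpoints),
        },
        "truth": {c: vars(truths[c]) for c in chemicals},
        "proteins": proteins,
        "planted": list(planted),
        "tables": ["morphology.csv", "traces.csv", "body_burden.csv",
                   "docking.csv"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
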
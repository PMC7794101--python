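"""Synthetic cohort and plate-data generator.

Emulates the study design end-to-end so the pipeline can be exercised and
calibrated without access to registry data: matched case-control pairs
(matched on sex and exact date of birth, one case and one control per
pair, always co-located on a plate), 96-well plates carrying triplicate
paper blanks, five medium-level QC (QC2) replicates and one low/high QC
well each, multiplicative per-plate batch factors, and metabolite
concentrations generated on the log scale.

The generative model for sample concentrations is

    log x_im = log TV_m + s_m * (delta_m * case_i
               + f * max(age_i - onset, 0) * bottle_i * 1[m affected]
               + gamma * g_i * 1[m is the genetic precursor])
               + a * F_i * 1[m affected] + eps_im

where ``TV_m`` is the metabolite target value, ``s_m`` the total log-scale
SD (so configured effects are in SD units), ``f`` the feeding effect per
day of age at sampling, ``bottle_i`` a latent bottle-feeding indicator,
``g_i`` an effect-allele dosage, ``F_i`` a standard-normal latent factor
shared by the affected metabolites (making them positively correlated) and
``eps`` lognormal residual noise.  The onset lag reflects that milk intake
(breast or formula) is negligible right after birth and ramps up over the
first week, so feeding-pattern contrasts are barely expressed at day-2
sampling but strongly at day-6 sampling.  A birth-era policy change moves the
median age at sampling from 6 days (pre) to 2 days (post), which scales
the feeding-mediated case-control contrast between eras.  The latent
bottle-feeding indicator also drives carriage of the ICD-10 P92.5 code
(difficulty feeding at breast) and its day of assignment.

Designed-to-fail metabolites let QC tests assert the filter funnel against
ground truth: ``fail_lod`` species get blank signal at sample level,
``fail_cv`` species get inflated QC2 replicate noise.  With all effect
parameters zero, cases and controls are exchangeable (type-I-error
testing).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import PanelDefinition

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SynthError",
    "AFFECTED_DEFAULT",
    "simulate_cohort",
    "simulate_concentrations",
    "simulate_plates",
    "simulate_dataset",
    "write_dataset",
]

#: the seven metabolites the association analysis is designed around
AFFECTED_DEFAULT = (
    "PC(38:4)", "PC(36:4)", "PC-O(36:4)", "PC(44:1)",
    "Histidine", "PC(38:3)", "AC(2:0)",
)


class SynthError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    Cohort-structure defaults reproduce the study: 267 matched pairs on
    eight 96-well plates, 87.3 % boys, gestational age ~40 weeks, a 2009
    screening-policy change moving median age at sampling from 6 to 2 days,
    and a pre-policy fraction of 98/267 pairs.  Effect-size defaults are
    synthetic (documented in the methods note): they produce the
    qualitative study pattern - a feeding-mediated case-control contrast
    that grows with age at sampling, P92.5 co-occurrence with case status,
    and a genotype acting on the precursor metabolite PC(38:3) and the
    product/precursor ratio but not on disease status.
    """

    n_pairs: int = 267
    n_plates: int = 8
    wells_per_plate: int = 96
    blanks_per_plate: int = 3
    qc2_reps_per_plate: int = 5
    year_min: int = 1997
    year_max: int = 2014
    policy_change_year: int = 2009
    pre_policy_fraction: float = 98.0 / 267.0
    age_sampling_pre: int = 6
    age_sampling_post: int = 2
    boy_fraction: float = 0.873

    # latent feeding structure
    bottle_prob_case: float = 0.60
    bottle_prob_control: float = 0.20
    feeding_effect_per_day: float = -0.30   # SD units per day past onset
    feeding_onset_day: int = 1              # milk intake negligible before this
    affected_metabolites: tuple[str, ...] = AFFECTED_DEFAULT
    affected_corr_loading: float = 0.5

    # diagnosis-code model: P(P92.5 | case status, feeding)
    code_prob_case_bottle: float = 0.10
    code_prob_case_breast: float = 0.02
    code_prob_control_bottle: float = 0.06
    code_prob_control_breast: float = 0.006
    code_day0_prob_bottle: float = 0.70
    code_day0_prob_breast: float = 0.20

    # genetics: effect allele acts on the precursor metabolite only
    genotype_maf: float = 0.33              # rs174547 C allele
    genotype_beta_precursor: float = 0.35   # SD units per allele on PC(38:3)
    precursor_metabolite: str = "PC(38:3)"
    null_snp_maf: float = 0.07              # rs12721025, no metabolite effect

    # direct disease effects (SD units) for injection studies
    disease_effects: tuple[tuple[str, float], ...] = ()

    # measurement model
    plate_factor_sd: float = 0.15           # log-scale SD of C_{m,p}
    blank_level_frac: float = 0.02          # blank signal as fraction of TV_m
    fail_lod_blank_frac: float = 1.5        # blank level for designed LOD failures
    qc_noise_cv: float = 0.05               # technical CV of QC and sample wells
    fail_cv_noise: float = 0.40             # QC2 CV for designed CV failures
    residual_log_sd: float = 0.25
    fail_lod_metabolites: tuple[str, ...] = ()
    fail_cv_metabolites: tuple[str, ...] = ()

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bottle_prob_case", "bottle_prob_control",
                     "pre_policy_fraction", "genotype_maf", "null_snp_maf",
                     "boy_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SynthError(f"{name} must be in [0,1], got {v}")
        if min(self.n_pairs, self.n_plates, self.wells_per_plate) <= 0:
            raise SynthError("n_pairs, n_plates, wells_per_plate must be positive")
        cap = self.sample_wells_per_plate()
        if cap < 2:
            raise SynthError("plate layout leaves no room for samples")
        if 2 * self.n_pairs > self.n_plates * cap:
            raise SynthError(
                f"{self.n_pairs} pairs do not fit on {self.n_plates} plates "
                f"({cap} sample wells each)")

    def sample_wells_per_plate(self) -> int:
        # blanks + QC2 replicates + one QC1 + one QC3
        return self.wells_per_plate - self.blanks_per_plate \
            - self.qc2_reps_per_plate - 2


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    plate_factors: pd.DataFrame | None = None   # metabolite x plate C_{m,p}
    bottle_fed: pd.Series | None = None         # per sample id
    genotype: pd.DataFrame | None = None        # dosage columns per sample
    disease_effects: dict[str, float] = field(default_factory=dict)
    affected_metabolites: tuple[str, ...] = ()
    feeding_effect_per_day: float = 0.0
    designed_failures: dict[str, str] = field(default_factory=dict)
    true_concentrations: pd.DataFrame | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "disease_effects": self.disease_effects,
            "affected_metabolites": list(self.affected_metabolites),
            "feeding_effect_per_day": self.feeding_effect_per_day,
            "designed_failures": self.designed_failures,
            "bottle_fed": None if self.bottle_fed is None
            else {k: int(v) for k, v in self.bottle_fed.items()},
            "genotype": None if self.genotype is None
            else self.genotype.astype(int).to_dict("index"),
            "plate_factors": None if self.plate_factors is None
            else {m: {str(p): float(v) for p, v in row.items()}
                  for m, row in self.plate_factors.iterrows()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw the matched cohort: sample sheet plus latent ground truth.

    Within each pair, sex and date of birth are identical by construction;
    ages at sampling follow the era medians with small integer jitter.
    """
    rng = _rng(config, 1)
    n = config.n_pairs

    pre = rng.random(n) < config.pre_policy_fraction
    year = np.where(
        pre,
        rng.integers(config.year_min, config.policy_change_year, n),
        rng.integers(config.policy_change_year, config.year_max + 1, n),
    )
    doy = rng.integers(1, 366, n)
    boy = rng.random(n) < config.boy_fraction

    age_pre = config.age_sampling_pre + rng.choice(
        [-1, 0, 1, 2], size=n, p=[0.25, 0.35, 0.25, 0.15])
    age_post = config.age_sampling_post + rng.choice(
        [0, 1], size=n, p=[0.70, 0.30])
    # drawn per individual, pairs share only the era median
    age_days = np.where(pre, age_pre, age_post)
    age_days2 = np.where(
        pre,
        config.age_sampling_pre + rng.choice([-1, 0, 1, 2], size=n,
                                             p=[0.25, 0.35, 0.25, 0.15]),
        config.age_sampling_post + rng.choice([0, 1], size=n, p=[0.7, 0.3]))

    rows = []
    for i in range(n):
        for j, is_case in enumerate((1, 0)):
            rows.append({
                "sample_id": f"S{2 * i + j:04d}",
                "pair_id": f"P{i:04d}",
                "case": is_case,
                "sex": "M" if boy[i] else "F",
                "year_of_birth": int(year[i]),
                "day_of_year": int(doy[i]),
                "age_at_sampling_days": int(age_days[i] if is_case
                                            else age_days2[i]),
            })
    samples = pd.DataFrame(rows)
    m = len(samples)
    case = samples["case"].to_numpy()

    samples["gestational_age_wk"] = np.round(rng.normal(40.0, 1.5, m), 1)
    samples["parity"] = 1 + rng.poisson(0.75, m)
    samples["maternal_age"] = np.round(rng.normal(30.0, 5.0, m), 1)
    samples["cesarean"] = (rng.random(m) <
                           np.where(case == 1, 0.213, 0.169)).astype(int)

    bottle = rng.random(m) < np.where(case == 1, config.bottle_prob_case,
                                      config.bottle_prob_control)
    p_code = np.where(
        case == 1,
        np.where(bottle, config.code_prob_case_bottle,
                 config.code_prob_case_breast),
        np.where(bottle, config.code_prob_control_bottle,
                 config.code_prob_control_breast))
    has_code = rng.random(m) < p_code
    p_day0 = np.where(bottle, config.code_day0_prob_bottle,
                      config.code_day0_prob_breast)
    day0 = rng.random(m) < p_day0
    code_day = np.where(day0, 0, rng.integers(1, 6, m))
    samples["p92_5"] = has_code.astype(int)
    samples["p92_5_day"] = np.where(has_code, code_day, np.nan)

    g_fads = rng.binomial(2, config.genotype_maf, m)
    g_apoa = rng.binomial(2, config.null_snp_maf, m)
    samples["rs174547"] = g_fads
    samples["rs12721025"] = g_apoa

    truth = GroundTruth(
        bottle_fed=pd.Series(bottle.astype(int),
                             index=samples["sample_id"].to_numpy()),
        genotype=pd.DataFrame({"rs174547": g_fads, "rs12721025": g_apoa},
                              index=samples["sample_id"].to_numpy()),
        disease_effects=dict(config.disease_effects),
        affected_metabolites=tuple(config.affected_metabolites),
        feeding_effect_per_day=config.feeding_effect_per_day,
    )
    return samples, truth


def simulate_concentrations(samples: pd.DataFrame, panel: PanelDefinition,
                            config: SimConfig, truth: GroundTruth
                            ) -> pd.DataFrame:
    """True (pre-measurement) concentrations per sample and metabolite."""
    rng = _rng(config, 2)
    mets = panel.names()
    tv = np.array([panel.get(m).target_value_uM for m in mets])
    n = len(samples)
    k = len(mets)

    affected = np.isin(mets, list(config.affected_metabolites))
    s_tot = np.sqrt(config.residual_log_sd ** 2
                    + np.where(affected, config.affected_corr_loading ** 2, 0))
    delta = np.zeros(k)
    for name, eff in dict(config.disease_effects).items():
        if name not in mets:
            raise SynthError(f"disease effect on unknown metabolite {name!r}")
        delta[mets.index(name)] = eff
    gamma = np.zeros(k)
    if config.genotype_beta_precursor and config.precursor_metabolite in mets:
        gamma[mets.index(config.precursor_metabolite)] = \
            config.genotype_beta_precursor

    case = samples["case"].to_numpy(float)
    age = samples["age_at_sampling_days"].to_numpy(float)
    bottle = truth.bottle_fed.loc[samples["sample_id"]].to_numpy(float)
    dose = truth.genotype.loc[samples["sample_id"], "rs174547"].to_numpy(float)
    factor = rng.standard_normal(n)            # shared latent factor F_i
    eps = rng.normal(0.0, config.residual_log_sd, (n, k))

    exposure = np.maximum(age - config.feeding_onset_day, 0.0)
    mean_shift = (np.outer(case, delta)
                  + config.feeding_effect_per_day
                  * np.outer(exposure * bottle, affected.astype(float))
                  + np.outer(dose, gamma))
    logx = (np.log(tv)[None, :]
            + s_tot[None, :] * mean_shift
            + config.affected_corr_loading
            * np.outer(factor, affected.astype(float))
            + eps)
    out = pd.DataFrame(np.exp(logx), index=samples["sample_id"].to_numpy(),
                       columns=mets)
    out.index.name = "sample_id"
    return out


def _plate_layout(samples: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Assign wells: control wells first, then pairs packed plate by plate
    (matched members always share a plate)."""
    cap = config.sample_wells_per_plate()
    pair_ids = samples["pair_id"].drop_duplicates().to_numpy()
    # spread pairs evenly; the capacity check lives in SimConfig
    chunks = np.array_split(pair_ids, config.n_plates)
    if any(2 * len(ch) > cap for ch in chunks):
        raise SynthError("plate layout infeasible for this pair count")
    rows = []
    for plate_i in range(config.n_plates):
        plate = f"PL{plate_i + 1}"
        well = 1
        for _ in range(config.blanks_per_plate):
            rows.append((plate, well, "blank", "blank")); well += 1
        rows.append((plate, well, "QC1", "QC1")); well += 1
        for _ in range(config.qc2_reps_per_plate):
            rows.append((plate, well, "QC2", "QC2")); well += 1
        rows.append((plate, well, "QC3", "QC3")); well += 1
        for pid in chunks[plate_i]:
            for sid in samples.loc[samples["pair_id"] == pid, "sample_id"]:
                rows.append((plate, well, sid, "sample")); well += 1
    placed = {r[2] for r in rows if r[3] == "sample"}
    missing = set(samples["sample_id"]) - placed
    if missing:
        raise SynthError(f"layout infeasible: {len(missing)} samples unplaced")
    return pd.DataFrame(rows, columns=["plate", "well", "sample_id", "role"])


def simulate_plates(samples: pd.DataFrame, panel: PanelDefinition,
                    config: SimConfig, truth: GroundTruth | None = None
                    ) -> tuple[pd.DataFrame, GroundTruth]:
    """Raw plate measurements for the cohort.

    Every well value is scaled by the multiplicative plate factor
    ``C_{m,p}`` and carries lognormal technical noise with CV
    ``qc_noise_cv``; blanks sit at ``blank_level_frac * TV_m`` (or at
    sample level for designed LOD failures) and QC2 wells at
    ``TV_m * C_{m,p}`` (with inflated noise for designed CV failures).
    """
    if truth is None:
        _, truth = simulate_cohort(config)
    rng = _rng(config, 3)
    conc = truth.true_concentrations
    if conc is None:
        conc = simulate_concentrations(samples, panel, config, truth)
        truth.true_concentrations = conc

    mets = panel.names()
    k = len(mets)
    tv = np.array([panel.get(m).target_value_uM for m in mets])
    unknown = (set(config.fail_lod_metabolites)
               | set(config.fail_cv_metabolites)) - set(mets)
    if unknown:
        raise SynthError(f"designed failures not on panel: {sorted(unknown)}")
    fail_lod = np.isin(mets, list(config.fail_lod_metabolites))
    fail_cv = np.isin(mets, list(config.fail_cv_metabolites))

    plates = [f"PL{i + 1}" for i in range(config.n_plates)]
    cmp_ = np.exp(rng.normal(0.0, config.plate_factor_sd,
                             (k, config.n_plates)))
    plate_factors = pd.DataFrame(cmp_, index=mets, columns=plates)

    layout = _plate_layout(samples, config)
    nw = len(layout)
    plate_idx = layout["plate"].map({p: i for i, p in enumerate(plates)})
    plate_idx = plate_idx.to_numpy()

    # broadcast to wells x metabolites
    cv = np.where(fail_cv, config.fail_cv_noise, config.qc_noise_cv)
    sigma = np.sqrt(np.log1p(cv ** 2))
    noise = np.exp(rng.normal(0.0, 1.0, (nw, k)) * sigma[None, :])
    cfac = cmp_.T[plate_idx, :]                      # per well row

    base = np.empty((nw, k))
    role = layout["role"].to_numpy()
    blank_level = np.where(fail_lod, config.fail_lod_blank_frac,
                           config.blank_level_frac) * tv
    base[role == "blank"] = blank_level
    base[role == "QC1"] = 0.5 * tv
    base[role == "QC2"] = tv
    base[role == "QC3"] = 2.0 * tv
    is_sample = role == "sample"
    base[is_sample] = conc.loc[layout.loc[is_sample, "sample_id"]].to_numpy()

    raw = base * cfac * noise
    table = pd.DataFrame({
        "plate": np.repeat(layout["plate"].to_numpy(), k),
        "well": np.repeat(layout["well"].to_numpy(), k),
        "sample_id": np.repeat(layout["sample_id"].to_numpy(), k),
        "role": np.repeat(role, k),
        "metabolite": np.tile(mets, nw),
        "raw_uM": raw.ravel(),
    })

    truth.plate_factors = plate_factors
    failures = {m: "lod" for m in config.fail_lod_metabolites}
    failures.update({m: "cv" for m in config.fail_cv_metabolites})
    truth.designed_failures = failures
    return table, truth


def simulate_dataset(panel: PanelDefinition, config: SimConfig
                     ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Cohort + plates in one call: (samples, plate table, ground truth)."""
    samples, truth = simulate_cohort(config)
    plates, truth = simulate_plates(samples, panel, config, truth)
    return samples, plates, truth


def write_dataset(outdir: str | Path, samples: pd.DataFrame,
                  plates: pd.DataFrame, panel: PanelDefinition,
                  truth: GroundTruth) -> dict[str, Path]:
    """Write the pipeline's three input files plus the ground-truth sidecar."""
    from .panel import write_panel

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "samples": outdir / "samples.tsv",
        "plates": outdir / "plates.csv",
        "panel": outdir / "panel.tsv",
        "truth": outdir / "truth.json",
    }
    samples.to_csv(paths["samples"], sep="\t", index=False)
    plates.to_csv(paths["plates"], index=False)
    write_panel(panel, paths["panel"])
    truth.to_json(paths["truth"])
    return paths
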
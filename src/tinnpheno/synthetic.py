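"""Synthetic two-timepoint cohort generator.

Emulates a patient-reported-outcome cohort with the latent structure the
downstream analysis assumes:

* four baseline **phenotypes** — an avoidant group with below-average burden
  on every index, a psychosomatic group with the highest emotional and
  somatic burden, a somatic group with above-average somatic complaints but
  near-average affect, and a distress group with above-average affective and
  stress scores;
* five **pathways of change** of graded magnitude, applied as a uniform mean
  shift to all continuous variables at the post-treatment timepoint, ordered
  from deterioration (positive shift) to strong improvement (negative
  shift) — binary tinnitus-characteristic items receive no shift, so
  pathways do not separate on them;
* **staged attrition**: of all enrolled patients only a fraction completes
  every questionnaire at baseline, and of those a further fraction completes
  everything again at discharge.

Continuous scores are generated on the standardized (z) scale as
``phenotype category offset (+ pathway shift at t1) + Gaussian noise`` and
affine-mapped onto each variable's declared raw range (z in [-3, 3] spans
the range; values are clipped at the bounds). Variables declared
higher-is-better are stored inverted, so that reverse-coding recovers the
latent burden score. Binary items are Bernoulli draws held fixed across the
two timepoints (localization and noise quality are stable traits).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortTable
from .errors import ConfigurationError
from .variables import CATEGORIES, VariableSpec, default_variable_specs, write_variable_specs

#: Default phenotype mixture weights (avoidant, psychosomatic, somatic, distress).
DEFAULT_PHENOTYPE_WEIGHTS: tuple[float, ...] = (0.568, 0.141, 0.152, 0.139)

#: Per-phenotype mean burden offset per variable category, standardized units.
DEFAULT_PHENOTYPE_PROFILES: tuple[dict[str, float], ...] = (
    # avoidant: substantially below-average symptom expression across the board
    {c: -0.55 for c in CATEGORIES} | {"tinnitus_characteristics": -0.4},
    # psychosomatic: highest emotional AND somatic burden
    {
        "tinnitus_characteristics": 0.8, "physical_qol": 1.2, "pain": 1.4,
        "somatic": 1.6, "affective": 1.4, "tinnitus_distress": 1.5,
        "internal_resources": 1.1, "perceived_stress": 1.3,
        "general_qol": 0.9, "mental_qol": 1.2,
    },
    # somatic: strongly above-average somatic complaints, near-average affect
    {
        "tinnitus_characteristics": 0.3, "physical_qol": 1.4, "pain": 1.5,
        "somatic": 1.6, "affective": -0.3, "tinnitus_distress": 0.2,
        "internal_resources": -0.2, "perceived_stress": -0.3,
        "general_qol": 0.0, "mental_qol": -0.3,
    },
    # distress: above-average affective, stress and quality-of-life burden,
    # near-average somatic expression
    {
        "tinnitus_characteristics": 0.3, "physical_qol": -0.2, "pain": -0.3,
        "somatic": -0.3, "affective": 1.2, "tinnitus_distress": 0.5,
        "internal_resources": 0.9, "perceived_stress": 1.3,
        "general_qol": 0.9, "mental_qol": 1.1,
    },
)

#: Default pathway mixture weights (high deterioration ... high improvement).
DEFAULT_PATHWAY_WEIGHTS: tuple[float, ...] = (0.046, 0.219, 0.345, 0.292, 0.098)

#: Default graded mean shifts at t1 (standardized units, strictly decreasing).
DEFAULT_PATHWAY_SHIFTS: tuple[float, ...] = (1.2, 0.45, -0.25, -0.95, -1.65)

DEFAULT_BINARY_RATES: dict[str, float] = {
    "tlq_loc_left": 0.25,
    "tlq_loc_right": 0.20,
    "tlq_loc_both": 0.40,
    "tlq_loc_head": 0.15,
    "tlq_noise_whistling": 0.50,
    "tlq_noise_hissing": 0.30,
    "tlq_noise_ringing": 0.40,
    "tlq_noise_rustling": 0.20,
    "phqk_panic": 0.12,
}

#: Staged attrition matching enrolment -> baseline completers -> both-timepoint
#: completers proportions of 4103 -> 1228 -> 989.
DEFAULT_ATTRITION: tuple[float, float] = (1 - 1228 / 4103, 1 - 989 / 1228)


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort generator (see module docstring)."""

    n_total: int = 4103
    phenotype_weights: tuple[float, ...] = DEFAULT_PHENOTYPE_WEIGHTS
    phenotype_profiles: tuple[dict[str, float], ...] = DEFAULT_PHENOTYPE_PROFILES
    pathway_weights: tuple[float, ...] = DEFAULT_PATHWAY_WEIGHTS
    pathway_shifts: tuple[float, ...] = DEFAULT_PATHWAY_SHIFTS
    noise_sd: float = 0.15
    noise_sd_overrides: Mapping[str, float] = field(default_factory=dict)
    binary_base_rates: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BINARY_RATES))
    attrition: tuple[float, float] = DEFAULT_ATTRITION
    attrition_phenotype_bias: tuple[float, ...] | None = None
    variable_specs: list[VariableSpec] = field(default_factory=default_variable_specs)
    seed: int = 0

    def validate(self) -> None:
        for fname, w in (("phenotype_weights", self.phenotype_weights),
                         ("pathway_weights", self.pathway_weights)):
            w = np.asarray(w, dtype=float)
            if len(w) == 0 or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
                raise ConfigurationError(f"{fname}: entries must be >= 0 and sum to 1")
        if len(self.phenotype_profiles) != len(self.phenotype_weights):
            raise ConfigurationError(
                "phenotype_profiles: need one profile per phenotype weight"
            )
        for i, prof in enumerate(self.phenotype_profiles):
            unknown = set(prof) - set(CATEGORIES)
            if unknown:
                raise ConfigurationError(
                    f"phenotype_profiles[{i}]: unknown categories {sorted(unknown)}"
                )
        if len(self.pathway_shifts) != len(self.pathway_weights):
            raise ConfigurationError("pathway_shifts: need one shift per pathway weight")
        shifts = np.asarray(self.pathway_shifts, dtype=float)
        if len(shifts) > 1 and not (np.diff(shifts) < 0).all():
            raise ConfigurationError(
                "pathway_shifts: must be strictly decreasing "
                "(deterioration first, improvement last)"
            )
        if not self.noise_sd > 0:
            raise ConfigurationError("noise_sd: must be > 0")
        for name, sd in self.noise_sd_overrides.items():
            if not sd > 0:
                raise ConfigurationError(f"noise_sd_overrides[{name!r}]: must be > 0")
        binary_names = {s.name for s in self.variable_specs if s.kind == "binary"}
        for name, p in self.binary_base_rates.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"binary_base_rates[{name!r}]: must be in [0, 1]")
        missing = binary_names - set(self.binary_base_rates)
        if missing:
            raise ConfigurationError(f"binary_base_rates: missing rates for {sorted(missing)}")
        p0, p1 = self.attrition
        if not (0.0 <= p0 <= 1.0 and 0.0 <= p1 <= 1.0):
            raise ConfigurationError("attrition: probabilities must be in [0, 1]")
        if self.attrition_phenotype_bias is not None and len(
            self.attrition_phenotype_bias
        ) != len(self.phenotype_weights):
            raise ConfigurationError(
                "attrition_phenotype_bias: need one entry per phenotype"
            )
        if self.n_total < 1:
            raise ConfigurationError("n_total: must be >= 1")

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "n_total": self.n_total,
            "phenotype_weights": list(self.phenotype_weights),
            "phenotype_profiles": [dict(p) for p in self.phenotype_profiles],
            "pathway_weights": list(self.pathway_weights),
            "pathway_shifts": list(self.pathway_shifts),
            "noise_sd": self.noise_sd,
            "noise_sd_overrides": dict(self.noise_sd_overrides),
            "binary_base_rates": dict(self.binary_base_rates),
            "attrition": list(self.attrition),
            "attrition_phenotype_bias": (
                None if self.attrition_phenotype_bias is None
                else list(self.attrition_phenotype_bias)
            ),
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("n_total", "noise_sd", "seed"):
            if key in payload:
                kwargs[key] = payload[key]
        for key in ("phenotype_weights", "pathway_weights", "pathway_shifts"):
            if key in payload:
                kwargs[key] = tuple(payload[key])
        if "phenotype_profiles" in payload:
            kwargs["phenotype_profiles"] = tuple(dict(p) for p in payload["phenotype_profiles"])
        if "noise_sd_overrides" in payload:
            kwargs["noise_sd_overrides"] = dict(payload["noise_sd_overrides"])
        if "binary_base_rates" in payload:
            kwargs["binary_base_rates"] = dict(payload["binary_base_rates"])
        if "attrition" in payload:
            kwargs["attrition"] = tuple(payload["attrition"])
        if payload.get("attrition_phenotype_bias") is not None:
            kwargs["attrition_phenotype_bias"] = tuple(payload["attrition_phenotype_bias"])
        return cls(**kwargs)


@dataclass
class SyntheticCohort:
    """Generated raw tables plus the latent ground truth behind them."""

    t0_raw: CohortTable
    t1_raw: CohortTable
    true_phenotype: pd.Series  # 1..K per patient
    true_pathway: pd.Series  # 1..M per patient, 1 = most deterioration
    completeness: pd.DataFrame  # bool columns: complete_t0, complete_both

    def __post_init__(self):
        ids = self.t0_raw.patient_ids
        for name, obj in (("t1_raw", self.t1_raw.patient_ids),
                          ("true_phenotype", self.true_phenotype.index),
                          ("true_pathway", self.true_pathway.index),
                          ("completeness", self.completeness.index)):
            if not ids.equals(pd.Index(obj)):
                raise ConfigurationError(f"{name}: patient ids misaligned with t0_raw")
        both_not_t0 = self.completeness["complete_both"] & ~self.completeness["complete_t0"]
        if both_not_t0.any():
            raise ConfigurationError(
                "completeness: complete_both must be a subset of complete_t0"
            )


def _z_to_raw(z: np.ndarray, spec: VariableSpec) -> np.ndarray:
    """Map standardized scores onto the raw range: z in [-3, 3] spans the scale."""
    center = 0.5 * (spec.raw_min + spec.raw_max)
    halfspan = 0.5 * (spec.raw_max - spec.raw_min)
    return np.clip(center + z * halfspan / 3.0, spec.raw_min, spec.raw_max)


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Draw a full two-timepoint cohort (latent labels included), then apply attrition.

    Same config and seed give byte-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_total
    specs = config.variable_specs
    ids = pd.Index([f"P{i:05d}" for i in range(1, n + 1)], name="patient_id")

    pheno = rng.choice(len(config.phenotype_weights), size=n, p=config.phenotype_weights)
    path = rng.choice(len(config.pathway_weights), size=n, p=config.pathway_weights)
    shifts = np.asarray(config.pathway_shifts, dtype=float)[path]

    t0 = np.empty((n, len(specs)))
    t1 = np.empty((n, len(specs)))
    for j, spec in enumerate(specs):
        if spec.kind == "binary":
            draw = (rng.random(n) < config.binary_base_rates[spec.name]).astype(float)
            t0[:, j] = draw
            t1[:, j] = draw  # stable trait: identical at both timepoints
            continue
        offset = np.array(
            [config.phenotype_profiles[z].get(spec.category, 0.0) for z in range(len(config.phenotype_weights))]
        )[pheno]
        sd = config.noise_sd_overrides.get(spec.name, config.noise_sd)
        z0 = offset + rng.normal(0.0, sd, size=n)
        z1 = offset + shifts + rng.normal(0.0, sd, size=n)
        if spec.polarity == "higher-is-better":
            # store inverted so reverse-coding (max - value) recovers the burden scale
            t0[:, j] = spec.raw_max - _z_to_raw(z0, spec)
            t1[:, j] = spec.raw_max - _z_to_raw(z1, spec)
        else:
            t0[:, j] = _z_to_raw(z0, spec)
            t1[:, j] = _z_to_raw(z1, spec)

    cols = [s.name for s in specs]
    cohort = SyntheticCohort(
        t0_raw=CohortTable("t0", pd.DataFrame(t0, index=ids, columns=cols), specs),
        t1_raw=CohortTable("t1", pd.DataFrame(t1, index=ids, columns=cols), specs),
        true_phenotype=pd.Series(pheno + 1, index=ids, name="true_phenotype"),
        true_pathway=pd.Series(path + 1, index=ids, name="true_pathway"),
        completeness=pd.DataFrame(
            {"complete_t0": True, "complete_both": True}, index=ids
        ),
    )
    return apply_attrition(cohort, config)


def apply_attrition(cohort: SyntheticCohort, config: GeneratorConfig) -> SyntheticCohort:
    """Redraw staged completeness flags and blank one answer per incomplete stage.

    Attrition is independent of phenotype unless ``attrition_phenotype_bias``
    adds a per-phenotype offset to the baseline-incompleteness probability.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 104729])  # sub-stream for attrition
    n = len(cohort.t0_raw.data)
    p0, p1 = config.attrition
    p0_vec = np.full(n, p0)
    if config.attrition_phenotype_bias is not None:
        bias = np.asarray(config.attrition_phenotype_bias, dtype=float)
        p0_vec = np.clip(p0 + bias[cohort.true_phenotype.to_numpy() - 1], 0.0, 1.0)
    complete_t0 = rng.random(n) >= p0_vec
    complete_both = complete_t0 & (rng.random(n) >= p1)

    t0 = cohort.t0_raw.data.copy()
    t1 = cohort.t1_raw.data.copy()
    n_vars = t0.shape[1]
    drop_t0 = rng.integers(0, n_vars, size=n)
    drop_t1 = rng.integers(0, n_vars, size=n)
    for i in np.flatnonzero(~complete_t0):
        t0.iat[i, drop_t0[i]] = np.nan
    for i in np.flatnonzero(complete_t0 & ~complete_both):
        t1.iat[i, drop_t1[i]] = np.nan

    return replace(
        cohort,
        t0_raw=cohort.t0_raw.with_data(t0),
        t1_raw=cohort.t1_raw.with_data(t1),
        completeness=pd.DataFrame(
            {"complete_t0": complete_t0, "complete_both": complete_both},
            index=cohort.t0_raw.patient_ids,
        ),
    )


def recovery_config(kind: str, n_total: int = 800, seed: int = 0) -> GeneratorConfig:
    """Study conditions for the label-recovery experiments.

    ``kind='phenotype'`` keeps the default four profiles (pairwise separation
    far above 2 noise SDs) with no attrition; ``kind='pathway'`` uses five
    shifts whose adjacent gaps equal exactly 2 noise SDs.
    """
    if kind == "phenotype":
        return GeneratorConfig(n_total=n_total, attrition=(0.0, 0.0), seed=seed)
    if kind == "pathway":
        return GeneratorConfig(
            n_total=n_total,
            attrition=(0.0, 0.0),
            pathway_shifts=(2.0, 1.0, 0.0, -1.0, -2.0),
            seed=seed,
        )
    raise ConfigurationError(f"recovery_config: unknown kind {kind!r}")


def export_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write t0/t1 tables, truth labels and the variable spec sidecar as CSV."""
    from .io import write_cohort  # local import to avoid a cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "t0": out / "t0_raw.csv",
        "t1": out / "t1_raw.csv",
        "truth": out / "truth.csv",
        "specs": out / "variable_specs.csv",
    }
    write_cohort(cohort.t0_raw, paths["t0"])
    write_cohort(cohort.t1_raw, paths["t1"])
    truth = pd.DataFrame(
        {
            "true_phenotype": cohort.true_phenotype,
            "true_pathway": cohort.true_pathway,
            "complete_t0": cohort.completeness["complete_t0"].astype(int),
            "complete_both": cohort.completeness["complete_both"].astype(int),
        }
    )
    truth.to_csv(paths["truth"], index_label="patient_id")
    write_variable_specs(cohort.t0_raw.specs, paths["specs"])
    return paths
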
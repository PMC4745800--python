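"""Synthetic matched RPPA / expression / clinical cohorts with known truth.

The generator emulates the data structure the pipeline is built for: a
latent pathway-activation level per protein drives both its RPPA readout and
the expression of its member genes, two cohorts on different intensity
scales exercise quantile alignment and external validation, and a
randomized two-arm survival outcome carries a treatment-interaction effect
through exactly one planted metagene.

Generative model (per cohort):

* latent activation ``A_p ~ N(0, 1)`` per protein and sample, independent
  across proteins;
* RPPA readout ``A_p + N(0, noise_sd_rppa)``;
* a member gene g of an informative protein has expression
  ``b_g + s_g * effect_size * A_p + N(0, noise_sd_expr)`` with baseline
  ``b_g ~ N(8, 2)`` (log-intensity scale) and coefficient ``s_g`` in
  {-1, +1}; pure-noise genes are ``b_g + N(0, noise_sd_expr)``;
* arm assigned 1:1 at random; survival times are exponential with
  ``log hazard = log(baseline_hazard) + arm * treatment_log_hr
  + arm * z * interaction_log_hr_per_sd`` where z is the standardized true
  signature score of the planted interaction protein; censoring is an
  independent exponential calibrated so the expected censored fraction
  equals ``censoring_rate``.

The default parameter values are the study conditions every recovery and
calibration test in this package runs under; see docs/methods.md for the
rationale behind each.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import DataError
from .io import ClinicalTable, ExpressionMatrix, RPPAMatrix


@dataclass
class SurvivalConfig:
    """Parameters of the synthetic survival outcome.

    ``baseline_hazard`` is per month (0.01 puts the median event time near
    70 months, a plausible adjuvant follow-up).  ``treatment_log_hr`` is the
    arm effect at the average score; ``interaction_log_hr_per_sd`` is the
    extra treated-arm log-hazard per SD of the planted metagene's score,
    anchored so the low/high median strata show a strong benefit contrast.
    """

    baseline_hazard: float = 0.01
    censoring_rate: float = 0.3
    treatment_log_hr: float = math.log(0.6)
    interaction_log_hr_per_sd: float = 1.25
    interaction_protein_index: int = 0


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohorts."""

    n_samples_derivation: int = 200
    n_samples_validation: int = 100
    n_proteins: int = 20
    n_informative_proteins: int = 10
    genes_per_metagene: int = 50
    n_genes_total: int = 1000
    effect_size: float = 1.0
    noise_sd_expr: float = 1.0
    noise_sd_rppa: float = 0.5
    frac_negative_members: float = 0.3
    validation_scale: float = 1.5
    validation_shift: float = 0.5
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.survival, dict):
            self.survival = SurvivalConfig(**self.survival)
        if min(self.n_samples_derivation, self.n_proteins,
               self.genes_per_metagene, self.n_genes_total) <= 0:
            raise DataError("counts must be positive")
        if self.n_informative_proteins > self.n_proteins:
            raise DataError("n_informative_proteins > n_proteins")
        if not 0 <= self.frac_negative_members <= 1:
            raise DataError("frac_negative_members must be in [0, 1]")
        if not 0 <= self.survival.censoring_rate < 1:
            raise DataError("censoring_rate must be in [0, 1)")
        if self.n_informative_proteins * self.genes_per_metagene > self.n_genes_total:
            raise DataError(
                "more member genes than n_genes_total: "
                f"{self.n_informative_proteins} x {self.genes_per_metagene} "
                f"> {self.n_genes_total}"
            )
        if not 0 <= self.survival.interaction_protein_index < max(self.n_informative_proteins, 1):
            raise DataError("interaction_protein_index out of range")


@dataclass
class GroundTruth:
    """What the generator planted: the targets every recovery test checks."""

    latent_activation: pd.DataFrame  # proteins x samples
    true_members: dict[str, dict[str, int]]
    interaction_protein: str

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_members": self.true_members,
            "interaction_protein": self.interaction_protein,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class Cohort:
    rppa: RPPAMatrix
    expr: ExpressionMatrix
    clinical: ClinicalTable
    truth: GroundTruth

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.expr.to_tsv(out / "expression.tsv")
        self.rppa.to_tsv(out / "rppa.tsv")
        self.clinical.to_csv(out / "clinical.csv")
        self.truth.to_json(out / "truth.json")


@dataclass
class _Structure:
    """Cohort-independent structure: gene baselines, member assignment."""

    gene_ids: list[str]
    protein_ids: list[str]
    baselines: np.ndarray
    members: dict[str, dict[str, int]]
    interaction_protein: str


def _draw_structure(config: SimConfig, rng: np.random.Generator) -> _Structure:
    width = len(str(config.n_genes_total))
    gene_ids = [f"G{i:0{width}d}" for i in range(1, config.n_genes_total + 1)]
    pwidth = max(2, len(str(config.n_proteins)))
    protein_ids = [f"P{i:0{pwidth}d}" for i in range(1, config.n_proteins + 1)]
    baselines = rng.normal(8.0, 2.0, size=config.n_genes_total)
    pool = rng.permutation(config.n_genes_total)
    members: dict[str, dict[str, int]] = {}
    gpm = config.genes_per_metagene
    n_neg = int(round(config.frac_negative_members * gpm))
    for k in range(config.n_informative_proteins):
        block = pool[k * gpm:(k + 1) * gpm]
        coeffs = np.ones(gpm, dtype=int)
        coeffs[:n_neg] = -1
        rng.shuffle(coeffs)
        members[protein_ids[k]] = {
            gene_ids[g]: int(c) for g, c in zip(block, coeffs)
        }
    interaction = protein_ids[config.survival.interaction_protein_index]
    return _Structure(gene_ids, protein_ids, baselines, members, interaction)


def _censoring_hazard(lam: np.ndarray, rate: float) -> float:
    """Exponential censoring hazard c with E[c / (c + lam)] = rate."""
    if rate <= 0:
        return 0.0
    lo, hi = 1e-12, float(lam.max()) * 1e6

    def frac(c: float) -> float:
        return float(np.mean(c / (c + lam))) - rate

    return float(brentq(frac, lo, hi, xtol=1e-14))


def _draw_cohort(
    config: SimConfig,
    structure: _Structure,
    rng: np.random.Generator,
    n_samples: int,
    prefix: str,
) -> Cohort:
    width = len(str(n_samples))
    samples = [f"{prefix}{i:0{width}d}" for i in range(1, n_samples + 1)]
    n_prot, n_genes = config.n_proteins, config.n_genes_total

    latent = rng.standard_normal((n_prot, n_samples))
    rppa_values = latent + rng.normal(0.0, config.noise_sd_rppa, latent.shape)

    expr_values = (
        structure.baselines[:, None]
        + rng.normal(0.0, config.noise_sd_expr, (n_genes, n_samples))
    )
    gene_pos = {g: i for i, g in enumerate(structure.gene_ids)}
    prot_pos = {p: i for i, p in enumerate(structure.protein_ids)}
    for pid, mem in structure.members.items():
        a = latent[prot_pos[pid]]
        for gene, coeff in mem.items():
            expr_values[gene_pos[gene]] += coeff * config.effect_size * a

    # survival: randomized 1:1 arms, interaction through the planted score
    arm = np.zeros(n_samples)
    arm[rng.permutation(n_samples)[: n_samples // 2]] = 1.0
    inter_members = structure.members.get(structure.interaction_protein, {})
    score = np.zeros(n_samples)
    for gene, coeff in inter_members.items():
        score += coeff * expr_values[gene_pos[gene]]
    z = (score - score.mean()) / score.std() if score.std() > 0 else score
    surv = config.survival
    lam = surv.baseline_hazard * np.exp(
        arm * surv.treatment_log_hr + arm * z * surv.interaction_log_hr_per_sd
    )
    event_times = rng.exponential(1.0 / lam)
    c = _censoring_hazard(lam, surv.censoring_rate)
    if c > 0:
        cens_times = rng.exponential(1.0 / c, n_samples)
        time = np.minimum(event_times, cens_times)
        event = (event_times <= cens_times).astype(int)
    else:
        time, event = event_times, np.ones(n_samples, dtype=int)

    age = np.round(rng.normal(55.0, 8.0, n_samples), 1)
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "time": time,
                "event": event,
                "arm": np.where(arm == 1.0, "treated", "control"),
                "age": age,
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )
    truth = GroundTruth(
        latent_activation=pd.DataFrame(
            latent, index=structure.protein_ids, columns=samples
        ),
        true_members=structure.members,
        interaction_protein=structure.interaction_protein,
    )
    return Cohort(
        rppa=RPPAMatrix(pd.DataFrame(rppa_values, index=structure.protein_ids,
                                     columns=samples)),
        expr=ExpressionMatrix(pd.DataFrame(expr_values, index=structure.gene_ids,
                                           columns=samples)),
        clinical=clinical,
        truth=truth,
    )


def generate_cohort(config: SimConfig | None = None) -> Cohort:
    """One matched RPPA + expression + clinical cohort, reproducible from the seed."""
    config = config or SimConfig()
    ss = np.random.SeedSequence(config.seed)
    s_struct, s_cohort = ss.spawn(2)
    structure = _draw_structure(config, np.random.default_rng(s_struct))
    return _draw_cohort(
        config, structure, np.random.default_rng(s_cohort),
        config.n_samples_derivation, "D",
    )


def generate_two_datasets(config: SimConfig | None = None) -> tuple[Cohort, Cohort]:
    """Derivation and validation cohorts from one generative model.

    Both cohorts share gene baselines, member assignments and coefficients;
    the validation expression matrix is put on a different intensity scale
    (``x * validation_scale + validation_shift``) so that cross-dataset use
    exercises quantile alignment.
    """
    config = config or SimConfig()
    ss = np.random.SeedSequence(config.seed)
    s_struct, s_deriv, s_val = ss.spawn(3)
    structure = _draw_structure(config, np.random.default_rng(s_struct))
    derivation = _draw_cohort(
        config, structure, np.random.default_rng(s_deriv),
        config.n_samples_derivation, "D",
    )
    validation = _draw_cohort(
        config, structure, np.random.default_rng(s_val),
        config.n_samples_validation, "V",
    )
    validation = Cohort(
        rppa=validation.rppa,
        expr=ExpressionMatrix(
            validation.expr.data * config.validation_scale + config.validation_shift
        ),
        clinical=validation.clinical,
        truth=validation.truth,
    )
    return derivation, validation
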
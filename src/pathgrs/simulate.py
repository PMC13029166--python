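"""Synthetic cohort generator.

Generates genotypes, ancestry-informative-marker (AIMs) genotypes, and lipid
phenotypes with the statistical structure the downstream analysis assumes:

* independent SNPs drawn as two Bernoulli(freq) allele draws (Hardy-Weinberg
  proportions by construction), optional LD blocks drawn as two sampled
  haplotypes per individual;
* two-way admixture: individual admixture proportions ``q`` drawn from a Beta
  distribution, per-AIM allele frequency ``q*p1 + (1-q)*p2``;
* phenotypes from the linear model the analysis fits — triglycerides on the
  natural-log scale, HDL-C on the raw scale — with additive per-allele SNP
  effects, age/sex/BMI terms, optional ancestry effects, and Gaussian noise.

One global seed governs all draws: the seed's ``SeedSequence`` is spawned
into named child streams (genotypes, missingness, aims, covariates, tg, hdl,
admixture) in a fixed order, so outputs are byte-identical across runs and
adding individuals to one stream never perturbs another.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .panel import SnpPanel, load_default_panel

__all__ = [
    "LdBlock",
    "AdmixtureConfig",
    "PhenotypeModel",
    "SimulationConfig",
    "default_study_config",
    "simulate_genotypes",
    "simulate_aims",
    "simulate_phenotypes",
    "simulate_cohort",
    "write_cohort",
]

_STREAMS = ("genotypes", "missingness", "aims", "covariates", "tg", "hdl", "admixture")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class LdBlock:
    """A set of SNPs drawn jointly from explicit haplotype frequencies.

    ``haplotypes`` are tuples of 0/1 (1 = counted allele), one entry per SNP
    in ``snp_ids``; ``frequencies`` must sum to 1.
    """

    snp_ids: tuple[str, ...]
    haplotypes: tuple[tuple[int, ...], ...]
    frequencies: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.haplotypes) != len(self.frequencies):
            raise SimulationError("haplotypes and frequencies differ in length")
        if any(len(h) != len(self.snp_ids) for h in self.haplotypes):
            raise SimulationError("haplotype length does not match snp_ids")
        if abs(sum(self.frequencies) - 1.0) > 1e-9:
            raise SimulationError("haplotype frequencies must sum to 1")
        if any(f < 0 for f in self.frequencies):
            raise SimulationError("negative haplotype frequency")


@dataclass(frozen=True)
class AdmixtureConfig:
    """Two-way admixture: per-AIM ancestral frequency pairs and a Beta law
    for individual admixture proportions q (weight on population 1)."""

    n_aims: int = 64
    ancestral_freq_pairs: tuple[tuple[float, float], ...] = ()
    beta_a: float = 6.0
    beta_b: float = 4.0

    def __post_init__(self) -> None:
        if self.n_aims < 2:
            raise SimulationError("admixture requires at least 2 AIMs")
        pairs = self.ancestral_freq_pairs or tuple((0.8, 0.2) for _ in range(self.n_aims))
        if len(pairs) != self.n_aims:
            raise SimulationError("ancestral_freq_pairs length must equal n_aims")
        for p1, p2 in pairs:
            if not (0 < p1 < 1 and 0 < p2 < 1):
                raise SimulationError("ancestral frequencies must lie in (0, 1)")
        object.__setattr__(self, "ancestral_freq_pairs", tuple(tuple(p) for p in pairs))


@dataclass(frozen=True)
class PhenotypeModel:
    """Generative model for one phenotype.

    For a log-scale phenotype (TG) effects and noise act on log(value);
    for a raw-scale phenotype (HDL-C) on the value itself.
    """

    intercept: float
    snp_effects: dict[str, float] = field(default_factory=dict)
    age_beta: float = 0.0
    sex_beta: float = 0.0
    bmi_beta: float = 0.0
    ancestry_beta: float = 0.0
    noise_sd: float = 1.0
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise SimulationError("noise_sd must be positive")


@dataclass
class SimulationConfig:
    n_individuals: int
    allele_freqs: dict[str, float]
    panel: SnpPanel | None = None
    ld_blocks: list[LdBlock] = field(default_factory=list)
    # genotype HW departure: inbreeding-style coefficient per SNP (het deficit)
    hwe_violation: dict[str, float] = field(default_factory=dict)
    # ancestry-dependent SNP frequencies (confounding simulations)
    snp_ancestral_freqs: dict[str, tuple[float, float]] = field(default_factory=dict)
    tg_model: PhenotypeModel | None = None
    hdl_model: PhenotypeModel | None = None
    # covariate distributions (means/SDs of the emulated cohort)
    p_male: float = 265 / 580
    age_mean: float = 18.9
    age_sd: float = 0.9
    age_bounds: tuple[float, float] = (18.0, 25.0)
    bmi_mean: float = 23.6
    bmi_sd: float = 4.0
    admixture: AdmixtureConfig | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise SimulationError("n_individuals must be positive")
        if not 0 <= self.missing_rate < 1:
            raise SimulationError("missing_rate must lie in [0, 1)")
        for snp, f in self.allele_freqs.items():
            if not 0.0 < f < 1.0:
                raise SimulationError(f"{snp}: allele frequency {f} outside (0, 1)")
        seen: set[str] = set()
        for block in self.ld_blocks:
            overlap = seen.intersection(block.snp_ids)
            if overlap:
                raise SimulationError(f"SNPs in more than one LD block: {sorted(overlap)}")
            seen.update(block.snp_ids)
            unknown = [s for s in block.snp_ids if s not in self.allele_freqs]
            if unknown:
                raise SimulationError(f"LD-block SNPs missing from allele_freqs: {unknown}")

    def streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {name: np.random.default_rng(seq) for name, seq in zip(_STREAMS, children)}


def _draw_admixture(config: SimulationConfig, rng: np.random.Generator) -> pd.Series:
    adm = config.admixture
    q = rng.beta(adm.beta_a, adm.beta_b, size=config.n_individuals)
    ids = [f"ind{i:04d}" for i in range(config.n_individuals)]
    return pd.Series(q, index=ids, name="admixture")


def simulate_genotypes(
    config: SimulationConfig, admixture: pd.Series | None = None
) -> GenotypeMatrix:
    """Draw the SNP genotype matrix.

    Independent SNPs are the sum of two Bernoulli(freq) allele draws, i.e.
    Hardy-Weinberg proportions by construction; a positive ``hwe_violation``
    coefficient F shifts a SNP's class probabilities to
    (p^2+Fpq, 2pq(1-F), q^2+Fpq) to emulate a heterozygote-deficit failure.
    LD-block SNPs are derived from two haplotypes sampled per individual.
    SNPs listed in ``snp_ancestral_freqs`` use the individual-specific
    frequency ``q*p1 + (1-q)*p2`` (requires *admixture*).
    """
    n = config.n_individuals
    streams = config.streams()
    rng = streams["genotypes"]
    ids = [f"ind{i:04d}" for i in range(n)]
    cols: dict[str, np.ndarray] = {}

    in_block = {s for b in config.ld_blocks for s in b.snp_ids}
    for snp, freq in config.allele_freqs.items():
        if snp in in_block:
            continue
        if snp in config.snp_ancestral_freqs:
            if admixture is None:
                raise SimulationError(
                    f"{snp} has ancestry-dependent frequency but no admixture supplied"
                )
            p1, p2 = config.snp_ancestral_freqs[snp]
            p = admixture.to_numpy() * p1 + (1 - admixture.to_numpy()) * p2
            cols[snp] = rng.binomial(1, p) + rng.binomial(1, p)
            continue
        f = config.hwe_violation.get(snp, 0.0)
        if f:
            p, q = freq, 1 - freq
            probs = [q * q + f * p * q, 2 * p * q * (1 - f), p * p + f * p * q]
            cols[snp] = rng.choice(3, size=n, p=np.array(probs) / sum(probs)).astype(float)
        else:
            cols[snp] = (rng.binomial(1, freq, size=n) + rng.binomial(1, freq, size=n)).astype(
                float
            )

    for block in config.ld_blocks:
        haps = np.array(block.haplotypes, dtype=float)
        idx1 = rng.choice(len(haps), size=n, p=block.frequencies)
        idx2 = rng.choice(len(haps), size=n, p=block.frequencies)
        geno = haps[idx1] + haps[idx2]
        for j, snp in enumerate(block.snp_ids):
            cols[snp] = geno[:, j]

    codes = pd.DataFrame({s: cols[s] for s in config.allele_freqs}, index=ids)

    if config.missing_rate > 0:
        miss = streams["missingness"].random(codes.shape) < config.missing_rate
        codes = codes.mask(miss)

    return GenotypeMatrix(codes, panel=config.panel, admixture=admixture)


def simulate_aims(
    config: SimulationConfig, admixture: pd.Series | None = None
) -> GenotypeMatrix:
    """Draw AIMs genotypes under two-way admixture.

    Individual i's allele frequency at AIM m is ``q_i*p1_m + (1-q_i)*p2_m``;
    the genotype is two Bernoulli draws at that frequency.  The admixture
    proportions used are attached to the result (``.admixture``) so ancestry
    recovery can be tested.
    """
    if config.admixture is None:
        raise SimulationError("config.admixture is not set")
    streams = config.streams()
    if admixture is None:
        admixture = _draw_admixture(config, streams["admixture"])
    rng = streams["aims"]
    q = admixture.to_numpy()[:, None]
    pairs = np.array(config.admixture.ancestral_freq_pairs)
    freqs = q * pairs[None, :, 0] + (1 - q) * pairs[None, :, 1]
    geno = rng.binomial(1, freqs) + rng.binomial(1, freqs)
    codes = pd.DataFrame(
        geno.astype(float),
        index=admixture.index,
        columns=[f"aim{m:03d}" for m in range(config.admixture.n_aims)],
    )
    return GenotypeMatrix(codes, admixture=admixture)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    admixture: pd.Series | None = None,
) -> pd.DataFrame:
    """Generate the phenotype table (age, sex, bmi, tg, hdl).

    TG is built on the natural-log scale and exponentiated; HDL-C on the raw
    scale.  Age and BMI enter centred at their configured means so the model
    intercepts are interpretable as covariate-average values.  SNP effects
    use pre-missingness dosages when available via the genotype matrix; with
    missing codes the missing entries contribute the SNP's mean dosage (the
    generative effect is defined on the latent complete genotype).
    """
    streams = config.streams()
    rng = streams["covariates"]
    n = genotypes.n_individuals
    ids = genotypes.individual_ids

    sex = rng.binomial(1, config.p_male, size=n).astype(float)  # 1 = male
    age = _truncated_normal(rng, config.age_mean, config.age_sd, *config.age_bounds, size=n)
    bmi = _truncated_normal(rng, config.bmi_mean, config.bmi_sd, 12.0, 60.0, size=n)

    if admixture is None:
        admixture = genotypes.admixture
    out = pd.DataFrame({"age": age, "sex": sex, "bmi": bmi}, index=ids)
    out.index.name = "individual_id"

    for name, model in (("tg", config.tg_model), ("hdl", config.hdl_model)):
        if model is None:
            continue
        missing_effect = [s for s in model.snp_effects if s not in genotypes.codes.columns]
        if missing_effect:
            raise SimulationError(f"{name}: effect SNPs absent from genotypes: {missing_effect}")
        lin = np.full(n, model.intercept, dtype=float)
        for snp, beta in model.snp_effects.items():
            g = genotypes.codes[snp]
            g = g.fillna(g.mean())
            lin += beta * g.to_numpy()
        lin += model.age_beta * (age - config.age_mean)
        lin += model.sex_beta * sex
        lin += model.bmi_beta * (bmi - config.bmi_mean)
        if model.ancestry_beta:
            if admixture is None:
                raise SimulationError(f"{name}: ancestry_beta set but no admixture available")
            lin += model.ancestry_beta * admixture.loc[ids].to_numpy()
        lin += streams[name].normal(0.0, model.noise_sd, size=n)
        out[name] = np.exp(lin) if model.log_scale else lin
    return out


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, GenotypeMatrix | None, pd.DataFrame]:
    """Orchestrate a full draw: (genotypes, aims or None, phenotypes).

    Admixture proportions are drawn once and shared by the genotype, AIMs
    and phenotype stages so ancestry confounding is coherent across them.
    """
    admixture = None
    aims = None
    if config.admixture is not None:
        admixture = _draw_admixture(config, config.streams()["admixture"])
        aims = simulate_aims(config, admixture=admixture)
    genotypes = simulate_genotypes(config, admixture=admixture)
    phenotypes = simulate_phenotypes(genotypes, config, admixture=admixture)
    return genotypes, aims, phenotypes


def default_study_config(
    panel: SnpPanel | None = None, n_individuals: int = 580, seed: int = 0
) -> SimulationConfig:
    """The emulated study conditions.

    Allele frequencies are the panel's cohort frequencies; the ANGPTL4 trio
    and the CD36 pair are drawn from D'=1 haplotype blocks so LD pruning has
    the structure the analysis expects; the flagged CD36 variant is drawn
    with a heterozygote deficit so Hardy-Weinberg screening rejects it.  TG
    acts on the log scale with residual SD 0.42 (cohort TG SD ~50 mg/dL at
    mean ~108); HDL-C on the raw scale with residual SD 11 (cohort SD ~11.6).
    Per-SNP effects are small positive log-TG effects concentrated in the
    RCT pathway and a dominant protective-variant effect on HDL-C, sized so
    single-SNP variance fractions are of order 1e-2.
    """
    panel = panel or load_default_panel()
    freqs = {r.snp_id: r.maf_cohort for r in panel}

    tg_effects = {
        "rs1532624": 0.040,
        "rs289714": 0.030,
        "rs5882": 0.030,
        "rs4149310": 0.030,
        "rs805743": 0.030,
        "rs10889337": 0.020,
        "rs2278236": 0.030,
        "rs10499859": 0.020,
        "rs12678919": 0.040,
        "rs1260326": 0.030,
        "rs1800588": 0.030,
        "rs2286276": 0.050,
        "rs1801282": 0.020,
        "rs12639162": 0.030,
    }
    hdl_effects = {
        "rs1532624": -0.8,
        "rs289714": -1.0,
        "rs5882": -0.8,
        "rs4149310": -0.8,
        "rs9282541": -3.5,
        "rs805743": -0.5,
        "rs10889337": -0.5,
        "rs2278236": -0.5,
        "rs10499859": -0.5,
        "rs12678919": 1.0,  # HDL-raising: its HDL risk allele is the partner allele
        "rs1260326": -0.3,
        "rs1800588": -1.0,
        "rs2286276": -0.3,
        "rs1801282": -0.3,
        "rs12639162": -0.3,
    }

    tg_noise, hdl_noise = 0.42, 11.0
    p_male = 265 / 580
    tg_sex_beta, hdl_sex_beta = 0.04, -4.0
    # intercepts back out the genetic and sex mean shifts so the simulated
    # cohort means land near the emulated study's (TG 108.5, HDL-C 49.6)
    tg_shift = sum(b * 2 * freqs[s] for s, b in tg_effects.items())
    hdl_shift = sum(b * 2 * freqs[s] for s, b in hdl_effects.items())
    tg_intercept = math.log(108.5) - 0.5 * tg_noise**2 - tg_shift - tg_sex_beta * p_male
    hdl_intercept = 49.6 - hdl_shift - hdl_sex_beta * p_male

    ld_blocks = [
        LdBlock(
            snp_ids=("rs1044250", "rs2278236", "rs7255436"),
            haplotypes=((1, 1, 1), (0, 1, 1), (0, 0, 1), (0, 0, 0)),
            frequencies=(0.40, 0.08, 0.01, 0.51),
        ),
        LdBlock(
            snp_ids=("rs1527483", "rs10499859"),
            haplotypes=((1, 1), (0, 1), (0, 0)),
            frequencies=(0.12, 0.36, 0.52),
        ),
    ]

    return SimulationConfig(
        n_individuals=n_individuals,
        allele_freqs=freqs,
        panel=panel,
        ld_blocks=ld_blocks,
        hwe_violation={"rs3173798": 0.35},
        tg_model=PhenotypeModel(
            intercept=tg_intercept,
            snp_effects=tg_effects,
            age_beta=0.010,
            sex_beta=tg_sex_beta,
            bmi_beta=0.015,
            noise_sd=tg_noise,
            log_scale=True,
        ),
        hdl_model=PhenotypeModel(
            intercept=hdl_intercept,
            snp_effects=hdl_effects,
            age_beta=-0.10,
            sex_beta=hdl_sex_beta,
            bmi_beta=-0.40,
            noise_sd=hdl_noise,
            log_scale=False,
        ),
        admixture=AdmixtureConfig(n_aims=64),
        missing_rate=0.01,
        seed=seed,
    )


def write_cohort(
    config: SimulationConfig,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Simulate and write genotypes/phenotypes/AIMs CSVs plus a JSON sidecar
    recording the true generative parameters for recovery tests."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genotypes, aims, phenotypes = simulate_cohort(config)

    paths = {
        "genotypes": out_dir / "genotypes.csv",
        "phenotypes": out_dir / "phenotypes.csv",
        "truth": out_dir / "truth.json",
    }
    genotypes.to_csv(paths["genotypes"])
    phenotypes.to_csv(paths["phenotypes"], float_format="%.6g")
    if aims is not None:
        paths["aims"] = out_dir / "aims.csv"
        aims.to_csv(paths["aims"])

    def model_dict(m: PhenotypeModel | None):
        if m is None:
            return None
        return {
            "intercept": m.intercept,
            "snp_effects": m.snp_effects,
            "age_beta": m.age_beta,
            "sex_beta": m.sex_beta,
            "bmi_beta": m.bmi_beta,
            "ancestry_beta": m.ancestry_beta,
            "noise_sd": m.noise_sd,
            "log_scale": m.log_scale,
        }

    truth = {
        "seed": config.seed,
        "n_individuals": config.n_individuals,
        "allele_freqs": config.allele_freqs,
        "missing_rate": config.missing_rate,
        "tg_model": model_dict(config.tg_model),
        "hdl_model": model_dict(config.hdl_model),
        "admixture": None
        if genotypes.admixture is None
        else genotypes.admixture.round(6).to_dict(),
    }
    paths["truth"].write_text(json.dumps(truth, indent=2))
    return paths
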
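"""Synthetic lipidomic cohort generator.

Emulates the statistical structure the mBMI analysis assumes: a plasma
lipidome of 575 species in 33 lipid classes whose (log-scale) abundances load
on two latent, mutually independent factors —

* ``A`` — adiposity: drives measured BMI (together with age, sex and
  non-lipid noise);
* ``M`` — metabolic dysregulation: loads on the *same* species as ``A``
  (proportional loadings, overlap ``kappa``) but does **not** enter BMI.
  Cardiometabolic traits and disease outcomes depend on ``M`` given BMI, which
  is exactly the signal the mBMI-delta score is built to recover.

Because the dysregulation factor loads proportionally on the adiposity
direction, the best linear lipid predictor of BMI is attenuated by
``1/(1+kappa^2)``; the generator solves this closed form so that the
population R^2 of BMI on (lipidome, age, sex) equals ``signal_r2`` exactly.

Technical structure: per-batch multiplicative median shifts, multiplicative
log-normal measurement noise with coefficient of variation ``batch_cv``, and
pooled-plasma (PQC) plus reference-material (NIST) replicate rows, so the QC
stage has real work to do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .tables import LipidTable

LOG10 = math.log(10.0)

# 33 lipid classes; sign of the shared adiposity/dysregulation loading mimics
# the known biology: glycerolipids and ceramides up with adiposity,
# lyso- and ether-phospholipids down, the rest mixed.
_POSITIVE_CLASSES = (
    "TG", "TG-O", "DG", "CE", "Cer", "dhCer", "Cer1P", "HexCer", "AC", "FFA",
)
_NEGATIVE_CLASSES = (
    "LPC", "LPC-O", "LPC-P", "LPE", "LPE-P", "LPI",
    "PC-O", "PC-P", "PE-O", "PE-P",
)
_MIXED_CLASSES = (
    "PC", "PE", "PI", "PS", "PG", "SM", "Hex2Cer", "Hex3Cer", "GM3",
    "S1P", "COH", "DE", "ST",
)
LIPID_CLASSES = _POSITIVE_CLASSES + _NEGATIVE_CLASSES + _MIXED_CLASSES
assert len(LIPID_CLASSES) == 33


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort.

    Parameters
    ----------
    n_samples:
        Number of cohort participants.
    n_species, n_classes:
        Size of the lipidome (defaults mirror a 575-species, 33-class panel).
    signal_r2:
        Population R^2 of the best linear (lipidome + age + sex) predictor of
        BMI; must lie strictly in (0, 1).
    delta_effect:
        Log-odds (and log-hazard) per SD of the latent dysregulation factor M
        on disease outcomes, conditional on BMI.
    batch_count:
        Number of measurement batches; ``None`` derives one batch per ~485
        cohort samples.
    batch_cv:
        Coefficient of variation of the multiplicative technical noise.
    qc_replicates:
        Number of NIST reference-plasma replicate rows.
    seed:
        Master seed; one child stream per component (species, lipids,
        phenotypes, outcomes, qc) so regenerating outcomes never perturbs the
        lipid matrix.
    """

    n_samples: int = 2000
    n_species: int = 575
    n_classes: int = 33
    signal_r2: float = 0.6
    delta_effect: float = 0.5
    batch_count: int | None = None
    batch_cv: float = 0.10
    qc_replicates: int = 200
    seed: int = 0
    # secondary knobs (documented defaults, rarely moved)
    dysregulation_overlap: float = 0.6   # kappa: loading of M relative to A
    covariate_r2: float = 0.03           # BMI variance from age + sex
    bmi_mean: float = 26.9               # kg/m^2
    bmi_sd: float = 4.9                  # kg/m^2
    loading_scale: float = 0.12          # mean |loading| on log10 scale
    loading_spread: float = 0.04
    class_factor_sd: float = 0.07        # shared within-class log10 noise
    species_noise_sd: float = 0.12       # per-species log10 noise
    batch_shift_sd: float = 0.03         # per-batch log10 median shift
    pqc_per_batch: int = 3
    followup_t2dm: float = 5.0           # years
    followup_cve: float = 10.0           # years

    def validate(self) -> None:
        errors = []
        for name in ("n_samples", "n_species", "n_classes", "qc_replicates"):
            if int(getattr(self, name)) <= 0:
                errors.append(f"{name} must be a positive count")
        if not 0.0 < self.signal_r2 < 1.0:
            errors.append("signal_r2 must lie strictly in (0, 1)")
        if self.n_classes > self.n_species:
            errors.append("n_classes must not exceed n_species")
        if self.batch_count is not None and self.batch_count <= 0:
            errors.append("batch_count must be a positive count or None")
        if self.batch_cv < 0:
            errors.append("batch_cv must be non-negative")
        if self.dysregulation_overlap < 0:
            errors.append("dysregulation_overlap must be non-negative")
        if not 0.0 <= self.covariate_r2 < self.signal_r2:
            errors.append("covariate_r2 must lie in [0, signal_r2)")
        w_a_sq = (self.signal_r2 - self.covariate_r2) * (
            1.0 + self.dysregulation_overlap**2
        )
        if w_a_sq + self.covariate_r2 >= 1.0:
            errors.append(
                "signal_r2 unattainable at this dysregulation_overlap: "
                "the attenuated adiposity signal would exceed total BMI variance"
            )
        if errors:
            raise ValueError("invalid GeneratorConfig: " + "; ".join(errors))

    @property
    def n_batches(self) -> int:
        if self.batch_count is not None:
            return int(self.batch_count)
        return max(1, round(self.n_samples / 485))


@dataclass
class SyntheticCohort:
    """A generated cohort plus the latent truth used to build it."""

    lipids: LipidTable               # cohort + PQC + NIST rows
    phenotypes: pd.DataFrame         # cohort rows only
    truth: pd.DataFrame              # per-sample latent A and M
    loadings: pd.DataFrame           # per-species loadings on A and M
    config: GeneratorConfig
    params: dict = field(default_factory=dict)


# ----------------------------------------------------------------------
def _species_metadata(cfg: GeneratorConfig, rng: np.random.Generator):
    """Species ids, class labels, loadings and baseline abundances."""
    classes = list(LIPID_CLASSES[: cfg.n_classes])
    base, rem = divmod(cfg.n_species, cfg.n_classes)
    sizes = [base + (1 if i < rem else 0) for i in range(cfg.n_classes)]

    species_ids, class_labels, display = [], [], []
    for cls, size in zip(classes, sizes):
        for k in range(size):
            carbons = 30 + (k % 14) * 2
            dbs = k % 7
            species_ids.append(f"{cls}_{k:03d}")
            class_labels.append(cls)
            display.append(f"{cls}({carbons}:{dbs})")

    sign_by_class = {}
    for cls in classes:
        if cls in _POSITIVE_CLASSES:
            sign_by_class[cls] = 1.0
        elif cls in _NEGATIVE_CLASSES:
            sign_by_class[cls] = -1.0
        else:
            sign_by_class[cls] = rng.choice([-1.0, 1.0])

    signs = np.array([sign_by_class[c] for c in class_labels])
    magnitudes = np.abs(
        rng.normal(cfg.loading_scale, cfg.loading_spread, cfg.n_species)
    )
    load_a = signs * magnitudes
    mu = rng.normal(1.0, 0.6, cfg.n_species)          # baseline log10 abundance
    nist_offset = rng.normal(0.0, 0.05, cfg.n_species)

    species = pd.DataFrame(
        {"lipid_class": class_labels, "display_name": display},
        index=pd.Index(species_ids, name="species_id"),
    )
    return species, load_a, mu, nist_offset


def _tech_noise_log10(rng, shape, cv):
    """Log10 increments of multiplicative log-normal noise with the given CV."""
    if cv <= 0:
        return np.zeros(shape)
    sigma_ln = math.sqrt(math.log1p(cv * cv))
    return rng.standard_normal(shape) * (sigma_ln / LOG10)


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort (lipids, phenotypes, outcomes, QC)."""
    cfg = config
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    rng_species, rng_lipids, rng_pheno, rng_out, rng_qc = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    species, load_a, mu, nist_offset = _species_metadata(cfg, rng_species)
    kappa = cfg.dysregulation_overlap
    n = cfg.n_samples
    n_batches = cfg.n_batches
    class_codes = species["lipid_class"].astype("category").cat.codes.to_numpy()

    # ---- latent factors and lipid matrix (log10 scale) ----------------
    A = rng_lipids.standard_normal(n)
    M = rng_lipids.standard_normal(n)
    S = A + kappa * M

    class_factors = rng_lipids.standard_normal((n, cfg.n_classes)) * cfg.class_factor_sd
    eps = rng_lipids.standard_normal((n, cfg.n_species)) * cfg.species_noise_sd
    batch_shifts = rng_lipids.standard_normal((n_batches, cfg.n_species)) * cfg.batch_shift_sd

    batch_of = np.minimum(
        (np.arange(n) * n_batches) // n, n_batches - 1
    )  # contiguous run-order blocks
    log10_x = (
        mu[None, :]
        + np.outer(S, load_a)
        + class_factors[:, class_codes]
        + eps
        + batch_shifts[batch_of, :]
        + _tech_noise_log10(rng_lipids, (n, cfg.n_species), cfg.batch_cv)
    )

    sample_ids = [f"S{i:06d}" for i in range(n)]
    batch_labels = [f"B{b:02d}" for b in batch_of]

    # ---- QC rows: pooled plasma per batch + NIST replicates ------------
    qc_frames = []
    pqc_ref = mu
    for b in range(n_batches):
        rows = (
            pqc_ref[None, :]
            + batch_shifts[b][None, :]
            + _tech_noise_log10(rng_qc, (cfg.pqc_per_batch, cfg.n_species), cfg.batch_cv)
        )
        qc_frames.append((rows, [f"PQC_B{b:02d}_{r}" for r in range(cfg.pqc_per_batch)],
                          f"B{b:02d}", "PQC"))
    nist_ref = mu + nist_offset
    nist_batches = np.arange(cfg.qc_replicates) % n_batches
    nist_rows = (
        nist_ref[None, :]
        + batch_shifts[nist_batches, :]
        + _tech_noise_log10(rng_qc, (cfg.qc_replicates, cfg.n_species), cfg.batch_cv)
    )

    all_log10 = [log10_x] + [f[0] for f in qc_frames] + [nist_rows]
    all_ids = (
        sample_ids
        + [sid for f in qc_frames for sid in f[1]]
        + [f"NIST_{r:03d}" for r in range(cfg.qc_replicates)]
    )
    all_batches = (
        batch_labels
        + [f[2] for f in qc_frames for _ in f[1]]
        + [f"B{b:02d}" for b in nist_batches]
    )
    all_types = (
        ["cohort"] * n
        + ["PQC"] * (n_batches * cfg.pqc_per_batch)
        + ["NIST"] * cfg.qc_replicates
    )

    data = pd.DataFrame(
        np.power(10.0, np.vstack(all_log10)),
        index=pd.Index(all_ids, name="sample_id"),
        columns=species.index,
    )
    samples = pd.DataFrame(
        {"batch": all_batches, "sample_type": all_types}, index=data.index
    )
    lipids = LipidTable(data, samples, species)

    # ---- phenotypes ----------------------------------------------------
    age = rng_pheno.uniform(25.0, 80.0, n)
    sex = (rng_pheno.uniform(size=n) < 0.55).astype(int)  # 1 = female
    age_z = (age - 52.5) / math.sqrt((80.0 - 25.0) ** 2 / 12.0)
    sex_z = (sex - 0.55) / math.sqrt(0.55 * 0.45)

    w_cov = math.sqrt(cfg.covariate_r2 / 2.0)
    w_a = math.sqrt((cfg.signal_r2 - cfg.covariate_r2) * (1.0 + kappa * kappa))
    w_e = math.sqrt(1.0 - cfg.covariate_r2 - w_a * w_a)
    e = rng_pheno.standard_normal(n)
    bmi_z = w_cov * age_z + w_cov * sex_z + w_a * A + w_e * e
    bmi = cfg.bmi_mean + cfg.bmi_sd * bmi_z

    def _pos_trait(m_load, bmi_load, noise_sd, scale):
        z = m_load * M + bmi_load * bmi_z + noise_sd * rng_pheno.standard_normal(n)
        return scale * np.exp(z)

    pheno = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    pheno["age"] = age
    pheno["sex"] = sex
    pheno["bmi"] = bmi
    pheno["total_chol"] = _pos_trait(0.08, 0.04, 0.14, 5.4)       # mmol/L
    pheno["hdl_c"] = _pos_trait(-0.18, -0.12, 0.18, 1.40)
    pheno["triglycerides"] = _pos_trait(0.30, 0.22, 0.30, 1.30)
    pheno["fbg"] = _pos_trait(0.10, 0.07, 0.07, 5.4)
    pheno["plg_2h"] = _pos_trait(0.25, 0.15, 0.22, 5.6)
    pheno["hba1c"] = _pos_trait(0.07, 0.04, 0.05, 5.3)            # %
    pheno["homa_ir"] = _pos_trait(0.45, 0.35, 0.40, 1.50)
    pheno["sbp"] = 125.0 + 5.0 * M + 4.0 * bmi_z + 12.0 * rng_pheno.standard_normal(n)
    pheno["dbp"] = 75.0 + 3.0 * M + 2.5 * bmi_z + 8.0 * rng_pheno.standard_normal(n)
    pheno["smoking"] = (
        rng_pheno.uniform(size=n) < _sigmoid(-1.9 + 0.15 * M)
    ).astype(int)
    pheno["family_history_diabetes"] = (rng_pheno.uniform(size=n) < 0.15).astype(int)

    # diet / lifestyle: healthy behaviours anti-correlated with dysregulation
    z = rng_pheno.standard_normal
    pheno["fruit_intake"] = 2.0 - 0.30 * M + 0.9 * z(n)           # serves/day
    pheno["fibre_intake"] = 22.0 - 2.0 * M + 6.0 * z(n)           # g/day
    pheno["leisure_pa_time"] = 150.0 - 25.0 * M + 90.0 * z(n)     # min/week
    pheno["tv_time"] = 120.0 + 20.0 * M + 60.0 * z(n)             # min/day
    pheno["energy_intake"] = 8700.0 + 400.0 * bmi_z + 1500.0 * z(n)  # kJ/day
    pheno["alcohol"] = np.maximum(0.0, 10.0 + 8.0 * z(n))         # g/day
    pheno["total_fat"] = 80.0 + 3.0 * bmi_z + 15.0 * z(n)
    pheno["carbohydrate"] = 220.0 + 40.0 * z(n)
    pheno["sugar"] = 90.0 + 1.5 * M + 25.0 * z(n)
    pheno["processed_meat"] = np.maximum(0.0, 20.0 + 2.0 * M + 15.0 * z(n))
    pheno["red_meat"] = np.maximum(0.0, 60.0 + 30.0 * z(n))
    pheno["tinned_fish"] = np.maximum(0.0, 10.0 + 10.0 * z(n))
    pheno["protein"] = 95.0 + 20.0 * z(n)
    pheno["education"] = (rng_pheno.uniform(size=n) < 0.45).astype(int)

    # ---- outcomes (separate stream) ------------------------------------
    d = cfg.delta_effect
    u = rng_out.uniform
    pheno["t2dm_prev"] = (
        u(size=n) < _sigmoid(-3.5 + d * M + 0.40 * bmi_z)
    ).astype(int)
    pheno["cvd_prev"] = (
        u(size=n) < _sigmoid(-3.1 + 0.5 * d * M + 0.25 * bmi_z + 0.02 * (age - 52.5))
    ).astype(int)
    free = pheno["t2dm_prev"] == 0
    ifg = (u(size=n) < _sigmoid(-3.0 + 0.6 * d * M + 0.25 * bmi_z)) & free
    igt = (u(size=n) < _sigmoid(-2.9 + 0.7 * d * M + 0.25 * bmi_z)) & free & ~ifg
    pheno["ifg"] = ifg.astype(int)
    pheno["igt"] = igt.astype(int)

    def _incident(base_rate, m_load, horizon):
        rate = base_rate * np.exp(m_load * M + 0.30 * bmi_z)
        t = rng_out.exponential(1.0 / rate)
        event = t <= horizon
        return event.astype(int), np.minimum(t, horizon)

    pheno["t2dm_incident"], pheno["t2dm_time"] = _incident(0.008, d, cfg.followup_t2dm)
    pheno["cve_incident"], pheno["cve_time"] = _incident(0.004, 0.5 * d, cfg.followup_cve)
    pheno["ihd_incident"], pheno["ihd_time"] = _incident(0.003, 0.5 * d, cfg.followup_cve)

    truth = pd.DataFrame({"A": A, "M": M}, index=pheno.index)
    loadings = pd.DataFrame(
        {"loading_A": load_a, "loading_M": kappa * load_a}, index=species.index
    )
    params = {
        "w_age": w_cov, "w_sex": w_cov, "w_A": w_a, "w_e": w_e,
        "kappa": kappa, "n_batches": n_batches, "seed": cfg.seed,
    }
    return SyntheticCohort(lipids, pheno, truth, loadings, cfg, params)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


# ----------------------------------------------------------------------
def generate_qc_replicates(
    config: GeneratorConfig,
    reference_sample: pd.Series,
    batch_shifts: np.ndarray | None = None,
    sample_type: str = "NIST",
) -> LipidTable:
    """Replicate rows of one reference sample with technical noise.

    Each replicate is the reference times multiplicative log-normal noise with
    coefficient of variation ``config.batch_cv``; ``batch_shifts`` (log10
    scale, one per batch) injects per-batch median shifts and defaults to
    none, so at ``batch_cv = 0`` replicates are identical to the reference.
    """
    cfg = config
    cfg.validate()
    ref = np.asarray(reference_sample, dtype=float)
    if np.any(ref <= 0):
        raise ValueError("reference sample must be strictly positive")
    n_rep = cfg.qc_replicates
    n_batches = cfg.n_batches
    if batch_shifts is None:
        batch_shifts = np.zeros(n_batches)
    batch_shifts = np.asarray(batch_shifts, dtype=float)
    if batch_shifts.shape[0] != n_batches:
        raise ValueError("batch_shifts must have one entry per batch")

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(6)[-1])
    rep_batch = np.arange(n_rep) % n_batches
    log10_rows = (
        np.log10(ref)[None, :]
        + batch_shifts[rep_batch, None]
        + _tech_noise_log10(rng, (n_rep, ref.size), cfg.batch_cv)
    )
    ids = pd.Index([f"{sample_type}_{r:03d}" for r in range(n_rep)], name="sample_id")
    data = pd.DataFrame(np.power(10.0, log10_rows), index=ids,
                        columns=reference_sample.index)
    samples = pd.DataFrame(
        {"batch": [f"B{b:02d}" for b in rep_batch], "sample_type": sample_type},
        index=ids,
    )
    species = pd.DataFrame(
        {"lipid_class": "unknown"}, index=pd.Index(reference_sample.index,
                                                   name="species_id")
    )
    return LipidTable(data, samples, species)


def config_to_dict(cfg: GeneratorConfig) -> dict:
    return asdict(cfg)
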
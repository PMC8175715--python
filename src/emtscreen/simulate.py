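"""Synthetic cohort generator with known ground truth.

The generative model mirrors the admixture mechanism that motivates the
whole analysis: every bulk tumor sample is a convex mixture, in linear
expression space, of an epithelial compartment and a stromal compartment,
with per-sample stromal fraction ``f``.  A block of stromal-archetype
genes is elevated in the stroma; a block of planted EMT-mediator genes
is epithelium-enriched yet co-varies with ``f`` in bulk (their expression
rises with EMT activity, which tracks stromal content).  Survival hazard
is exponential in the per-sample EMT activity, so mediators carry a real
prognostic signal.  A pure-tumor cell-line panel (no stromal admixture)
contains an EMT-prone subset, and a clinical table carries a binary
marker with a configurable odds-ratio association to a covariate.

Every generator is deterministic given the config seed; independent
numbered RNG streams keep the outputs of the different generators
decoupled from one another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

from .containers import MicrodissectionSet
from .exceptions import ConfigError, ConsistencyError

GENE_ROLES = ("stromal_archetype", "planted_mediator", "epithelial_background")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults describe the study conditions used throughout the test
    suite: 2000 genes, 200 bulk samples, 13 micro-dissection pairs,
    150 stromal-archetype genes and 60 planted mediators.
    """

    n_genes: int = 2000
    n_bulk_samples: int = 200
    n_microdissection_pairs: int = 13
    n_celllines: int = 30
    n_stromal_archetype: int = 150
    n_planted_mediators: int = 60
    # per-sample stromal fraction f ~ Beta(alpha, beta)
    stromal_fraction_alpha: float = 2.0
    stromal_fraction_beta: float = 3.0
    stromal_fraction_fixed: float | None = None  # pin f (degenerate Beta)
    # log2-space effect sizes
    mediator_coupling: float = 2.0  # bulk log2 shift per unit f for mediators
    noise_sd: float = 0.25  # log2-space Gaussian noise
    stromal_offset: float = 3.0  # archetype elevation in stroma (log2)
    mediator_epithelial_offset: float = 1.0  # mediator elevation in epithelium (log2)
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.5
    # survival model
    hazard_coef: float = 2.0  # log-hazard per unit EMT activity
    censor_rate: float = 0.25
    baseline_hazard: float = 0.1
    # cell-line panel
    n_emt_prone: int = 10
    emt_marker_offset: float = 2.0
    emt_mediator_offset: float = 1.5
    # clinical table
    marker_prevalence: float = 0.3
    covariate_base_rate: float = 0.4
    covariate_odds_ratio: float = 2.0
    marker_hazard_ratio: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = (
            "n_genes",
            "n_bulk_samples",
            "n_microdissection_pairs",
            "n_celllines",
            "n_stromal_archetype",
            "n_planted_mediators",
            "n_emt_prone",
        )
        for name in counts:
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_stromal_archetype + self.n_planted_mediators > self.n_genes:
            raise ConfigError(
                "n_stromal_archetype + n_planted_mediators must not exceed n_genes"
            )
        if self.n_emt_prone > self.n_celllines:
            raise ConfigError("n_emt_prone must not exceed n_celllines")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ConfigError(f"censor_rate must be in [0, 1), got {self.censor_rate}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for name in ("stromal_fraction_alpha", "stromal_fraction_beta"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.stromal_fraction_fixed is not None and not (
            0.0 <= self.stromal_fraction_fixed <= 1.0
        ):
            raise ConfigError("stromal_fraction_fixed must lie in [0, 1]")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be > 0")
        for name in ("marker_prevalence", "covariate_base_rate"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ConfigError(f"{name} must lie in (0, 1)")
        if self.covariate_odds_ratio <= 0:
            raise ConfigError("covariate_odds_ratio must be > 0")

    def null(self) -> "SimConfig":
        """The matched no-signal configuration: mediators uncoupled from
        stromal fraction and hazard independent of EMT activity."""
        return replace(self, mediator_coupling=0.0, hazard_coef=0.0)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, mapping: dict) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**mapping)


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the synthetic cohort."""

    gene_role: pd.Series  # gene_id -> role
    stromal_fraction: pd.Series  # sample_id -> f in [0, 1]
    emt_activity: pd.Series  # sample_id -> scalar EMT activity
    true_hazard_coef: float

    def __post_init__(self) -> None:
        bad = set(self.gene_role.unique()) - set(GENE_ROLES)
        if bad:
            raise ConsistencyError(f"unknown gene roles {sorted(bad)}")
        frac = self.stromal_fraction.to_numpy(dtype=float)
        if ((frac < 0) | (frac > 1)).any():
            raise ConsistencyError("stromal_fraction outside [0, 1]")

    def genes_with_role(self, role: str) -> list[str]:
        if role not in GENE_ROLES:
            raise ValueError(f"unknown role {role!r}")
        return self.gene_role.index[self.gene_role == role].tolist()

    @property
    def mediators(self) -> list[str]:
        return self.genes_with_role("planted_mediator")

    @property
    def archetypes(self) -> list[str]:
        return self.genes_with_role("stromal_archetype")


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _gene_ids(config: SimConfig) -> pd.Index:
    width = max(4, len(str(config.n_genes)))
    return pd.Index([f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)], name="gene_id")


def _archetype_profiles(config: SimConfig):
    """Deterministic per-gene epithelial (E) and stromal (S) log2 profiles
    plus gene roles; shared by the bulk and micro-dissection generators."""
    rng = _rng(config, 0)
    genes = _gene_ids(config)
    epi = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)
    roles = np.full(config.n_genes, "epithelial_background", dtype=object)
    idx = rng.permutation(config.n_genes)
    arch = idx[: config.n_stromal_archetype]
    medi = idx[config.n_stromal_archetype : config.n_stromal_archetype + config.n_planted_mediators]
    roles[arch] = "stromal_archetype"
    roles[medi] = "planted_mediator"
    # per-gene effect-size weights: marker blocks in real data are not a
    # uniform shift, and a rank-one shift would be invisible to
    # correlation distance after per-gene standardization
    weight = rng.uniform(0.5, 1.5, config.n_genes)
    stro = epi.copy()
    stro[arch] += config.stromal_offset * weight[arch]
    stro[medi] -= config.mediator_epithelial_offset * weight[medi]
    role_series = pd.Series(roles, index=genes, name="role")
    return genes, role_series, epi, stro, weight


def _stromal_fractions(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if config.stromal_fraction_fixed is not None:
        return np.full(config.n_bulk_samples, config.stromal_fraction_fixed)
    return rng.beta(
        config.stromal_fraction_alpha, config.stromal_fraction_beta, config.n_bulk_samples
    )


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate the bulk genes-by-samples log2 expression matrix and truth.

    Mixing is performed in linear space (transcript admixture is additive
    in counts) and reported in log2:
    ``bulk = log2((1-f) * 2**E + f * 2**S) + coupling + noise``,
    where planted mediators additionally gain ``mediator_coupling * f``.
    EMT activity per sample is the mediators' shared coupling signal
    ``mediator_coupling * f``.
    """
    genes, roles, epi, stro, _ = _archetype_profiles(config)
    rng = _rng(config, 1)
    f = _stromal_fractions(config, rng)
    samples = pd.Index(
        [f"S{i:04d}" for i in range(1, config.n_bulk_samples + 1)], name="sample_id"
    )
    mixture = np.log2(
        (1.0 - f)[None, :] * np.exp2(epi)[:, None] + f[None, :] * np.exp2(stro)[:, None]
    )
    emt_activity = config.mediator_coupling * f
    is_mediator = (roles == "planted_mediator").to_numpy()
    mixture[is_mediator, :] += emt_activity[None, :]
    if config.noise_sd > 0:
        mixture += rng.normal(0.0, config.noise_sd, mixture.shape)
    bulk = pd.DataFrame(mixture, index=genes, columns=samples)
    truth = SyntheticTruth(
        gene_role=roles,
        stromal_fraction=pd.Series(f, index=samples, name="stromal_fraction"),
        emt_activity=pd.Series(emt_activity, index=samples, name="emt_activity"),
        true_hazard_coef=config.hazard_coef,
    )
    return bulk, truth


def _check_truth(config: SimConfig, truth: SyntheticTruth) -> None:
    counts = truth.gene_role.value_counts()
    ok = (
        len(truth.gene_role) == config.n_genes
        and counts.get("stromal_archetype", 0) == config.n_stromal_archetype
        and counts.get("planted_mediator", 0) == config.n_planted_mediators
        and len(truth.stromal_fraction) == config.n_bulk_samples
    )
    if not ok:
        raise ConsistencyError(
            "truth does not match config (gene roles or sample counts differ); "
            "it must come from generate_cohort with the same config"
        )


def generate_microdissection(config: SimConfig, truth: SyntheticTruth) -> MicrodissectionSet:
    """Paired pure epithelium / pure stroma profiles for each specimen.

    Epithelium columns are drawn around the epithelial archetype profile
    and stroma columns around the stromal archetype profile, with
    independent log2-space noise, so stromal-archetype genes are higher
    in stroma and planted mediators higher in epithelium.
    """
    _check_truth(config, truth)
    genes, _, epi, stro, _ = _archetype_profiles(config)
    rng = _rng(config, 2)
    n = config.n_microdissection_pairs
    epi_cols = [f"E{i:02d}" for i in range(1, n + 1)]
    stro_cols = [f"T{i:02d}" for i in range(1, n + 1)]
    epi_mat = np.tile(epi[:, None], (1, n))
    stro_mat = np.tile(stro[:, None], (1, n))
    if config.noise_sd > 0:
        epi_mat = epi_mat + rng.normal(0.0, config.noise_sd, epi_mat.shape)
        stro_mat = stro_mat + rng.normal(0.0, config.noise_sd, stro_mat.shape)
    return MicrodissectionSet(
        epithelium=pd.DataFrame(epi_mat, index=genes, columns=epi_cols),
        stroma=pd.DataFrame(stro_mat, index=genes, columns=stro_cols),
        pairing=list(zip(epi_cols, stro_cols)),
        log2=True,
    )


def generate_survival(config: SimConfig, truth: SyntheticTruth) -> pd.DataFrame:
    """Exponential event times with hazard tied to EMT activity.

    Per sample ``lambda_s = baseline_hazard * exp(hazard_coef * activity)``.
    Censoring is an independent exponential clock whose rate is set so the
    expected censored fraction is ``censor_rate``; with rate 0 every
    subject is observed to the event.
    """
    _check_truth(config, truth)
    rng = _rng(config, 3)
    activity = truth.emt_activity.to_numpy()
    hazard = config.baseline_hazard * np.exp(config.hazard_coef * activity)
    event_time = rng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        censor_hazard = config.censor_rate / (1.0 - config.censor_rate) * hazard.mean()
        censor_time = rng.exponential(1.0 / censor_hazard, size=event_time.shape)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    else:
        time = event_time
        event = np.ones(event_time.shape, dtype=int)
    return pd.DataFrame(
        {"time": time, "event": event}, index=truth.emt_activity.index
    )


def generate_cellline_panel(config: SimConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Pure tumor-cell expression panel with an EMT-prone subset.

    No stromal admixture: every line is drawn around the epithelial
    profile.  EMT-prone lines gain ``emt_marker_offset`` on the
    stromal-archetype (mesenchymal marker) block and
    ``emt_mediator_offset`` on the planted mediators.
    """
    genes, roles, epi, _, weight = _archetype_profiles(config)
    rng = _rng(config, 4)
    lines = pd.Index(
        [f"CL{i:02d}" for i in range(1, config.n_celllines + 1)], name="sample_id"
    )
    labels = np.array(["epithelial"] * config.n_celllines, dtype=object)
    labels[rng.choice(config.n_celllines, config.n_emt_prone, replace=False)] = "EMT_prone"
    mat = np.tile(epi[:, None], (1, config.n_celllines))
    prone = labels == "EMT_prone"
    # The EMT program is modelled as a two-axis continuum (partial-EMT
    # sub-programs): EMT-prone lines express both axes strongly with
    # line-to-line variation, the rest barely at all, and every marker /
    # mediator gene has its own pair of axis loadings.  A rank-one
    # program would be invisible to correlation distance after per-gene
    # standardization; the rank-two structure with heterogeneous
    # loadings is what marker-subset clustering actually reads.
    axes = np.where(
        prone[None, :],
        rng.normal(1.0, 0.3, (2, config.n_celllines)),
        rng.normal(0.0, 0.12, (2, config.n_celllines)),
    )
    loadings = rng.uniform(0.2, 1.3, (2, config.n_genes))
    is_arch = (roles == "stromal_archetype").to_numpy()
    is_medi = (roles == "planted_mediator").to_numpy()
    scale = np.zeros(config.n_genes)
    scale[is_arch] = config.emt_marker_offset
    scale[is_medi] = config.emt_mediator_offset
    signal = (loadings[0] * scale)[:, None] * axes[0] + (loadings[1] * scale)[:, None] * axes[1]
    mat += signal
    # gene-specific biological variability across lines, independent of
    # the EMT program: without it every marker gene's variance would be
    # dominated by its own program loading, and per-gene standardization
    # would flatten the group structure out of the correlation distance
    biological_sd = rng.uniform(0.3, 1.2, config.n_genes)
    mat += biological_sd[:, None] * rng.standard_normal(mat.shape)
    if config.noise_sd > 0:
        mat = mat + rng.normal(0.0, config.noise_sd, mat.shape)
    return pd.DataFrame(mat, index=genes, columns=lines), pd.Series(
        labels, index=lines, name="label"
    )


def clinical_cell_probabilities(config: SimConfig) -> np.ndarray:
    """Analytic 2x2 joint probabilities P(marker, covariate) implied by the
    configured prevalence, base rate and odds ratio (rows = marker 0/1,
    columns = covariate absent/present)."""
    p_m = config.marker_prevalence
    base_logit = np.log(config.covariate_base_rate / (1 - config.covariate_base_rate))
    probs = np.empty((2, 2))
    for m in (0, 1):
        p_x = 1.0 / (1.0 + np.exp(-(base_logit + np.log(config.covariate_odds_ratio) * m)))
        p_marker = p_m if m else 1 - p_m
        probs[m, 0] = p_marker * (1 - p_x)
        probs[m, 1] = p_marker * p_x
    return probs


def generate_clinical_table(config: SimConfig, n_patients: int | None = None) -> pd.DataFrame:
    """Per-patient clinical table: binary marker status, a binary covariate
    with the configured odds-ratio association to the marker, an
    independent categorical covariate, a continuous covariate, and
    survival columns in which the marker carries ``marker_hazard_ratio``.
    """
    rng = _rng(config, 5)
    n = int(n_patients) if n_patients is not None else config.n_bulk_samples
    marker = (rng.random(n) < config.marker_prevalence).astype(int)
    base_logit = np.log(config.covariate_base_rate / (1 - config.covariate_base_rate))
    p_x = 1.0 / (1.0 + np.exp(-(base_logit + np.log(config.covariate_odds_ratio) * marker)))
    risk_factor = np.where(rng.random(n) < p_x, "present", "absent")
    site = np.where(rng.random(n) < 0.7, "colon", "rectum")
    age = rng.normal(66.0, 12.0, n)
    hazard = config.baseline_hazard * config.marker_hazard_ratio**marker
    event_time = rng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        censor_hazard = config.censor_rate / (1.0 - config.censor_rate) * hazard.mean()
        censor_time = rng.exponential(1.0 / censor_hazard, size=n)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    else:
        time, event = event_time, np.ones(n, dtype=int)
    index = pd.Index([f"P{i:04d}" for i in range(1, n + 1)], name="patient_id")
    return pd.DataFrame(
        {
            "marker": marker,
            "risk_factor": risk_factor,
            "site": site,
            "age": age,
            "time": time,
            "event": event,
        },
        index=index,
    )


def write_cohort_tsvs(outdir, config: SimConfig) -> dict:
    """Generate the full synthetic input set and write it as TSVs.

    Returns the mapping of logical names to file paths.  Used by the
    ``simulate`` CLI subcommand.
    """
    from pathlib import Path

    from .io import write_expression_tsv, write_table_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config": config.to_dict()}
    bulk, truth = generate_cohort(config)
    micro = generate_microdissection(config, truth)
    survival = generate_survival(config, truth)
    panel, labels = generate_cellline_panel(config)
    clinical = generate_clinical_table(config)
    paths = {
        "bulk": outdir / "bulk_expression.tsv",
        "epithelium": outdir / "microdissection_epithelium.tsv",
        "stroma": outdir / "microdissection_stroma.tsv",
        "survival": outdir / "survival.tsv",
        "celllines": outdir / "cellline_expression.tsv",
        "cellline_labels": outdir / "cellline_labels.tsv",
        "clinical": outdir / "clinical.tsv",
        "truth_genes": outdir / "truth_gene_roles.tsv",
        "truth_samples": outdir / "truth_stromal_fraction.tsv",
    }
    write_expression_tsv(bulk, paths["bulk"], meta)
    write_expression_tsv(micro.epithelium, paths["epithelium"], meta)
    write_expression_tsv(micro.stroma, paths["stroma"], meta)
    write_table_tsv(survival, paths["survival"], meta)
    write_expression_tsv(panel, paths["celllines"], meta)
    write_table_tsv(labels.to_frame(), paths["cellline_labels"], meta)
    write_table_tsv(clinical, paths["clinical"], meta)
    write_table_tsv(truth.gene_role.to_frame(), paths["truth_genes"], meta)
    truth_samples = pd.concat([truth.stromal_fraction, truth.emt_activity], axis=1)
    write_table_tsv(truth_samples, paths["truth_samples"], meta)
    return {k: str(v) for k, v in paths.items()}
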
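"""Seeded generators producing synthetic inputs with known ground truth
for every downstream stage.

Expression counts are negative-binomial on a log-normal mean, with
regulator-target coupling imposed on the latent log2 scale and a
condition-specific coupling strength for planted "rewired" hubs.  Tracer
series follow the linear two-pool enrichment model.  Amplicon tables are
Dirichlet-multinomial with family-level fold enrichment in the treatment
group.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io
from .errors import ValidationError
from .expression import ExpressionMatrix
from .isotope import TracerSeries, atom_fraction_to_delta

# ---------------------------------------------------------------------------
# expression


@dataclass
class PlantedHub:
    """One rewired regulator: its targets follow the regulator's latent
    signal with strength ``coupling_1`` in condition 1 and ``coupling_2``
    in condition 2."""

    tf_index: int
    target_indices: list[int]
    coupling_1: float
    coupling_2: float


@dataclass
class ExpressionSimParams:
    n_tf: int = 20
    n_target_genes: int = 200
    n_background_genes: int = 100
    samples_per_condition: int = 6
    planted_hubs: list[PlantedHub] = field(default_factory=list)
    de_shift: float = 2.0  # log2-scale shift applied to target genes in condition 2
    dispersion: float = 0.02
    base_log_mean: float = 9.0  # log2 scale
    base_log_sd: float = 0.5
    depth_log_sd: float = 0.25  # log-normal spread of per-sample depth factors
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tf", "n_target_genes", "n_background_genes"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.samples_per_condition < 3:
            raise ValidationError(
                "samples_per_condition must be >= 3 (correlations undefined below)"
            )
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be positive")
        for hub in self.planted_hubs:
            if not 0 <= hub.tf_index < self.n_tf:
                raise ValidationError(f"hub tf_index {hub.tf_index} out of range")
            for t in hub.target_indices:
                if not 0 <= t < self.n_target_genes:
                    raise ValidationError(f"hub target index {t} out of range")
            for c in (hub.coupling_1, hub.coupling_2):
                if not -1.0 <= c <= 1.0:
                    raise ValidationError("couplings must lie in [-1, 1]")


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + dispersion * mu^2."""
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_expression(
    params: ExpressionSimParams,
) -> tuple[ExpressionMatrix, dict]:
    """Two-condition count matrix plus a ground-truth record.

    Target genes carry an expected condition-2 vs condition-1 log2 ratio of
    ``de_shift``; targets of planted hubs additionally track their hub's
    latent signal with the condition-specific coupling.
    """
    rng = np.random.default_rng(params.seed)
    n_per = params.samples_per_condition
    n_samples = 2 * n_per
    tf_ids = [f"tf_{i:03d}" for i in range(params.n_tf)]
    target_ids = [f"target_{i:04d}" for i in range(params.n_target_genes)]
    bg_ids = [f"bg_{i:04d}" for i in range(params.n_background_genes)]
    genes = tf_ids + target_ids + bg_ids
    samples = [f"c1_s{j}" for j in range(n_per)] + [f"c2_s{j}" for j in range(n_per)]
    cond2 = np.zeros(n_samples, dtype=bool)
    cond2[n_per:] = True

    # standardized latent signals
    z_tf = rng.standard_normal((params.n_tf, n_samples))
    z_target = rng.standard_normal((params.n_target_genes, n_samples))
    z_bg = rng.standard_normal((params.n_background_genes, n_samples))

    coupling = np.zeros((params.n_target_genes, n_samples))
    hub_of_target = np.full(params.n_target_genes, -1)
    for hub in params.planted_hubs:
        for t in hub.target_indices:
            if hub_of_target[t] != -1:
                raise ValidationError(f"target {t} assigned to two hubs")
            hub_of_target[t] = hub.tf_index
            coupling[t, ~cond2] = hub.coupling_1
            coupling[t, cond2] = hub.coupling_2

    for t in range(params.n_target_genes):
        h = hub_of_target[t]
        if h >= 0:
            c = coupling[t]
            z_target[t] = c * z_tf[h] + np.sqrt(1.0 - c**2) * z_target[t]

    mean = np.full((len(genes), n_samples), params.base_log_mean)
    mean[params.n_tf : params.n_tf + params.n_target_genes, cond2] += params.de_shift
    latent = mean + params.base_log_sd * np.vstack([z_tf, z_target, z_bg])

    depth = np.exp(rng.normal(0.0, params.depth_log_sd, size=n_samples))
    mu = depth[None, :] * 2.0**latent
    counts = _nb_counts(rng, mu, params.dispersion)

    values = pd.DataFrame(counts, index=genes, columns=samples)
    condition = pd.Series(np.where(cond2, 2, 1), index=samples, name="condition")
    is_tf = pd.Series([g in set(tf_ids) for g in genes], index=genes, name="is_tf")
    matrix = ExpressionMatrix(values=values, condition=condition, is_tf=is_tf)

    truth = {
        "planted_hub_tfs": [tf_ids[h.tf_index] for h in params.planted_hubs],
        "planted_hubs": [
            {
                "tf": tf_ids[h.tf_index],
                "targets": [target_ids[t] for t in h.target_indices],
                "coupling_1": h.coupling_1,
                "coupling_2": h.coupling_2,
            }
            for h in params.planted_hubs
        ],
        "de_genes": target_ids if params.de_shift != 0 else [],
        "de_shift": params.de_shift,
        "tf_ids": tf_ids,
        "background_genes": bg_ids,
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# tracer


@dataclass
class TracerSimParams:
    uptake_rate: float = 8.0e-10  # nmol substrate/cell/hr
    carbon_quota: float = 1.0e-6  # nmol C/cell
    carbons_per_molecule: int = 9
    x_base: float = 0.010852  # atom fraction of the unlabeled pool
    x_tracer: float = 0.99  # atom fraction of the tracer
    timepoints: tuple = (0.0, 15.0, 30.0, 60.0, 120.0)  # minutes
    n_replicates: int = 3
    noise_sd_permil: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.x_base < self.x_tracer <= 1.0:
            raise ValidationError("require 0 < x_base < x_tracer <= 1")
        if self.carbon_quota <= 0:
            raise ValidationError("carbon_quota must be positive")
        if self.noise_sd_permil < 0:
            raise ValidationError("noise_sd_permil must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("need at least one replicate")


def simulate_tracer_series(params: TracerSimParams) -> tuple[TracerSeries, float]:
    """Forward two-pool model: f(t) = rate * carbons * t / quota (capped at
    1, with a saturation note recorded), converted to delta13C with
    Gaussian measurement noise."""
    rng = np.random.default_rng(params.seed)
    t_min = np.repeat(np.asarray(params.timepoints, dtype=float), params.n_replicates)
    t_hr = t_min / 60.0
    f = params.uptake_rate * params.carbons_per_molecule * t_hr / params.carbon_quota
    notes = []
    if (f > 1.0).any():
        notes.append("saturation: tracer fraction capped at 1 for late timepoints")
        f = np.minimum(f, 1.0)
    x = params.x_base + f * (params.x_tracer - params.x_base)
    x = np.clip(x, 1e-12, 1 - 1e-12)
    delta = np.atleast_1d(atom_fraction_to_delta(x))
    delta = delta + rng.normal(0.0, params.noise_sd_permil, size=delta.shape)
    series = TracerSeries(
        time_min=t_min,
        delta_permil=delta,
        x_base=params.x_base,
        x_tracer=params.x_tracer,
        carbon_quota=params.carbon_quota,
        carbons_per_molecule=params.carbons_per_molecule,
        warnings_log=notes,
    )
    return series, params.uptake_rate


# ---------------------------------------------------------------------------
# amplicon community


@dataclass
class AsvSimParams:
    n_families: int = 10
    asvs_per_family: int = 4
    n_samples_per_group: int = 4
    base_concentrations: float = 50.0  # Dirichlet concentration per family
    enriched_families: list = field(default_factory=list)  # [(family_idx, fold), ...]
    depth_mean: float = 50_000.0
    depth_sd: float = 5_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families <= 0 or self.asvs_per_family <= 0:
            raise ValidationError("family/ASV counts must be positive")
        if self.n_samples_per_group < 1:
            raise ValidationError("need at least one sample per group")
        conc = np.atleast_1d(np.asarray(self.base_concentrations, dtype=float))
        if (conc <= 0).any():
            raise ValidationError("concentrations must be positive")
        for fam, fold in self.enriched_families:
            if not 0 <= fam < self.n_families:
                raise ValidationError(f"enriched family index {fam} out of range")
            if fold <= 0:
                raise ValidationError("fold-enrichment must be positive")
        if self.depth_mean <= 0:
            raise ValidationError("depth_mean must be positive")


def simulate_asv_table(params: AsvSimParams):
    """Dirichlet-multinomial ASV table with planted family enrichment.

    Returns the table (groups ``control`` and ``treatment``) and a ground
    truth record listing the enriched families and their ASV ids.
    """
    from .community import ASVTable

    rng = np.random.default_rng(params.seed)
    conc = np.atleast_1d(np.asarray(params.base_concentrations, dtype=float))
    if conc.size == 1:
        conc = np.full(params.n_families, conc[0])
    if conc.size != params.n_families:
        raise ValidationError("base_concentrations length must match n_families")

    asv_ids, families, genera = [], [], []
    for i in range(params.n_families):
        for j in range(params.asvs_per_family):
            asv_ids.append(f"asv_f{i:02d}_{j:02d}")
            families.append(f"family_{i:02d}")
            genera.append(f"family_{i:02d}_genus_{j:02d}")
    alpha_base = np.repeat(conc / params.asvs_per_family, params.asvs_per_family)

    alpha_trt = alpha_base.copy()
    for fam, fold in params.enriched_families:
        lo, hi = fam * params.asvs_per_family, (fam + 1) * params.asvs_per_family
        alpha_trt[lo:hi] *= fold

    # log-normal depth with the requested mean and sd
    cv2 = (params.depth_sd / params.depth_mean) ** 2
    sigma = np.sqrt(np.log1p(cv2))
    mu = np.log(params.depth_mean) - sigma**2 / 2.0

    samples, data, groups = [], [], []
    for label, alpha in (("control", alpha_base), ("treatment", alpha_trt)):
        for j in range(params.n_samples_per_group):
            name = f"{label}_s{j}"
            depth = max(int(round(np.exp(rng.normal(mu, sigma)))), 1)
            p = rng.dirichlet(alpha)
            data.append(rng.multinomial(depth, p))
            samples.append(name)
            groups.append(label)

    counts = pd.DataFrame(np.array(data).T, index=asv_ids, columns=samples)
    taxonomy = pd.DataFrame(
        {"family": families, "genus": genera}, index=pd.Index(asv_ids, name="asv")
    )
    group = pd.Series(groups, index=samples, name="group")
    table = ASVTable(counts=counts, taxonomy=taxonomy, group=group)
    truth = {
        "enriched_families": [
            {
                "family": f"family_{fam:02d}",
                "fold": fold,
                "asvs": [a for a, f in zip(asv_ids, families) if f == f"family_{fam:02d}"],
            }
            for fam, fold in params.enriched_families
        ]
    }
    return table, truth


# ---------------------------------------------------------------------------
# writers


def write_expression_dataset(
    matrix: ExpressionMatrix, truth: dict, outdir: str, pathways: dict | None = None
) -> None:
    """Emit the TSV dialects the pipeline reads plus a JSON truth sidecar."""
    os.makedirs(outdir, exist_ok=True)
    io.write_counts_tsv(matrix.values, os.path.join(outdir, "counts.tsv"))
    io.write_condition_map(
        matrix.condition.loc[matrix.samples], os.path.join(outdir, "conditions.tsv")
    )
    io.write_gene_list(
        [g for g in matrix.genes if matrix.is_tf[g]], os.path.join(outdir, "tfs.txt")
    )
    if pathways:
        io.write_pathways(pathways, os.path.join(outdir, "pathways.tsv"))
    with open(os.path.join(outdir, "truth.json"), "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)


def write_tracer_dataset(series: TracerSeries, rate: float, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    reps: dict[float, int] = {}
    rep_ids = []
    for t in series.time_min:
        reps[t] = reps.get(t, 0) + 1
        rep_ids.append(reps[t])
    df = pd.DataFrame(
        {
            "time_min": series.time_min,
            "replicate": rep_ids,
            "delta_permil": series.delta_permil,
        }
    )
    io.write_tracer_tsv(df, os.path.join(outdir, "tracer.tsv"))
    truth = {"uptake_rate": rate, "warnings": series.warnings_log}
    with open(os.path.join(outdir, "truth.json"), "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)


def write_asv_dataset(table, truth: dict, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    io.write_counts_tsv(table.counts, os.path.join(outdir, "asv_counts.tsv"), "asv")
    io.write_taxonomy(table.taxonomy, os.path.join(outdir, "taxonomy.tsv"))
    io.write_group_map(
        table.group.loc[table.counts.columns], os.path.join(outdir, "groups.tsv")
    )
    with open(os.path.join(outdir, "truth.json"), "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
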
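"""Synthetic multi-modal melanoma-organoid cohorts with planted effects.

Every downstream stage of the package (fidelity, signature discovery,
scoring, survival, spatial rules, TCR clonality) can be exercised end-to-end
on cohorts generated here, with ground truth known by construction:

* paired metastasis / organoid transcriptomes sharing a per-patient signal;
* a T-cell activation program induced on stimulation only in cultures from
  ICB responders (CCL1, ICOS, CTLA4, CXCL13, TNFRSF4/OX40 plus generated
  gene names);
* single-cell counts in which the planted program is expressed (essentially)
  only in T cells;
* TCR repertoires with clonal expansion restricted to stimulated responder
  cultures, coupled to the bulk T-cell marker level;
* spatial arms in which tumor MHC-I (B2M) decays with distance to immune
  cells (responder) or is uniformly lost (resistant);
* a validation cohort with pre/on-treatment pairs and survival hazards tied
  to the planted signature score.

Each modality draws from its own seed sub-stream, so modalities can be
regenerated independently yet reproducibly from one root seed.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse

from .errors import DomainError
from .types import (
    CloneTable,
    ExpressionMatrix,
    GenePositionTable,
    SampleMetadata,
    SpatialCellTable,
)

# fixed sub-stream indices per modality
_STREAM_BULK = 1
_STREAM_CELLS = 2
_STREAM_CLONES = 3
_STREAM_SPATIAL = 4
_STREAM_TCELL_LEVELS = 5
_STREAM_VALIDATION = 6

DEFAULT_SIGNATURE_SEED_GENES = ("CCL1", "ICOS", "CTLA4", "CXCL13", "TNFRSF4")

HOUSEKEEPING_GENES = ("ACTB", "GAPDH", "RPL13A", "PPIA", "TBP", "UBC")

_TYPE_MARKERS = {
    "T_cell": ("CD3D", "CD3E", "CD3G", "CD2", "CD5", "TRAC",
               "CD8A", "CD8B", "GZMA", "GZMB", "PRF1", "NKG7", "KLRD1"),
    "B_cell": ("CD19", "MS4A1", "CD79A", "CD79B", "IGHM"),
    "myeloid": ("CD14", "CD163", "CSF1R", "FCGR3A", "ITGAM", "CD1C", "FLT3",
                "CLEC10A", "FCGR3B", "CSF3R", "S100A8", "S100A9"),
    "melanoma": ("SOX10", "MITF", "TYR", "PMEL", "MLANA", "NGFR", "AXL"),
    "fibroblast": ("COL1A1", "COL1A2", "COL3A1", "DCN", "PDGFRB", "FAP"),
    "endothelial": ("PECAM1", "VWF", "CDH5", "KDR"),
}

STROMAL_MARKER_GENES = tuple(
    _TYPE_MARKERS["myeloid"][:5] + _TYPE_MARKERS["fibroblast"] + _TYPE_MARKERS["endothelial"]
)

_OTHER_NAMED = ("HLA-A", "HLA-B", "HLA-C", "B2M", "TAP1", "NCR1", "KLRC1", "KIR2DL3")


@dataclass
class SpatialConfig:
    """Per-arm layout of the synthetic CosMx-like panel."""

    n_tumor_cells: int = 400
    n_immune_other: int = 150       # T/B/myeloid cells beyond the CD8 pool
    n_stromal_cells: int = 100
    n_cd8_responder: int = 261      # CD8 pool sizes mirror the two profiled lesions
    n_cd8_resistant: int = 20
    n_immune_clusters: int = 3
    field_um: float = 1000.0
    cluster_sd_um: float = 50.0
    b2m_scale: float = 40.0         # peak tumor B2M mean count (responder arm)
    b2m_decay_um: float = 75.0      # exponential decay length of B2M with immune distance
    b2m_resistant_mean: float = 0.2
    melanin_mean: float = 3.0
    melanin_zero_prob_responder: float = 0.1
    melanin_zero_prob_resistant: float = 0.7
    checkpoint_mean_responder: float = 4.0
    checkpoint_mean_resistant: float = 0.05


@dataclass
class SimulationConfig:
    seed: int = 0
    n_patients: int = 8                 # split half responder / half non-responder
    n_genes: int = 2000
    signature_size: int = 14
    signature_genes: Optional[list[str]] = None
    induction_lfc: float = 2.0          # log2 FC planted in stimulated responder cultures
    tumor_pdo_noise_sd: float = 0.4     # log2 noise between matched tissues
    between_patient_sd: float = 1.2     # log2 patient effect
    residual_sd: float = 0.2
    baseline_mean: float = 3.0
    baseline_sd: float = 1.5
    stroma_tumor_lfc: float = 1.0       # stromal/monocytic elevation in metastases
    tcell_coupling: float = 1.0         # T-cell marker shift per log2 of T-cell level
    tcell_level_sd: float = 0.7         # lognormal sd of per-patient T-cell abundance
    n_cells_per_type: int = 300
    exclusivity_leak: float = 0.005
    n_clones: int = 200
    n_expanded_clones: int = 15
    clone_expansion_factor: float = 5.0
    n_validation_patients: int = 300
    responder_fraction: float = 0.5
    score_effect: float = 2.0           # log2 shift of signature genes per SD of planted score
    hazard_ratio_high_vs_low: float = 0.4
    baseline_hazard: float = 0.06       # events per month in the low tertile
    censor_horizon: float = 60.0        # months
    spatial: SpatialConfig = field(default_factory=SpatialConfig)

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_genes", "signature_size", "n_cells_per_type",
                     "n_clones", "n_validation_patients"):
            if getattr(self, name) < 1:
                raise DomainError(f"{name} must be a positive count")
        if self.induction_lfc < 0:
            raise DomainError("induction_lfc must be >= 0")
        if not 0 <= self.exclusivity_leak <= 1:
            raise DomainError("exclusivity_leak must be in [0, 1]")
        if self.n_patients < 2:
            raise DomainError("need >= 2 patients")
        if isinstance(self.spatial, dict):
            self.spatial = SpatialConfig(**self.spatial)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery experiments."""

    signature_genes: list[str] = field(default_factory=list)
    patient_response: dict = field(default_factory=dict)
    tcell_levels: dict = field(default_factory=dict)          # patient -> level
    planted_scores: dict = field(default_factory=dict)        # validation patient -> latent score
    planted_tertiles: dict = field(default_factory=dict)      # validation patient -> low/mid/high
    planted_hazards: dict = field(default_factory=dict)       # validation patient -> rate/month
    spatial_truth: Optional[pd.DataFrame] = None              # per-cell planted state

    def to_dict(self) -> dict:
        d = {
            "signature_genes": self.signature_genes,
            "patient_response": self.patient_response,
            "tcell_levels": {k: float(v) for k, v in self.tcell_levels.items()},
            "planted_scores": {k: float(v) for k, v in self.planted_scores.items()},
            "planted_tertiles": self.planted_tertiles,
            "planted_hazards": {k: float(v) for k, v in self.planted_hazards.items()},
        }
        if self.spatial_truth is not None:
            d["spatial_truth"] = self.spatial_truth.to_dict(orient="list")
        return d


# ---------------------------------------------------------------------------
# gene universe

def signature_gene_names(config: SimulationConfig) -> list[str]:
    if config.signature_genes is not None:
        genes = list(config.signature_genes)
        if len(genes) != config.signature_size:
            raise DomainError("signature_genes length must equal signature_size")
        return genes
    genes = list(DEFAULT_SIGNATURE_SEED_GENES[: config.signature_size])
    i = len(genes) + 1
    while len(genes) < config.signature_size:
        genes.append(f"TSIG{i:02d}")
        i += 1
    return genes


def gene_universe(config: SimulationConfig) -> list[str]:
    """Deterministic gene-id list: named marker/housekeeping/signature genes
    first, then generated identifiers up to n_genes."""
    named: list[str] = []
    for g in signature_gene_names(config):
        if g not in named:
            named.append(g)
    for group in _TYPE_MARKERS.values():
        for g in group:
            if g not in named:
                named.append(g)
    for g in HOUSEKEEPING_GENES + _OTHER_NAMED:
        if g not in named:
            named.append(g)
    if config.n_genes < len(named):
        raise DomainError(f"n_genes must be >= {len(named)} to hold the named genes")
    filler = [f"G{i:05d}" for i in range(1, config.n_genes - len(named) + 1)]
    return named + filler


def patient_ids(config: SimulationConfig) -> list[str]:
    return [f"P{i:02d}" for i in range(1, config.n_patients + 1)]


def patient_responses(config: SimulationConfig) -> dict[str, str]:
    pats = patient_ids(config)
    n_resp = config.n_patients // 2
    return {p: ("responder" if i < n_resp else "non_responder")
            for i, p in enumerate(pats)}


def tcell_levels(config: SimulationConfig) -> dict[str, float]:
    """Per-patient latent T-cell abundance (lognormal), shared between the
    bulk and clone generators so clonality and expression stay coupled."""
    rng = np.random.default_rng([config.seed, _STREAM_TCELL_LEVELS])
    pats = patient_ids(config)
    levels = np.exp(rng.normal(0.0, config.tcell_level_sd, len(pats)))
    return dict(zip(pats, levels))


# ---------------------------------------------------------------------------
# bulk cohort

def simulate_bulk(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, list[SampleMetadata], GroundTruth]:
    """Metastasis + baseline PDO + stimulated PDO per patient.

    Log2 expression = gene baseline + patient effect + tissue noise
    + stromal elevation (metastasis only) + T-cell-marker coupling (PDO)
    + induction (signature genes, stimulated responder PDOs)
    + residual noise; exported on raw scale as 2^x - 1 floored at 0.
    """
    rng = np.random.default_rng([config.seed, _STREAM_BULK])
    genes = gene_universe(config)
    sig = signature_gene_names(config)
    pats = patient_ids(config)
    responses = patient_responses(config)
    levels = tcell_levels(config)

    n_g = len(genes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, n_g)
    patient_effect = rng.normal(0.0, config.between_patient_sd, (n_g, len(pats)))

    sig_idx = np.array([gene_idx[g] for g in sig])
    stroma_idx = np.array([gene_idx[g] for g in STROMAL_MARKER_GENES if g in gene_idx])
    tcell_idx = np.array([gene_idx[g] for g in _TYPE_MARKERS["T_cell"]])

    columns: dict[str, np.ndarray] = {}
    metadata: list[SampleMetadata] = []
    for j, pat in enumerate(pats):
        resp = responses[pat]
        log_level = np.log2(levels[pat])
        for kind in ("MET", "PDO_B", "PDO_S"):
            x = baseline + patient_effect[:, j]
            x = x + rng.normal(0.0, config.tumor_pdo_noise_sd, n_g)
            if kind == "MET":
                x[stroma_idx] += config.stroma_tumor_lfc
            else:
                x[tcell_idx] += config.tcell_coupling * log_level
            if kind == "PDO_S" and resp == "responder":
                x[sig_idx] += config.induction_lfc
            x = x + rng.normal(0.0, config.residual_sd, n_g)
            sample_id = f"{pat}_{kind}"
            columns[sample_id] = np.maximum(np.exp2(x) - 1.0, 0.0)
            metadata.append(SampleMetadata(
                sample_id=sample_id,
                patient_id=pat,
                tissue="metastasis" if kind == "MET" else "pdo",
                culture_type="none" if kind == "MET" else "semi_solid",
                timepoint={"MET": "none", "PDO_B": "baseline", "PDO_S": "stimulated"}[kind],
                response=resp,
            ))
    values = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
    truth = GroundTruth(signature_genes=list(sig), patient_response=dict(responses),
                        tcell_levels={p: float(levels[p]) for p in pats})
    return ExpressionMatrix(values, scale="raw"), metadata, truth


def synthetic_gene_positions(gene_ids: Sequence[str], n_chromosomes: int = 22) -> GenePositionTable:
    """Assign genes to contiguous blocks on chr1..chrN (1-based, 1 kb loci)."""
    n = len(gene_ids)
    per = int(np.ceil(n / n_chromosomes))
    rows = []
    for i, g in enumerate(gene_ids):
        chrom = i // per + 1
        within = i % per
        start = within * 1000 + 1
        rows.append({"gene_id": g, "chromosome": f"chr{chrom}",
                     "start": start, "end": start + 999})
    return GenePositionTable(pd.DataFrame(rows))


def apply_copy_number_change(
    matrix: ExpressionMatrix,
    positions: GenePositionTable,
    samples: Sequence[str],
    chromosomes: Sequence[str],
    log2_ratio: float = -1.0,
) -> ExpressionMatrix:
    """Scale raw expression of all genes on given chromosomes in given
    samples by 2**log2_ratio (e.g. -1 halves them: a one-copy loss)."""
    if matrix.scale != "raw":
        raise DomainError("apply_copy_number_change expects a raw-scale matrix")
    genes = positions.positions.loc[
        positions.positions["chromosome"].isin(chromosomes), "gene_id"]
    genes = [g for g in genes if g in matrix.values.index]
    values = matrix.values.copy()
    values.loc[genes, list(samples)] *= 2.0 ** log2_ratio
    return ExpressionMatrix(values, scale="raw")


# ---------------------------------------------------------------------------
# single-cell cohort

def simulate_cells(config: SimulationConfig) -> ad.AnnData:
    """Labeled single-cell counts with T-cell-exclusive signature expression.

    Negative-binomial counts; signature genes are detected in well over half
    of T cells and leak into other types with probability
    ``exclusivity_leak``; housekeeping genes are detected broadly; canonical
    type markers are enriched in their own compartment.
    """
    rng = np.random.default_rng([config.seed, _STREAM_CELLS])
    sig = signature_gene_names(config)
    types = ("T_cell", "B_cell", "myeloid", "melanoma", "fibroblast", "endothelial")
    genes: list[str] = list(sig)
    for group in _TYPE_MARKERS.values():
        genes += [g for g in group if g not in genes]
    genes += [g for g in HOUSEKEEPING_GENES if g not in genes]
    n_per = config.n_cells_per_type
    n_cells = n_per * len(types)
    counts = np.zeros((n_cells, len(genes)), dtype=np.int64)
    cell_types: list[str] = []
    gidx = {g: i for i, g in enumerate(genes)}
    hk_idx = [gidx[g] for g in HOUSEKEEPING_GENES]
    sig_idx = [gidx[g] for g in sig]
    for t_i, ctype in enumerate(types):
        rows = slice(t_i * n_per, (t_i + 1) * n_per)
        # housekeeping: NB mean 5, dispersion n=2
        counts[rows, :][:, hk_idx] = rng.negative_binomial(2, 2 / 7, (n_per, len(hk_idx)))
        # own markers: NB mean 3, elsewhere rare leak
        for m_type, markers in _TYPE_MARKERS.items():
            m_idx = [gidx[g] for g in markers]
            block = np.zeros((n_per, len(m_idx)), dtype=np.int64)
            if m_type == ctype:
                block = rng.negative_binomial(2, 2 / 5, (n_per, len(m_idx)))
            else:
                block = (rng.random((n_per, len(m_idx))) < 0.02).astype(np.int64)
            counts[rows, :][:, m_idx] = np.maximum(counts[rows, :][:, m_idx], block)
        # signature genes: expressed in T cells, leaking elsewhere
        if ctype == "T_cell":
            block = rng.negative_binomial(1, 1 / 3, (n_per, len(sig_idx)))  # P(detect)~2/3
        else:
            detected = rng.random((n_per, len(sig_idx))) < config.exclusivity_leak
            block = detected * (1 + rng.poisson(0.5, (n_per, len(sig_idx))))
        counts[rows, :][:, sig_idx] = block
        cell_types += [ctype] * n_per
    obs = pd.DataFrame({
        "cell_type": cell_types,
        "origin": "synthetic_reference",
    }, index=pd.Index([f"cell{i:05d}" for i in range(n_cells)], name="barcode"))
    adata = ad.AnnData(
        X=scipy.sparse.csr_matrix(counts),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
    )
    return adata


# ---------------------------------------------------------------------------
# TCR repertoires

def simulate_clones(config: SimulationConfig) -> CloneTable:
    """Power-law repertoires per PDO sample; stimulated responder samples
    additionally expand a random subset of clonotypes."""
    if config.n_clones < 1:
        raise DomainError("n_clones must be >= 1")
    rng = np.random.default_rng([config.seed, _STREAM_CLONES])
    responses = patient_responses(config)
    levels = tcell_levels(config)
    rows = []
    for pat in patient_ids(config):
        n_pool = max(3, int(round(config.n_clones * levels[pat])))
        clonotypes = [f"{pat}_CL{j:04d}" for j in range(n_pool)]
        for kind, sample in (("baseline", f"{pat}_PDO_B"), ("stimulated", f"{pat}_PDO_S")):
            counts = np.minimum(rng.zipf(2.5, n_pool), 10_000).astype(np.int64)
            if kind == "stimulated" and responses[pat] == "responder":
                k = min(config.n_expanded_clones, n_pool)
                expanded = rng.choice(n_pool, size=k, replace=False)
                counts[expanded] = np.maximum(
                    1, np.round(counts[expanded] * config.clone_expansion_factor)
                ).astype(np.int64)
            rows += [{"sample": sample, "clonotype": c, "count": int(n)}
                     for c, n in zip(clonotypes, counts)]
    return CloneTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# spatial arms

def _spatial_arm(
    rng: np.random.Generator,
    config: SimulationConfig,
    arm: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    sp = config.spatial
    n_cd8 = sp.n_cd8_responder if arm == "responder" else sp.n_cd8_resistant
    centers = rng.uniform(0.15 * sp.field_um, 0.85 * sp.field_um,
                          (sp.n_immune_clusters, 2))

    def clustered(n: int) -> np.ndarray:
        which = rng.integers(0, sp.n_immune_clusters, n)
        return centers[which] + rng.normal(0, sp.cluster_sd_um, (n, 2))

    rows = []
    cid = 0

    def add_cells(n: int, ctype: str, xy: np.ndarray) -> list[int]:
        nonlocal cid
        idx = []
        for i in range(n):
            rows.append({"cell_id": f"{arm}_c{cid:05d}", "x": float(xy[i, 0]),
                         "y": float(xy[i, 1]), "cell_type": ctype, "sample_id": arm})
            idx.append(cid)
            cid += 1
        return idx

    add_cells(n_cd8, "CD8_T", clustered(n_cd8))
    per = sp.n_immune_other // 3
    add_cells(per, "T_cell", clustered(per))
    add_cells(per, "B_cell", clustered(per))
    add_cells(sp.n_immune_other - 2 * per, "myeloid", clustered(sp.n_immune_other - 2 * per))
    n_imm = cid
    add_cells(sp.n_tumor_cells, "melanoma",
              rng.uniform(0, sp.field_um, (sp.n_tumor_cells, 2)))
    half = sp.n_stromal_cells // 2
    add_cells(half, "fibroblast", rng.uniform(0, sp.field_um, (half, 2)))
    add_cells(sp.n_stromal_cells - half, "endothelial",
              rng.uniform(0, sp.field_um, (sp.n_stromal_cells - half, 2)))

    df = pd.DataFrame(rows)
    panel_genes = ("B2M", "MITF", "TYR", "MLANA", "PMEL",
                   "PDCD1", "LAG3", "TIGIT", "HAVCR2")
    for g in panel_genes:
        df[g] = 0

    imm_xy = df.loc[df.index[:n_imm], ["x", "y"]].to_numpy()
    tumor = df["cell_type"] == "melanoma"
    tumor_xy = df.loc[tumor, ["x", "y"]].to_numpy()
    d = np.sqrt(((tumor_xy[:, None, :] - imm_xy[None, :, :]) ** 2).sum(-1)).min(axis=1)

    truth_rows = []
    # tumor B2M: proximity-decaying (responder) or uniformly low (resistant)
    if arm == "responder":
        b2m_mean = sp.b2m_scale * np.exp(-d / sp.b2m_decay_um)
    else:
        b2m_mean = np.full(len(d), sp.b2m_resistant_mean)
    df.loc[tumor, "B2M"] = rng.poisson(b2m_mean)
    # immune/stromal B2M is ubiquitous but irrelevant to the tumor classifier
    df.loc[~tumor, "B2M"] = rng.poisson(8.0, (~tumor).sum())

    zero_p = (sp.melanin_zero_prob_responder if arm == "responder"
              else sp.melanin_zero_prob_resistant)
    melanin_zero = rng.random(tumor.sum()) < zero_p
    for g in ("MITF", "TYR", "MLANA", "PMEL"):
        vals = rng.poisson(sp.melanin_mean, tumor.sum())
        vals[melanin_zero] = 0
        df.loc[tumor, g] = vals

    cp_mean = (sp.checkpoint_mean_responder if arm == "responder"
               else sp.checkpoint_mean_resistant)
    cd8 = df["cell_type"] == "CD8_T"
    other_t = df["cell_type"] == "T_cell"
    for g in ("PDCD1", "LAG3", "TIGIT", "HAVCR2"):
        df.loc[cd8, g] = rng.poisson(cp_mean, cd8.sum())
        df.loc[other_t, g] = rng.poisson(min(cp_mean, 0.5), other_t.sum())

    truth = pd.DataFrame({
        "cell_id": df.loc[tumor, "cell_id"].to_numpy(),
        "arm": arm,
        "planted_b2m_mean": b2m_mean,
        "planted_melanin_zero": melanin_zero,
        "immune_distance": d,
    })
    return df, truth


def simulate_spatial(config: SimulationConfig) -> tuple[dict[str, SpatialCellTable], GroundTruth]:
    """Responder and resistant arms of the spatial panel."""
    rng = np.random.default_rng([config.seed, _STREAM_SPATIAL])
    arms = {}
    truths = []
    for arm in ("responder", "resistant"):
        df, truth = _spatial_arm(rng, config, arm)
        arms[arm] = SpatialCellTable(df)
        truths.append(truth)
    gt = GroundTruth(spatial_truth=pd.concat(truths, ignore_index=True))
    return arms, gt


# ---------------------------------------------------------------------------
# validation cohort (pre/on pairs + survival)

def planted_tertiles(scores: dict[str, float]) -> dict[str, str]:
    """Rank-based thirds, remainder to the low tertile, ties broken by id."""
    items = sorted(scores.items(), key=lambda kv: (kv[1], kv[0]))
    n = len(items)
    base, rem = divmod(n, 3)
    n_low = base + (1 if rem >= 1 else 0)
    n_mid = base + (1 if rem >= 2 else 0)
    out = {}
    for i, (pat, _) in enumerate(items):
        out[pat] = "low" if i < n_low else ("mid" if i < n_low + n_mid else "high")
    return out


def simulate_validation(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, list[SampleMetadata], GroundTruth]:
    """ICB validation cohort: paired pre/on-treatment transcriptomes plus
    survival outcomes whose hazard is tied to the planted signature score.

    Each patient carries a latent score u ~ N(0,1); signature genes are
    shifted by ``score_effect * u`` in both samples, responders additionally
    receive the activation program in their on-treatment sample. Survival is
    exponential with per-tertile hazard (low tertile = baseline_hazard, high
    tertile = baseline_hazard * hazard_ratio_high_vs_low), censored
    uniformly on [0, censor_horizon].
    """
    rng = np.random.default_rng([config.seed, _STREAM_VALIDATION])
    genes = gene_universe(config)
    sig = signature_gene_names(config)
    n_g = len(genes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    sig_idx = np.array([gene_idx[g] for g in sig])

    n = config.n_validation_patients
    if n < 3:
        raise DomainError("n_validation_patients must be >= 3")
    pats = [f"V{i:04d}" for i in range(1, n + 1)]
    n_resp = int(round(n * config.responder_fraction))
    responses = {p: ("responder" if i < n_resp else "non_responder")
                 for i, p in enumerate(pats)}
    u = rng.normal(0.0, 1.0, n)
    scores = dict(zip(pats, u))
    tertiles = planted_tertiles(scores)
    hr = config.hazard_ratio_high_vs_low
    tert_hazard = {"low": config.baseline_hazard,
                   "mid": config.baseline_hazard * np.sqrt(hr),
                   "high": config.baseline_hazard * hr}

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, n_g)
    columns: dict[str, np.ndarray] = {}
    metadata: list[SampleMetadata] = []
    hazards = {}
    for i, pat in enumerate(pats):
        patient_effect = rng.normal(0.0, config.between_patient_sd, n_g)
        lam = tert_hazard[tertiles[pat]]
        hazards[pat] = lam
        t_event = rng.exponential(1.0 / lam)
        t_cens = rng.uniform(0.0, config.censor_horizon)
        time = float(min(t_event, t_cens))
        event = int(t_event <= t_cens)
        for tp, tag in (("pre_treatment", "PRE"), ("on_treatment", "ON")):
            x = baseline + patient_effect + rng.normal(0.0, config.residual_sd, n_g)
            x[sig_idx] += config.score_effect * u[i]
            if tp == "on_treatment" and responses[pat] == "responder":
                x[sig_idx] += config.induction_lfc
            sample_id = f"{pat}_{tag}"
            columns[sample_id] = np.maximum(np.exp2(x) - 1.0, 0.0)
            metadata.append(SampleMetadata(
                sample_id=sample_id, patient_id=pat, tissue="metastasis",
                culture_type="none", timepoint=tp, response=responses[pat],
                survival_time=time if tp == "pre_treatment" else None,
                survival_event=event if tp == "pre_treatment" else None,
            ))
    values = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
    truth = GroundTruth(
        signature_genes=list(sig),
        patient_response=responses,
        planted_scores={p: float(scores[p]) for p in pats},
        planted_tertiles=tertiles,
        planted_hazards={p: float(hazards[p]) for p in pats},
    )
    return ExpressionMatrix(values, scale="raw"), metadata, truth
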
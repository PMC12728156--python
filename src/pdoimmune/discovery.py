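"""T-cell activation signature discovery.

The discovery recipe: (1) per-patient log2 fold changes between baseline and
T-cell-stimulated organoid cultures; (2) keep genes consistently induced in
cultures from ICB responders but flat in non-responders; (3) keep only genes
that single-cell data show to be expressed (essentially) exclusively in
T cells. The surviving genes form a T-cell-specific activation signature.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse

from .errors import DomainError
from .types import ExpressionMatrix, GeneSet, SampleMetadata, metadata_to_frame

logger = logging.getLogger(__name__)


@dataclass
class FoldChangeTable:
    """Genes x patients log2 fold changes (stimulated vs baseline) with
    response-group means."""

    lfc: pd.DataFrame                  # genes x patients
    patient_response: pd.Series        # patient -> responder / non_responder
    responder_mean: pd.Series = field(init=False)
    nonresponder_mean: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        resp = self.patient_response
        r = resp.index[resp == "responder"]
        nr = resp.index[resp == "non_responder"]
        self.responder_mean = self.lfc[list(r)].mean(axis=1) if len(r) else pd.Series(
            np.nan, index=self.lfc.index)
        self.nonresponder_mean = self.lfc[list(nr)].mean(axis=1) if len(nr) else pd.Series(
            np.nan, index=self.lfc.index)


def paired_fold_change(
    matrix: ExpressionMatrix,
    metadata: Sequence[SampleMetadata],
    pseudocount: float = 1.0,
) -> FoldChangeTable:
    """Per-gene, per-patient log2((stimulated + 1) / (baseline + 1)) on raw
    abundances, for patients with exactly one sample at each timepoint."""
    if matrix.scale != "raw":
        raise DomainError("paired_fold_change expects a raw-scale matrix")
    meta = metadata_to_frame(metadata)
    meta = meta.loc[meta["sample_id"].isin(matrix.sample_ids) & (meta["tissue"] == "pdo")]
    cols = {}
    responses = {}
    for patient, grp in meta.groupby("patient_id"):
        base = grp.loc[grp["timepoint"] == "baseline", "sample_id"]
        stim = grp.loc[grp["timepoint"] == "stimulated", "sample_id"]
        if len(base) != 1 or len(stim) != 1:
            logger.warning("patient %s lacks a unique baseline/stimulated pair; skipped",
                           patient)
            continue
        b = matrix.values[base.iloc[0]] + pseudocount
        s = matrix.values[stim.iloc[0]] + pseudocount
        cols[patient] = np.log2(s / b)
        responses[patient] = grp["response"].iloc[0]
    if not cols:
        raise DomainError("no patient has both a baseline and a stimulated PDO sample")
    lfc = pd.DataFrame(cols)
    return FoldChangeTable(lfc=lfc, patient_response=pd.Series(responses))


def select_upregulated(
    fc: FoldChangeTable,
    min_responder_lfc: float = 1.0,
    min_responder_fraction: float = 0.75,
    max_nonresponder_lfc: float = 0.5,
) -> GeneSet:
    """Genes induced on stimulation in responders and flat in non-responders.

    A gene is selected iff its responder mean lfc >= ``min_responder_lfc``,
    it is induced (lfc > 0) in at least ``min_responder_fraction`` of
    responder patients, and its non-responder mean lfc stays below
    ``max_nonresponder_lfc``.
    """
    resp = fc.patient_response
    responders = list(resp.index[resp == "responder"])
    nonresponders = list(resp.index[resp == "non_responder"])
    if len(responders) < 2 or len(nonresponders) < 1:
        raise DomainError("need >= 2 responder and >= 1 non-responder patients")
    r = fc.lfc[responders]
    keep = (
        (r.mean(axis=1) >= min_responder_lfc)
        & ((r > 0).mean(axis=1) >= min_responder_fraction)
        & (fc.lfc[nonresponders].mean(axis=1) < max_nonresponder_lfc)
    )
    genes = sorted(fc.lfc.index[keep])
    if not genes:
        logger.warning("no gene passed the upregulation filter; returning empty candidate set")
    return GeneSet(name="upregulated_candidates", genes=genes,
                   description="responder-specific induced genes")


@dataclass
class ExclusivityStats:
    table: pd.DataFrame  # per gene: tcell_fraction, max_other_fraction, max_other_type, exclusive


def detection_fractions(cells: ad.AnnData, genes: Sequence[str]) -> pd.DataFrame:
    """Per cell type, the fraction of cells with count > 0 per gene."""
    present = [g for g in genes if g in cells.var_names]
    x = cells[:, present].X
    dense = x.toarray() if scipy.sparse.issparse(x) else np.asarray(x)
    detected = pd.DataFrame(dense > 0, columns=present, index=cells.obs_names)
    detected["cell_type"] = cells.obs["cell_type"].values
    return detected.groupby("cell_type", observed=True).mean()


def tcell_exclusivity(
    candidates: GeneSet,
    cells: ad.AnnData,
    min_tcell_detection: float = 0.10,
    max_other_detection: float = 0.02,
    tcell_labels: Sequence[str] = ("T_cell", "CD8_T"),
) -> tuple[GeneSet, ExclusivityStats]:
    """Restrict candidates to genes expressed exclusively in T cells.

    A gene survives iff its detection fraction (count > 0) across T cells is
    >= ``min_tcell_detection`` and its detection fraction in every other
    cell type is <= ``max_other_detection``.
    """
    genes = list(candidates.genes)
    if not genes:
        raise DomainError("empty candidate set")
    types = set(map(str, cells.obs["cell_type"].unique()))
    if not (types & set(tcell_labels)):
        raise DomainError("no T cells present in the cell matrix")
    if len(types) < 2:
        raise DomainError("need >= 2 distinct cell types")
    present = [g for g in genes if g in cells.var_names]
    absent = sorted(set(genes) - set(present))
    if absent:
        logger.warning("exclusivity filter: %d candidates absent from cell matrix: %s",
                       len(absent), absent)
    frac = detection_fractions(cells, present)
    tmask = frac.index.isin(tcell_labels)
    tcell_frac = frac.loc[tmask].max(axis=0)
    other = frac.loc[~tmask]
    rows = []
    kept = []
    for g in present:
        tf = float(tcell_frac[g])
        mo = float(other[g].max()) if len(other) else 0.0
        mo_type = other[g].idxmax() if len(other) else ""
        exclusive = tf >= min_tcell_detection and mo <= max_other_detection
        rows.append({"gene": g, "tcell_fraction": tf, "max_other_fraction": mo,
                     "max_other_type": mo_type, "exclusive": exclusive})
        if exclusive:
            kept.append(g)
    columns = ["gene", "tcell_fraction", "max_other_fraction", "max_other_type",
               "exclusive"]
    stats = ExclusivityStats(pd.DataFrame(rows, columns=columns).set_index("gene"))
    if not kept:
        logger.warning("no candidate gene is T-cell exclusive")
    sig = GeneSet(name="tcell_signature", genes=sorted(kept),
                  description="T-cell-specific activation signature")
    return sig, stats


@dataclass
class DiscoveryParams:
    min_responder_lfc: float = 1.0
    min_responder_fraction: float = 0.75
    max_nonresponder_lfc: float = 0.5
    min_tcell_detection: float = 0.10
    max_other_detection: float = 0.02


@dataclass
class SignatureResult:
    signature: GeneSet
    candidates: GeneSet
    fold_changes: FoldChangeTable
    exclusivity: ExclusivityStats
    params: DiscoveryParams

    @property
    def signature_genes(self) -> list[str]:
        return list(self.signature.genes)

    def to_json(self) -> str:
        return json.dumps({
            "signature": self.signature_genes,
            "candidates": list(self.candidates.genes),
            "params": vars(self.params),
            "responder_mean_lfc": {
                g: float(self.fold_changes.responder_mean[g]) for g in self.signature_genes
            },
            "exclusivity": {
                g: {
                    "tcell_fraction": float(self.exclusivity.table.loc[g, "tcell_fraction"]),
                    "max_other_fraction": float(self.exclusivity.table.loc[g, "max_other_fraction"]),
                }
                for g in self.signature_genes
            },
        }, indent=2, sort_keys=True)


def discover_signature(
    matrix: ExpressionMatrix,
    metadata: Sequence[SampleMetadata],
    cells: ad.AnnData,
    params: Optional[DiscoveryParams] = None,
) -> SignatureResult:
    """Full discovery pipeline: paired fold change -> responder-specific
    selection -> T-cell exclusivity; deterministic with full provenance."""
    params = params or DiscoveryParams()
    fc = paired_fold_change(matrix, metadata)
    candidates = select_upregulated(
        fc,
        min_responder_lfc=params.min_responder_lfc,
        min_responder_fraction=params.min_responder_fraction,
        max_nonresponder_lfc=params.max_nonresponder_lfc,
    )
    if not candidates.genes:
        empty = ExclusivityStats(pd.DataFrame(
            columns=["tcell_fraction", "max_other_fraction", "max_other_type", "exclusive"]))
        return SignatureResult(signature=candidates, candidates=candidates,
                               fold_changes=fc, exclusivity=empty, params=params)
    signature, stats = tcell_exclusivity(
        candidates, cells,
        min_tcell_detection=params.min_tcell_detection,
        max_other_detection=params.max_other_detection,
    )
    return SignatureResult(signature=signature, candidates=candidates,
                           fold_changes=fc, exclusivity=stats, params=params)
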
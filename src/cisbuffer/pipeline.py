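"""End-to-end analysis chain: filter, normalise, fit, test, call.

The same chain is applied to the primary dataset and, unchanged, to
every simulated dataset inside the buffering calibration and the
permutation bootstrap ("the exact same analysis").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import EFFECT_COLUMNS, SPORE_HYBRID, canonical_sample_sheet
from .model import AlleleSpecificGLM, call_genes, wald_fdr
from .preprocess import estimate_size_factors, filter_min_expression


@dataclass
class PipelineResult:
    """Everything downstream stages need: the per-gene fit table (with
    FDR and call flags), the offsets actually used, and the fitted
    model/design for re-simulation."""

    fits: pd.DataFrame
    size_factors: pd.Series
    filter_report: object
    design: pd.DataFrame
    sample_sheet: pd.DataFrame
    fl_offsets: pd.DataFrame | None
    total_offsets: np.ndarray
    model: AlleleSpecificGLM
    dataset_kind: str
    params: dict = field(default_factory=dict)

    @property
    def cis_column(self) -> str:
        return EFFECT_COLUMNS[self.dataset_kind]["cis"]

    @property
    def trans_column(self) -> str:
        return EFFECT_COLUMNS[self.dataset_kind]["trans"]

    @property
    def cis_genes(self) -> pd.Index:
        return self.fits.index[self.fits[f"called_{self.cis_column}"]]


def run_ase_pipeline(counts: pd.DataFrame, sample_sheet: pd.DataFrame | None = None,
                     fl_offsets: pd.DataFrame | None = None,
                     dataset_kind: str = SPORE_HYBRID,
                     min_mean: float = 10.0, fold: float = 1.5,
                     fdr: float = 0.2, model: AlleleSpecificGLM | None = None,
                     **model_kwargs) -> PipelineResult:
    """Minimum-expression filter, median-of-ratios size factors,
    per-gene NB GLM with offsets, BH FDR and (fold, FDR) gene calls.

    ``fl_offsets`` are the known per-gene log offsets ``log(f * l)``
    (allele frequency x allele length); size factors are estimated from
    the counts and added to them.
    """
    counts = pd.DataFrame(counts)
    if sample_sheet is None:
        sample_sheet = canonical_sample_sheet(dataset_kind)
    missing = [c for c in counts.columns if c not in sample_sheet.index]
    if missing:
        raise ValueError(f"count columns not in sample sheet: {missing}")

    kept, report = filter_min_expression(counts, min_mean)
    if kept.empty:
        raise ValueError("no genes pass the minimum-expression filter")
    size_factors = estimate_size_factors(kept)

    if fl_offsets is not None:
        fl = fl_offsets.reindex(index=kept.index, columns=kept.columns)
        if fl.isna().any().any():
            raise ValueError("fl_offsets missing for some kept gene/unit")
        total = fl.to_numpy(float) + np.log(size_factors.to_numpy())
    else:
        fl = None
        total = np.broadcast_to(
            np.log(size_factors.to_numpy()), kept.shape).copy()

    if model is None:
        model = AlleleSpecificGLM(dataset_kind=dataset_kind, **model_kwargs)
    model.fit(kept, sample_sheet,
              offsets=pd.DataFrame(total, index=kept.index,
                                   columns=kept.columns))
    fits = wald_fdr(model.results(), dataset_kind=dataset_kind)
    for role, colname in EFFECT_COLUMNS[dataset_kind].items():
        fits[f"called_{colname}"] = call_genes(
            fits, fold=fold, fdr=fdr, coefficient=colname,
            dataset_kind=dataset_kind)
    return PipelineResult(
        fits=fits, size_factors=size_factors, filter_report=report,
        design=model.design_, sample_sheet=sample_sheet, fl_offsets=fl,
        total_offsets=total, model=model, dataset_kind=dataset_kind,
        params={"min_mean": min_mean, "fold": fold, "fdr": fdr})
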
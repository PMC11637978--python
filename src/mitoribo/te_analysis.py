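"""Spike-in normalization and translation-efficiency (TE) statistics.

The normalization chain mirrors the mitoribosome-profiling design: per-library
counts are converted to reads per kilobase (RPK), divided by the library's
spike-in factor (the raw sum of reads assigned to spike-in features), and TE
is the ratio of spike-normalized RPF RPK to spike-normalized RNA RPK for the
same condition.  Contrasts are expressed as log2 fold changes of KO over
rescue.  Whole-cell RNAseq, which carries no spike-in, is normalized by read
depth (counts per million).

Zeros are never hidden behind a pseudocount by default: where a denominator
is zero the quantity is flagged undefined (NaN) rather than set to infinity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .counting import CountTable
from .io_formats import Annotation

__all__ = [
    "spike_factor",
    "rpk",
    "spike_normalize",
    "translation_efficiency",
    "log2_fold_change",
    "read_depth_normalize",
    "compute_te_result",
]


def spike_factor(table: CountTable, library_id: str) -> float:
    """Spike-in scale factor: raw sum of counts over spike-in features.

    All downstream contrasts are ratios, so no per-million rescaling is
    applied.  Zero spike-in reads leave the factor undefined and raise.
    """
    if library_id not in table.counts.columns:
        raise KeyError(f"unknown library {library_id!r}")
    spike_ids = [f.feature_id for f in table.annotation.spikein_features]
    total = float(table.counts.loc[spike_ids, library_id].sum())
    if total <= 0:
        raise ValueError(f"library {library_id!r}: zero spike-in reads, factor undefined")
    return total


def rpk(table: CountTable, annotation: Annotation | None = None) -> pd.DataFrame:
    """Reads per kilobase of feature: count / (length_nt / 1000)."""
    annotation = annotation or table.annotation
    lengths = pd.Series(
        {f.feature_id: f.length_nt for f in annotation}, name="length_nt"
    ).reindex(table.counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])
        raise ValueError(f"features missing from annotation: {missing}")
    return table.counts.div(lengths / 1000.0, axis=0)


def spike_normalize(rpk_matrix: pd.DataFrame, table: CountTable) -> pd.DataFrame:
    """Divide each library's RPK column by its spike-in factor.

    Spike-in rows are retained (they are the QC anchor) — callers slice to
    target features for biology.
    """
    factors = pd.Series({lib: spike_factor(table, lib) for lib in rpk_matrix.columns})
    return rpk_matrix.div(factors, axis=1)


def translation_efficiency(
    rpf_norm: pd.Series, rna_norm: pd.Series, pseudocount: float = 0.0
) -> pd.Series:
    """TE per feature: spike-normalized RPF RPK over spike-normalized RNA RPK.

    With the default zero pseudocount, TE is NaN (flagged undefined) where
    the RNA denominator is zero, never infinity.
    """
    if not rpf_norm.index.equals(rna_norm.index):
        if set(rpf_norm.index) != set(rna_norm.index):
            raise ValueError("RPF and RNA feature sets differ")
        rna_norm = rna_norm.reindex(rpf_norm.index)
    num = rpf_norm + pseudocount
    den = rna_norm + pseudocount
    te = num / den
    te[den == 0] = np.nan
    return te


def log2_fold_change(metric_ko: pd.Series, metric_rescue: pd.Series) -> pd.Series:
    """log2(KO / rescue) per feature; NaN where either side is non-positive."""
    ko = metric_ko.astype(float)
    rescue = metric_rescue.reindex(ko.index).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(ko / rescue)
    lfc[(ko <= 0) | (rescue <= 0) | ko.isna() | rescue.isna()] = np.nan
    return lfc


def read_depth_normalize(table: CountTable) -> pd.DataFrame:
    """Counts per million: count / library total x 1e6 (whole-cell RNAseq)."""
    totals = table.counts.sum(axis=0)
    zero = list(totals.index[totals == 0])
    if zero:
        raise ValueError(f"zero-total library(ies): {zero}")
    return table.counts.div(totals, axis=1) * 1e6


def _condition_norm(table: CountTable, assay: str, condition: str) -> pd.Series:
    """Mean spike-normalized RPK across the libraries of one assay/condition."""
    libs = table.libraries_for(assay, condition)
    if not libs:
        raise ValueError(f"no libraries with assay={assay!r}, condition={condition!r}")
    normed = spike_normalize(rpk(table)[libs], table)
    return normed.mean(axis=1)


def compute_te_result(
    table: CountTable,
    contrast: tuple[str, str] = ("KO", "rescue"),
    pseudocount: float = 0.0,
    target_only: bool = True,
) -> pd.DataFrame:
    """Full TE analysis for a KO-vs-rescue contrast.

    Returns a per-feature frame with spike-normalized RPK for both assays and
    conditions, TE per condition, and the three log2 fold changes.  By
    construction ``log2fc_synthesis = log2fc_rna + log2fc_te`` wherever all
    quantities are defined (synthesis change decomposes into abundance change
    plus translation change).
    """
    cond_a, cond_b = contrast
    rpf_a = _condition_norm(table, "RPF", cond_a)
    rpf_b = _condition_norm(table, "RPF", cond_b)
    rna_a = _condition_norm(table, "RNA", cond_a)
    rna_b = _condition_norm(table, "RNA", cond_b)

    te_a = translation_efficiency(rpf_a, rna_a, pseudocount)
    te_b = translation_efficiency(rpf_b, rna_b, pseudocount)

    out = pd.DataFrame(
        {
            f"rpf_norm_rpk_{cond_a}": rpf_a,
            f"rpf_norm_rpk_{cond_b}": rpf_b,
            f"rna_norm_rpk_{cond_a}": rna_a,
            f"rna_norm_rpk_{cond_b}": rna_b,
            f"te_{cond_a}": te_a,
            f"te_{cond_b}": te_b,
            "log2fc_te": log2_fold_change(te_a, te_b),
            "log2fc_rna": log2_fold_change(rna_a, rna_b),
            "log2fc_synthesis": log2_fold_change(rpf_a, rpf_b),
        }
    )
    out.index.name = "feature_id"
    if target_only:
        target_ids = [f.feature_id for f in table.annotation.target_features]
        out = out.loc[out.index.intersection(target_ids)].reindex(
            [f for f in target_ids if f in out.index]
        )
    return out
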
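"""Survival scoring and resistance-hit calling for a pooled variant screen.

The computation follows the screen's hit-calling recipe: per-sample variant
fractions (with a pseudocount), exclusion of variants in the bottom 8% of
mean baseline (T0) fraction, normalization of each arm to T0, replicate
averaging, treatment-versus-control log2 fold changes, Z-standardization,
and a hit rule of LFC more than one standard deviation above the mean with
LFC > 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .read_deconvolution import CountsMatrix

__all__ = [
    "CONDITIONS",
    "SampleSheet",
    "ScoringParams",
    "compute_fractions",
    "filter_low_t0",
    "survival_lfc",
    "z_scores",
    "call_hits",
    "score_screen",
]

CONDITIONS = ("T0", "DMSO", "DNMDP10", "DNMDP100", "TREQ100")


class SampleSheet:
    """Sample metadata: sample_id, condition, replicate."""

    def __init__(self, table: pd.DataFrame):
        required = {"sample_id", "condition", "replicate"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        bad = set(table["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")
        if table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id")
        if not (table["condition"] == "T0").any():
            raise ValueError("sample sheet needs at least one T0 sample")
        self.table = table.reset_index(drop=True)

    def samples(self, condition: str) -> list[str]:
        sel = self.table[self.table["condition"] == condition]
        return list(sel.sort_values("replicate")["sample_id"])

    @classmethod
    def from_tsv(cls, path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ScoringParams:
    t0_percentile: float = 8.0
    pseudocount: float = 0.5
    log_base: float = 2.0
    hit_sd_multiplier: float = 1.0
    control_condition: str = "DMSO"
    treatment_condition: str = "DNMDP100"

    def __post_init__(self) -> None:
        if not 0 < self.t0_percentile < 100:
            raise ValueError("t0_percentile must be in (0, 100)")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")


def compute_fractions(
    counts: CountsMatrix, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Per-sample variant fractions of the assigned reads.

    fraction(v, s) = (count(v, s) + pseudocount) / (assigned_total(s) + pseudocount),
    where assigned reads are WT plus designed variants (discard classes are
    not part of the denominator).
    """
    variant_ids = counts.variant_ids
    out = {}
    for s in counts.sample_ids:
        total = counts.assigned_total(s)
        if total <= 0:
            raise ValueError(f"sample {s!r} has zero assigned reads")
        out[s] = (counts.counts.loc[variant_ids, s] + pseudocount) / (
            total + pseudocount
        )
    return pd.DataFrame(out, index=variant_ids)


def nearest_rank_threshold(values: pd.Series, percentile: float) -> float:
    """The nearest-rank p-th percentile: smallest value with at least p% of
    observations at or below it."""
    n = len(values)
    if n == 0:
        raise ValueError("no values")
    rank = max(1, math.ceil(percentile / 100.0 * n))
    return float(np.sort(values.to_numpy())[rank - 1])


def filter_low_t0(t0_fractions: pd.Series, params: ScoringParams) -> pd.Series:
    """Low-confidence flags: mean-T0 fraction at or below the nearest-rank
    percentile threshold.  Values tied with the threshold are all flagged."""
    thr = nearest_rank_threshold(t0_fractions, params.t0_percentile)
    return t0_fractions <= thr


def normalized_abundance(
    fractions: pd.DataFrame, sheet: SampleSheet, condition: str
) -> pd.DataFrame:
    """Per-replicate day-5 fraction over pooled-T0 fraction.

    T0 is harvested once before the split into arms, so every arm replicate
    is normalized by the pooled (replicate-averaged) T0 fraction.
    """
    t0_samples = sheet.samples("T0")
    t0_pooled = fractions[t0_samples].mean(axis=1)
    samples = sheet.samples(condition)
    if not samples:
        raise ValueError(f"condition {condition!r} absent from sample sheet")
    return fractions[samples].div(t0_pooled, axis=0)


def survival_lfc(
    fractions: pd.DataFrame,
    sheet: SampleSheet,
    treatment: str,
    control: str,
    params: ScoringParams = ScoringParams(),
) -> pd.Series:
    """log2 of (replicate-mean normalized abundance under treatment) over
    (replicate-mean normalized abundance under control)."""
    norm_t = normalized_abundance(fractions, sheet, treatment).mean(axis=1)
    norm_c = normalized_abundance(fractions, sheet, control).mean(axis=1)
    return np.log(norm_t / norm_c) / np.log(params.log_base)


def z_scores(lfc: pd.Series) -> pd.Series:
    """Standardize an LFC vector to mean 0 and sample SD (n-1) of 1."""
    clean = lfc.dropna()
    if len(clean) < 2:
        raise ValueError("need at least 2 values to standardize")
    sd = clean.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation")
    return (lfc - clean.mean()) / sd


def call_hits(lfc: pd.Series, params: ScoringParams = ScoringParams()) -> pd.Series:
    """Resistance-hit flags: LFC above mean + k*SD and above zero."""
    clean = lfc.dropna()
    thr = clean.mean() + params.hit_sd_multiplier * clean.std(ddof=1)
    return (lfc > thr) & (lfc > 0)


def score_screen(
    counts: CountsMatrix,
    sheet: SampleSheet,
    params: ScoringParams = ScoringParams(),
    design=None,
    excluded_variants: set[str] | None = None,
) -> pd.DataFrame:
    """Full scoring pass: fractions, T0 filter, LFCs, Z, hit calls.

    Returns a table indexed like the design with columns t0_fraction,
    low_confidence, per-comparison LFCs, z (treatment vs control) and
    resistance_hit (nullable boolean: NA for low-confidence variants).
    ``excluded_variants`` (e.g. a user-supplied fold-destabilizing set) are
    never flagged as hits but are otherwise scored normally.
    """
    fractions = compute_fractions(counts, params.pseudocount)
    t0_mean = fractions[sheet.samples("T0")].mean(axis=1)
    low_conf = filter_low_t0(t0_mean, params)
    retained = fractions.loc[~low_conf]

    table = pd.DataFrame(index=fractions.index)
    table.index.name = "variant_id"
    if design is not None:
        specs = design.by_id()
        table["codon_number"] = [specs[v].codon_number for v in table.index]
        table["alt_aa"] = [specs[v].alt_aa for v in table.index]
        table["var_class"] = [specs[v].var_class for v in table.index]
    table["t0_fraction"] = t0_mean
    table["low_confidence"] = low_conf

    treatment, control = params.treatment_condition, params.control_condition
    lfc = survival_lfc(retained, sheet, treatment, control, params)
    col = f"lfc_{treatment.lower()}_vs_{control.lower()}"
    table[col] = lfc.reindex(table.index)
    # secondary comparison against trequinsin where present
    if sheet.samples("TREQ100") and control != "TREQ100":
        lfc_treq = survival_lfc(retained, sheet, treatment, "TREQ100", params)
        table[f"lfc_{treatment.lower()}_vs_treq100"] = lfc_treq.reindex(table.index)

    try:
        z = z_scores(lfc)
    except ValueError:
        z = pd.Series(np.nan, index=lfc.index)  # degenerate (constant) LFC
    table["z"] = z.reindex(table.index)
    hits = call_hits(lfc, params)
    if excluded_variants:
        hits[hits.index.isin(excluded_variants)] = False
    table["resistance_hit"] = (
        hits.reindex(table.index).astype("boolean")
    )
    return table
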
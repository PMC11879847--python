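"""Count normalization and the ratio statistics of the gene-level analyses.

Two normalizations are provided, matching how single-cohort and pooled
analyses are scaled:

* GCPM (gene count per million), for single cohorts:
  ``GCPM_i = (q_i / l_i) / sum_j (q_j / l_j) * 1e6`` with raw mapped reads
  ``q_i`` and gene length ``l_i`` — accounts for gene length and depth.
* CPM (count per million), for pooled, batch-adjusted counts ``A_i``:
  ``CPM_i = A_i / sum A_i * 1e6``.  The pooled pipeline log-transforms the
  batch-adjusted matrix with a 1e-6 pseudocount before scaling
  (``cpm_pipeline(mode="pseudolog")``, the default); ``mode="raw"`` applies
  the plain CPM formula to the adjusted counts instead.

Plus: CLR for compositional heatmap views, per-weight normalization for
faecal samples, rare-feature and zero-sample filters, and guarded ratio
series (hexa:penta taxa ratios, lpxM:lpxL gene ratios).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

PSEUDOCOUNT = 1e-6
MILLION = 1e6


def _check_matrix(df: pd.DataFrame, name: str = "matrix") -> None:
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{name} contains negative values")


def compute_gcpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Gene count per million: length- and depth-normalized abundance.

    Parameters
    ----------
    counts
        Features x samples raw mapped-read counts ``q_i``.
    lengths
        Per-feature gene lengths ``l_i`` in bp, indexed like ``counts``.

    Returns
    -------
    Features x samples GCPM values; every sample column sums to 1e6.
    """
    _check_matrix(counts, "count matrix")
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])
        raise ValueError(f"missing gene length for feature(s): {missing[:5]}")
    if (lengths <= 0).any():
        bad = list(lengths.index[lengths <= 0])
        raise ValueError(f"non-positive gene length for feature(s): {bad[:5]}")
    rates = counts.div(lengths, axis=0)
    totals = rates.sum(axis=0)
    dead = list(totals.index[totals <= 0])
    if dead:
        raise ValueError(f"all-zero sample(s): {dead}")
    return rates.div(totals, axis=1) * MILLION


def compute_cpm(adjusted: pd.DataFrame) -> pd.DataFrame:
    """Count per million of (batch-adjusted) counts: ``A_i / sum A * 1e6``."""
    _check_matrix(adjusted, "count matrix")
    totals = adjusted.sum(axis=0)
    dead = list(totals.index[totals <= 0])
    if dead:
        raise ValueError(f"all-zero sample(s): {dead}")
    return adjusted.div(totals, axis=1) * MILLION


def pseudolog_transform(
    values: pd.DataFrame | pd.Series, pseudocount: float = PSEUDOCOUNT
):
    """Natural log after adding a pseudocount: ``log(A + pseudocount)``.

    Monotone in A; zeros map to ``log(pseudocount)``.
    """
    arr = values if isinstance(values, (pd.DataFrame, pd.Series)) else pd.Series(values)
    if (np.asarray(arr) < 0).any():
        raise ValueError("negative values cannot be log-transformed")
    return np.log(arr + pseudocount)


def cpm_pipeline(
    adjusted: pd.DataFrame,
    mode: str = "pseudolog",
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Pooled-cohort scaling of a batch-adjusted count matrix.

    ``mode="pseudolog"`` (default): add the pseudocount, take the natural
    log, then scale each sample to one million — the transform-then-scale
    order.  ``mode="raw"``: apply the plain CPM formula directly to the
    adjusted counts.
    """
    if mode == "raw":
        return compute_cpm(adjusted)
    if mode != "pseudolog":
        raise ValueError(f"unknown CPM mode {mode!r}")
    logged = pseudolog_transform(adjusted, pseudocount)
    totals = logged.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("degenerate sample: pseudolog values sum to zero")
    return logged.div(totals, axis=1) * MILLION


def filter_rare_features(
    matrix: pd.DataFrame, min_samples: int = 5
) -> tuple[pd.DataFrame, list[str]]:
    """Drop features detected (nonzero) in fewer than ``min_samples`` samples.

    A feature present in so few samples is treated as sporadic or
    misannotated.  The boundary is inclusive: nonzero in exactly
    ``min_samples`` samples is retained.

    Returns (filtered matrix, list of dropped feature ids).
    """
    if matrix.empty:
        return matrix, []
    detected = (matrix != 0).sum(axis=1)
    keep = detected >= min_samples
    dropped = [str(f) for f in matrix.index[~keep]]
    return matrix.loc[keep], dropped


def nonzero_subset(values: pd.Series) -> tuple[pd.Series, int]:
    """Exclude undetected (zero-value) samples from a per-sample series.

    Returns (nonzero subset, number of excluded samples)."""
    kept = values[values != 0]
    n_excluded = len(values) - len(kept)
    if kept.empty:
        warnings.warn("all samples are zero; returning empty subset", stacklevel=2)
    return kept, n_excluded


def hexa_penta_ratio(
    abundances: pd.DataFrame, numerator: str = "hexa_total"
) -> pd.Series:
    """Per-sample ratio of hexa- to penta-acylated-LPS-encoding taxa.

    ``numerator`` is ``hexa_total`` (lpxM- plus lpxJ-route taxa) or
    ``hexa_lpxM``.  Samples with zero penta abundance are undefined (NaN)
    and excluded from downstream summaries.
    """
    if numerator not in ("hexa_total", "hexa_lpxM"):
        raise ValueError(f"numerator must be hexa_total or hexa_lpxM, got {numerator!r}")
    penta = abundances["penta"]
    num = abundances[numerator]
    out = num.where(penta != 0) / penta.where(penta != 0)
    return out.rename(f"{numerator}:penta")


def gene_ratio(num: pd.Series, den: pd.Series) -> pd.Series:
    """Per-sample gene-abundance ratio (e.g. lpxM:lpxL on CPM values).

    Zero denominators yield NaN (undefined, excluded from summaries)."""
    if not num.index.equals(den.index):
        raise ValueError("numerator and denominator sample sets differ")
    return num.where(den != 0) / den.where(den != 0)


def clr_normalize(
    counts: pd.DataFrame, zero_replacement: str | float = "half-min"
) -> pd.DataFrame:
    """Centred log-ratio transform of per-sample compositions.

    Each sample (column) is closed to a composition; zeros are replaced by
    half the smallest nonzero value of that sample (multiplicative
    replacement, deterministic) or by a fixed value; then
    ``clr_i = log(x_i) - mean_j log(x_j)``.  Per-sample CLR values sum to 0.

    Parameters
    ----------
    counts
        Features x samples non-negative matrix.
    zero_replacement
        ``"half-min"`` (default) or a positive float used verbatim.
    """
    _check_matrix(counts, "count matrix")
    out = {}
    for sample in counts.columns:
        x = counts[sample].to_numpy(dtype=float)
        if x.sum() <= 0:
            raise ValueError(f"all-zero sample: {sample!r}")
        if (x == 0).any():
            if zero_replacement == "half-min":
                repl = x[x > 0].min() / 2.0
            else:
                repl = float(zero_replacement)
                if repl <= 0:
                    raise ValueError("zero_replacement must be positive")
            x = np.where(x == 0, repl, x)
        logx = np.log(x / x.sum())
        out[sample] = logx - logx.mean()
    return pd.DataFrame(out, index=counts.index)


def weight_normalize(
    taxa: pd.DataFrame, faecal_weight_mg: pd.Series
) -> pd.DataFrame:
    """Normalize per-sample taxon counts by faecal pellet weight (reads/mg).

    ``taxa`` is samples x taxa; weights are mg per sample."""
    weights = faecal_weight_mg.reindex(taxa.index)
    if weights.isna().any():
        missing = list(weights.index[weights.isna()])
        raise ValueError(f"missing faecal weight for sample(s): {missing}")
    if (weights <= 0).any():
        bad = list(weights.index[weights <= 0])
        raise ValueError(f"non-positive faecal weight for sample(s): {bad}")
    return taxa.div(weights, axis=0)


def simple_batch_adjust(
    counts: pd.DataFrame, batches: pd.Series
) -> pd.DataFrame:
    """Remove per-batch multiplicative shifts by median log-ratio centring.

    For each feature, the median log-count within each batch (over samples
    where the feature is detected) is centred to the feature's global median
    log-count; counts in that batch are rescaled by the corresponding
    factor.  Zeros stay zero, output is non-negative, and with a single
    batch the operation is the identity.  Batches with fewer than two
    samples are left unadjusted with a warning.

    This is deliberately simple plumbing: it targets constant per-batch
    study effects only, not count-model batch correction.
    """
    batches = batches.reindex(counts.columns)
    if batches.isna().any():
        missing = list(batches.index[batches.isna()])
        raise ValueError(f"missing batch label for sample(s): {missing}")
    labels = batches.unique()
    if len(labels) == 1:
        return counts.astype(float)

    arr = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logarr = np.where(arr > 0, np.log(arr), np.nan)
    global_med = np.nanmedian(logarr, axis=1)

    out = arr.copy()
    for label in labels:
        mask = (batches == label).to_numpy()
        if mask.sum() < 2:
            warnings.warn(
                f"batch {label!r} has a single sample; left unadjusted",
                stacklevel=2,
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            batch_med = np.nanmedian(logarr[:, mask], axis=1)
        shift = global_med - batch_med
        shift = np.where(np.isfinite(shift), shift, 0.0)
        out[:, mask] = arr[:, mask] * np.exp(shift)[:, None]
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)
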
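"""Replicate aggregation, QC and poor-binding masks for array scans.

Turns raw per-replicate scan tables into per-locus log-ratio and Cy5
matrices (loci x individuals), computes the QC comparisons used to check
that the platform behaved as designed (channel separation on cut-site
tiles, control-tile intensity ordering, inter-array consistency), and
masks loci whose Cy5 binding is indistinguishable from the negative
controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hybsim import apply_pmt_normalization
from .tiles import TileSpec, manifest_frame


def aggregate_replicates(scan: pd.DataFrame) -> pd.DataFrame:
    """Average replicate tiles into one row per tile.

    Channel means are averaged before forming the ratio (robust to a
    single replicate dropout); ``replicate_cv`` is the coefficient of
    variation of the per-replicate intensities (sd/mean, averaged over the
    two channels), matching how replicate-tile consistency is usually
    summarized.  Tiles with a non-positive channel mean get ``log_ratio``
    NaN and ``ok=False``.
    """
    if scan.empty:
        raise ValueError("empty scan")
    g = scan.groupby("tile_id", sort=False)
    mean = g[["cy3", "cy5"]].mean()
    sd = g[["cy3", "cy5"]].std(ddof=1)
    n = g.size()
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 0.5 * (sd["cy3"] / mean["cy3"] + sd["cy5"] / mean["cy5"])
    out = pd.DataFrame({
        "mean_cy3": mean["cy3"],
        "mean_cy5": mean["cy5"],
        "replicate_cv": cv.fillna(0.0),
        "n_replicates": n,
    })
    ok = (out["mean_cy3"] > 0) & (out["mean_cy5"] > 0)
    out["log_ratio"] = np.where(ok, np.log2(out["mean_cy5"].where(ok, 1.0) /
                                            out["mean_cy3"].where(ok, 1.0)),
                                np.nan)
    out["ok"] = ok
    return out


@dataclass
class SignalMatrices:
    """Per-locus signal matrices (rows = cut-site tiles, columns =
    individuals).  ``cy5`` is on the raw (pre-normalization) scale so that
    absolute indel cutoffs apply; ``log_ratio`` is computed after per-array
    channel-sum normalization."""
    log_ratio: pd.DataFrame
    cy5: pd.DataFrame
    replicate_cv: pd.DataFrame


def build_signal_matrices(scans: Mapping[str, pd.DataFrame],
                          tiles: Sequence[TileSpec],
                          normalize: bool = True) -> SignalMatrices:
    """Aggregate every individual's scan into the locus x individual
    matrices used for polymorphism identification and indel detection."""
    cutsite_ids = [t.tile_id for t in tiles if t.tile_type == "cutsite"]
    lr, cy5, cv = {}, {}, {}
    for ind, scan in scans.items():
        raw = aggregate_replicates(scan)
        norm = aggregate_replicates(apply_pmt_normalization(scan)) \
            if normalize else raw
        lr[ind] = norm["log_ratio"].reindex(cutsite_ids)
        cy5[ind] = raw["mean_cy5"].reindex(cutsite_ids)
        cv[ind] = norm["replicate_cv"].reindex(cutsite_ids)
    individuals = list(scans)
    return SignalMatrices(
        log_ratio=pd.DataFrame(lr, columns=individuals),
        cy5=pd.DataFrame(cy5, columns=individuals),
        replicate_cv=pd.DataFrame(cv, columns=individuals))


# ---------------------------------------------------------------------------
# QC


@dataclass
class QCReport:
    ks_tests: pd.DataFrame       # comparison, statistic, pvalue
    array_r2: pd.DataFrame       # array_a, array_b, r2
    replicate_cv: pd.Series      # pooled per-tile CV distribution
    warnings: list[str]


def qc_report(scans: Mapping[str, pd.DataFrame],
              tiles: Sequence[TileSpec]) -> QCReport:
    """Check that simulated (or real) scans reproduce the platform's
    signature signal patterns.

    Kolmogorov-Smirnov comparisons: digested vs non-digested channel on
    cut-site tiles (digestion should depress Cy3), the same on non-cut
    tiles (no digestion effect expected), and negative / positive controls
    vs cut-site Cy5.  Also reports the squared Pearson correlation of
    per-tile intensities between every pair of arrays and the pooled
    replicate-CV distribution.
    """
    meta = manifest_frame(tiles)
    warns: list[str] = []
    agg = {ind: aggregate_replicates(scan) for ind, scan in scans.items()}
    pooled = pd.concat(
        [a.join(meta[["tile_type"]]) for a in agg.values()])

    def _klass(tt: str, col: str) -> np.ndarray:
        sel = pooled[pooled["tile_type"] == tt][col].dropna().to_numpy()
        return sel

    comparisons = []
    cut3, cut5 = _klass("cutsite", "mean_cy3"), _klass("cutsite", "mean_cy5")
    pairs = [
        ("cutsite_cy3_vs_cy5", cut3, cut5),
        ("noncut_cy3_vs_cy5", _klass("noncut_control", "mean_cy3"),
         _klass("noncut_control", "mean_cy5")),
        ("negative_vs_cutsite_cy5", _klass("negative_control", "mean_cy5"),
         cut5),
        ("positive_vs_cutsite_cy5", _klass("positive_control", "mean_cy5"),
         cut5),
    ]
    for name, a, b in pairs:
        if len(a) == 0 or len(b) == 0:
            warns.append(f"comparison {name} omitted: tile class absent")
            continue
        res = stats.ks_2samp(a, b)
        comparisons.append((name, res.statistic, res.pvalue,
                            float(np.mean(a) - np.mean(b))))
    ks = pd.DataFrame(comparisons,
                      columns=["comparison", "statistic", "pvalue",
                               "mean_difference"])

    inds = list(agg)
    rows = []
    for i in range(len(inds)):
        for j in range(i + 1, len(inds)):
            a, b = agg[inds[i]], agg[inds[j]]
            common = a.index.intersection(b.index)
            x = np.concatenate([a.loc[common, "mean_cy3"],
                                a.loc[common, "mean_cy5"]])
            y = np.concatenate([b.loc[common, "mean_cy3"],
                                b.loc[common, "mean_cy5"]])
            r = np.corrcoef(x, y)[0, 1]
            rows.append((inds[i], inds[j], r * r))
    r2 = pd.DataFrame(rows, columns=["array_a", "array_b", "r2"])

    cvs = pd.concat([a["replicate_cv"] for a in agg.values()])
    for w in warns:
        warnings.warn(w)
    return QCReport(ks, r2, cvs, warns)


def flag_poor_binding(cy5: pd.DataFrame,
                      negative_cy5: np.ndarray | pd.Series,
                      quantile: float = 0.95,
                      genomic_class: pd.Series | None = None
                      ) -> tuple[pd.Series, float, pd.Series | None]:
    """Mask loci whose across-individual mean Cy5 does not exceed the given
    quantile of the negative-control Cy5 distribution.

    Masked loci are unreliable for polymorphism calling (the sample DNA did
    not bind, e.g. because the region is too diverged from the reference).
    Returns (mask, threshold, per-class masked fraction).  With no negative
    controls, masking is disabled with a warning.
    """
    negative_cy5 = np.asarray(negative_cy5, dtype=float)
    negative_cy5 = negative_cy5[~np.isnan(negative_cy5)]
    if negative_cy5.size == 0:
        warnings.warn("no negative-control intensities: poor-binding "
                      "masking disabled")
        mask = pd.Series(False, index=cy5.index)
        return mask, float("nan"), None
    threshold = float(np.quantile(negative_cy5, quantile))
    mask = cy5.mean(axis=1) <= threshold
    by_class = None
    if genomic_class is not None:
        by_class = mask.groupby(genomic_class.reindex(mask.index)).mean()
    return mask, threshold, by_class


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="locus_id")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="locus_id")
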
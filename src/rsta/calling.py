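"""Polymorphism identification and genotype calling.

A locus is called polymorphic when its per-individual log ratios span more
than ``range_threshold`` (default 0.7 log2 units) AND a univariate
Gaussian mixture with component-specific variances, selected by BIC over
1..4 components, supports more than one cluster.  Genotypes at polymorphic
loci are then assigned by fixed log-ratio thresholds: below -0.6
homozygous uncut, between -0.6 and -0.1 heterozygous, above -0.1
homozygous cut.  Indel loci are detected separately from the non-digested
(Cy5) channel on its raw intensity scale: a 2-3 cluster structure with one
cluster mean below 50 (background-like: deleted allele) and one above 150
(normal binding).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

HOM_CUT = "CC"
HET = "CU"
HOM_UNCUT = "UU"
MISSING = "NA"

GENOTYPE_CODES = (HOM_CUT, HET, HOM_UNCUT, MISSING)

#: component-variance floor as a fraction of the data standard deviation;
#: chosen so that BIC neither collapses components onto coincident points
#: (spurious clusters) nor merges well-separated ones
VAR_FLOOR_FRACTION = 0.2


@dataclass
class CallingConfig:
    """Thresholds and mixture settings; defaults follow the platform's
    calibration against sequence-confirmed genotypes."""
    range_threshold: float = 0.7
    k_max: int = 4
    het_lower: float = -0.6
    het_upper: float = -0.1
    indel_low_cutoff: float = 50.0
    indel_high_cutoff: float = 150.0
    indel_k_max: int = 3
    n_init: int = 10
    seed: int = 0
    tol: float = 1e-8
    max_iter: int = 500

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CallingConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__annotations__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


@dataclass
class MixtureFit:
    """A fitted 1-D Gaussian mixture with BIC-selected component count."""
    k: int
    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    bic: dict[int, float]
    assignments: np.ndarray
    converged: bool

    def __post_init__(self) -> None:
        order = np.argsort(self.means)
        self.means = self.means[order]
        self.variances = self.variances[order]
        self.weights = self.weights[order]
        remap = np.empty_like(order)
        remap[order] = np.arange(len(order))
        self.assignments = remap[self.assignments]


def _log_density(x: np.ndarray, means: np.ndarray, variances: np.ndarray,
                 weights: np.ndarray) -> np.ndarray:
    """Weighted log component densities, shape (n, k)."""
    d = x[:, None] - means[None, :]
    return (np.log(weights)[None, :]
            - 0.5 * (np.log(2.0 * np.pi * variances)[None, :]
                     + d * d / variances[None, :]))


def _kmeanspp_centers(x: np.ndarray, k: int,
                      rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding: first center uniform, subsequent centers
    drawn with probability proportional to squared distance."""
    centers = [x[rng.integers(x.size)]]
    for _ in range(1, k):
        d2 = np.min((x[:, None] - np.array(centers)[None, :]) ** 2, axis=1)
        total = d2.sum()
        if total <= 0:
            centers.append(x[rng.integers(x.size)])
        else:
            centers.append(x[rng.choice(x.size, p=d2 / total)])
    return np.array(centers)


def _em_once(x: np.ndarray, centers: np.ndarray, var_floor: float,
             tol: float, max_iter: int
             ) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, bool]:
    """One EM run from the given initial centers; returns (loglik, means,
    variances, weights, converged)."""
    n, k = x.size, centers.size
    assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
    resp = np.zeros((n, k))
    resp[np.arange(n), assign] = 1.0
    loglik = -np.inf
    converged = False
    means = centers.astype(float).copy()
    variances = np.full(k, max(x.var(), var_floor))
    weights = np.full(k, 1.0 / k)
    for _ in range(max_iter):
        # M step
        nk = resp.sum(axis=0) + 1e-12
        means = resp.T @ x / nk
        variances = np.einsum(
            "nk,nk->k", resp, (x[:, None] - means[None, :]) ** 2) / nk
        variances = np.maximum(variances, var_floor)
        weights = nk / n
        # E step
        logd = _log_density(x, means, variances, weights)
        m = logd.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logd - m).sum(axis=1))
        new_loglik = float(lse.sum())
        resp = np.exp(logd - lse[:, None])
        if new_loglik - loglik < tol and np.isfinite(loglik):
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
    return loglik, means, variances, weights, converged


def fit_gmm_1d(values, k_max: int = 4, n_init: int = 10, seed: int = 0,
               tol: float = 1e-8, max_iter: int = 500) -> MixtureFit:
    """EM fit of univariate Gaussian mixtures with component-specific
    variances for k = 1..k_max; the component count minimizing BIC wins.

    Each k is fitted with ``n_init`` seeded k-means++-style restarts,
    keeping the best log-likelihood.  Component variances are floored at
    (VAR_FLOOR_FRACTION * data standard deviation)^2: without a floor, EM
    collapses a component onto near-coincident points and the likelihood
    spike makes BIC prefer spurious clusters.  ``k_max`` is reduced when
    fewer than 2*k_max observations are available.  Components are
    returned sorted by mean.  Deterministic given the seed.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite values to fit")
    k_max = max(1, min(k_max, x.size // 2 or 1))
    var_floor = max(1e-10, (VAR_FLOOR_FRACTION * float(x.std())) ** 2)
    rng = np.random.default_rng(seed)
    n = x.size
    best_overall = None
    bics: dict[int, float] = {}
    fits: dict[int, tuple] = {}
    for k in range(1, k_max + 1):
        best = None
        for _ in range(n_init if k > 1 else 1):
            centers = _kmeanspp_centers(x, k, rng)
            run = _em_once(x, centers, var_floor, tol, max_iter)
            if best is None or run[0] > best[0]:
                best = run
        loglik = best[0]
        bics[k] = -2.0 * loglik + (3 * k - 1) * np.log(n)
        fits[k] = best
        if best_overall is None or bics[k] < bics[best_overall]:
            best_overall = k
    k = best_overall
    loglik, means, variances, weights, converged = fits[k]
    logd = _log_density(x, means, variances, weights)
    return MixtureFit(
        k=k,
        means=means,
        variances=variances,
        weights=weights,
        bic=bics,
        assignments=np.argmax(logd, axis=1),
        converged=bool(converged),
    )


@dataclass
class PolymorphismCall:
    polymorphic: bool | None  # None when uncallable
    status: str  # "ok" or reason
    log_ratio_range: float
    n_used: int
    fit: MixtureFit | None = None


def identify_polymorphic(values, range_threshold: float = 0.7,
                         k_max: int = 4, seed: int = 0,
                         min_individuals: int = 3,
                         n_init: int = 10) -> PolymorphismCall:
    """Apply the combined range > threshold AND >1 mixture cluster rule.

    The mixture is only fitted when the range rule passes (a locus failing
    either rule is monomorphic regardless of the other).  Loci with fewer
    than ``min_individuals`` finite values are reported uncallable.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < min_individuals:
        return PolymorphismCall(None, "uncallable", float("nan"), x.size)
    rng_span = float(x.max() - x.min())
    if rng_span <= range_threshold:
        return PolymorphismCall(False, "ok", rng_span, x.size)
    fit = fit_gmm_1d(x, k_max=k_max, seed=seed, n_init=n_init)
    return PolymorphismCall(fit.k >= 2, "ok", rng_span, x.size, fit)


def call_genotypes(values, lower: float = -0.6, upper: float = -0.1
                   ) -> np.ndarray:
    """Threshold genotype calls from per-individual log ratios.

    Below ``lower``: homozygous uncut; within [lower, upper] (closed):
    heterozygous; above ``upper``: homozygous cut; non-finite: missing.
    Every finite value receives exactly one call.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, MISSING, dtype=object)
    finite = np.isfinite(x)
    out[finite & (x < lower)] = HOM_UNCUT
    out[finite & (x >= lower) & (x <= upper)] = HET
    out[finite & (x > upper)] = HOM_CUT
    return out


@dataclass
class IndelCall:
    is_indel: bool
    status: str
    dosage: np.ndarray | None = None  # deletion count 0/1/2 per individual
    fit: MixtureFit | None = None


def detect_indels(cy5_values, low_cutoff: float = 50.0,
                  high_cutoff: float = 150.0, k_max: int = 3,
                  seed: int = 0, n_init: int = 10) -> IndelCall:
    """Detect a deletion polymorphism from raw Cy5 intensities at a locus.

    The locus is an indel locus iff the BIC-selected mixture has 2 or 3
    clusters with at least one cluster mean below ``low_cutoff`` and at
    least one above ``high_cutoff``.  Per-individual deletion dosage comes
    from cluster membership: clusters ordered by mean map low -> 2 copies
    deleted, intermediate -> 1, high -> 0.
    """
    x = np.asarray(cy5_values, dtype=float)
    finite = np.isfinite(x)
    xs = x[finite]
    if xs.size < 3:
        return IndelCall(False, "uncallable")
    if xs.min() >= low_cutoff or xs.max() <= high_cutoff:
        # no observation on one side of the cutoffs: no cluster mean can
        # fall below/above them, so the locus cannot qualify
        return IndelCall(False, "ok")
    fit = fit_gmm_1d(xs, k_max=k_max, seed=seed, n_init=n_init)
    if fit.k < 2:
        return IndelCall(False, "ok", fit=fit)
    if not (fit.means.min() < low_cutoff and fit.means.max() > high_cutoff):
        return IndelCall(False, "ok", fit=fit)
    if fit.k == 2:
        cluster_dosage = np.array([2, 0])
    else:
        cluster_dosage = np.array([2, 1, 0])
    dosage = np.full(x.shape, -1, dtype=int)
    dosage[finite] = cluster_dosage[fit.assignments]
    return IndelCall(True, "ok", dosage=dosage, fit=fit)


# ---------------------------------------------------------------------------
# matrix-level driver


@dataclass
class CallResult:
    """Per-locus polymorphism/genotype/indel calls for a whole dataset."""
    genotypes: pd.DataFrame           # polymorphic loci x individuals codes
    locus_summary: pd.DataFrame       # all loci: status, range, k, flags
    indel_dosage: pd.DataFrame        # indel loci x individuals (0/1/2)


def call_genotype_matrix(log_ratio: pd.DataFrame,
                         cy5: pd.DataFrame | None = None,
                         mask: pd.Series | None = None,
                         config: CallingConfig | None = None) -> CallResult:
    """Run polymorphism identification, threshold genotyping and indel
    detection over full loci x individuals matrices.

    ``mask`` (poor-binding loci) marks loci to exclude.  Genotypes are
    reported only for loci flagged polymorphic; indel flags are reported
    independently of the SNP flag.
    """
    cfg = config or CallingConfig()
    summary_rows = []
    geno = {}
    indel = {}
    for locus in log_ratio.index:
        if mask is not None and bool(mask.get(locus, False)):
            summary_rows.append((locus, "masked", np.nan, 0, False, False))
            continue
        values = log_ratio.loc[locus].to_numpy(dtype=float)
        res = identify_polymorphic(values, cfg.range_threshold, cfg.k_max,
                                   seed=cfg.seed, n_init=cfg.n_init)
        is_indel = False
        if cy5 is not None:
            ic = detect_indels(cy5.loc[locus].to_numpy(dtype=float),
                               cfg.indel_low_cutoff, cfg.indel_high_cutoff,
                               cfg.indel_k_max, seed=cfg.seed,
                               n_init=cfg.n_init)
            is_indel = ic.is_indel
            if ic.is_indel:
                indel[locus] = ic.dosage
        if res.polymorphic is None:
            summary_rows.append((locus, res.status, res.log_ratio_range,
                                 res.n_used, False, is_indel))
            continue
        summary_rows.append((locus, "ok", res.log_ratio_range, res.n_used,
                             res.polymorphic, is_indel))
        if res.polymorphic:
            geno[locus] = call_genotypes(values, cfg.het_lower, cfg.het_upper)
    locus_summary = pd.DataFrame(
        summary_rows, columns=["locus_id", "status", "log_ratio_range",
                               "n_used", "polymorphic", "indel"]
    ).set_index("locus_id")
    genotypes = pd.DataFrame.from_dict(geno, orient="index",
                                       columns=log_ratio.columns)
    indel_dosage = pd.DataFrame.from_dict(indel, orient="index",
                                          columns=log_ratio.columns)
    return CallResult(genotypes, locus_summary, indel_dosage)


def evaluate_calls(calls: pd.DataFrame, truth: pd.DataFrame
                   ) -> dict[str, object]:
    """Concordance of called genotypes against a truth matrix.

    Both frames hold CC/CU/UU/NA codes; only loci present in ``calls`` and
    entries with non-missing truth enter the denominator (a missing call
    against known truth counts as an error).
    """
    common = calls.index.intersection(truth.index)
    c = calls.loc[common]
    t = truth.loc[common, calls.columns]
    valid = t.to_numpy() != MISSING
    agree = (c.to_numpy() == t.to_numpy()) & valid
    total = int(valid.sum())
    confusion = pd.crosstab(
        pd.Series(t.to_numpy()[valid].ravel(), name="truth"),
        pd.Series(c.to_numpy()[valid].ravel(), name="called"))
    return {
        "concordance": float(agree.sum() / total) if total else float("nan"),
        "n_compared": total,
        "n_errors": int(total - agree.sum()),
        "confusion": confusion,
    }


# ---------------------------------------------------------------------------
# genotype matrix I/O


def write_genotype_matrix(genotypes: pd.DataFrame,
                          populations: pd.Series | Mapping[str, str],
                          path: str | Path,
                          popmap_path: str | Path | None = None) -> None:
    """Write the loci x individuals genotype matrix TSV (cells CC/CU/UU/NA)
    with columns ordered by the population map, plus the map itself."""
    pops = pd.Series(populations)
    order = [ind for ind in pops.index if ind in genotypes.columns]
    genotypes.loc[:, order].to_csv(path, sep="\t", index_label="locus_id")
    if popmap_path is not None:
        pops.rename_axis("individual_id").to_csv(popmap_path, sep="\t",
                                                 header=["population"])


def read_genotype_matrix(path: str | Path,
                         popmap_path: str | Path | None = None
                         ) -> tuple[pd.DataFrame, pd.Series | None]:
    geno = pd.read_csv(path, sep="\t", index_col="locus_id",
                       dtype=str, keep_default_na=False)
    pops = None
    if popmap_path is not None:
        pops = pd.read_csv(popmap_path, sep="\t",
                           index_col="individual_id")["population"]
    return geno, pops


def write_vcf(genotypes: pd.DataFrame, path: str | Path,
              contig: str = "array") -> None:
    """Minimal VCF-style export: the cut (reference-matching) allele is REF,
    the uncut allele is a symbolic ALT; positions are locus ranks."""
    code_to_gt = {HOM_CUT: "0/0", HET: "0/1", HOM_UNCUT: "1/1",
                  MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##ALT=<ID=UNCUT,Description="Recognition-site-disrupting '
                 'allele">\n')
        fh.write("##FORMAT=<ID=GT,Number=1,Type=String,Description="
                 '"Genotype">\n')
        cols = "\t".join(genotypes.columns)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
                 f"\t{cols}\n")
        for pos, (locus, row) in enumerate(genotypes.iterrows(), start=1):
            gts = "\t".join(code_to_gt.get(v, "./.") for v in row)
            fh.write(f"{contig}\t{pos}\t{locus}\tN\t<UNCUT>\t.\tPASS\t.\tGT"
                     f"\t{gts}\n")
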
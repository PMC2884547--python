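"""Population-genetic analyses of the genotype matrix.

Implements allele-frequency-based heterozygosity and per-locus F_ST in
G_ST form, F_ST = (H_T - H_S)/H_T with H_T the expected heterozygosity at
the pooled (equal-weight) mean allele frequency and H_S the mean
within-population expected heterozygosity; Hardy-Weinberg chi-square tests
with Benjamini-Hochberg correction; an allele-permutation test of
panmixia; PCA of individuals from the log-ratio matrix with top-F_ST locus
subsetting; paired-locus F_ST correlation; a permutation-based linkage
screen; and Fisher's combined probability test.

The plug-in G_ST estimator carries an upward sampling bias of order
1/(2n) per population sample; :func:`fst_table` optionally applies the
Nei-Chesser small-sample correction, which is what parameter-recovery
checks against simulations with known F_ST use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .calling import HOM_CUT, HET, HOM_UNCUT, MISSING

_DOSAGE = {HOM_CUT: 0, HET: 1, HOM_UNCUT: 2, MISSING: -1}


def _dosage_matrix(matrix: pd.DataFrame) -> np.ndarray:
    """Genotype codes -> mutant-allele dosage; missing -> -1."""
    codes = matrix.to_numpy(dtype=object)
    out = np.empty(codes.shape, dtype=np.int64)
    for code, d in _DOSAGE.items():
        out[codes == code] = d
    bad = ~np.isin(codes, list(_DOSAGE))
    if bad.any():
        raise ValueError(f"invalid genotype codes: "
                         f"{sorted(set(codes[bad].ravel()))}")
    return out


def _pop_blocks(matrix: pd.DataFrame, populations: pd.Series
                ) -> dict[str, np.ndarray]:
    pops = populations.reindex(matrix.columns)
    if pops.isna().any():
        missing = list(matrix.columns[pops.isna()])
        raise ValueError(f"individuals missing from population map: {missing}")
    return {p: np.flatnonzero((pops == p).to_numpy())
            for p in pd.unique(pops)}


def allele_frequencies(matrix: pd.DataFrame, populations: pd.Series
                       ) -> pd.DataFrame:
    """Per-locus, per-population mutant ("uncut") allele frequency
    p = (2*#UU + #CU) / (2*n_called), with per-locus pairwise deletion of
    missing genotypes.  Returns columns p_<pop> and n_called_<pop>."""
    dos = _dosage_matrix(matrix)
    blocks = _pop_blocks(matrix, populations)
    out = {}
    for pop, cols in blocks.items():
        sub = dos[:, cols]
        called = sub >= 0
        n_called = called.sum(axis=1)
        mutant = np.where(called, sub, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_called > 0, mutant / (2.0 * n_called), np.nan)
        out[f"p_{pop}"] = p
        out[f"n_called_{pop}"] = n_called
    return pd.DataFrame(out, index=matrix.index)


def fst_from_frequencies(p: np.ndarray,
                         n_called: np.ndarray | None = None,
                         corrected: bool = False) -> tuple[float, float, float]:
    """(H_S, H_T, F_ST) from per-population allele frequencies.

    Populations are weighted equally.  With ``corrected=True`` the
    Nei-Chesser small-sample correction is applied (requires per-population
    called sample sizes ``n_called``): within-population heterozygosities
    get the 2n/(2n-1) factor and H_T the +H_S/(2*n_tilde*k) term, removing
    the O(1/2n) bias of the plug-in estimator.
    """
    p = np.asarray(p, dtype=float)
    k = p.size
    h_i = 2.0 * p * (1.0 - p)
    p_bar = p.mean()
    h_s = h_i.mean()
    h_t = 2.0 * p_bar * (1.0 - p_bar)
    if corrected:
        if n_called is None:
            raise ValueError("corrected estimator needs n_called")
        n = np.asarray(n_called, dtype=float)
        if np.any(n < 2):
            return h_s, h_t, np.nan
        n_harm = k / np.sum(1.0 / n)
        h_s = np.mean(2.0 * n / (2.0 * n - 1.0) * h_i)
        h_t = 2.0 * p_bar * (1.0 - p_bar) + h_s / (2.0 * n_harm * k)
    if h_t <= 0:
        return h_s, h_t, np.nan
    return float(h_s), float(h_t), float((h_t - h_s) / h_t)


def fst_locus(p: Sequence[float]) -> float:
    """Plug-in per-locus F_ST = (H_T - H_S)/H_T from population allele
    frequencies (equal weights)."""
    p = np.asarray(p, dtype=float)
    if p.size < 2:
        raise ValueError("F_ST needs at least two populations")
    return fst_from_frequencies(p)[2]


def fst_table(matrix: pd.DataFrame, populations: pd.Series,
              corrected: bool = False,
              min_called_fraction: float = 0.5) -> pd.DataFrame:
    """Per-locus F_ST table: frequencies, H_S, H_T, fst, and a ``usable``
    flag (False when any population has fewer than ``min_called_fraction``
    of its individuals called)."""
    blocks = _pop_blocks(matrix, populations)
    if len(blocks) < 2:
        raise ValueError("F_ST needs at least two populations")
    freqs = allele_frequencies(matrix, populations)
    pops = list(blocks)
    p_cols = [f"p_{p}" for p in pops]
    n_cols = [f"n_called_{p}" for p in pops]
    p_mat = freqs[p_cols].to_numpy()
    n_mat = freqs[n_cols].to_numpy()
    pop_sizes = np.array([len(blocks[p]) for p in pops], dtype=float)
    usable = np.all(n_mat >= min_called_fraction * pop_sizes, axis=1) & \
        ~np.isnan(p_mat).any(axis=1)
    h_s = np.full(len(freqs), np.nan)
    h_t = np.full(len(freqs), np.nan)
    fst = np.full(len(freqs), np.nan)
    for i in np.flatnonzero(usable):
        h_s[i], h_t[i], fst[i] = fst_from_frequencies(
            p_mat[i], n_mat[i], corrected=corrected)
    out = freqs.copy()
    out["H_S"] = h_s
    out["H_T"] = h_t
    out["fst"] = fst
    out["usable"] = usable
    return out


def mean_fst(table: pd.DataFrame, weighted: bool = False) -> float:
    """Genome-wide mean F_ST: simple mean over usable loci (default) or the
    H_T-weighted ratio-of-sums multilocus estimator."""
    sub = table[table["usable"] & table["fst"].notna()]
    if weighted:
        return float((sub["H_T"] - sub["H_S"]).sum() / sub["H_T"].sum())
    return float(sub["fst"].mean())


def individual_heterozygosity(matrix: pd.DataFrame, populations: pd.Series
                              ) -> tuple[pd.Series, dict[str, float]]:
    """Observed per-individual heterozygosity (fraction of HET calls over
    non-missing loci) and a two-sample KS comparison between the first two
    populations."""
    dos = _dosage_matrix(matrix)
    called = dos >= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(called.sum(0) > 0,
                       (dos == 1).sum(0) / called.sum(0), np.nan)
    het_s = pd.Series(het, index=matrix.columns, name="heterozygosity")
    blocks = _pop_blocks(matrix, populations)
    ks: dict[str, float] = {}
    if len(blocks) >= 2:
        (pa, ca), (pb, cb) = list(blocks.items())[:2]
        a = het_s.iloc[ca].dropna()
        b = het_s.iloc[cb].dropna()
        res = stats.ks_2samp(a, b)
        ks = {"pop_a": pa, "pop_b": pb, "mean_a": float(a.mean()),
              "mean_b": float(b.mean()), "statistic": float(res.statistic),
              "pvalue": float(res.pvalue)}
    return het_s, ks


def hwe_test(matrix: pd.DataFrame, populations: pd.Series) -> pd.DataFrame:
    """Per-locus, per-population Hardy-Weinberg chi-square test (1 df).

    Expected genotype counts come from the sample allele frequency;
    Benjamini-Hochberg adjustment is applied over all tests.  Tests where
    the smallest expected count is below 1 are flagged low-power.
    """
    dos = _dosage_matrix(matrix)
    blocks = _pop_blocks(matrix, populations)
    rows = []
    for pop, cols in blocks.items():
        sub = dos[:, cols]
        for i, locus in enumerate(matrix.index):
            g = sub[i]
            g = g[g >= 0]
            n = g.size
            if n == 0:
                continue
            counts = np.array([(g == 0).sum(), (g == 1).sum(),
                               (g == 2).sum()], dtype=float)
            p = (2 * counts[2] + counts[1]) / (2.0 * n)
            if p <= 0 or p >= 1:
                continue  # monomorphic in this population: HWE undefined
            expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
            chi2 = float(((counts - expected) ** 2 / expected).sum())
            pval = float(stats.chi2.sf(chi2, df=1))
            rows.append((locus, pop, n, p, chi2, pval,
                         bool(expected.min() < 1.0)))
    out = pd.DataFrame(rows, columns=["locus_id", "population", "n",
                                      "p_mutant", "chi2", "pvalue",
                                      "low_power"])
    if len(out):
        out["pvalue_bh"] = benjamini_hochberg(out["pvalue"].to_numpy())
    else:
        out["pvalue_bh"] = []
    return out


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    return multipletests(np.asarray(pvalues, dtype=float),
                         method="fdr_bh")[1]


def fishers_combined(pvalues) -> tuple[float, float]:
    """Fisher's combined probability test: X = -2 sum(ln p_i) ~ chi2(2k)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    x = float(-2.0 * np.log(p).sum())
    return x, float(stats.chi2.sf(x, df=2 * p.size))


# ---------------------------------------------------------------------------
# permutation test of panmixia


@dataclass
class PermutationSummary:
    """Observed vs allele-permuted genome-wide F_ST distributions."""
    n_permutations: int
    observed_mean: float
    observed_median: float
    observed_sd: float
    permuted_means: np.ndarray
    permuted_medians: np.ndarray
    permuted_sds: np.ndarray
    rank_of_observed_mean: float       # fraction of permuted means < observed
    fraction_narrower: float           # permuted sds < observed sd
    ks_statistic: float                # observed vs mean-permuted per-locus
    ks_pvalue: float
    tail_cutoffs: tuple[float, ...]
    observed_tail_counts: dict[float, int]
    permuted_tail_counts: dict[float, np.ndarray]

    @property
    def pvalue_mean(self) -> float:
        """One-sided p-value for the observed mean under panmixia."""
        return 1.0 - self.rank_of_observed_mean


def permute_panmixia(matrix: pd.DataFrame, populations: pd.Series,
                     n_permutations: int = 10000, seed: int = 0,
                     tail_cutoffs: Sequence[float] = (0.2,),
                     unit: str = "allele") -> PermutationSummary:
    """Permutation test of panmixia on the genome-wide F_ST distribution.

    Per locus and permutation, the 2n called allele copies are shuffled
    across all individuals and dealt back into the populations (respecting
    each population's called sample size), and the plug-in F_ST is
    recomputed.  Shuffling allele copies without replacement is realized by
    drawing the pop-1 mutant-allele count from the matching hypergeometric
    distribution, which is exact and vectorizes over permutations.
    ``unit="individual"`` instead permutes whole individuals (genotypes)
    across populations, as a sensitivity analysis.
    """
    if unit not in ("allele", "individual"):
        raise ValueError("unit must be 'allele' or 'individual'")
    rng = np.random.default_rng(seed)
    dos = _dosage_matrix(matrix)
    blocks = _pop_blocks(matrix, populations)
    if len(blocks) != 2:
        raise ValueError("permutation test implemented for two populations")
    (pa, ca), (pb, cb) = blocks.items()

    obs_fst = []
    perm_fst = np.full((len(matrix.index), n_permutations), np.nan)
    for i in range(dos.shape[0]):
        ga, gb = dos[i, ca], dos[i, cb]
        ga, gb = ga[ga >= 0], gb[gb >= 0]
        na, nb = 2 * ga.size, 2 * gb.size
        if na == 0 or nb == 0:
            obs_fst.append(np.nan)
            continue
        ka, kb = int(ga.sum()), int(gb.sum())
        p = np.array([ka / na, kb / nb])
        obs_fst.append(fst_from_frequencies(p)[2])
        total = ka + kb
        if unit == "allele":
            ka_perm = rng.hypergeometric(total, na + nb - total, na,
                                         size=n_permutations)
            pa_perm = ka_perm / na
            pb_perm = (total - ka_perm) / nb
        else:
            genotypes = np.concatenate([ga, gb])
            ka_perm = np.empty(n_permutations)
            for t in range(n_permutations):
                rng.shuffle(genotypes)
                ka_perm[t] = genotypes[:ga.size].sum()
            pa_perm = ka_perm / na
            pb_perm = (total - ka_perm) / nb
        pbar = (pa_perm + pb_perm) / 2.0
        h_t = 2.0 * pbar * (1.0 - pbar)
        h_s = pa_perm * (1.0 - pa_perm) + pb_perm * (1.0 - pb_perm)
        with np.errstate(invalid="ignore", divide="ignore"):
            perm_fst[i] = np.where(h_t > 0, (h_t - h_s) / h_t, np.nan)

    obs = np.asarray(obs_fst, dtype=float)
    ok = ~np.isnan(obs)
    obs = obs[ok]
    perm = perm_fst[ok]
    with np.errstate(invalid="ignore"):
        perm_means = np.nanmean(perm, axis=0)
        perm_medians = np.nanmedian(perm, axis=0)
        perm_sds = np.nanstd(perm, axis=0, ddof=1)
    observed_mean = float(obs.mean())
    less = float(np.mean(perm_means < observed_mean))
    ties = float(np.mean(perm_means == observed_mean))
    mean_permuted_locus = np.nanmean(perm, axis=1)
    ks = stats.ks_2samp(obs, mean_permuted_locus)
    cutoffs = tuple(tail_cutoffs)
    return PermutationSummary(
        n_permutations=n_permutations,
        observed_mean=observed_mean,
        observed_median=float(np.median(obs)),
        observed_sd=float(obs.std(ddof=1)),
        permuted_means=perm_means,
        permuted_medians=perm_medians,
        permuted_sds=perm_sds,
        rank_of_observed_mean=less + 0.5 * ties,
        fraction_narrower=float(np.mean(perm_sds < obs.std(ddof=1))),
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        tail_cutoffs=cutoffs,
        observed_tail_counts={c: int((obs > c).sum()) for c in cutoffs},
        permuted_tail_counts={c: (perm > c).sum(axis=0) for c in cutoffs},
    )


# ---------------------------------------------------------------------------
# PCA and F_ST-based locus subsets


def top_fst_subset(fst: pd.Series, n_sd: float = 2.0
                   ) -> tuple[pd.Index, float]:
    """Loci strictly above mean + n_sd * sd of the genome-wide F_ST
    distribution, with the threshold used."""
    vals = fst.dropna()
    threshold = float(vals.mean() + n_sd * vals.std(ddof=1))
    return vals.index[vals > threshold], threshold


def pca_individuals(log_ratio: pd.DataFrame,
                    loci: Iterable[str] | None = None,
                    n_components: int = 3) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of individuals from the per-locus log-ratio matrix.

    Rows of ``log_ratio`` are loci, columns individuals; loci are centered
    and individuals projected onto the leading principal components.
    Deterministic up to component sign (full SVD).  Loci with missing
    values are dropped.
    """
    mat = log_ratio if loci is None else log_ratio.loc[list(loci)]
    mat = mat.dropna(axis=0)
    if mat.empty:
        raise ValueError("no complete loci for PCA")
    x = mat.to_numpy(dtype=float).T  # individuals x loci
    n_components = min(n_components, min(x.shape) - 1) or 1
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x - x.mean(axis=0))
    out = pd.DataFrame(coords, index=mat.columns,
                       columns=[f"PC{i + 1}" for i in range(n_components)])
    return out, pca.explained_variance_ratio_


def paired_fst_correlation(pairs: pd.DataFrame,
                           n_permutations: int = 10000,
                           seed: int = 0) -> dict[str, float]:
    """Pearson correlation between the F_ST values of paired loci (e.g. a
    coding locus and the upstream locus of the same gene), with a
    pair-label permutation p-value.

    ``pairs`` needs columns ``fst_a`` and ``fst_b``; an optional ``gene``
    column deduplicates genes appearing more than once (first pair kept).
    """
    df = pairs.dropna(subset=["fst_a", "fst_b"])
    if "gene" in df.columns:
        df = df.drop_duplicates(subset="gene")
    a = df["fst_a"].to_numpy(dtype=float)
    b = df["fst_b"].to_numpy(dtype=float)
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    r = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    bb = b.copy()
    for _ in range(n_permutations):
        rng.shuffle(bb)
        if abs(np.corrcoef(a, bb)[0, 1]) >= abs(r):
            count += 1
    return {"r": r, "n_pairs": int(a.size),
            "pvalue": (count + 1) / (n_permutations + 1)}


def ld_screen(matrix: pd.DataFrame, loci: Sequence[str],
              n_permutations: int = 1000, seed: int = 0,
              min_joint: int = 5) -> pd.DataFrame:
    """Pairwise genotypic-association screen among ``loci``.

    For each locus pair, the chi-square statistic of the 3x3 genotype
    contingency table is compared against its permutation null (genotype
    labels of one locus shuffled among jointly called individuals); BH
    adjustment over all tested pairs.  Pairs with fewer than ``min_joint``
    jointly called individuals are skipped.  This is a permutation
    contingency test, not an exact haplotypic linkage test.
    """
    rng = np.random.default_rng(seed)
    dos = _dosage_matrix(matrix.loc[list(loci)])
    rows = []
    for i in range(len(loci)):
        for j in range(i + 1, len(loci)):
            a, b = dos[i], dos[j]
            joint = (a >= 0) & (b >= 0)
            if joint.sum() < min_joint:
                rows.append((loci[i], loci[j], int(joint.sum()),
                             np.nan, np.nan, True))
                continue
            aa, bb = a[joint], b[joint]
            obs = _chi2_stat(aa, bb)
            perm = bb.copy()
            count = 0
            for _ in range(n_permutations):
                rng.shuffle(perm)
                if _chi2_stat(aa, perm) >= obs:
                    count += 1
            rows.append((loci[i], loci[j], int(joint.sum()), obs,
                         (count + 1) / (n_permutations + 1), False))
    out = pd.DataFrame(rows, columns=["locus_a", "locus_b", "n_joint",
                                      "chi2", "pvalue", "skipped"])
    tested = ~out["skipped"]
    out["pvalue_bh"] = np.nan
    if tested.any():
        out.loc[tested, "pvalue_bh"] = benjamini_hochberg(
            out.loc[tested, "pvalue"].to_numpy())
    return out


def _chi2_stat(a: np.ndarray, b: np.ndarray) -> float:
    """Chi-square statistic of the genotype contingency table (no p-value;
    the permutation supplies the null)."""
    table = np.zeros((3, 3))
    np.add.at(table, (a, b), 1.0)
    rows = table.sum(1, keepdims=True)
    cols = table.sum(0, keepdims=True)
    expected = rows @ cols / table.sum()
    mask = expected > 0
    return float(((table - expected)[mask] ** 2 / expected[mask]).sum())
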
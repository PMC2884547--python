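"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from rsta import calling, hybsim, tiles
from rsta.signal import build_signal_matrices


# ---------------------------------------------------------------------------
# brute-force oracles (kept independent of the implementation paths they
# check: plain python / numpy sliding windows, no shared helpers)


def brute_force_hits(query: str, genome: dict[str, str],
                     identity_threshold: float = 0.90) -> set[tuple]:
    """Ungapped alignment of ``query`` against every genome position on
    both strands; returns {(record, start, strand)} with identity above
    threshold."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    rc = "".join(comp[c] for c in reversed(query))
    L = len(query)
    hits = set()
    for rec, seq in genome.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for strand, q in (("+", query), ("-", rc)):
            qa = np.frombuffer(q.encode(), dtype=np.uint8)
            if len(arr) < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(arr, L)
            ident = (windows == qa).sum(axis=1) / L
            for start in np.flatnonzero(ident > identity_threshold):
                hits.add((rec, int(start), strand))
    return hits


def brute_force_allele_freq(column_codes: list[str]) -> float:
    """Mutant allele frequency by explicit genotype counting."""
    n = uu = cu = 0
    for c in column_codes:
        if c == "NA":
            continue
        n += 1
        uu += c == "UU"
        cu += c == "CU"
    return (2 * uu + cu) / (2 * n)


def brute_force_fst(p_list: list[float]) -> float:
    h = [2 * p * (1 - p) for p in p_list]
    h_s = sum(h) / len(h)
    p_bar = sum(p_list) / len(p_list)
    h_t = 2 * p_bar * (1 - p_bar)
    return (h_t - h_s) / h_t if h_t > 0 else float("nan")


def brute_force_bh(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up by hand."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvalues[i] * m / rank_from_top)
        adj[i] = running
    return adj


def brute_force_fisher(pvalues: list[float]) -> tuple[float, float]:
    """Fisher's combined test with the closed-form chi-square survival
    function for even degrees of freedom."""
    x = -2.0 * sum(math.log(p) for p in pvalues)
    k = len(pvalues)  # df = 2k, even
    term = 1.0
    total = 1.0
    for i in range(1, k):
        term *= (x / 2.0) / i
        total += term
    return x, math.exp(-x / 2.0) * total


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def genome20k() -> dict[str, str]:
    return tiles.random_genome(20_000, seed=101)


@pytest.fixture(scope="session")
def sim_default() -> dict:
    """A 300-locus, 20-individual simulation at default (calibrated noise)
    conditions, with signal matrices and calls.  Session-scoped: several
    modules assert different properties of the same dataset."""
    spec = hybsim.PopulationSpec(n_loci=300, seed=11)
    ds = hybsim.simulate_dataset(spec)
    mats = build_signal_matrices(ds.scans, ds.tiles)
    result = calling.call_genotype_matrix(mats.log_ratio, mats.cy5)
    return {"spec": spec, "ds": ds, "truth": ds.truth, "mats": mats,
            "result": result}


@pytest.fixture(scope="session")
def sim_zero_noise() -> dict:
    spec = hybsim.PopulationSpec(n_loci=150, seed=23)
    ds = hybsim.simulate_dataset(spec, model=hybsim.HybModel(noise_cv=0.0))
    mats = build_signal_matrices(ds.scans, ds.tiles)
    result = calling.call_genotype_matrix(mats.log_ratio, mats.cy5)
    return {"spec": spec, "ds": ds, "truth": ds.truth, "mats": mats,
            "result": result}


@pytest.fixture(scope="session")
def genotype_matrix_small() -> tuple[pd.DataFrame, pd.Series]:
    """A random 40 x 20 genotype matrix with ~5% missing calls."""
    rng = np.random.default_rng(7)
    codes = np.array(["CC", "CU", "UU"])
    mat = codes[rng.integers(0, 3, size=(40, 20))].astype(object)
    mask = rng.random(mat.shape) < 0.05
    mat[mask] = "NA"
    inds = [f"pop{1 + (j >= 10)}_ind{j % 10 + 1:02d}" for j in range(20)]
    geno = pd.DataFrame(mat, index=[f"L{i:03d}" for i in range(40)],
                        columns=inds)
    pops = pd.Series([f"pop{1 + (j >= 10)}" for j in range(20)], index=inds)
    return geno, pops
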
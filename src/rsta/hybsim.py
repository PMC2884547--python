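"""Two-channel hybridization simulator.

Simulates diploid genotypes for a set of populations under a
Balding-Nichols allele-frequency model, then renders each individual's
genotypes into per-tile, per-replicate Cy3 (restriction-digested channel)
and Cy5 (non-digested control channel) intensities.

Signal model, per allele and tile:

* an allele matching the recognition site (``CUT``) is digested, so its
  Cy3 contribution is reduced to a residual ``cut_binding`` fraction of the
  full-match intensity (the sonicated-then-cut fragment halves still
  overlap the 50-mer probe), while its Cy5 contribution is full;
* an allele with a point mutation in the 4-bp site (``SNP``) escapes
  digestion but hybridizes with a single-mismatch penalty in both channels;
* a deleted allele (``DEL``) contributes ``deletion_efficiency`` (~0) in
  both channels.

Mismatch penalties follow an exponential decay ``exp(-lambda * m)`` with
``lambda = ln(5)/4``, i.e. an 80% intensity loss at four mismatches.
Each channel receives additive background and multiplicative log-normal
noise (mean 1) independently per replicate.

The default intensity scale (background 30, full-match intensity uniform
in [400, 700]) and array composition (20% non-cut, 2% negative, 0.2%
positive control tiles) are calibrated so that, after channel-sum
normalization, the three genotype clusters of a cut-site locus sit at
about +0.55 (homozygous cut), -0.33 (heterozygous) and -1.0 (homozygous
uncut) log2(Cy5/Cy3) units -- inside the fixed genotype-calling bins --
and so that the absolute Cy5 indel cutoffs (<50 background-like, >150
normal binding) are meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tiles import TileSpec, DEFAULT_TILE_LEN, DEFAULT_MOTIF, NONCUT_MOTIF

LN5_OVER_4 = math.log(5.0) / 4.0

CUT, SNP, DEL = "CUT", "SNP", "DEL"

SCAN_COLUMNS = ["tile_id", "replicate", "cy3", "cy5"]


@dataclass
class PopulationSpec:
    """Design of a simulated study: how many populations and individuals,
    how many cut-site loci, and how polymorphism is distributed.

    ``fst_sim`` is the target F_ST between populations as measured by the
    equal-weight (H_T - H_S)/H_T statistic on the true per-population
    allele frequencies; the Balding-Nichols dispersion is calibrated
    internally so the target is recovered (see
    :func:`balding_nichols_theta`).
    """
    n_populations: int = 2
    n_per_population: int = 10
    n_loci: int = 2000
    fraction_polymorphic: float = 0.24
    fraction_indel: float = 0.03
    fst_sim: float = 0.003
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_polymorphic", "fraction_indel"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.fst_sim < 1.0:
            raise ValueError("fst_sim must be in [0, 1)")
        if self.n_populations < 1 or self.n_per_population < 1:
            raise ValueError("population sizes must be positive")

    @property
    def n_individuals(self) -> int:
        return self.n_populations * self.n_per_population


@dataclass
class HybModel:
    """Hybridization physics parameters (arbitrary fluorescence units)."""
    base_intensity_range: tuple[float, float] = (400.0, 700.0)
    background: float = 30.0
    mismatch_decay: float = LN5_OVER_4
    noise_cv: float = 0.08
    deletion_efficiency: float = 0.0
    cut_binding: float = 0.30
    replicate_count: int = 3
    positive_gain: float = 10.0

    def __post_init__(self) -> None:
        if self.base_intensity_range[0] <= self.background:
            raise ValueError("base intensity must exceed background")
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if self.mismatch_decay <= 0:
            raise ValueError("mismatch_decay must be > 0")


def binding_efficiency(n_mismatches, mismatch_decay: float = LN5_OVER_4):
    """Fraction of full-match binding retained with ``n_mismatches``
    probe/target mismatches: exp(-mismatch_decay * n).  The default decay
    gives exactly 0.20 at four mismatches."""
    n = np.asarray(n_mismatches, dtype=float)
    if np.any(n < 0):
        raise ValueError("n_mismatches must be >= 0")
    out = np.exp(-mismatch_decay * n)
    return float(out) if np.isscalar(n_mismatches) else out


def balding_nichols_theta(fst: float, n_populations: int) -> float:
    """Balding-Nichols dispersion parameter theta such that the expected
    equal-weight G_ST over ``n_populations`` demes equals ``fst``.

    With k demes at dispersion theta, E[H_S] = 2pq(1-theta) and
    E[H_T] = 2pq(1-theta/k), giving G_ST = theta(1-1/k)/(1-theta/k);
    inverting yields theta = k*fst / (k - 1 + fst).
    """
    if n_populations < 2:
        return fst
    return n_populations * fst / (n_populations - 1 + fst)


def draw_allele_frequencies(p_ancestral: float, fst_sim: float,
                            n_populations: int,
                            rng: np.random.Generator,
                            theta: float | None = None) -> np.ndarray:
    """Per-population allele frequencies under the Balding-Nichols model.

    Frequencies are Beta-distributed with mean ``p_ancestral`` and variance
    ``theta * p * (1 - p)``.  By default ``theta`` equals ``fst_sim``
    directly (the textbook parameterization); pass the value from
    :func:`balding_nichols_theta` to target a measured k-deme G_ST instead.
    Fixed loci (p in {0, 1}) and ``fst_sim == 0`` are returned unchanged.
    """
    p = float(p_ancestral)
    if theta is None:
        theta = fst_sim
    if p <= 0.0 or p >= 1.0 or theta == 0.0:
        return np.full(n_populations, p)
    if not 0.0 < p < 1.0:
        raise ValueError("p_ancestral must be in (0, 1)")
    a = p * (1.0 - theta) / theta
    b = (1.0 - p) * (1.0 - theta) / theta
    return rng.beta(a, b, size=n_populations)


@dataclass
class SimulatedTruth:
    """Ground truth of a simulated study.

    ``dosage`` holds the mutant-allele count (0, 1, 2) per locus and
    individual; ``loci`` holds per-locus metadata including the true
    per-population mutant frequencies (``freq_pop1``...); ``populations``
    maps individual id to population label.
    """
    spec: PopulationSpec
    locus_ids: list[str]
    individual_ids: list[str]
    populations: pd.Series  # index: individual_id, value: population label
    dosage: np.ndarray  # (n_loci, n_individuals) int
    mutant_kind: np.ndarray  # (n_loci,) object: SNP / DEL / None
    loci: pd.DataFrame  # per-locus truth table

    def genotype_codes(self) -> pd.DataFrame:
        """Truth as a loci x individuals matrix of CC/CU/UU codes."""
        codes = np.array(["CC", "CU", "UU"])[self.dosage]
        return pd.DataFrame(codes, index=self.locus_ids,
                            columns=self.individual_ids)


def simulate_genotypes(spec: PopulationSpec) -> SimulatedTruth:
    """Draw diploid genotypes by binomial (Hardy-Weinberg) sampling within
    each population from Balding-Nichols per-population frequencies.

    A ``1 - fraction_polymorphic`` subset of loci is monomorphic (all
    reference/CUT); a ``fraction_indel`` subset of the polymorphic loci
    carries a deletion rather than a point mutation as its mutant allele.
    """
    rng = np.random.default_rng(spec.seed)
    n_loci, k, n_per = spec.n_loci, spec.n_populations, spec.n_per_population
    n_ind = spec.n_individuals

    locus_ids = [f"L{i + 1:06d}" for i in range(n_loci)]
    individual_ids = [f"pop{p + 1}_ind{j + 1:02d}"
                      for p in range(k) for j in range(n_per)]
    populations = pd.Series([f"pop{p + 1}" for p in range(k)
                             for _ in range(n_per)],
                            index=individual_ids, name="population")

    n_poly = int(round(spec.fraction_polymorphic * n_loci))
    poly_idx = np.sort(rng.choice(n_loci, size=n_poly, replace=False))
    is_poly = np.zeros(n_loci, dtype=bool)
    is_poly[poly_idx] = True
    n_indel = int(round(spec.fraction_indel * n_poly))
    indel_idx = (np.sort(rng.choice(poly_idx, size=n_indel, replace=False))
                 if n_indel else np.array([], dtype=int))

    mutant_kind = np.full(n_loci, None, dtype=object)
    mutant_kind[is_poly] = SNP
    mutant_kind[indel_idx] = DEL

    lo, hi = spec.ancestral_freq_range
    p_anc = np.zeros(n_loci)
    p_anc[is_poly] = rng.uniform(lo, hi, size=n_poly)

    theta = balding_nichols_theta(spec.fst_sim, k)
    freqs = np.zeros((n_loci, k))
    for i in poly_idx:
        freqs[i] = draw_allele_frequencies(p_anc[i], spec.fst_sim, k, rng,
                                           theta=theta)

    dosage = np.zeros((n_loci, n_ind), dtype=np.int64)
    for p in range(k):
        cols = slice(p * n_per, (p + 1) * n_per)
        q = freqs[:, p][:, None]
        dosage[:, cols] = rng.binomial(2, np.broadcast_to(q, (n_loci, n_per)))

    loci = pd.DataFrame({
        "locus_id": locus_ids,
        "polymorphic": is_poly,
        "mutant_kind": mutant_kind,
        "p_ancestral": p_anc,
        **{f"freq_pop{p + 1}": freqs[:, p] for p in range(k)},
    }).set_index("locus_id")
    return SimulatedTruth(spec, locus_ids, individual_ids, populations,
                          dosage, mutant_kind, loci)


# ---------------------------------------------------------------------------
# array composition and rendering

#: default control-tile fractions relative to the cut-site tile count,
#: mirroring the composition of a real cut-site-dominated array; the
#: equal-channel control mass sets the channel-sum normalization offset.
DEFAULT_CONTROL_FRACTIONS = {"noncut": 0.14, "negative": 0.02,
                             "positive": 0.002}


def make_locus_manifest(locus_ids: Sequence[str],
                        n_noncut: int | None = None,
                        n_negative: int | None = None,
                        n_positive: int | None = None,
                        n_degradation_bases: int = 0,
                        max_mutations: int = 10,
                        tile_len: int = DEFAULT_TILE_LEN,
                        seed: int = 0) -> list[TileSpec]:
    """Synthesize an abstract tile manifest for simulated loci.

    One cut-site tile per locus (random flanks around a central TCGA) plus
    control tiles in the default proportions.  Used when simulating
    hybridizations without a concrete genome; tiles designed from a real
    genome with :mod:`rsta.tiles` work identically.
    """
    n = len(locus_ids)
    if n_noncut is None:
        n_noncut = int(round(DEFAULT_CONTROL_FRACTIONS["noncut"] * n))
    if n_negative is None:
        n_negative = int(round(DEFAULT_CONTROL_FRACTIONS["negative"] * n))
    if n_positive is None:
        n_positive = max(2, int(round(DEFAULT_CONTROL_FRACTIONS["positive"] * n)))
    rng = np.random.default_rng(seed)
    flank = (tile_len - 4) // 2

    def _random_tile(motif: str) -> str:
        bases = rng.integers(0, 4, size=tile_len)
        seq = "".join("ACGT"[b] for b in bases)
        return seq[:flank] + motif + seq[flank + 4:]

    tiles = [TileSpec(lid, "simulated", i * tile_len, (i + 1) * tile_len,
                      _random_tile(DEFAULT_MOTIF), "cutsite",
                      genomic_class="intergenic", site_start=i * tile_len + flank)
             for i, lid in enumerate(locus_ids)]
    tiles += [TileSpec(f"NC{i + 1:05d}", "simulated_nc", 0, tile_len,
                       _random_tile(NONCUT_MOTIF), "noncut_control")
              for i in range(n_noncut)]
    tiles += [TileSpec(f"NEG{i + 1:05d}", "synthetic", 0, tile_len,
                       _random_tile("ACGT"), "negative_control")
              for i in range(n_negative)]
    tiles += [TileSpec(f"POS{i + 1:04d}", "multicopy", 0, tile_len,
                       _random_tile("ACGT"), "positive_control")
              for i in range(n_positive)]
    for b in range(n_degradation_bases):
        base_seq = _random_tile(DEFAULT_MOTIF)
        for m in range(max_mutations + 1):
            tiles.append(TileSpec(f"DG{b + 1:04d}_deg{m:02d}", "simulated",
                                  0, tile_len, base_seq, "degradation",
                                  n_mutations=m))
    return tiles


def draw_tile_intensities(tiles: Sequence[TileSpec], model: HybModel,
                          rng: np.random.Generator) -> pd.Series:
    """Per-tile full-match intensity I0, drawn once per array design."""
    lo, hi = model.base_intensity_range
    vals = rng.uniform(lo, hi, size=len(tiles))
    return pd.Series(vals, index=[t.tile_id for t in tiles], name="I0")


def _channel_efficiencies(tiles: Sequence[TileSpec],
                          dosage: Mapping[str, int] | np.ndarray,
                          mutant_kind: Mapping[str, str] | None,
                          model: HybModel, digest: bool
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Per-tile binding efficiency of the digested (cy3) and non-digested
    (cy5) fractions, on the 0..positive_gain scale."""
    eff1 = binding_efficiency(1, model.mismatch_decay)
    e_cut3 = model.cut_binding if digest else 1.0
    eff3 = np.empty(len(tiles))
    eff5 = np.empty(len(tiles))
    for i, t in enumerate(tiles):
        if t.tile_type == "cutsite":
            d = int(dosage[t.tile_id]) if isinstance(dosage, Mapping) \
                else int(dosage[i])
            kind = mutant_kind.get(t.tile_id, SNP) if mutant_kind else SNP
            em3 = em5 = eff1 if kind != DEL else model.deletion_efficiency
            eff3[i] = ((2 - d) * e_cut3 + d * em3) / 2.0
            eff5[i] = ((2 - d) * 1.0 + d * em5) / 2.0
        elif t.tile_type == "noncut_control":
            eff3[i] = eff5[i] = 1.0
        elif t.tile_type == "negative_control":
            eff3[i] = eff5[i] = 0.0
        elif t.tile_type == "positive_control":
            eff3[i] = eff5[i] = model.positive_gain
        else:  # degradation: rendered as undigested single-copy sequence
            e = binding_efficiency(t.n_mutations or 0, model.mismatch_decay)
            eff3[i] = eff5[i] = e
    return eff3, eff5


def simulate_scan(tiles: Sequence[TileSpec],
                  dosage: Mapping[str, int] | np.ndarray,
                  intensities: pd.Series,
                  model: HybModel,
                  rng: np.random.Generator,
                  mutant_kind: Mapping[str, str] | None = None,
                  digest: bool = True) -> pd.DataFrame:
    """Render one individual's genotypes into a replicate-level scan table.

    ``dosage`` gives the mutant-allele count per cut-site tile (by tile_id,
    or positionally aligned with ``tiles``).  ``digest=False`` disables the
    restriction step (every allele treated as uncut), which makes the two
    channels exchangeable -- useful for channel-symmetry checks.
    """
    eff3, eff5 = _channel_efficiencies(tiles, dosage, mutant_kind, model,
                                       digest)
    i0 = intensities.reindex([t.tile_id for t in tiles]).to_numpy()
    clean3 = model.background + i0 * eff3
    clean5 = model.background + i0 * eff5

    reps = model.replicate_count
    if model.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + model.noise_cv ** 2))
        noise = rng.lognormal(-0.5 * sigma ** 2, sigma,
                              size=(2, len(tiles), reps))
    else:
        noise = np.ones((2, len(tiles), reps))
    cy3 = clean3[:, None] * noise[0]
    cy5 = clean5[:, None] * noise[1]

    n = len(tiles)
    return pd.DataFrame({
        "tile_id": np.repeat([t.tile_id for t in tiles], reps),
        "replicate": np.tile(np.arange(1, reps + 1), n),
        "cy3": cy3.ravel(),
        "cy5": cy5.ravel(),
    })


def apply_pmt_normalization(scan: pd.DataFrame) -> pd.DataFrame:
    """Rescale the digested channel by a single scalar so the slide-wide
    channel sums are equal (the in-silico analogue of setting scanner PMT
    gains so the overall slide count ratio equals one).

    Cy5 is left untouched, so absolute Cy5 cutoffs keep their scale; all
    per-tile log ratios shift by one common constant.
    """
    if scan.empty:
        raise ValueError("empty scan")
    s3, s5 = scan["cy3"].sum(), scan["cy5"].sum()
    if s3 <= 0 or s5 <= 0:
        raise ValueError("cannot normalize a scan with an all-zero channel")
    out = scan.copy()
    out["cy3"] = scan["cy3"] * (s5 / s3)
    return out


@dataclass
class SimulatedDataset:
    """A full simulated study: truth, array design, and one raw scan per
    individual."""
    truth: SimulatedTruth
    tiles: list[TileSpec]
    intensities: pd.Series
    scans: dict[str, pd.DataFrame]
    model: HybModel = field(default_factory=HybModel)


def simulate_dataset(spec: PopulationSpec,
                     model: HybModel | None = None,
                     tiles: Sequence[TileSpec] | None = None,
                     n_degradation_bases: int = 0) -> SimulatedDataset:
    """Simulate genotypes and render one raw (un-normalized) scan per
    individual.  Seeds for the manifest, tile intensities and per-individual
    noise all derive from ``spec.seed``."""
    if model is None:
        model = HybModel()
    truth = simulate_genotypes(spec)
    root = np.random.SeedSequence(spec.seed)
    manifest_seed, intensity_seed, *scan_seeds = root.spawn(
        2 + truth.spec.n_individuals)
    if tiles is None:
        tiles = make_locus_manifest(
            truth.locus_ids, n_degradation_bases=n_degradation_bases,
            seed=manifest_seed.generate_state(1)[0] % (2 ** 31))
    tiles = list(tiles)
    cutsite_ids = [t.tile_id for t in tiles if t.tile_type == "cutsite"]
    if len(cutsite_ids) != spec.n_loci:
        raise ValueError(f"manifest has {len(cutsite_ids)} cut-site tiles "
                         f"but the design asks for {spec.n_loci} loci")
    if cutsite_ids != truth.locus_ids:
        # simulate against an externally designed manifest: loci take the
        # manifest's cut-site tile ids (in manifest order)
        mapping = dict(zip(truth.locus_ids, cutsite_ids))
        truth.locus_ids = cutsite_ids
        truth.loci.index = pd.Index(cutsite_ids, name="locus_id")
    intensities = draw_tile_intensities(
        tiles, model, np.random.default_rng(intensity_seed))
    kind_map = {lid: k for lid, k in zip(truth.locus_ids, truth.mutant_kind)
                if k is not None}
    scans = {}
    for j, ind in enumerate(truth.individual_ids):
        dosage = dict(zip(truth.locus_ids, truth.dosage[:, j]))
        scans[ind] = simulate_scan(tiles, dosage, intensities, model,
                                   np.random.default_rng(scan_seeds[j]),
                                   mutant_kind=kind_map)
    return SimulatedDataset(truth, tiles, intensities, scans, model)


# ---------------------------------------------------------------------------
# scan I/O


def write_scan(scan: pd.DataFrame, path: str | Path) -> None:
    scan.loc[:, SCAN_COLUMNS].to_csv(path, sep="\t", index=False)


def read_scan(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SCAN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"scan file missing columns: {missing}")
    return df.loc[:, SCAN_COLUMNS]


def write_truth(truth: SimulatedTruth, genotypes_path: str | Path,
                frequencies_path: str | Path,
                popmap_path: str | Path | None = None) -> None:
    """Write the simulation truth (genotype codes, per-locus frequency
    table, and optionally the population map) as TSVs."""
    truth.genotype_codes().to_csv(genotypes_path, sep="\t",
                                  index_label="locus_id")
    truth.loci.to_csv(frequencies_path, sep="\t")
    if popmap_path is not None:
        truth.populations.rename_axis("individual_id").to_csv(
            popmap_path, sep="\t", header=["population"])
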
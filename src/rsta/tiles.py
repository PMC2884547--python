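"""Restriction-site-centered array tile design.

Scans a genome for restriction recognition sites (TaqalphaI, TCGA, by
default), builds 50-bp tiles centered on each site, classifies tiles by
genomic context (coding / upstream / intergenic), screens tiles for
uniqueness against the whole genome, and generates the four control tile
classes (non-cut, negative, positive, degradation series).

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DEFAULT_MOTIF = "TCGA"
NONCUT_MOTIF = "TTGA"
DEFAULT_TILE_LEN = 50

TILE_TYPES = ("cutsite", "noncut_control", "negative_control",
              "positive_control", "degradation")
GENOMIC_CLASSES = ("coding", "upstream", "intergenic", "not_applicable")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

MANIFEST_COLUMNS = ["tile_id", "record_id", "start", "end", "tile_type",
                    "genomic_class", "site_start", "n_mutations", "sequence"]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AnnotationRegion:
    """A gene or exon interval on a genome record (0-based, half-open)."""
    record_id: str
    start: int
    end: int
    kind: str  # "gene" or "exon"
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.kind not in ("gene", "exon"):
            raise ValueError(f"unknown annotation kind {self.kind!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class TileSpec:
    """One array probe: a 50-bp window of genome sequence (or a synthetic
    control sequence) together with its provenance."""
    tile_id: str
    record_id: str
    start: int
    end: int
    sequence: str
    tile_type: str
    genomic_class: str = "not_applicable"
    site_start: int | None = None
    n_mutations: int | None = None

    def __post_init__(self) -> None:
        if self.tile_type not in TILE_TYPES:
            raise ValueError(f"unknown tile_type {self.tile_type!r}")
        if self.genomic_class not in GENOMIC_CLASSES:
            raise ValueError(f"unknown genomic_class {self.genomic_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# genome / annotation I/O


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-record) FASTA into {record_id: uppercase sequence}."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate FASTA record id {rec.id!r}")
        genome[rec.id] = str(rec.seq).upper()
    return genome


def write_fasta(sequences: Mapping[str, str] | Iterable[tuple[str, str]],
                path: str | Path) -> None:
    items = sequences.items() if isinstance(sequences, Mapping) else sequences
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in items]
    SeqIO.write(records, str(path), "fasta")


def read_annotation(path: str | Path) -> list[AnnotationRegion]:
    """Read gene/exon intervals from GFF3 (``gene``/``exon`` features) or
    6-column BED (the name column carries the kind, default ``gene``)."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_gff3(path)
    return _read_bed(path)


def _read_gff3(path: Path) -> list[AnnotationRegion]:
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                continue
            record_id, _src, kind, start, end, _score, strand = parts[:7]
            kind = kind.lower()
            if kind not in ("gene", "exon"):
                continue
            # GFF3 is 1-based inclusive
            regions.append(AnnotationRegion(record_id, int(start) - 1,
                                            int(end), kind,
                                            strand if strand in "+-" else "+"))
    return regions


def _read_bed(path: Path) -> list[AnnotationRegion]:
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            record_id, start, end = parts[0], int(parts[1]), int(parts[2])
            kind = parts[3].lower() if len(parts) > 3 and parts[3] else "gene"
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "+"
            if kind not in ("gene", "exon"):
                kind = "gene"
            regions.append(AnnotationRegion(record_id, start, end, kind, strand))
    return regions


# ---------------------------------------------------------------------------
# site scanning and tile construction


def scan_recognition_sites(sequence: str, motif: str = DEFAULT_MOTIF,
                           both_strands: bool = False) -> list[int]:
    """Return sorted 0-based start positions of every occurrence of ``motif``.

    Overlapping occurrences are all reported.  Windows containing ``N`` never
    match (exact string comparison).  For a non-palindromic motif pass
    ``both_strands=True`` to also scan the reverse-complement strand; the
    returned positions are deduplicated forward-strand coordinates.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    motifs = {motif.upper()}
    if both_strands:
        motifs.add(reverse_complement(motif.upper()))
    sequence = sequence.upper()
    positions: set[int] = set()
    for m in motifs:
        start = sequence.find(m)
        while start != -1:
            positions.add(start)
            start = sequence.find(m, start + 1)
    return sorted(positions)


def scan_genome(genome: Mapping[str, str], motif: str = DEFAULT_MOTIF,
                both_strands: bool = False) -> dict[str, list[int]]:
    return {rec: scan_recognition_sites(seq, motif, both_strands)
            for rec, seq in genome.items()}


def expected_site_spacing(motif: str = DEFAULT_MOTIF) -> int:
    """Expected spacing (bp) between motif occurrences on i.i.d.
    equal-frequency sequence: 4**len(motif)."""
    if not motif:
        raise ValueError("motif must be non-empty")
    return 4 ** len(motif)


def projected_tile_count(total_bp: float, motif: str = DEFAULT_MOTIF) -> float:
    """Expected number of cut-site tiles obtainable from ``total_bp`` of
    sequence with equal nucleotide frequencies."""
    return total_bp / expected_site_spacing(motif)


def design_cut_site_tiles(genome: Mapping[str, str],
                          sites: Mapping[str, Sequence[int]],
                          tile_len: int = DEFAULT_TILE_LEN,
                          motif_len: int = 4,
                          tile_type: str = "cutsite",
                          id_prefix: str = "T") -> list[TileSpec]:
    """Center a ``tile_len``-bp tile on each recognition site.

    Sites too close to a record edge are skipped.  Sites whose tiles would
    overlap are dropped symmetrically (both members of an overlapping pair),
    so that no two retained tiles share a genome base.  Tiles containing N
    are skipped.  Output is sorted by (record, start).
    """
    if tile_len <= motif_len:
        raise ValueError("tile_len must exceed the motif length")
    if (tile_len - motif_len) % 2:
        raise ValueError("tile_len - motif length must be even for centering")
    flank = (tile_len - motif_len) // 2

    tiles: list[TileSpec] = []
    counter = 0
    for record_id in sorted(sites):
        seq = genome[record_id]
        positions = sorted(sites[record_id])
        starts = [p - flank for p in positions]
        keep = []
        for i, (p, s) in enumerate(zip(positions, starts)):
            if s < 0 or s + tile_len > len(seq):
                continue  # insufficient flank
            # symmetric drop: overlap with a neighbour's (even hypothetical)
            # tile excludes both members of the pair
            overlaps = (i > 0 and starts[i - 1] + tile_len > s) or \
                       (i + 1 < len(starts) and s + tile_len > starts[i + 1])
            if not overlaps:
                keep.append((p, s))
        for p, s in keep:
            window = seq[s:s + tile_len]
            if "N" in window:
                continue
            counter += 1
            tiles.append(TileSpec(
                tile_id=f"{id_prefix}{counter:06d}",
                record_id=record_id, start=s, end=s + tile_len,
                sequence=window, tile_type=tile_type, site_start=p))
    return tiles


def classify_tiles(tiles: Sequence[TileSpec],
                   annotation: Sequence[AnnotationRegion],
                   upstream_window: int = 1000,
                   motif_len: int = 4) -> list[TileSpec]:
    """Assign a genomic class to each cut-site/non-cut tile.

    The 4-bp recognition site (not the whole tile) is intersected with the
    annotation: ``coding`` if it overlaps any exon, else ``upstream`` if it
    lies within ``upstream_window`` bp 5' of a gene start (strand-aware),
    else ``intergenic``.  Records without annotation yield ``intergenic``.
    """
    exons: dict[str, list[tuple[int, int]]] = defaultdict(list)
    windows: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for region in annotation:
        if region.kind == "exon":
            exons[region.record_id].append((region.start, region.end))
        else:
            if region.strand == "+":
                w = (max(0, region.start - upstream_window), region.start)
            else:
                w = (region.end, region.end + upstream_window)
            if w[0] < w[1]:
                windows[region.record_id].append(w)

    out = []
    for tile in tiles:
        if tile.site_start is None:
            out.append(tile)
            continue
        a, b = tile.site_start, tile.site_start + motif_len
        cls = "intergenic"
        if any(s < b and a < e for s, e in exons.get(tile.record_id, ())):
            cls = "coding"
        elif any(s < b and a < e for s, e in windows.get(tile.record_id, ())):
            cls = "upstream"
        out.append(replace(tile, genomic_class=cls))
    return out


# ---------------------------------------------------------------------------
# uniqueness screening (seed + ungapped extension, replaces BLASTN)


class GenomeIndex:
    """Exact k-mer index of the forward genome strand for seed-and-extend
    ungapped alignment.

    The seed length is derived from the tile length and identity threshold
    so that every window with identity above the threshold is guaranteed to
    share at least one exact seed with the query (pigeonhole over the
    maximum number of mismatches), making the screen equivalent to
    brute-force sliding-window alignment.
    """

    def __init__(self, genome: Mapping[str, str], tile_len: int = DEFAULT_TILE_LEN,
                 identity_threshold: float = 0.90):
        self.genome = {r: s.upper() for r, s in genome.items()}
        self.tile_len = tile_len
        self.identity_threshold = identity_threshold
        max_mismatches = tile_len - math.floor(identity_threshold * tile_len) - 1
        self.seed_len = max(1, tile_len // (max_mismatches + 1))
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        k = self.seed_len
        for rec, seq in self.genome.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if "N" not in kmer:
                    self._index[kmer].append((rec, i))

    def hits(self, query: str, max_hits: int | None = None
             ) -> list[tuple[str, int, str, float]]:
        """All genome locations (record, start, strand, identity) whose
        ungapped alignment with ``query`` exceeds the identity threshold.
        Both strands are searched.  Stops early once ``max_hits`` is reached.
        """
        query = query.upper()
        L = len(query)
        k = self.seed_len
        found: dict[tuple[str, int, str], float] = {}
        for strand, q in (("+", query), ("-", reverse_complement(query))):
            seen: set[tuple[str, int]] = set()
            for j in range(L - k + 1):
                for rec, pos in self._index.get(q[j:j + k], ()):
                    start = pos - j
                    if start < 0 or (rec, start) in seen:
                        continue
                    seen.add((rec, start))
                    seq = self.genome[rec]
                    if start + L > len(seq):
                        continue
                    window = seq[start:start + L]
                    ident = sum(a == b for a, b in zip(q, window)) / L
                    if ident > self.identity_threshold:
                        found[(rec, start, strand)] = ident
                        if max_hits is not None and len(found) >= max_hits:
                            return [(r, s, st, i)
                                    for (r, s, st), i in found.items()]
        return [(r, s, st, i) for (r, s, st), i in found.items()]


def uniqueness_filter(tiles: Sequence[TileSpec], genome: Mapping[str, str],
                      identity_threshold: float = 0.90,
                      index: GenomeIndex | None = None
                      ) -> tuple[list[TileSpec], pd.DataFrame]:
    """Drop tiles matching more than one genome location at > threshold
    identity (both strands, origin included).

    Returns the retained tiles and a per-tile report with hit counts.
    """
    if not tiles:
        return [], pd.DataFrame(columns=["tile_id", "n_hits", "retained"])
    tile_len = tiles[0].length
    if index is None:
        index = GenomeIndex(genome, tile_len, identity_threshold)
    retained, rows = [], []
    for tile in tiles:
        hits = index.hits(tile.sequence, max_hits=2)
        ok = len(hits) == 1
        if ok:
            retained.append(tile)
        rows.append((tile.tile_id, len(hits), ok))
    report = pd.DataFrame(rows, columns=["tile_id", "n_hits", "retained"])
    return retained, report


# ---------------------------------------------------------------------------
# control tiles


def generate_control_tiles(genome: Mapping[str, str],
                           n_noncut: int = 0,
                           n_negative: int = 0,
                           n_positive: int = 0,
                           multicopy_sequence: str | None = None,
                           rng_seed: int = 0,
                           tile_len: int = DEFAULT_TILE_LEN,
                           noncut_motif: str = NONCUT_MOTIF,
                           identity_threshold: float = 0.90,
                           index: GenomeIndex | None = None,
                           exclude: Sequence[TileSpec] = ()) -> list[TileSpec]:
    """Build the three synthesized control classes.

    Non-cut tiles are centered on ``noncut_motif`` occurrences and pass the
    same overlap and uniqueness screens as cut-site tiles (tiles overlapping
    an ``exclude`` tile on the genome are also dropped).  Negative tiles are
    random sequences with zero genome hits above the identity threshold.
    Positive tiles are consecutive windows of ``multicopy_sequence``.
    """
    rng = np.random.default_rng(rng_seed)
    controls: list[TileSpec] = []
    if index is None and (n_noncut or n_negative):
        index = GenomeIndex(genome, tile_len, identity_threshold)

    if n_noncut:
        sites = scan_genome(genome, noncut_motif)
        candidates = design_cut_site_tiles(genome, sites, tile_len,
                                           motif_len=len(noncut_motif),
                                           tile_type="noncut_control",
                                           id_prefix="NC")
        if exclude:
            occupied = defaultdict(list)
            for t in exclude:
                occupied[t.record_id].append((t.start, t.end))
            candidates = [t for t in candidates
                          if not any(s < t.end and t.start < e
                                     for s, e in occupied[t.record_id])]
        candidates, _ = uniqueness_filter(candidates, genome,
                                          identity_threshold, index)
        if len(candidates) < n_noncut:
            raise ValueError(
                f"noncut_control: only {len(candidates)} candidate sites "
                f"available, {n_noncut} requested")
        pick = rng.choice(len(candidates), size=n_noncut, replace=False)
        controls.extend(candidates[i] for i in sorted(pick))

    if n_negative:
        bases = np.frombuffer(b"ACGT", dtype="S1")
        made = 0
        attempts = 0
        while made < n_negative:
            attempts += 1
            if attempts > 50 * n_negative:
                raise ValueError("negative_control: cannot generate enough "
                                 "genome-free random tiles")
            seq = b"".join(rng.choice(bases, size=tile_len)).decode()
            if index.hits(seq, max_hits=1):
                continue
            made += 1
            controls.append(TileSpec(f"NEG{made:05d}", "synthetic", 0,
                                     tile_len, seq, "negative_control"))

    if n_positive:
        if multicopy_sequence is None:
            raise ValueError("positive_control: multicopy_sequence required")
        n_windows = len(multicopy_sequence) // tile_len
        if n_windows < n_positive:
            raise ValueError(
                f"positive_control: multicopy sequence yields {n_windows} "
                f"windows, {n_positive} requested")
        for i in range(n_positive):
            s = i * tile_len
            controls.append(TileSpec(f"POS{i + 1:04d}", "multicopy", s,
                                     s + tile_len,
                                     multicopy_sequence[s:s + tile_len].upper(),
                                     "positive_control"))
    return controls


def generate_degradation_series(base_tiles: Sequence[TileSpec],
                                max_mutations: int = 10,
                                rng_seed: int = 0) -> list[TileSpec]:
    """For each base tile emit the perfect-match tile (0 mutations) plus one
    tile per mutation count 1..max_mutations, mutated positions drawn
    uniformly without replacement and each base changed to a different one.
    """
    if not base_tiles:
        return []
    tile_len = base_tiles[0].length
    if max_mutations > tile_len:
        raise ValueError("max_mutations exceeds the tile length")
    rng = np.random.default_rng(rng_seed)
    alternatives = {b: [c for c in "ACGT" if c != b] for b in "ACGTN"}
    out = []
    for tile in base_tiles:
        for m in range(max_mutations + 1):
            seq = list(tile.sequence)
            if m:
                for pos in rng.choice(tile_len, size=m, replace=False):
                    seq[pos] = alternatives[seq[pos]][rng.integers(3)]
            out.append(TileSpec(
                tile_id=f"{tile.tile_id}_deg{m:02d}",
                record_id=tile.record_id, start=tile.start, end=tile.end,
                sequence="".join(seq), tile_type="degradation",
                n_mutations=m))
    return out


# ---------------------------------------------------------------------------
# manifest I/O


def write_manifest(tiles: Sequence[TileSpec], path: str | Path,
                   fasta_path: str | Path | None = None) -> None:
    """Write the tile manifest TSV (and optionally a companion FASTA)."""
    rows = [{
        "tile_id": t.tile_id, "record_id": t.record_id,
        "start": t.start, "end": t.end, "tile_type": t.tile_type,
        "genomic_class": t.genomic_class,
        "site_start": "" if t.site_start is None else t.site_start,
        "n_mutations": "" if t.n_mutations is None else t.n_mutations,
        "sequence": t.sequence,
    } for t in tiles]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t",
                                                        index=False)
    if fasta_path is not None:
        write_fasta([(t.tile_id, t.sequence) for t in tiles], fasta_path)


def read_manifest(path: str | Path) -> list[TileSpec]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    tiles = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        try:
            tiles.append(TileSpec(
                tile_id=row.tile_id, record_id=row.record_id,
                start=int(row.start), end=int(row.end),
                sequence=row.sequence, tile_type=row.tile_type,
                genomic_class=row.genomic_class or "not_applicable",
                site_start=int(row.site_start) if row.site_start != "" else None,
                n_mutations=(int(row.n_mutations)
                             if row.n_mutations != "" else None)))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed manifest row at line {line_no}: {exc}"
                             ) from exc
    return tiles


def manifest_frame(tiles: Sequence[TileSpec]) -> pd.DataFrame:
    """Tile metadata as a DataFrame indexed by tile_id."""
    df = pd.DataFrame([{
        "tile_id": t.tile_id, "record_id": t.record_id, "start": t.start,
        "end": t.end, "tile_type": t.tile_type,
        "genomic_class": t.genomic_class, "site_start": t.site_start,
        "n_mutations": t.n_mutations} for t in tiles])
    return df.set_index("tile_id")


def random_genome(length: int, seed: int = 0, record_id: str = "chr1",
                  n_records: int = 1) -> dict[str, str]:
    """I.i.d. equal-frequency random genome, for simulations and tests."""
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    if n_records == 1:
        return {record_id: b"".join(rng.choice(bases, size=length)).decode()}
    per = length // n_records
    return {f"{record_id.rstrip('0123456789')}{i + 1}":
            b"".join(rng.choice(bases, size=per)).decode()
            for i in range(n_records)}
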
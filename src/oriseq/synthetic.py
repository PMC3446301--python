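"""Synthetic genomes and sequencing reads with planted replication origins.

The generator emulates the statistical structure of copy-number replication
profiling in HU-arrested fission yeast:

* a genome partitioned into genes and intergenes, with origins placed in
  intergenes and origin-proximal sequence given species-style composition —
  polyA/polyT tracts (the *S. pombe*/*S. octosporus* character) or
  polyG tracts, Sap1-like sites and CTCGCT repeats (the *S. japonicus*
  character);
* S-phase read starts drawn from a copy-number intensity
  ``1 + sum_i h_i exp(-(x-mu_i)^2 / 2 sigma^2)``, optionally multiplied by a
  central Gaussian "notch" that mimics the loss of bubble-shaped replication
  intermediates during library preparation; G2 read starts uniform;
* mononucleosome read starts drawn from a phased-nucleosome intensity that is
  near zero inside nucleosome-free regions (NFRs), with origin NFRs generated
  deeper and broader than non-origin NFRs.

All randomness flows from ``SyntheticSpec.seed`` through named substreams, so
a fixed seed gives byte-identical FASTA/BED output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import BED6_COLUMNS, write_bed, write_fasta

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "make_genome",
    "simulate_replication_reads",
    "simulate_nucleosome_reads",
    "plant_motifs",
    "simulate_dataset",
    "replication_intensity",
    "nucleosome_intensity",
    "SAP1_LIKE_CONSENSUS",
]

BASES = np.frombuffer(b"ACGT", dtype="S1")

# Species-style origin composition constants.  Background AT fractions loosely
# mirror the AT-rich vs GC-rich genome difference; they are fixture parameters,
# not measured genome statistics.
AT_FRACTION = {"polyA_rich": 0.60, "GC_motif": 0.45}
ORIGIN_CORE = 500          # bp either side of the origin center that carries planted sequence
N_POLYA_TRACTS = 6         # planted homopolymer tracts per polyA-mode origin
TRACT_LEN_RANGE = (8, 15)
SAP1_LIKE_CONSENSUS = "TAACGCGGGT"  # synthetic Sap1-like site (GC-rich, asymmetric)
CTCGCT_REPEAT = "CTCGCT" * 2

# NFR generation: origin-proximal NFRs are deeper and broader than others.
# Non-origin NFRs appear at a fraction of all intergenes (promoter NFRs are a
# genome-wide feature, not an origin-matched one).
ORIGIN_NFR_WIDTH = 300
ORIGIN_NFR_DEPTH = 0.95
OTHER_NFR_WIDTH = 200
OTHER_NFR_DEPTH = 0.80
NFR_INTERGENE_FRACTION = 0.25
NFR_TAPER = 50             # bp linear ramp at NFR edges
NUC_PERIOD = 165           # bp nucleosome repeat length of the phased background
NUC_PHASING_AMP = 0.4


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset (the generator's study conditions)."""

    chromosome_lengths: list[int] = field(default_factory=lambda: [3_000_000])
    species_mode: str = "polyA_rich"          # or "GC_motif"
    n_origins: int = 20
    origin_efficiency_range: tuple[float, float] = (0.5, 1.5)  # peak height above baseline
    peak_sigma: float = 2_000.0               # bp; ~10 kb peaks at full width
    notch_depth: float = 0.3                  # 0 disables the central dip
    notch_width: float = 2_000.0              # bp full width of the dip
    s_read_count: int = 2_500_000
    g2_read_count: int = 2_500_000
    nuc_read_count: int = 2_000_000
    read_length: int = 50
    replicated_fraction_n: float | None = None  # None: derive from planted intensity
    gene_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if any(length <= 0 for length in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.species_mode not in AT_FRACTION:
            raise ValueError(f"unknown species_mode {self.species_mode!r}")
        if not 0 <= self.notch_depth < 1:
            raise ValueError("notch_depth must be in [0, 1)")
        if self.replicated_fraction_n is not None and not 0 <= self.replicated_fraction_n <= 1:
            raise ValueError("replicated_fraction_n must be in [0, 1]")
        if not 0 <= self.gene_fraction < 1:
            raise ValueError("gene_fraction must be in [0, 1)")
        if self.peak_sigma <= 0 or self.read_length <= 0:
            raise ValueError("peak_sigma and read_length must be positive")
        lo, hi = self.origin_efficiency_range
        if not 0 < lo <= hi:
            raise ValueError("origin_efficiency_range must be 0 < lo <= hi")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(len(self.chromosome_lengths))]

    def chrom_lengths_dict(self) -> dict[str, int]:
        return dict(zip(self.chrom_names(), self.chromosome_lengths))


@dataclass
class SyntheticTruth:
    """Ground truth recorded while generating a dataset."""

    origin_positions: list[tuple[str, int]] = field(default_factory=list)
    origin_heights: list[float] = field(default_factory=list)
    motif_instances: list[tuple[str, int, int, str]] = field(default_factory=list)
    nfr_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    nfr_is_origin: list[bool] = field(default_factory=list)
    gene_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    replicated_fraction_n: float | None = None

    def validate(self, chrom_lengths: dict[str, int]) -> None:
        for chrom, s, e in self.nfr_intervals + self.gene_intervals:
            if not (0 <= s < e <= chrom_lengths[chrom]):
                raise ValueError(f"interval ({chrom}, {s}, {e}) out of bounds")


def _substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic named substream derived from the one global seed."""
    h = int.from_bytes(label.encode(), "big") % (2**32)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(h,)))


# ---------------------------------------------------------------------------
# genome


def _segment_chromosome(L: int, gene_fraction: float, rng: np.random.Generator):
    """Alternate intergene/gene segments covering [0, L)."""
    mean_intergene = 1650.0
    mean_gene = mean_intergene * gene_fraction / max(1e-9, 1.0 - gene_fraction)
    intergenes, genes = [], []
    pos = 0
    while pos < L:
        ilen = int(rng.integers(800, 2501))
        end = min(pos + ilen, L)
        intergenes.append((pos, end))
        pos = end
        if pos >= L:
            break
        glen = max(200, int(rng.uniform(0.5, 1.5) * mean_gene))
        genes.append((pos, min(pos + glen, L)))
        pos += glen
    return intergenes, genes


def _pick_origin_intergenes(
    intergenes: list[tuple[int, int]],
    L: int,
    n: int,
    min_sep: float,
    edge: float,
) -> list[int]:
    """Choose n intergene centers, evenly spread, pairwise >= min_sep apart."""
    if n == 0:
        return []
    centers = [(s + e) // 2 for s, e in intergenes]
    eligible = [
        c
        for (s, e), c in zip(intergenes, centers)
        if (e - s) >= 2 * ORIGIN_CORE + 100 and edge <= c <= L - edge
    ]
    if n * min_sep > L - 2 * edge or len(eligible) < n:
        raise ValueError(
            f"chromosome too short: cannot place {n} origins separated by "
            f">= {min_sep:.0f} bp in {L} bp with {len(eligible)} eligible intergenes"
        )
    chosen: list[int] = []
    eligible_arr = np.array(eligible)
    for k in range(n):
        target = edge + (k + 0.5) * (L - 2 * edge) / n
        order = np.argsort(np.abs(eligible_arr - target))
        placed = False
        for idx in order:
            c = int(eligible_arr[idx])
            if all(abs(c - prev) >= min_sep for prev in chosen):
                chosen.append(c)
                placed = True
                break
        if not placed:
            raise ValueError(
                f"chromosome too short: no intergene >= {min_sep:.0f} bp from "
                f"previously placed origins near {target:.0f}"
            )
    return sorted(chosen)


def _plant_string(seq: np.ndarray, start: int, s: str) -> None:
    seq[start : start + len(s)] = np.frombuffer(s.encode(), dtype="S1")


def make_genome(spec: SyntheticSpec) -> tuple[dict[str, str], SyntheticTruth]:
    """Generate a genome and its ground truth.

    Origin intergenes receive planted composition: in ``polyA_rich`` mode,
    runs of >= 8 A or T; in ``GC_motif`` mode, polyG/polyC runs, Sap1-like
    sites, and a tandem CTCGCT repeat.  Gene intervals, origin positions and
    heights, planted motif instances, and NFR intervals (origin-proximal ones
    deeper/broader) are recorded in the returned :class:`SyntheticTruth`.
    """
    rng_seq = _substream(spec.seed, "genome")
    rng_place = _substream(spec.seed, "placement")
    at = AT_FRACTION[spec.species_mode]
    base_p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])

    truth = SyntheticTruth()
    genome: dict[str, str] = {}
    names = spec.chrom_names()
    lengths = np.array(spec.chromosome_lengths, dtype=float)
    # origins per chromosome proportional to length (largest remainder)
    quota = lengths / lengths.sum() * spec.n_origins
    counts = np.floor(quota).astype(int)
    rema = quota - counts
    for idx in np.argsort(-rema)[: spec.n_origins - counts.sum()]:
        counts[idx] += 1

    lo, hi = spec.origin_efficiency_range
    min_sep = 4 * spec.peak_sigma
    edge = 3 * spec.peak_sigma
    for name, L, n_c in zip(names, spec.chromosome_lengths, counts):
        seq = rng_seq.choice(BASES, size=L, p=base_p)
        intergenes, genes = _segment_chromosome(L, spec.gene_fraction, rng_place)
        truth.gene_intervals.extend((name, s, e) for s, e in genes)
        origins = _pick_origin_intergenes(intergenes, L, int(n_c), min_sep, edge)
        heights = rng_place.uniform(lo, hi, size=len(origins))
        for mu, h in zip(origins, heights):
            truth.origin_positions.append((name, int(mu)))
            truth.origin_heights.append(float(h))
            _plant_origin_sequence(seq, int(mu), spec.species_mode, rng_seq, truth, name)
        # NFRs: one per origin plus promoter-style NFRs at a fraction of all
        # other intergenes, so origin NFRs are a small minority genome-wide
        for mu in origins:
            s = int(mu) - ORIGIN_NFR_WIDTH // 2
            truth.nfr_intervals.append((name, s, s + ORIGIN_NFR_WIDTH))
            truth.nfr_is_origin.append(True)
        others = [
            (s + e) // 2
            for s, e in intergenes
            if all(abs((s + e) // 2 - mu) > 4000 for mu in origins)
            and OTHER_NFR_WIDTH < (s + e) // 2 < L - OTHER_NFR_WIDTH
        ]
        if others:
            n_other = max(len(origins), int(NFR_INTERGENE_FRACTION * len(others)))
            n_other = min(n_other, len(others))
            picks = rng_place.choice(len(others), size=n_other, replace=False)
            for i in sorted(picks):
                c = others[int(i)]
                s = c - OTHER_NFR_WIDTH // 2
                truth.nfr_intervals.append((name, s, s + OTHER_NFR_WIDTH))
                truth.nfr_is_origin.append(False)
        genome[name] = seq.tobytes().decode()
    truth.validate(spec.chrom_lengths_dict())
    return genome, truth


def _plant_origin_sequence(
    seq: np.ndarray,
    mu: int,
    mode: str,
    rng: np.random.Generator,
    truth: SyntheticTruth,
    chrom: str,
) -> None:
    """Overwrite the origin core with species-style motifs; record instances."""
    core_lo = mu - ORIGIN_CORE

    def random_offsets(n_items: int, widths: list[int]) -> list[int]:
        # non-overlapping offsets inside the core, deterministic under rng
        taken: list[tuple[int, int]] = []
        out = []
        for w in widths:
            for _ in range(200):
                off = int(rng.integers(0, 2 * ORIGIN_CORE - w))
                if all(off + w <= s or off >= e for s, e in taken):
                    taken.append((off, off + w))
                    out.append(off)
                    break
            else:  # pragma: no cover - core is far larger than planted content
                raise RuntimeError("could not place motif in origin core")
        return out

    if mode == "polyA_rich":
        widths = [int(rng.integers(*TRACT_LEN_RANGE)) + 1 for _ in range(N_POLYA_TRACTS)]
        offs = random_offsets(N_POLYA_TRACTS, widths)
        for off, w in zip(offs, widths):
            letter = "A" if rng.random() < 0.5 else "T"
            _plant_string(seq, core_lo + off, letter * w)
            truth.motif_instances.append((chrom, core_lo + off, core_lo + off + w, "polyA"))
    else:
        items = [
            ("polyG", ("G" if rng.random() < 0.5 else "C") * int(rng.integers(9, 14))),
            ("Sap1", SAP1_LIKE_CONSENSUS),
            ("Sap1", SAP1_LIKE_CONSENSUS),
            ("CTCGCTx2", CTCGCT_REPEAT),
        ]
        offs = random_offsets(len(items), [len(s) for _, s in items])
        for off, (mid, s) in zip(offs, items):
            _plant_string(seq, core_lo + off, s)
            truth.motif_instances.append((chrom, core_lo + off, core_lo + off + len(s), mid))


# ---------------------------------------------------------------------------
# read simulation


def replication_intensity(spec: SyntheticSpec, truth: SyntheticTruth, chrom: str) -> np.ndarray:
    """Per-bp S-phase copy-number intensity 1 + sum_i h_i g_i(x), notched."""
    L = spec.chrom_lengths_dict()[chrom]
    lam = np.ones(L)
    sig = spec.peak_sigma
    notch_sig = spec.notch_width / 2.0
    half = int(5 * sig)
    for (c, mu), h in zip(truth.origin_positions, truth.origin_heights):
        if c != chrom:
            continue
        lo, hi = max(0, mu - half), min(L, mu + half + 1)
        x = np.arange(lo, hi) - mu
        peak = h * np.exp(-(x**2) / (2 * sig**2))
        if spec.notch_depth > 0:
            peak *= 1.0 - spec.notch_depth * np.exp(-(x**2) / (2 * notch_sig**2))
        lam[lo:hi] += peak
    return lam


def _sample_reads(
    intensities: dict[str, np.ndarray],
    total: int,
    read_length: int,
    rng: np.random.Generator,
    name_prefix: str,
) -> pd.DataFrame:
    """Sample exactly ``total`` stranded fixed-length reads from per-bp intensities."""
    chroms = list(intensities)
    if total == 0:
        return pd.DataFrame(columns=BED6_COLUMNS)
    weights = np.array([intensities[c].sum() for c in chroms])
    counts = rng.multinomial(total, weights / weights.sum())
    frames = []
    for chrom, n_c in zip(chroms, counts):
        if n_c == 0:
            continue
        lam = intensities[chrom]
        cum = np.cumsum(lam)
        starts = np.searchsorted(cum, rng.random(n_c) * cum[-1], side="right")
        starts = np.minimum(starts, len(lam) - read_length)
        starts = np.maximum(starts, 0)
        starts.sort()
        strands = np.where(rng.random(n_c) < 0.5, "+", "-")
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + read_length,
                    "name": [f"{name_prefix}{i}" for i in range(len(starts))],
                    "score": "0",
                    "strand": strands,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=BED6_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def simulate_replication_reads(
    genome: dict[str, str], truth: SyntheticTruth, spec: SyntheticSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample S-phase and G2 read sets (BED6 DataFrames).

    G2 read starts are uniform; S-phase starts follow the planted copy-number
    intensity.  The realized replicated fraction (mean intensity - 1) is
    stored in ``truth.replicated_fraction_n`` unless the spec pins a value —
    this is the simulator's analogue of the flow-cytometry measurement used
    by the profile formula.
    """
    lengths = spec.chrom_lengths_dict()
    lam_s = {c: replication_intensity(spec, truth, c) for c in lengths}
    total_len = sum(lengths.values())
    realized_n = sum(float(lam.sum()) - len(lam) for lam in lam_s.values()) / total_len
    truth.replicated_fraction_n = (
        spec.replicated_fraction_n if spec.replicated_fraction_n is not None else realized_n
    )
    lam_g2 = {c: np.ones(L) for c, L in lengths.items()}
    s_reads = _sample_reads(lam_s, spec.s_read_count, spec.read_length, _substream(spec.seed, "s-reads"), "S")
    g2_reads = _sample_reads(lam_g2, spec.g2_read_count, spec.read_length, _substream(spec.seed, "g2-reads"), "G")
    return s_reads, g2_reads


def nucleosome_intensity(spec: SyntheticSpec, truth: SyntheticTruth, chrom: str) -> np.ndarray:
    """Phased-nucleosome intensity: oscillatory background, near-zero in NFRs."""
    L = spec.chrom_lengths_dict()[chrom]
    x = np.arange(L)
    lam = 1.0 + NUC_PHASING_AMP * np.cos(2 * np.pi * x / NUC_PERIOD)
    for (c, s, e), is_origin in zip(truth.nfr_intervals, truth.nfr_is_origin):
        if c != chrom:
            continue
        depth = ORIGIN_NFR_DEPTH if is_origin else OTHER_NFR_DEPTH
        lo, hi = max(0, s - NFR_TAPER), min(L, e + NFR_TAPER)
        xs = np.arange(lo, hi)
        ramp_in = np.clip((xs - (s - NFR_TAPER)) / NFR_TAPER, 0, 1)
        ramp_out = np.clip(((e + NFR_TAPER) - xs) / NFR_TAPER, 0, 1)
        lam[lo:hi] *= 1.0 - depth * np.minimum(ramp_in, ramp_out)
    return lam


def simulate_nucleosome_reads(
    genome: dict[str, str], truth: SyntheticTruth, spec: SyntheticSpec
) -> pd.DataFrame:
    """Sample mononucleosome reads from the phased/NFR intensity."""
    lengths = spec.chrom_lengths_dict()
    lam = {c: nucleosome_intensity(spec, truth, c) for c in lengths}
    return _sample_reads(lam, spec.nuc_read_count, spec.read_length, _substream(spec.seed, "nuc-reads"), "N")


# ---------------------------------------------------------------------------
# controlled motif planting


def plant_motifs(
    genome: dict[str, str],
    pwms,
    placements: list[tuple[str, int, str]],
    rng: np.random.Generator | None = None,
    sample: bool = False,
) -> tuple[dict[str, str], list[tuple[str, int, int, str]]]:
    """Overwrite genome positions with PWM sites; return new genome + instances.

    ``placements`` is a list of ``(chrom, start, motif_id)``.  Sites are the
    PWM consensus, or sampled column-wise from the PWM when ``sample`` is True
    (requires ``rng``).  Overlapping placements raise, listing the collisions.
    """
    by_id = {p.motif_id: p for p in pwms}
    widths = {mid: len(by_id[mid].matrix) for mid in by_id}
    spans = []
    for chrom, start, mid in placements:
        if mid not in by_id:
            raise ValueError(f"unknown motif id {mid!r}")
        w = widths[mid]
        if start < 0 or start + w > len(genome[chrom]):
            raise ValueError(f"placement ({chrom}, {start}, {mid}) out of bounds")
        spans.append((chrom, start, start + w, mid))
    collisions = [
        (a, b)
        for i, a in enumerate(spans)
        for b in spans[i + 1 :]
        if a[0] == b[0] and a[1] < b[2] and b[1] < a[2]
    ]
    if collisions:
        raise ValueError(f"overlapping motif placements: {collisions}")
    out = {c: np.frombuffer(s.encode(), dtype="S1").copy() for c, s in genome.items()}
    instances = []
    for chrom, start, end, mid in spans:
        pwm = by_id[mid]
        site = pwm.sample(rng) if sample else pwm.consensus()
        _plant_string(out[chrom], start, site)
        instances.append((chrom, start, end, mid))
    return {c: a.tobytes().decode() for c, a in out.items()}, instances


# ---------------------------------------------------------------------------
# dataset emission


def simulate_dataset(spec: SyntheticSpec, outdir) -> SyntheticTruth:
    """Generate and write a full dataset (FASTA + BED6 files) to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, truth = make_genome(spec)
    s_reads, g2_reads = simulate_replication_reads(genome, truth, spec)
    nuc_reads = simulate_nucleosome_reads(genome, truth, spec)

    write_fasta(outdir / "genome.fa", genome)
    write_bed(outdir / "s_reads.bed", s_reads, seed=spec.seed)
    write_bed(outdir / "g2_reads.bed", g2_reads, seed=spec.seed)
    write_bed(outdir / "nuc_reads.bed", nuc_reads, seed=spec.seed)

    genes = pd.DataFrame(
        [(c, s, e, f"gene{i}", "0", "+") for i, (c, s, e) in enumerate(truth.gene_intervals)],
        columns=BED6_COLUMNS,
    )
    write_bed(outdir / "genes.bed", genes, seed=spec.seed)
    origins = pd.DataFrame(
        [
            (c, p, p + 1, f"ori{i}", f"{h:.4f}", ".")
            for i, ((c, p), h) in enumerate(zip(truth.origin_positions, truth.origin_heights))
        ],
        columns=BED6_COLUMNS,
    )
    write_bed(outdir / "origins_truth.bed", origins, seed=spec.seed)
    nfrs = pd.DataFrame(
        [
            (c, s, e, "origin_nfr" if flag else "nfr", "0", ".")
            for (c, s, e), flag in zip(truth.nfr_intervals, truth.nfr_is_origin)
        ],
        columns=BED6_COLUMNS,
    )
    write_bed(outdir / "nfr_truth.bed", nfrs, seed=spec.seed)
    with open(outdir / "truth.json", "w") as fh:
        import json

        json.dump(
            {
                "replicated_fraction_n": truth.replicated_fraction_n,
                "origin_positions": truth.origin_positions,
                "origin_heights": truth.origin_heights,
                "motif_instances": truth.motif_instances,
            },
            fh,
            indent=1,
        )
    return truth
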
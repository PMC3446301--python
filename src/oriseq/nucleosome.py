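"""Nucleosome occupancy, NFR detection, and origin-proximal depletion testing.

Mononucleosome reads are extended to the nucleosomal fragment length (147 bp)
from their 5' end, binned like the replication data, and normalized so the
genome-wide mean occupancy is exactly 1; figures report the log2 of this
ratio.  Nucleosome-free regions (NFRs) are maximal runs of bins below a
fraction of the genome mean, and origin-proximal depletion is tested with the
empirical permutation: the NFRs nearest the replication peaks are compared to
the NFRs nearest an equal number of random coordinates, repeated ``n_iter``
times, with ``p = n / n_iter`` where ``n`` counts the random draws at least
as depleted as the observed origin-proximal set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .track import BinnedTrack, aggregate_signal

__all__ = [
    "NFR",
    "PermutationResult",
    "occupancy_from_reads",
    "detect_nfrs",
    "nearest_nfr",
    "nfr_depletion_test",
    "motif_occupancy_profile",
]


@dataclass
class NFR:
    chrom: str
    start: int
    end: int
    mean_depth: float

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class PermutationResult:
    observed_depletion: float
    n_more_depleted: int
    n_total: int
    seed: int

    @property
    def p_value(self) -> float:
        return self.n_more_depleted / self.n_total

    @property
    def p_floor_note(self) -> str | None:
        if self.n_more_depleted == 0:
            return f"p reported as 0; permutation floor is < 1/{self.n_total}"
        return None


def occupancy_from_reads(
    nuc_reads: pd.DataFrame,
    chrom_lengths: dict[str, int],
    frag_len: int = 147,
    window: int = 200,
    step: int = 20,
    exclusion_intervals=None,
) -> BinnedTrack:
    """Mean-1 nucleosome occupancy from stranded mononucleosome read starts.

    Each read is extended to ``frag_len`` bp 3'-ward from its 5' end (the
    nucleosomal footprint), coverage is windowed, and unmasked bins are scaled
    to genome mean exactly 1.
    """
    if len(nuc_reads) == 0:
        raise ValueError("no nucleosome reads")
    track = BinnedTrack(chrom_lengths=dict(chrom_lengths), window=window, step=step)
    strand = nuc_reads["strand"].to_numpy()
    start = nuc_reads["start"].to_numpy(dtype=np.int64)
    end = nuc_reads["end"].to_numpy(dtype=np.int64)
    frag_start = np.where(strand == "-", end - frag_len, start)
    frag_end = np.where(strand == "-", end, start + frag_len)
    track.add_intervals(zip(nuc_reads["chrom"], frag_start, frag_end))
    if exclusion_intervals:
        track.mask_intervals(exclusion_intervals)
    mean = track.mean()
    if mean <= 0:
        raise ValueError("cannot normalize an all-zero occupancy track")
    for chrom in track.chroms:
        keep = ~track.mask[chrom]
        track.values[chrom][keep] /= mean
    return track


def detect_nfrs(
    track: BinnedTrack,
    threshold: float = 0.5,
    min_width: int = 125,
    merge_gap: int = 1,
) -> list[NFR]:
    """Maximal sub-threshold runs, merged across short gaps, filtered by width.

    ``threshold`` is a fraction of the (mean-1) occupancy; runs separated by
    at most ``merge_gap`` above-threshold bins merge; intervals narrower than
    ``min_width`` bp are dropped.  Masked bins break runs.
    """
    out: list[NFR] = []
    for chrom in track.chroms:
        v, m = track.values[chrom], track.mask[chrom]
        low = (v < threshold) & ~m
        idx = np.flatnonzero(low)
        if len(idx) == 0:
            continue
        runs: list[list[int]] = [[int(idx[0]), int(idx[0])]]
        for i in idx[1:]:
            if i - runs[-1][1] <= merge_gap + 1:
                runs[-1][1] = int(i)
            else:
                runs.append([int(i), int(i)])
        for i0, i1 in runs:
            start = i0 * track.step
            end = i1 * track.step + track.window
            if end - start >= min_width:
                out.append(
                    NFR(
                        chrom=chrom,
                        start=start,
                        end=end,
                        mean_depth=float(v[i0 : i1 + 1].mean()),
                    )
                )
    return out


def _point_interval_distance(pos: float, nfr: NFR) -> float:
    if nfr.start <= pos < nfr.end:
        return 0.0
    return min(abs(pos - nfr.start), abs(pos - (nfr.end - 1)))


def nearest_nfr(
    positions: list[tuple[str, float]], nfrs: list[NFR]
) -> list[tuple[NFR, float]]:
    """Map each position to the NFR minimizing point-to-interval distance.

    Distance is 0 inside an NFR, otherwise the gap to the nearest end.
    Equidistant NFRs resolve to the leftmost.  Positions on chromosomes with
    no NFR raise, as does an empty NFR list.
    """
    if not nfrs:
        raise ValueError("empty NFR list")
    by_chrom: dict[str, list[NFR]] = {}
    for nfr in nfrs:
        by_chrom.setdefault(nfr.chrom, []).append(nfr)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda n: n.start)
    out = []
    for chrom, pos in positions:
        cands = by_chrom.get(chrom)
        if not cands:
            raise ValueError(f"no NFRs on chromosome {chrom!r}")
        starts = np.array([n.start for n in cands])
        i = int(np.searchsorted(starts, pos))
        best, best_d = None, np.inf
        for j in range(max(0, i - 2), min(len(cands), i + 2)):
            d = _point_interval_distance(pos, cands[j])
            if d < best_d:  # strict: leftmost wins ties
                best, best_d = cands[j], d
        out.append((best, best_d))
    return out


def _nfr_set_depletion(
    track: BinnedTrack, nfrs: list[NFR], stat_halfwidth: int
) -> float:
    """Depletion statistic: mean occupancy within +/- stat_halfwidth bp of the
    centers of the aggregate NFR profile."""
    offsets, mean, _ = aggregate_signal(
        track, [(n.chrom, n.center) for n in nfrs], flank=stat_halfwidth
    )
    vals = mean[np.isfinite(mean)]
    if len(vals) == 0:
        return np.nan
    return float(vals.mean())


def nfr_depletion_test(
    peaks: list[tuple[str, float]],
    track: BinnedTrack,
    nfrs: list[NFR],
    n_iter: int = 10_000,
    seed: int = 0,
    stat_halfwidth: int = 200,
) -> PermutationResult:
    """Are the NFRs nearest the replication peaks unusually depleted?

    Observed statistic: mean occupancy around the centers of the
    origin-proximal NFRs (the NFRs nearest each peak).  Each iteration draws
    an equal number of uniform random genomic coordinates, takes their
    nearest NFRs, and recomputes the statistic; ``p = n / n_iter`` where
    ``n`` counts iterations at least as depleted (null <= observed).
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    if not nfrs:
        raise ValueError("empty NFR list")
    observed = _nfr_set_depletion(
        track, [n for n, _ in nearest_nfr(peaks, nfrs)], stat_halfwidth
    )
    rng = np.random.default_rng(seed)
    chroms = track.chroms
    lengths = np.array([track.chrom_lengths[c] for c in chroms], dtype=float)
    p_chrom = lengths / lengths.sum()
    n_more = 0
    k = len(peaks)
    for _ in range(n_iter):
        counts = rng.multinomial(k, p_chrom)
        coords = [
            (chrom, float(x))
            for chrom, c in zip(chroms, counts)
            for x in rng.uniform(0, track.chrom_lengths[chrom], size=c)
        ]
        null_stat = _nfr_set_depletion(
            track, [n for n, _ in nearest_nfr(coords, nfrs)], stat_halfwidth
        )
        if null_stat <= observed:
            n_more += 1
    return PermutationResult(
        observed_depletion=observed, n_more_depleted=n_more, n_total=n_iter, seed=seed
    )


def motif_occupancy_profile(
    motif_instances: list[tuple[str, int, int, str]],
    track: BinnedTrack,
    flank: int = 1000,
    peaks: list[tuple[str, float]] | None = None,
    proximal_dist: float = 1000.0,
    strands: list[str] | None = None,
):
    """Aggregate log2 occupancy over motif instances, split by peak proximity.

    Returns ``(offsets, log2_profile, split)`` where ``split`` maps
    ``"proximal"``/``"distal"`` to ``(count, log2_profile)`` when peaks are
    supplied.  Instances are centered (strand-oriented when ``strands`` is
    given, for asymmetric motifs); proximal means within ``proximal_dist`` of
    the nearest peak.  An empty instance list raises — a motif absent from
    the genome must be reported, not silently averaged.
    """
    if not motif_instances:
        raise ValueError("no motif instances: motif absent from this genome")
    centers = [(c, (s + e) / 2) for c, s, e, _ in motif_instances]

    def log2_profile(anchors, anchor_strands):
        offsets, mean, _ = aggregate_signal(track, anchors, flank, strands=anchor_strands)
        with np.errstate(divide="ignore"):
            return offsets, np.where(mean > 0, np.log2(np.maximum(mean, 1e-12)), -np.inf)

    offsets, full = log2_profile(centers, strands)
    split = {}
    if peaks is not None:
        peak_by_chrom: dict[str, list[float]] = {}
        for c, p in peaks:
            peak_by_chrom.setdefault(c, []).append(p)
        sorted_peaks = {c: np.sort(np.array(v)) for c, v in peak_by_chrom.items()}
        prox_idx, dist_idx = [], []
        for i, (c, pos) in enumerate(centers):
            arr = sorted_peaks.get(c)
            d = np.inf
            if arr is not None and len(arr):
                j = np.searchsorted(arr, pos)
                for jj in (j - 1, j):
                    if 0 <= jj < len(arr):
                        d = min(d, abs(arr[jj] - pos))
            (prox_idx if d <= proximal_dist else dist_idx).append(i)
        for name, idxs in (("proximal", prox_idx), ("distal", dist_idx)):
            if idxs:
                sub_strands = [strands[i] for i in idxs] if strands else None
                _, prof = log2_profile([centers[i] for i in idxs], sub_strands)
            else:
                prof = None
            split[name] = (len(idxs), prof)
    return offsets, full, split
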
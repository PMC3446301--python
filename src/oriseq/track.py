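"""Fixed-step sliding-window genomic tracks.

A :class:`BinnedTrack` stores one real value per window position for each
chromosome.  Bin ``i`` covers the half-open interval
``[i*step, i*step + window)``; with the default 200-bp window and 20-bp step
adjacent bins overlap, which is what produces the smoothed appearance of
copy-number replication profiles.  A per-bin boolean mask marks excluded
regions (assembly artifacts, repeats); masked bins are ignored by all
statistics but their values are carried along unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BinnedTrack", "aggregate_signal"]


def n_bins(chrom_length: int, window: int, step: int) -> int:
    """Number of complete windows that fit in a chromosome."""
    if chrom_length < window:
        return 0
    return (chrom_length - window) // step + 1


@dataclass
class BinnedTrack:
    """Per-chromosome windowed signal with an exclusion mask.

    Parameters
    ----------
    chrom_lengths
        Mapping chromosome name -> length in bp.
    window, step
        Window size and step in bp; ``window >= step`` so windows tile the
        chromosome without gaps.
    values
        Mapping chromosome -> float array of length
        ``(L - window)//step + 1``.  Auto-initialised to zeros.
    mask
        Mapping chromosome -> bool array, True where the bin is excluded.
    """

    chrom_lengths: dict[str, int]
    window: int = 200
    step: int = 20
    values: dict[str, np.ndarray] = field(default_factory=dict)
    mask: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.window < self.step:
            raise ValueError(f"window ({self.window}) must be >= step ({self.step})")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length")
            nb = n_bins(length, self.window, self.step)
            if chrom not in self.values:
                self.values[chrom] = np.zeros(nb)
            elif len(self.values[chrom]) != nb:
                raise ValueError(
                    f"{chrom}: expected {nb} bins, got {len(self.values[chrom])}"
                )
            if chrom not in self.mask:
                self.mask[chrom] = np.zeros(nb, dtype=bool)
            elif len(self.mask[chrom]) != nb:
                raise ValueError(f"{chrom}: mask length mismatch")

    # -- geometry -----------------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    def bin_start(self, i: int) -> int:
        return i * self.step

    def bin_centers(self, chrom: str) -> np.ndarray:
        """Midpoint (bp, float) of every window on ``chrom``."""
        return np.arange(len(self.values[chrom])) * self.step + self.window / 2

    def pos_to_bin(self, chrom: str, pos: float) -> int:
        """Index of the bin whose center is nearest ``pos``, clipped in range."""
        i = int(round((pos - self.window / 2) / self.step))
        return int(np.clip(i, 0, len(self.values[chrom]) - 1))

    def bins_overlapping(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Inclusive index range [i0, i1] of bins whose window intersects [start, end)."""
        nb = len(self.values[chrom])
        i0 = max(0, (start - self.window) // self.step + 1)
        i1 = min(nb - 1, (end - 1) // self.step)
        return i0, i1

    # -- statistics ---------------------------------------------------------

    def unmasked_values(self, chrom: str | None = None) -> np.ndarray:
        if chrom is not None:
            return self.values[chrom][~self.mask[chrom]]
        parts = [self.values[c][~self.mask[c]] for c in self.chroms]
        return np.concatenate(parts) if parts else np.array([])

    def mean(self) -> float:
        vals = self.unmasked_values()
        if vals.size == 0:
            raise ValueError("track has no unmasked bins")
        return float(vals.mean())

    # -- construction helpers ----------------------------------------------

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(
            chrom_lengths=dict(self.chrom_lengths),
            window=self.window,
            step=self.step,
            values={c: v.copy() for c, v in self.values.items()},
            mask={c: m.copy() for c, m in self.mask.items()},
        )

    def like(self, fill: float = 0.0) -> "BinnedTrack":
        """New track with the same geometry and mask, values set to ``fill``."""
        out = self.copy()
        for c in out.chroms:
            out.values[c][:] = fill
        return out

    def compatible_with(self, other: "BinnedTrack") -> bool:
        if (self.window, self.step) != (other.window, other.step):
            return False
        if self.chrom_lengths != other.chrom_lengths:
            return False
        return all(np.array_equal(self.mask[c], other.mask[c]) for c in self.chroms)

    def add_intervals(self, intervals) -> int:
        """Increment, for every interval, each bin whose window it overlaps.

        ``intervals`` is an iterable of ``(chrom, start, end)``.  Uses a
        difference-array accumulation, so cost is O(reads + bins).  Returns the
        number of intervals clipped at chromosome boundaries.
        """
        per_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in self.chroms}
        clipped = 0
        for chrom, start, end in intervals:
            if chrom not in per_chrom:
                raise ValueError(f"unknown chromosome {chrom!r}")
            L = self.chrom_lengths[chrom]
            if start < 0 or end > L:
                clipped += 1
                start, end = max(start, 0), min(end, L)
            if end > start:
                per_chrom[chrom].append((start, end))
        for chrom, ivs in per_chrom.items():
            if not ivs:
                continue
            nb = len(self.values[chrom])
            starts = np.array([s for s, _ in ivs])
            ends = np.array([e for _, e in ivs])
            i0 = np.maximum(0, (starts - self.window) // self.step + 1)
            i1 = np.minimum(nb - 1, (ends - 1) // self.step)
            keep = i1 >= i0
            diff = np.zeros(nb + 1)
            np.add.at(diff, i0[keep], 1.0)
            np.add.at(diff, i1[keep] + 1, -1.0)
            self.values[chrom] += np.cumsum(diff[:-1])
        return clipped

    def mask_intervals(self, intervals) -> None:
        """Mask every bin whose window overlaps any ``(chrom, start, end)``."""
        for chrom, start, end in intervals:
            if chrom not in self.mask:
                continue
            i0, i1 = self.bins_overlapping(chrom, int(start), int(end))
            if i1 >= i0:
                self.mask[chrom][i0 : i1 + 1] = True


def aggregate_signal(
    track: BinnedTrack,
    anchors,
    flank: int,
    strands=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average a track over anchor-centered windows (a genomic signal aggregator).

    Parameters
    ----------
    track
        Source signal.
    anchors
        Iterable of ``(chrom, position_bp)``.
    flank
        Half-width of the window in bp; the profile covers offsets
        ``-flank .. +flank`` at the track's step.
    strands
        Optional per-anchor strand ('+'/'-'); minus-strand windows are
        reversed so the profile is orientation-aware.

    Returns
    -------
    offsets, mean, n
        ``offsets`` in bp relative to the anchor, the position-wise mean over
        anchors (NaN where no anchor contributed), and the contributing anchor
        count per position.  Windows running off a chromosome end are
        truncated, not dropped; masked bins are excluded from the mean.
    """
    anchors = list(anchors)
    if not anchors:
        raise ValueError("aggregate_signal requires at least one anchor")
    fb = int(round(flank / track.step))
    width = 2 * fb + 1
    total = np.zeros(width)
    count = np.zeros(width)
    strands = list(strands) if strands is not None else [None] * len(anchors)
    for (chrom, pos), strand in zip(anchors, strands):
        v = track.values[chrom]
        m = track.mask[chrom]
        c = track.pos_to_bin(chrom, pos)
        lo, hi = c - fb, c + fb + 1
        src_lo, src_hi = max(lo, 0), min(hi, len(v))
        win = np.full(width, np.nan)
        win[src_lo - lo : src_hi - lo] = np.where(
            m[src_lo:src_hi], np.nan, v[src_lo:src_hi]
        )
        if strand == "-":
            win = win[::-1]
        ok = ~np.isnan(win)
        total[ok] += win[ok]
        count[ok] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    offsets = (np.arange(width) - fb) * track.step
    return offsets, mean, count
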